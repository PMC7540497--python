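# Methods notes

## Scope and model

The package runs a mass-univariate environment-wide association scan: one
covariate-adjusted OLS model per exposure, outcome `y = sqrt(mean SRS item
score)`, a 75/25 discovery/test split fixed before any model fitting, and
Benjamini–Hochberg FDR applied within the discovery stage over all tested
variables and within the test stage over the carried-forward subset only.
Bonferroni-adjusted p-values are reported alongside at both stages. No
joint model over exposures and no summary risk score is fit: the scan's
purpose is per-variable screening under strict error control, and the high
covariance between exposures makes multivariable coefficients
uninterpretable at this breadth.

### Exposure coding

- continuous: raw value; a centered quadratic term is screened in the
  discovery set and, when significant at alpha, kept in that variable's
  model for both stages (decided in discovery only, to avoid test-set
  leakage);
- ordered categorical: consecutive integer scores over the observed
  levels, giving one "lowest to highest" slope;
- unordered categorical: indicators against the most frequent level
  (a deterministic reference), with the joint F-test over the indicator
  block as the per-variable p so every variable contributes exactly one
  p-value to the correction.

Complete-case analysis is per variable: subjects missing the outcome or
that exposure are dropped for that model only. Covariates are imputed
beforehand (below), so the covariate matrix is complete. Confidence
intervals are classical t-distribution intervals; heteroscedasticity-robust
covariance is available via the `cov_type` argument (e.g. `"HC3"`) but is
not the default, because the scan's headline quantities (per-variable
p-values entering FDR) follow the standard linear-model t/F tests.

### Multiplicity

`adjust_pvalues` delegates to `statsmodels.stats.multitest.multipletests`
(`fdr_bh`, with `fdr_by` available behind the config switch) and to a
direct `min(1, m*p)` for Bonferroni. Under a complete null with independent
tests, BH controls the family-wise error rate at exactly alpha (FDR and
FWER coincide when every hypothesis is null), so the single-stage design
has a 5% chance of any false positive over 920 tests and the two-stage
design alpha² = 0.25%. `validation.estimate_fwer` verifies both by
simulation; the simulation kernel uses the closed-form simple-regression
p-value (the correlation t-test), which the test suite asserts is
numerically identical to the scan's covariate-free OLS fit.

## Harmonization

Per-variable, in a fixed order:

1. **Conditional merges.** A skip-logic child question is merged into its
   parent: non-gate parent answers become levels of the combined variable,
   gate-branch answers become `gate:child` levels (optionally renamed).
   Chains are merged deepest-first; cycles are a dictionary error. Merges
   run before "Do not know" recoding so a parent's "Do not know" propagates
   to missing. The merged variable keeps ordered semantics only when the
   parent is binary and the child ordered (the never/past/current pattern);
   otherwise it is unordered.
2. **"Do not know" recoding** to missing, with the label removed from the
   level set.
3. **Category collapsing**, rules applied a→b→c: (a) ordered scales with
   ≥4 levels whose terminal level holds ≥ `lopsided_threshold` (default
   0.50) collapse to terminal / adjacent band (the next ⌊(k−1)/2⌋ levels) /
   remainder; (b) ordered scales with ≥5 levels whose middle level is modal
   with share ≥ `centered_threshold` (default 0.40) collapse to left /
   middle / right; (c) levels below `sparse_threshold` (default 0.05) merge
   into the smaller adjacent neighbor (ordered) or a pooled "other"
   (unordered) until none remain or two levels are left.

The qualitative "leaned to one side" / "most answers in the center"
patterns have no canonical numeric definition; the three thresholds are
declared, configurable choices that reproduce the intended label patterns.
Every transformation appends an audit record mapping raw to harmonized
labels; `replay_audit` reconstructs the harmonized values from raw values
exactly, and the whole pipeline is idempotent.

Types omitted from the dictionary are inferred (numeric with >10 distinct
values ⇒ continuous; a declared level list ⇒ ordered; otherwise unordered)
and flagged in the audit; mixing numeric and text values without a
declaration is an error rather than a guess.

## QC cascade

Order is fixed: near-constant variables (modal share **strictly greater**
than 0.95 among nonmissing respondents), then subjects with **strictly more**
than 60% missingness over the remaining exposures, then variables still
**strictly over** 50% missing. Strict inequalities follow the rule wording
("more than", "over"); boundary cases are retained. The modal share uses
the nonmissing denominator so that missingness is handled only by the
missingness filters; this is configurable. All three thresholds are exposed
so the robustness sweep (varying them and comparing results) can be rerun.

## Outcome scoring

A subject with more than 25% of the 18 items missing (i.e. ≥5 items) is
excluded (strict ">", so exactly 25% — impossible with 18 items — would be
kept). Otherwise the mean item score is the mean of nonmissing items, the
weighted total is 18 × that mean (equal to the plain sum when complete,
which is the natural reading of a count-weighted total), and the regression
outcome is the square root of the mean item score.

## Covariate imputation

Single imputation by chained equations, because the scan produces one
results table; multiple imputation with pooling is out of scope. Sweep
order is descending missingness; initial fill is the observed mean/mode;
each sweep refits a linear model of the target on all other covariates plus
the outcome (standard practice, so imputation does not attenuate
exposure–outcome associations). Continuous targets receive a seeded
residual-SD noise draw; categorical targets are predicted on integer codes
and snapped to the nearest observed code. Observed values are never
altered; the per-sweep mean absolute change of imputed values is the
convergence trace. Ten sweeps is the default and ample for the nearly
linear covariate structures involved. This is a deliberately small,
deterministic implementation: predictive-mean-matching multiple-imputation
machinery is a different contract (pooled inference over several completed
datasets) than the single completed covariate matrix the scan consumes.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

- **Domains:** ten topical domains (parental health 260, parental
  psychopathology 134, sociodemographic 91, lifestyle/life events 87,
  nutrition/toxins 76, family and rearing 123, maternal expectations 50,
  maternal biomarkers 40, perinatal/obstetrics 43, cord-blood biomarkers 7
  variables — 911 in total by default).
- **Correlation:** one latent factor per domain with loading 0.6, giving
  within-domain pairwise correlations near 0.6² = 0.36 and zero
  across domains — the simplest generator reproducing the blocked
  covariance structure of real questionnaire batteries.
- **Types:** 30% continuous / 50% ordered / 20% unordered by default;
  biomarker domains are always continuous. Ordered and unordered variables
  discretize the latent value at random quantile cuts (3–6 levels);
  unordered labels are permuted so they carry no ordinal signal.
- **Structure probes:** a configurable number of conditional parent/child
  pairs and "Do not know" injections exercise every harmonization path.
- **Missingness:** variables are assigned round-robin to four
  questionnaire waves; each subject misses a whole wave with probability
  0.10 and any single answer with probability 0.05.
- **Covariates:** marginals and cross-correlations at realistic cohort
  values (maternal age 31.4 ± 4.5 correlated 0.34 with education and 0.29
  with parity, birth weight correlated 0.61 with gestational age, birth
  year correlated −0.5 with age at assessment, 68% Dutch ethnicity, GSI
  lognormal), with per-unit outcome effects at published-study magnitudes
  (e.g. −0.007 per year of maternal age, 0.063 for boys, ~0.1 for
  non-western ethnicity, all on the sqrt-score scale).
- **Outcome:** the linear predictor `lp` (intercept + covariate effects +
  planted effects) is multiplied by a bounded, mean-one, right-skewed
  noise multiplier `exp(U)/E[exp(U)]` with uniform `U`; item totals are
  then drawn by stochastic straddle quantization on the representable grid
  `sqrt(k/18)`, which preserves the conditional mean on the measured
  (sqrt) scale. Consequently `E[y | exposures, covariates]` is *exactly*
  linear, OLS recovers planted slopes without bias, and the intercept and
  noise spread are calibrated by a deterministic fixed point so the
  realized mean item score hits the configured mean 0.22 / SD 0.23.
  Planted continuous exposures are truncated-normal (±2.5 SD) so the
  linear predictor stays positive over the whole exposure range.

  Two consequences are worth knowing. First, the noise SD is proportional
  to the linear predictor (unavoidable for a positive outcome with
  CV ≈ 1 on the score scale), so classical t-intervals undercover by a few
  points at the largest planted effects (measured ≈ 92% at B = 0.15
  against the nominal 95%); robust intervals (`cov_type="HC3"`) close most
  of that gap. Second, the grid quantization adds variance on the score
  scale, which the calibration absorbs.
- **Mediation and confounding probes:** `plant_mediation` reroutes a share
  of a planted effect through the GSI while keeping the total effect
  fixed; the path loading is capped at the GSI's own spread (raising the
  GSI's outcome coefficient to compensate) so the mediator never becomes
  near-collinear with the exposure. `plant_confounding` makes a variable a
  pure marker of non-western ethnicity with no direct effect, which the
  Dutch-only sensitivity run should de-significate.

What the generator does **not** emulate: real questionnaire text and
response psychology, informative (non-MCAR) missingness, rater bias shared
between the SRS and maternal self-reports, assay noise structure, and
anything about the real cohort's joint distribution beyond the moments
listed above. Passing tests therefore demonstrate the pipeline's
correctness and the design's operating characteristics under these stated
conditions, not the epidemiological validity of any real-data finding.

## Split and determinism

The discovery set holds `round(n × 0.75)` subjects, drawn by a seeded
permutation, unstratified. Every stochastic component (generator,
split, imputation noise, simulations) takes an explicit seed, and the full
pipeline is byte-identical across runs with the same seed and config.

## Simulation sizes

The error-rate simulation uses 1,000 replicates for the single-stage rate
and 4,000 for the two-stage rate (expected count 10 at 0.25%), with n=500
and n=800 subjects per replicate respectively — under the complete null the
family-wise rate does not depend on n, so these sizes are chosen to keep a
full run in the low minutes on one CPU while the binomial CI is informative.
Parameter-recovery checks use 500 replicates of 800-subject cohorts per
effect size.

## Reporting conventions

The Manhattan y-axis is −log10 of the FDR-adjusted p (a raw-p axis is
available behind a flag). The red FDR line sits at −log10(0.05). The green
(uncorrected 0.05) and purple (Bonferroni 0.05) lines are placed through
the empirical monotone raw→adjusted step map — the smallest adjusted p
among variables with raw p at or above the threshold — so that a variable
is above a line exactly when it is significant at that criterion, and a
variable with raw p exactly at a threshold sits exactly on the line. Figures
are pure functions of the saved results table and regenerate
byte-identically (SVG metadata dates are stripped).

## Known limitations

- Ordered exposures are modeled as linear integer scores (indicator coding
  is available via the exposure-design helper but not the default).
- The two-stage FWER arithmetic assumes independent exposures; with the
  generator's correlated blocks the complete-null FWER is conservative
  relative to alpha², and no analytic correction is attempted.
- Chained-equations imputation assumes roughly linear conditional
  structures; heavily nonlinear covariate relationships would need a
  richer conditional model.
- The nonresponse comparison reports marginal tests only; it is a
  diagnostic table, not a selection model.
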