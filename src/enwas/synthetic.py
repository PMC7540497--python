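"""Synthetic cohort generator emulating a prenatal/perinatal exposure study.

The generator produces a dictionary + raw cohort pair with the structural
features the analysis pipeline must survive: ~900 mixed-type exposures in 10
topical domains with high within-domain correlation (a single latent factor
per domain; loading 0.6 gives within-domain pairwise correlations of about
0.36), questionnaire-wave block missingness plus item-level MCAR,
conditional (skip-logic) question pairs, "Do not know" answers, an 18-item
SRS outcome whose mean item score is calibrated to mean 0.22 / SD 0.23, and
epidemiological covariates with literature-scale effects.

The outcome is simulated on the square-root scale as
``sqrt_score = lp * M`` where ``lp`` is the linear predictor holding the
covariate and planted exposure effects and ``M`` is a bounded, mean-one,
right-skewed multiplicative noise (``exp(U)`` with uniform ``U``,
normalized). This keeps the sqrt-scale outcome strictly positive while
leaving ``E[sqrt_score | x] = lp`` exactly linear. Item totals are then
drawn by stochastic straddle quantization on the representable grid
``sqrt(k/18)``, which preserves the conditional mean on the sqrt scale, so
ordinary least squares on the scored outcome recovers planted coefficients
without bias. The intercept and noise spread are calibrated by a
deterministic fixed point so that the realized (quantized) mean item score
matches the configured mean/SD. Planted continuous exposures are
truncated-normal (+-2.5 SD) so the linear predictor stays positive across
the whole exposure range.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dictionary import CONTINUOUS, ORDERED, UNORDERED, DataDictionary
from .errors import SpecError

#: Default topical domains and variables per domain.
DEFAULT_DOMAINS: dict[str, int] = {
    "parental_health": 260,
    "parental_psychopathology": 134,
    "sociodemographic": 91,
    "lifestyle_life_events": 87,
    "nutrition_toxins": 76,
    "family_rearing": 123,
    "maternal_expectations": 50,
    "maternal_biomarkers": 40,
    "perinatal_obstetrics": 43,
    "cord_blood_biomarkers": 7,
}

#: Per-unit (or per-level) covariate effects on the sqrt-score scale.
DEFAULT_COVARIATE_EFFECTS: dict = {
    "maternal_age": -0.007,
    "maternal_education": {"low": 0.158, "middle": 0.053, "high": 0.0},
    "maternal_ethnicity": {"dutch": 0.0, "other_western": 0.0, "nonwestern": 0.10},
    "child_sex": {"girl": 0.0, "boy": 0.063},
    "parity": 0.001,
    "birth_year": -0.008,  # per year after 2002
    "birth_weight": -1.2e-5,
    "gestational_age": -0.003,
    "gsi": 0.106,
}

COVARIATE_COLUMNS = [
    "age_srs", "maternal_age", "maternal_education", "maternal_ethnicity",
    "child_sex", "parity", "birth_year", "birth_weight", "gestational_age", "gsi",
]
FLAG_COLUMNS = ["dutch_parents", "asd_diagnosis"]
SRS_PREFIX = "srs_"


@dataclass(frozen=True)
class PlantedEffect:
    variable: str
    beta: float  # per-unit effect on the sqrt-score scale


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a synthetic cohort."""

    n_subjects: int = 3891
    domains: tuple = tuple(DEFAULT_DOMAINS.items())
    factor_loading: float = 0.6
    type_mix: tuple = (0.3, 0.5, 0.2)  # continuous, ordered, unordered
    n_waves: int = 4
    wave_missing_rate: float = 0.10
    item_missing_rate: float = 0.05
    n_conditional_pairs: int = 10
    n_dont_know: int = 15
    dont_know_rate: float = 0.03
    covariate_effects: tuple = tuple(
        (k, tuple(v.items()) if isinstance(v, dict) else v)
        for k, v in DEFAULT_COVARIATE_EFFECTS.items()
    )
    covariate_missing_rate: float = 0.05
    planted_effects: tuple[PlantedEffect, ...] = ()
    mediation: tuple = ()  # ((variable, share), ...), mediator = GSI
    confounded: tuple = ()  # ((variable, delta on nonwestern indicator), ...)
    outcome_mean: float = 0.22
    outcome_sd: float = 0.23
    srs_missing_rate: float = 0.02
    srs_excluded_rate: float = 0.03
    asd_rate: float = 0.0136
    seed: int = 0

    @property
    def domain_counts(self) -> dict[str, int]:
        return dict(self.domains)

    @property
    def n_variables(self) -> int:
        return sum(self.domain_counts.values())

    def effects(self) -> dict:
        return {
            k: dict(v) if isinstance(v, tuple) else v for k, v in self.covariate_effects
        }

    def validate(self) -> None:
        if any(c <= 0 for c in self.domain_counts.values()):
            raise SpecError("domain variable counts must be positive")
        if self.outcome_mean <= 0 or self.outcome_sd <= 0:
            raise SpecError("outcome mean/sd must be positive")
        names = {v for d in self.domain_counts for v in ()}  # noqa: F841
        planted_names = [p.variable for p in self.planted_effects]
        if len(set(planted_names)) != len(planted_names):
            raise SpecError("duplicate planted variables")


def plant_mediation(spec: SyntheticSpec, exposure: str, share: float,
                    mediator: str = "gsi") -> SyntheticSpec:
    """Reroute `share` of a planted exposure's total effect through the GSI.

    The total effect is unchanged: the direct path keeps (1 - share) x beta
    and the mediator path carries share x beta via the GSI's own outcome
    coefficient. share=0 leaves the spec unchanged.
    """
    if not 0 <= share <= 1:
        raise SpecError("mediation share must be in [0, 1]")
    if mediator != "gsi":
        raise SpecError("only GSI mediation is supported")
    if exposure not in {p.variable for p in spec.planted_effects}:
        raise SpecError(f"{exposure!r} is not a planted variable")
    if share == 0:
        return spec
    med = dict(spec.mediation)
    med[exposure] = share
    return replace(spec, mediation=tuple(med.items()))


def plant_confounding(spec: SyntheticSpec, variable: str, delta: float) -> SyntheticSpec:
    """Make `variable` a pure marker of non-western ethnicity (no direct effect)."""
    conf = dict(spec.confounded)
    conf[variable] = delta
    return replace(spec, confounded=tuple(conf.items()))


def _variable_names(spec: SyntheticSpec) -> dict[str, list[str]]:
    return {
        dom: [f"{dom}_{i + 1:03d}" for i in range(count)]
        for dom, count in spec.domain_counts.items()
    }


@dataclass
class GeneratedCohort:
    table: pd.DataFrame
    dictionary: DataDictionary
    truth: dict


def _truncnorm(rng: np.random.Generator, n: int, bound: float = 2.5) -> np.ndarray:
    """Standard normal truncated to [-bound, bound] via inverse-CDF sampling."""
    from scipy.special import ndtr, ndtri

    lo, hi = ndtr(-bound), ndtr(bound)
    return ndtri(lo + rng.random(n) * (hi - lo))


#: Representable outcome values: sqrt(total / 18) for item totals 0..54.
_SQRT_GRID = np.sqrt(np.arange(55) / 18.0)


def _noise_multiplier(c: float, u: np.ndarray) -> np.ndarray:
    """Bounded, mean-one, right-skewed multiplier exp(U)/E[exp(U)], U ~ Unif(-c, c)."""
    if c < 1e-8:
        return np.ones_like(u)
    return np.exp(c * (2.0 * u - 1.0)) / (np.sinh(c) / c)


def _straddle_totals(y_star: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Quantize sqrt-scale outcomes onto item totals, preserving E[sqrt(T/18)|y*].

    Each value is randomized between the two adjacent representable grid
    points with straddle probabilities, so the quantization is conditionally
    unbiased on the measured (square-root) scale.
    """
    y = np.clip(y_star, 0.0, _SQRT_GRID[-1])
    k = np.clip(np.searchsorted(_SQRT_GRID, y, side="right") - 1, 0, 53)
    p_up = (y - _SQRT_GRID[k]) / (_SQRT_GRID[k + 1] - _SQRT_GRID[k])
    return (k + (u < p_up)).astype(int)


def _calibrated_item_totals(
    spec: SyntheticSpec, rng: np.random.Generator, contribs: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Item totals whose realized mean score matches the configured mean/SD.

    The intercept b0 and the noise spread c are solved by a damped fixed
    point against the realized quantized score moments; all random draws are
    made once, so the calibration is deterministic given the seed.
    """
    n = len(contribs)
    u_noise = rng.random(n)
    u_quant = rng.random(n)
    target_m, target_s = spec.outcome_mean, spec.outcome_sd
    b0 = float(np.sqrt(target_m * 0.85))
    c = float(np.sqrt(3.0) * np.sqrt(np.log1p((target_s / target_m) ** 2) / 4.0))
    total = None
    for _ in range(40):
        lp = np.maximum(b0 + contribs, 0.02)
        y_star = lp * _noise_multiplier(c, u_noise)
        total = _straddle_totals(y_star, u_quant)
        score = total / 18.0
        m, s = float(score.mean()), float(score.std())
        if abs(m - target_m) < 0.002 and abs(s - target_s) < 0.004:
            break
        b0 *= float(np.clip(np.sqrt(target_m / max(m, 1e-6)), 0.7, 1.4)) ** 0.8
        cv_ratio = (target_s / target_m) / max(s / max(m, 1e-6), 1e-6)
        c *= float(np.clip(cv_ratio, 0.7, 1.4)) ** 0.6
        c = float(np.clip(c, 1e-4, 3.0))
    return total, b0, c


def _generate_covariates(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    z_age_srs = rng.standard_normal(n)
    # birth year negatively correlated with age at SRS administration
    z_year = -0.5 * z_age_srs + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    year_probs = np.array([0.092, 0.283, 0.325, 0.295, 0.005])
    year_edges = np.quantile(z_year, np.cumsum(year_probs)[:-1])
    birth_year = 2002 + np.searchsorted(year_edges, z_year)

    z_mage = rng.standard_normal(n)
    maternal_age = 31.4 + 4.46 * z_mage
    z_edu = 0.34 * z_mage + np.sqrt(1 - 0.34**2) * rng.standard_normal(n)
    edu_edges = np.quantile(z_edu, [0.05, 0.41])  # low 5%, middle 36%, high 59%
    maternal_education = np.array(["low", "middle", "high"])[
        np.searchsorted(edu_edges, z_edu)
    ]
    z_par = 0.29 * z_mage + np.sqrt(1 - 0.29**2) * rng.standard_normal(n)
    par_edges = np.quantile(z_par, [0.61, 0.90])
    parity = np.searchsorted(par_edges, z_par).astype(float)

    maternal_ethnicity = rng.choice(
        ["dutch", "other_western", "nonwestern"], size=n, p=[0.68, 0.09, 0.23]
    )
    child_sex = rng.choice(["girl", "boy"], size=n, p=[0.51, 0.49])
    z_ga = rng.standard_normal(n)
    gestational_age = 39.9 + 1.7 * z_ga
    birth_weight = 3447 + 559 * (0.61 * z_ga + np.sqrt(1 - 0.61**2) * rng.standard_normal(n))
    gsi = np.exp(rng.normal(np.log(0.25), 0.7, size=n))
    return pd.DataFrame(
        {
            "age_srs": 6.1 + 0.43 * z_age_srs,
            "maternal_age": maternal_age,
            "maternal_education": maternal_education,
            "maternal_ethnicity": maternal_ethnicity,
            "child_sex": child_sex,
            "parity": parity,
            "birth_year": birth_year.astype(float),
            "birth_weight": birth_weight,
            "gestational_age": gestational_age,
            "gsi": gsi,
        }
    )


def generate(spec: SyntheticSpec) -> GeneratedCohort:
    """Generate the full dictionary + raw cohort table + ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    names_by_domain = _variable_names(spec)
    all_names = [v for names in names_by_domain.values() for v in names]

    cov = _generate_covariates(spec, rng)
    effects = spec.effects()
    planted = {p.variable: p.beta for p in spec.planted_effects}
    mediation = dict(spec.mediation)
    confounded = dict(spec.confounded)
    special = set(planted) | set(confounded)

    # latent standard-normal value per exposure; block structure via domain factors
    lam = spec.factor_loading
    latent: dict[str, np.ndarray] = {}
    nonwestern = (cov["maternal_ethnicity"] == "nonwestern").to_numpy(float)
    for dom, names in names_by_domain.items():
        factor = rng.standard_normal(n)
        for v in names:
            if v in confounded:
                delta = confounded[v]
                latent[v] = delta * (nonwestern - nonwestern.mean()) + _truncnorm(rng, n)
            elif v in planted:
                # independent of other exposures and covariates; bounded range
                # keeps the outcome's linear predictor positive everywhere
                latent[v] = _truncnorm(rng, n)
            else:
                latent[v] = lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(n)

    # GSI mediation: the mediator inherits part of the planted signal. The
    # path loading is capped at the GSI's own spread (and the GSI outcome
    # coefficient raised to compensate) so the mediator never becomes
    # near-collinear with the exposure; the total mediated effect share*B
    # is preserved either way.
    gsi_coef = effects["gsi"]
    if mediation:
        if gsi_coef == 0:
            raise SpecError("GSI outcome coefficient is zero; mediation impossible")
        sigma_g = float(np.std(cov["gsi"]))
        strongest = max(abs(share * planted[v]) for v, share in mediation.items())
        gsi_coef = max(abs(gsi_coef), strongest / sigma_g)
        for v, share in mediation.items():
            a = share * planted[v] / gsi_coef
            cov["gsi"] = cov["gsi"] + a * latent[v]

    # variable types, values, dictionary entries
    type_labels = np.array([CONTINUOUS, ORDERED, UNORDERED])
    entries: dict[str, dict] = {}
    columns: dict[str, np.ndarray | pd.Series] = {}
    conditional_budget = spec.n_conditional_pairs
    dont_know_budget = spec.n_dont_know
    for dom, names in names_by_domain.items():
        for v in names:
            z = latent[v]
            if v in special:
                vtype = CONTINUOUS
            elif dom in ("maternal_biomarkers", "cord_blood_biomarkers"):
                vtype = CONTINUOUS  # assay values are numeric
            else:
                vtype = str(rng.choice(type_labels, p=spec.type_mix))
            entry: dict = {"name": v, "domain": dom, "type": vtype, "levels": None}
            if vtype == CONTINUOUS:
                if v in special:
                    values = pd.Series(z)
                else:
                    mu, sd = rng.normal(0, 1), rng.uniform(0.5, 2.0)
                    values = pd.Series(mu + sd * z)
            else:
                k = int(rng.integers(3, 7 if vtype == ORDERED else 6))
                probs = rng.dirichlet(np.full(k, 2.0))
                edges = np.quantile(z, np.cumsum(probs)[:-1])
                codes = np.searchsorted(edges, z)
                if vtype == ORDERED:
                    levels = [f"L{i + 1}" for i in range(k)]
                else:
                    levels = [f"C{i + 1}" for i in range(k)]
                    codes = rng.permutation(k)[codes]  # break any ordinal reading
                    levels = sorted(levels)
                values = pd.Series(np.array(levels)[codes], dtype=object)
                entry["levels"] = levels
            columns[v] = values
            entries[v] = entry

    # conditional question pairs: demote a categorical variable to a yes/no
    # parent plus a gated child holding the detail
    cond_pairs: list[tuple[str, str]] = []
    for v in all_names:
        if conditional_budget == 0:
            break
        e = entries[v]
        if e["type"] != ORDERED or v in special or len(e["levels"]) < 3:
            continue
        detail = f"{v}_detail"
        vals = columns[v].astype(str)
        gate_open = vals != e["levels"][0]  # any non-first answer opens the gate
        parent_vals = pd.Series(np.where(gate_open, "Yes", "No"), dtype=object)
        child_vals = vals.where(gate_open, np.nan)
        child_levels = e["levels"][1:]
        columns[v] = parent_vals
        columns[detail] = child_vals
        entries[v] = {"name": v, "domain": e["domain"], "type": UNORDERED,
                      "levels": ["No", "Yes"]}
        entries[detail] = {"name": detail, "domain": e["domain"], "type": ORDERED,
                           "levels": child_levels, "parent": v, "parent_gate": "Yes"}
        cond_pairs.append((v, detail))
        conditional_budget -= 1

    # "Do not know" options on some categoricals
    dk_vars: list[str] = []
    for v in all_names:
        if dont_know_budget == 0:
            break
        e = entries[v]
        if e["type"] == CONTINUOUS or v in special or v in dict(cond_pairs):
            continue
        vals = columns[v]
        mask = rng.random(n) < spec.dont_know_rate
        vals = vals.mask(mask, "Do not know")
        columns[v] = vals
        entries[v]["dont_know_labels"] = ["Do not know"]
        dk_vars.append(v)
        dont_know_budget -= 1

    # rebuild ordered name list including conditional children after parents
    ordered_names: list[str] = []
    for v in all_names:
        ordered_names.append(v)
        if f"{v}_detail" in entries:
            ordered_names.append(f"{v}_detail")

    # outcome linear predictor on the sqrt-score scale
    contribs = np.zeros(n)
    contribs += effects["maternal_age"] * cov["maternal_age"].to_numpy()
    contribs += cov["maternal_education"].map(effects["maternal_education"]).to_numpy()
    contribs += cov["maternal_ethnicity"].map(effects["maternal_ethnicity"]).to_numpy()
    contribs += cov["child_sex"].map(effects["child_sex"]).to_numpy()
    contribs += effects["parity"] * cov["parity"].to_numpy()
    contribs += effects["birth_year"] * (cov["birth_year"].to_numpy() - 2002)
    contribs += effects["birth_weight"] * cov["birth_weight"].to_numpy()
    contribs += effects["gestational_age"] * cov["gestational_age"].to_numpy()
    contribs += gsi_coef * cov["gsi"].to_numpy()
    for v, beta in planted.items():
        direct = beta * (1.0 - mediation.get(v, 0.0))
        contribs += direct * latent[v]
    contribs = contribs - contribs.mean()
    if np.var(contribs) > 0.25 * spec.outcome_mean:
        raise SpecError("covariate/planted effects too large for the outcome calibration")

    total, b0, c_noise = _calibrated_item_totals(spec, rng, contribs)
    score = total / 18.0
    q, r = np.divmod(total, 18)
    items = np.tile(q[:, None], (1, 18)).astype(float)
    bump_order = np.argsort(rng.random((n, 18)), axis=1)
    bump = bump_order < r[:, None]
    items[bump] += 1
    items = np.clip(items, 0, 3)
    item_missing = rng.random((n, 18)) < spec.srs_missing_rate
    n_excl = int(round(spec.srs_excluded_rate * n))
    excl_rows = rng.choice(n, size=n_excl, replace=False)
    for row in excl_rows:
        drop = rng.choice(18, size=6, replace=False)
        item_missing[row, drop] = True
    items[item_missing] = np.nan

    # exposure missingness: questionnaire-wave blocks + item-level MCAR
    wave_of = {v: i % spec.n_waves for i, v in enumerate(ordered_names)}
    wave_missing = rng.random((n, spec.n_waves)) < spec.wave_missing_rate
    for v in ordered_names:
        vals = pd.Series(columns[v]).copy()
        miss = wave_missing[:, wave_of[v]] | (rng.random(n) < spec.item_missing_rate)
        vals[miss] = np.nan
        columns[v] = vals

    # flags
    asd_k = int(round(spec.asd_rate * n))
    asd_score = score + np.std(score) * rng.standard_normal(n)
    asd_flag = np.zeros(n, dtype=bool)
    asd_flag[np.argsort(asd_score)[::-1][:asd_k]] = True
    dutch_parents = (cov["maternal_ethnicity"] == "dutch").to_numpy()

    # covariate MCAR missingness (the imputation module's workload)
    cov_out = cov.copy()
    for c in ["maternal_age", "maternal_education", "birth_weight",
              "gestational_age", "gsi"]:
        mask = rng.random(n) < spec.covariate_missing_rate
        cov_out.loc[mask, c] = np.nan

    table = pd.DataFrame({v: columns[v] for v in ordered_names})
    for c in COVARIATE_COLUMNS:
        table[c] = cov_out[c].to_numpy()
    for j in range(18):
        table[f"{SRS_PREFIX}{j + 1:02d}"] = items[:, j]
    table["dutch_parents"] = dutch_parents
    table["asd_diagnosis"] = asd_flag

    dictionary = DataDictionary({v: entries[v] for v in ordered_names})
    truth = {
        "planted_effects": planted,
        "mediation": mediation,
        "confounded": confounded,
        "calibration": {"b0": float(b0), "noise_spread": float(c_noise)},
        "conditional_pairs": cond_pairs,
        "dont_know_variables": dk_vars,
        "latent_score": score.tolist() if n <= 2000 else None,
    }
    return GeneratedCohort(table=table, dictionary=dictionary, truth=truth)


def generate_dictionary(spec: SyntheticSpec) -> DataDictionary:
    """The data dictionary of the generated cohort (deterministic given seed)."""
    return generate(spec).dictionary


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """The raw cohort table of the generated cohort (deterministic given seed)."""
    return generate(spec).table
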