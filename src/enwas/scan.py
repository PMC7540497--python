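"""Mass-univariate environment-wide association scan.

One covariate-adjusted ordinary-least-squares model is fit per exposure,
with the square-root mean SRS item score as the outcome. The cohort is
split a priori into a discovery set (75%) and a test set (25%); every
exposure is tested in the discovery set, p-values are corrected by
Benjamini-Hochberg FDR across all tested exposures, and only the
FDR-significant exposures are refit in the test set, where FDR is applied
again across that subset. Bonferroni-adjusted p-values are reported
alongside at both stages.

Exposure coding by type: continuous -> a single slope (with an optional
quadratic term retained when the discovery-stage screen finds it
significant); ordered categorical -> a consecutive-integer score, giving a
single lowest-to-highest contrast; unordered categorical -> indicator
coding against the most frequent level, with the per-variable p taken from
the joint F-test on the exposure block so every variable contributes
exactly one p-value to the multiple-testing correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .dictionary import CONTINUOUS, ORDERED, UNORDERED
from .errors import ConfigError, DegenerateFitError, RankDeficiencyError

#: Named covariate sets; base < main6 < extended8 as lists.
COVARIATE_SETS: dict[str, list[str]] = {
    "base": ["age_srs"],
    "main6": [
        "age_srs", "maternal_age", "maternal_education", "maternal_ethnicity",
        "child_sex", "parity", "birth_year",
    ],
    "extended8": [
        "age_srs", "maternal_age", "maternal_education", "maternal_ethnicity",
        "child_sex", "parity", "birth_year", "birth_weight", "gestational_age",
    ],
    "main6_gsi": [
        "age_srs", "maternal_age", "maternal_education", "maternal_ethnicity",
        "child_sex", "parity", "birth_year", "gsi",
    ],
}

#: Domains removed from the tested set when adjusting for the GSI.
GSI_EXCLUDED_DOMAINS = ("parental_health", "parental_psychopathology")


class VariableMeta(NamedTuple):
    domain: str
    var_type: str
    levels: list[str] | None


@dataclass
class ScanConfig:
    split_fraction: float = 0.75
    seed: int = 0
    covariate_set: str = "main6"
    alpha: float = 0.05
    correction: str = "fdr_bh"  # or "fdr_by"
    quadratic_screen: bool = True
    sensitivity: str = "none"  # none | dutch_only | exclude_asd | gsi_adjusted

    def covariates(self) -> list[str]:
        if self.covariate_set not in COVARIATE_SETS:
            raise ConfigError(f"unknown covariate set {self.covariate_set!r}")
        return COVARIATE_SETS[self.covariate_set]


@dataclass
class CohortData:
    """Analysis-ready cohort: harmonized exposures + metadata + covariates + outcome."""

    exposures: pd.DataFrame
    meta: dict[str, VariableMeta]
    covariates: pd.DataFrame
    y: pd.Series
    flags: pd.DataFrame | None = None  # e.g. dutch_parents, asd_diagnosis

    def subset(self, index) -> "CohortData":
        return CohortData(
            exposures=self.exposures.loc[index],
            meta=self.meta,
            covariates=self.covariates.loc[index],
            y=self.y.loc[index],
            flags=self.flags.loc[index] if self.flags is not None else None,
        )

    @property
    def n(self) -> int:
        return len(self.y)


class Contrast(NamedTuple):
    label: str
    B: float
    ci_low: float
    ci_high: float


@dataclass
class AssociationResult:
    variable: str
    domain: str
    var_type: str
    n: int
    contrasts: list[Contrast]
    b_intercept: float
    p_joint: float
    p_quadratic: float | None = None
    stage: str = "discovery"
    p_fdr: float = np.nan
    p_bonf: float = np.nan
    sig_fdr: bool = False
    sig_bonf: bool = False

    def to_rows(self) -> list[dict]:
        return [
            {
                "variable": self.variable,
                "domain": self.domain,
                "var_type": self.var_type,
                "contrast": c.label,
                "n": self.n,
                "B": c.B,
                "B_intercept": self.b_intercept,
                "CI_low": c.ci_low,
                "CI_high": c.ci_high,
                "p_joint": self.p_joint,
                "p_quadratic": self.p_quadratic,
                "stage": self.stage,
                "p_fdr": self.p_fdr,
                "p_bonf": self.p_bonf,
                "sig_fdr": self.sig_fdr,
                "sig_bonf": self.sig_bonf,
            }
            for c in self.contrasts
        ]


@dataclass
class EnwasReport:
    """Per-stage and per-domain counts of tested and significant variables."""

    stage_counts: dict = field(default_factory=dict)
    domain_counts: pd.DataFrame | None = None
    survivors: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ScanResult:
    results: pd.DataFrame
    associations: dict[str, list[AssociationResult]]
    report: EnwasReport


def split_cohort(data: CohortData, split_fraction: float = 0.75, seed: int = 0):
    """Deterministically partition subjects into discovery and test sets.

    Discovery size is round(n x split_fraction); the partition is disjoint
    and exhaustive, and identical for a fixed seed.
    """
    if not 0 < split_fraction < 1:
        raise ConfigError("split_fraction must be in (0, 1)")
    n = data.n
    if n < 2:
        raise ConfigError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_disc = int(np.round(n * split_fraction))
    idx = data.y.index
    return data.subset(idx[np.sort(perm[:n_disc])]), data.subset(idx[np.sort(perm[n_disc:])])


def adjust_pvalues(p, method: str = "fdr_bh") -> np.ndarray:
    """Multiplicity-adjusted p-values (BH/BY step-up or Bonferroni), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    return multipletests(p, method=method)[1]


def build_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: continuous as-is, categoricals as indicators
    against the most frequent level (deterministic reference choice)."""
    cols = {}
    for c in covariates.columns:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            s = col.astype(str)
            ref = s.value_counts().index[0]
            for lvl in sorted(s.unique()):
                if lvl != ref:
                    cols[f"{c}[{lvl} vs {ref}]"] = (s == lvl).astype(float)
        else:
            cols[c] = pd.to_numeric(col, errors="coerce").astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _exposure_design(
    x: pd.Series, var_type: str, levels: list[str] | None, quadratic: bool
) -> tuple[pd.DataFrame, list[str]]:
    """Exposure columns and contrast labels for one variable."""
    if var_type == CONTINUOUS:
        xc = pd.to_numeric(x, errors="coerce").astype(float)
        cols = {"x": xc}
        labels = ["per unit"]
        if quadratic:
            centered = xc - xc.mean()
            cols["x2"] = centered**2
            labels.append("per unit^2 (centered)")
        return pd.DataFrame(cols, index=x.index), labels
    s = x.astype(str)
    observed = [lvl for lvl in (levels or sorted(s.unique())) if lvl in set(s)]
    if var_type == ORDERED:
        score = s.map({lvl: float(i) for i, lvl in enumerate(observed)})
        label = f"{observed[0]} to {observed[-1]}" if len(observed) > 1 else "score"
        return pd.DataFrame({"x": score}, index=x.index), [label]
    counts = s.value_counts()
    ref = max(observed, key=lambda lvl: (counts[lvl], -observed.index(lvl)))
    others = [lvl for lvl in observed if lvl != ref]
    cols = {f"x[{lvl}]": (s == lvl).astype(float) for lvl in others}
    return pd.DataFrame(cols, index=x.index), [f"{lvl} vs {ref}" for lvl in others]


def fit_exposure_model(
    y: pd.Series,
    x: pd.Series,
    var_type: str,
    covariates: pd.DataFrame,
    levels: list[str] | None = None,
    quadratic: bool = False,
    domain: str = "unknown",
    name: str | None = None,
    cov_type: str = "nonrobust",
) -> AssociationResult:
    """OLS of the outcome on one coded exposure plus the covariate design.

    Subjects missing the outcome or the exposure are dropped for this model
    (complete-case per variable); the covariate matrix must be complete.
    The per-variable p is the exposure coefficient's two-sided t-test p for
    single-column codings and the joint F-test p over the exposure block
    otherwise. 95% confidence intervals come from the t distribution;
    heteroscedasticity-robust intervals are available via `cov_type`
    (e.g. "HC3").
    """
    name = name or (x.name if x.name is not None else "x")
    mask = y.notna() & x.notna()
    ys = y[mask].astype(float)
    xs = x[mask]
    n = int(mask.sum())
    if n == 0 or xs.nunique(dropna=True) < 2:
        raise DegenerateFitError(f"{name}: exposure constant after complete-case restriction")
    expo, labels = _exposure_design(xs, var_type, levels, quadratic)
    if expo.shape[1] == 0 or (expo.nunique() < 2).any():
        raise DegenerateFitError(f"{name}: exposure design degenerate")
    cov = covariates.loc[mask.index[mask]]
    cov_design = build_covariate_design(cov)
    X = pd.concat([expo, cov_design], axis=1)
    X.insert(0, "const", 1.0)
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficiencyError(f"{name}: exposure collinear with covariates")
    res = sm.OLS(ys.to_numpy(), arr).fit(cov_type=cov_type)
    params = pd.Series(res.params, index=X.columns)
    ci = pd.DataFrame(res.conf_int(alpha=0.05), index=X.columns, columns=["lo", "hi"])
    pvals = pd.Series(res.pvalues, index=X.columns)
    expo_cols = list(expo.columns)
    if len(expo_cols) == 1:
        p_joint = float(pvals[expo_cols[0]])
    else:
        R = np.zeros((len(expo_cols), arr.shape[1]))
        for i, cname in enumerate(expo_cols):
            R[i, X.columns.get_loc(cname)] = 1.0
        p_joint = float(res.f_test(R).pvalue)
    p_joint = max(p_joint, np.finfo(float).tiny)  # keep p in (0, 1]
    contrasts = [
        Contrast(lbl, float(params[cname]), float(ci.loc[cname, "lo"]), float(ci.loc[cname, "hi"]))
        for cname, lbl in zip(expo_cols, labels)
    ]
    return AssociationResult(
        variable=name, domain=domain, var_type=var_type, n=n,
        contrasts=contrasts, b_intercept=float(params["const"]), p_joint=p_joint,
    )


def screen_quadratic(
    y: pd.Series, x: pd.Series, covariates: pd.DataFrame, name: str | None = None
) -> float:
    """p-value of the centered squared term in y ~ x + x^2 + covariates."""
    mask = y.notna() & x.notna()
    if mask.sum() < 4 or x[mask].nunique() < 3:
        raise DegenerateFitError(f"{name or x.name}: too few distinct values for a quadratic")
    xc = pd.to_numeric(x[mask], errors="coerce").astype(float)
    centered = xc - xc.mean()
    cov_design = build_covariate_design(covariates.loc[mask.index[mask]])
    X = pd.concat(
        [pd.DataFrame({"x": xc, "x2": centered**2}, index=xc.index), cov_design], axis=1
    )
    X.insert(0, "const", 1.0)
    res = sm.OLS(y[mask].astype(float).to_numpy(), X.to_numpy(dtype=float)).fit()
    return float(pd.Series(res.pvalues, index=X.columns)["x2"])


def _scan_stage(
    data: CohortData,
    variables: list[str],
    covariate_cols: list[str],
    stage: str,
    quad_retained: dict[str, bool],
    alpha: float,
    correction: str,
    report: EnwasReport,
) -> list[AssociationResult]:
    keep = data.y.notna()
    covariates = data.covariates.loc[keep, covariate_cols]
    results: list[AssociationResult] = []
    for var in variables:
        meta = data.meta[var]
        try:
            r = fit_exposure_model(
                data.y[keep], data.exposures.loc[keep, var], meta.var_type,
                covariates, levels=meta.levels,
                quadratic=quad_retained.get(var, False),
                domain=meta.domain, name=var,
            )
        except (DegenerateFitError, RankDeficiencyError) as err:
            report.skipped.append((var, f"{stage}: {err}"))
            continue
        r.stage = stage
        results.append(r)
    if results:
        p = np.array([r.p_joint for r in results])
        p_fdr = adjust_pvalues(p, correction)
        p_bonf = adjust_pvalues(p, "bonferroni")
        for r, pf, pb in zip(results, p_fdr, p_bonf):
            r.p_fdr, r.p_bonf = float(pf), float(pb)
            r.sig_fdr = bool(pf < alpha)
            r.sig_bonf = bool(pb < alpha)
    return results


def _tabulate(results_by_stage: dict[str, list[AssociationResult]], alpha: float,
              report: EnwasReport) -> None:
    rows = []
    for stage, results in results_by_stage.items():
        report.stage_counts[stage] = {
            "total": len(results),
            "p<0.05": int(sum(r.p_joint < alpha for r in results)),
            "fdr": int(sum(r.sig_fdr for r in results)),
            "bonferroni": int(sum(r.sig_bonf for r in results)),
        }
        for r in results:
            rows.append({"stage": stage, "domain": r.domain,
                         "tested": 1, "p<0.05": int(r.p_joint < alpha),
                         "fdr": int(r.sig_fdr), "bonferroni": int(r.sig_bonf)})
    if rows:
        report.domain_counts = (
            pd.DataFrame(rows).groupby(["stage", "domain"]).sum().reset_index()
        )


def _results_frame(results_by_stage: dict[str, list[AssociationResult]]) -> pd.DataFrame:
    rows: list[dict] = []
    for results in results_by_stage.values():
        for r in results:
            rows.extend(r.to_rows())
    columns = ["variable", "domain", "var_type", "contrast", "n", "B", "B_intercept",
               "CI_low", "CI_high", "p_joint", "p_quadratic", "stage", "p_fdr",
               "p_bonf", "sig_fdr", "sig_bonf"]
    return pd.DataFrame(rows, columns=columns)


def run_enwas(data: CohortData, config: ScanConfig,
              variables: list[str] | None = None) -> ScanResult:
    """Run the full two-stage discovery/test scan.

    Stage 1 fits every exposure in the discovery set and corrects across all
    tested variables; stage 2 refits only the discovery-FDR-significant
    variables in the test set and corrects across that subset only.
    """
    cov_cols = config.covariates()
    absent = [c for c in cov_cols if c not in data.covariates.columns]
    if absent:
        raise ConfigError(f"covariates absent from cohort: {absent}")
    if data.covariates[cov_cols].isna().any().any():
        raise ConfigError("covariates contain missing values; impute first")
    variables = list(variables if variables is not None else data.exposures.columns)

    report = EnwasReport()
    discovery, test = split_cohort(data, config.split_fraction, config.seed)

    # quadratic screening is decided in the discovery stage only
    quad_retained: dict[str, bool] = {}
    quad_p: dict[str, float] = {}
    if config.quadratic_screen:
        keep = discovery.y.notna()
        cov = discovery.covariates.loc[keep, cov_cols]
        for var in variables:
            if data.meta[var].var_type != CONTINUOUS:
                continue
            try:
                pq = screen_quadratic(
                    discovery.y[keep], discovery.exposures.loc[keep, var], cov, name=var
                )
            except (DegenerateFitError, RankDeficiencyError):
                continue
            quad_p[var] = pq
            quad_retained[var] = pq < config.alpha

    disc_results = _scan_stage(
        discovery, variables, cov_cols, "discovery", quad_retained,
        config.alpha, config.correction, report,
    )
    for r in disc_results:
        r.p_quadratic = quad_p.get(r.variable)

    carried = [r.variable for r in disc_results if r.sig_fdr]
    test_results = _scan_stage(
        test, carried, cov_cols, "test", quad_retained,
        config.alpha, config.correction, report,
    )
    for r in test_results:
        r.p_quadratic = quad_p.get(r.variable)

    by_stage = {"discovery": disc_results, "test": test_results}
    _tabulate(by_stage, config.alpha, report)
    report.survivors = [r.variable for r in test_results if r.sig_fdr]
    return ScanResult(_results_frame(by_stage), by_stage, report)


def _single_stage_scan(data: CohortData, config: ScanConfig,
                       variables: list[str]) -> ScanResult:
    cov_cols = config.covariates()
    report = EnwasReport()
    results = _scan_stage(
        data, variables, cov_cols, "combined", {}, config.alpha,
        config.correction, report,
    )
    by_stage = {"combined": results}
    _tabulate(by_stage, config.alpha, report)
    report.survivors = [r.variable for r in results if r.sig_fdr]
    return ScanResult(_results_frame(by_stage), by_stage, report)


def run_sensitivity(data: CohortData, config: ScanConfig, mode: str,
                    variables: list[str] | None = None) -> ScanResult:
    """Sensitivity reruns of the scan.

    ``dutch_only``: restrict to children of two ethnically Dutch parents and
    run a single combined-set scan (the subset is too small to split),
    normally over the main-analysis hits passed as `variables`.
    ``exclude_asd``: drop clinically diagnosed subjects, rerun the full
    two-stage scan. ``gsi_adjusted``: add the maternal GSI to the covariates
    and drop the parental-health and parental-psychopathology domains from
    the tested set.
    """
    if mode == "dutch_only":
        if data.flags is None or "dutch_parents" not in data.flags.columns:
            raise ConfigError("dutch_only requires a 'dutch_parents' flag column")
        sub = data.subset(data.flags.index[data.flags["dutch_parents"].astype(bool)])
        variables = list(variables if variables is not None else data.exposures.columns)
        return _single_stage_scan(sub, config, variables)
    if mode == "exclude_asd":
        if data.flags is None or "asd_diagnosis" not in data.flags.columns:
            raise ConfigError("exclude_asd requires an 'asd_diagnosis' flag column")
        sub = data.subset(data.flags.index[~data.flags["asd_diagnosis"].astype(bool)])
        return run_enwas(sub, config, variables)
    if mode == "gsi_adjusted":
        cfg = replace(config, covariate_set="main6_gsi")
        if "gsi" not in data.covariates.columns:
            raise ConfigError("gsi_adjusted requires a 'gsi' covariate column")
        tested = [
            v for v in (variables if variables is not None else data.exposures.columns)
            if data.meta[v].domain not in GSI_EXCLUDED_DOMAINS
        ]
        return run_enwas(data, cfg, tested)
    raise ConfigError(f"unknown sensitivity mode {mode!r}")
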