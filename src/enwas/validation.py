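"""Operating characteristics of the two-stage scan under the global null.

Under a complete null with independent exposures, the Benjamini-Hochberg
step-up procedure controls the family-wise error rate at exactly alpha
(false discovery rate and FWER coincide when every hypothesis is null), so
a single discovery stage at alpha = 0.05 over 920 independent tests has a
5% chance of producing at least one false positive, and the full
discovery -> test procedure, with FDR applied again in the test stage to
the carried-forward variables, has an alpha^2 = 0.25% chance. These rates
are estimated here by direct simulation.

For speed the simulation kernel uses the closed-form simple-regression
p-value (the t-test of the correlation coefficient), which is numerically
identical to the scan's covariate-free OLS fit; the equivalence is asserted
in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError
from .scan import adjust_pvalues


@dataclass
class SimulationReport:
    """Monte-Carlo estimate of a family-wise rate or per-effect power."""

    n_reps: int
    config: dict = field(default_factory=dict)
    fwer: float | None = None
    fwer_ci: tuple[float, float] | None = None
    stage1_fwer: float | None = None
    stage1_ci: tuple[float, float] | None = None
    power: dict | None = None  # beta -> (estimate, ci)


def simple_regression_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the slope in y ~ x for every column of X.

    Closed form via the correlation coefficient: t = r sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom, identical to the OLS slope t-test.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _split_sizes(n: int, split_fraction: float) -> int:
    return int(np.round(n * split_fraction))


def _two_stage_rejections(
    X: np.ndarray, y: np.ndarray, split_fraction: float, alpha: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """(discovery rejections, final survivors) for one replicate."""
    n = len(y)
    perm = rng.permutation(n)
    n_disc = _split_sizes(n, split_fraction)
    disc, test = perm[:n_disc], perm[n_disc:]
    p_disc = simple_regression_pvalues(X[disc], y[disc])
    sig = adjust_pvalues(p_disc, "fdr_bh") < alpha
    if not sig.any():
        return 0, 0
    p_test = simple_regression_pvalues(X[test][:, sig], y[test])
    surv = adjust_pvalues(p_test, "fdr_bh") < alpha
    return int(sig.sum()), int(surv.sum())


def estimate_fwer(
    m: int = 920,
    n: int = 500,
    alpha: float = 0.05,
    stages: int = 1,
    n_reps: int = 1000,
    seed: int = 0,
    split_fraction: float = 0.75,
) -> SimulationReport:
    """Share of replicate null cohorts with >= 1 surviving variable.

    Each replicate draws m independent standard-normal exposures and an
    independent outcome, applies BH at `alpha` in the discovery stage (all
    subjects for stages=1; the 75% split for stages=2), and for stages=2
    carries the significant variables into the held-out 25% where BH is
    applied again.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if stages not in (1, 2):
        raise ConfigError("stages must be 1 or 2")
    rng = np.random.default_rng(seed)
    hits_s1 = 0
    hits_final = 0
    for _ in range(n_reps):
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        if alpha == 0:
            continue
        if stages == 1:
            p = simple_regression_pvalues(X, y)
            k = int((adjust_pvalues(p, "fdr_bh") < alpha).sum())
            hits_s1 += k > 0
            hits_final += k > 0
        else:
            k1, k2 = _two_stage_rejections(X, y, split_fraction, alpha, rng)
            hits_s1 += k1 > 0
            hits_final += k2 > 0
    est = hits_final / n_reps
    ci = proportion_confint(hits_final, n_reps, alpha=0.05, method="wilson")
    est1 = hits_s1 / n_reps
    ci1 = proportion_confint(hits_s1, n_reps, alpha=0.05, method="wilson")
    return SimulationReport(
        n_reps=n_reps,
        config={"m": m, "n": n, "alpha": alpha, "stages": stages,
                "split_fraction": split_fraction, "correction": "fdr_bh",
                "seed": seed},
        fwer=est, fwer_ci=tuple(ci),
        stage1_fwer=est1, stage1_ci=tuple(ci1),
    )


def estimate_power(
    planted: list[float],
    m: int = 920,
    n: int = 500,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
    split_fraction: float = 0.75,
    noise_sd: float = 1.0,
) -> SimulationReport:
    """Per-effect share of replicates in which a planted variable survives
    both stages of the two-stage procedure.

    The first len(planted) exposure columns carry the planted slopes (on the
    same scale as the outcome); the remaining columns are null.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if len(planted) > m:
        raise ConfigError("more planted effects than tests")
    rng = np.random.default_rng(seed)
    betas = np.asarray(planted, dtype=float)
    survive = np.zeros(len(betas), dtype=int)
    for _ in range(n_reps):
        X = rng.standard_normal((n, m))
        y = X[:, : len(betas)] @ betas + noise_sd * rng.standard_normal(n)
        perm = rng.permutation(n)
        n_disc = _split_sizes(n, split_fraction)
        disc, test = perm[:n_disc], perm[n_disc:]
        p_disc = simple_regression_pvalues(X[disc], y[disc])
        sig = adjust_pvalues(p_disc, "fdr_bh") < alpha
        if not sig.any():
            continue
        p_test = simple_regression_pvalues(X[test][:, sig], y[test])
        surv_idx = np.flatnonzero(sig)[adjust_pvalues(p_test, "fdr_bh") < alpha]
        survive += np.isin(np.arange(len(betas)), surv_idx)
    power = {}
    for i, b in enumerate(betas):
        ci = proportion_confint(int(survive[i]), n_reps, alpha=0.05, method="wilson")
        power[float(b)] = (survive[i] / n_reps, tuple(ci))
    return SimulationReport(
        n_reps=n_reps,
        config={"m": m, "n": n, "alpha": alpha, "stages": 2,
                "split_fraction": split_fraction, "seed": seed},
        power=power,
    )
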