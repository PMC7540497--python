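"""Single imputation of missing covariate values by chained equations.

Only covariates are imputed (exposures are analyzed complete-case per
variable). Each sweep visits covariates in descending order of initial
missingness and refits a conditional model on all other covariates plus the
outcome: ordinary least squares for continuous covariates (with a seeded
residual-scale noise draw), and a linear model on integer category codes
snapped back to the nearest observed code for categoricals. Observed values
are never altered and imputed categories always come from the observed
label set. The per-iteration mean absolute change of imputed values is
recorded as a convergence trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class ImputationModel:
    """Description and convergence record of one chained-equations run."""

    covariates: list[str]
    model_types: dict[str, str]
    n_iter: int
    seed: int
    trace: list[float] = field(default_factory=list)  # mean |change| per sweep


def _is_categorical(col: pd.Series) -> bool:
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)


def impute_covariates(
    table: pd.DataFrame,
    covariates: list[str],
    outcome: str | None = None,
    n_iter: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, ImputationModel]:
    """Return a copy of `table` with the listed covariates completed.

    `outcome`, when given, names a numeric column used as an extra predictor
    in every conditional model (standard practice so that imputation does
    not attenuate exposure-outcome associations).
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    missing_cols = [c for c in covariates if c not in table.columns]
    if missing_cols:
        raise ConfigError(f"covariates absent from table: {missing_cols}")
    for c in covariates:
        if table[c].notna().sum() == 0:
            raise ConfigError(f"covariate {c!r} is fully missing; cannot impute")

    rng = np.random.default_rng(seed)
    work = table.copy()

    # numeric coding: categoricals -> integer codes over observed labels
    codes: dict[str, list] = {}
    model_types: dict[str, str] = {}
    Z = pd.DataFrame(index=table.index)
    for c in covariates:
        col = work[c]
        if _is_categorical(col):
            labels = sorted(col.dropna().astype(str).unique())
            codes[c] = labels
            lut = {lbl: i for i, lbl in enumerate(labels)}
            Z[c] = col.astype(str).map(lut).where(col.notna(), np.nan)
            model_types[c] = "categorical_score"
        else:
            Z[c] = pd.to_numeric(col, errors="coerce")
            model_types[c] = "linear"

    obs_mask = {c: Z[c].notna().to_numpy() for c in covariates}
    targets = [c for c in covariates if not obs_mask[c].all()]
    # sweep order: descending missingness
    targets.sort(key=lambda c: (-(~obs_mask[c]).mean(), covariates.index(c)))

    # initial fill: observed mean (continuous) / mode (categorical)
    for c in targets:
        col = Z[c]
        if model_types[c] == "categorical_score":
            fill = col.dropna().mode().iloc[0]
        else:
            fill = col.dropna().mean()
        Z.loc[~obs_mask[c], c] = fill

    y_pred = None
    if outcome is not None:
        y_pred = pd.to_numeric(table[outcome], errors="coerce")
        y_pred = y_pred.fillna(y_pred.mean()).to_numpy()

    model = ImputationModel(
        covariates=list(covariates), model_types=model_types, n_iter=n_iter, seed=seed
    )

    for _ in range(n_iter):
        total_change, n_imputed = 0.0, 0
        for c in targets:
            miss = ~obs_mask[c]
            predictors = [p for p in covariates if p != c]
            X = Z[predictors].to_numpy(dtype=float)
            if y_pred is not None:
                X = np.column_stack([X, y_pred])
            X = np.column_stack([np.ones(len(X)), X])
            z = Z[c].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X[~miss], z[~miss], rcond=None)
            fitted = X @ beta
            resid_sd = float(np.std(z[~miss] - fitted[~miss]))
            pred = fitted[miss]
            if model_types[c] == "linear":
                pred = pred + rng.normal(0.0, resid_sd, size=miss.sum())
            else:
                valid = np.arange(len(codes[c]), dtype=float)
                pred = valid[np.abs(pred[:, None] - valid[None, :]).argmin(axis=1)]
            old = z[miss]
            total_change += float(np.abs(pred - old).sum())
            n_imputed += int(miss.sum())
            z[miss] = pred
            Z[c] = z
        model.trace.append(total_change / n_imputed if n_imputed else 0.0)

    out = table.copy()
    for c in covariates:
        if model_types[c] == "categorical_score":
            labels = codes[c]
            out[c] = Z[c].round().clip(0, len(labels) - 1).astype(int).map(
                dict(enumerate(labels))
            )
        else:
            out[c] = Z[c]
        # contract: observed values are never altered
        out.loc[obs_mask[c], c] = table.loc[obs_mask[c], c]
    return out, model
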