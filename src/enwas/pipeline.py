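"""End-to-end orchestration: raw table + dictionary -> scan results.

The stages run in the fixed study order: harmonization, the QC exclusion
cascade (on exposures only), SRS outcome scoring, covariate imputation by
chained equations, then the two-stage scan (or a sensitivity variant).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dictionary import DataDictionary
from .harmonize import HarmonizeResult, harmonize_table
from .impute import ImputationModel, impute_covariates
from .outcome import score_srs
from .qc import FilterReport, apply_qc_cascade
from .scan import CohortData, ScanConfig, ScanResult, VariableMeta, run_enwas, run_sensitivity
from .synthetic import COVARIATE_COLUMNS, FLAG_COLUMNS, SRS_PREFIX


@dataclass
class PipelineResult:
    scan: ScanResult
    cohort: CohortData
    harmonized: HarmonizeResult
    filter_report: FilterReport
    imputation: ImputationModel
    outcome: pd.DataFrame


def build_cohort_data(
    table: pd.DataFrame,
    dictionary: DataDictionary,
    covariate_columns: list[str] | None = None,
    flag_columns: list[str] | None = None,
    item_prefix: str = SRS_PREFIX,
    constancy_threshold: float = 0.95,
    subject_threshold: float = 0.60,
    variable_threshold: float = 0.50,
    impute_iters: int = 10,
    seed: int = 0,
) -> tuple[CohortData, HarmonizeResult, FilterReport, ImputationModel, pd.DataFrame]:
    """Harmonize, filter, score and impute a raw cohort into a CohortData."""
    covariate_columns = covariate_columns or [
        c for c in COVARIATE_COLUMNS if c in table.columns
    ]
    flag_columns = flag_columns or [c for c in FLAG_COLUMNS if c in table.columns]

    harm = harmonize_table(table[[c for c in table.columns if c in dictionary]],
                           dictionary)
    filtered, freport = apply_qc_cascade(
        harm.data, constancy_threshold, subject_threshold, variable_threshold
    )
    kept = filtered.index

    item_cols = [c for c in table.columns if c.startswith(item_prefix)]
    scored = score_srs(table.loc[kept, item_cols])

    imputed, imodel = impute_covariates(
        pd.concat([table.loc[kept, covariate_columns], scored[["y"]]], axis=1),
        covariates=covariate_columns,
        outcome="y",
        n_iter=impute_iters,
        seed=seed,
    )

    meta = {
        name: VariableMeta(hv.domain, hv.var_type, hv.levels)
        for name, hv in harm.variables.items()
        if name in filtered.columns
    }
    cohort = CohortData(
        exposures=filtered,
        meta=meta,
        covariates=imputed[covariate_columns],
        y=scored["y"],
        flags=table.loc[kept, flag_columns] if flag_columns else None,
    )
    return cohort, harm, freport, imodel, scored


def run_pipeline(
    table: pd.DataFrame,
    dictionary: DataDictionary,
    config: ScanConfig,
    **build_kwargs,
) -> PipelineResult:
    """Run the whole study pipeline on a raw cohort table."""
    cohort, harm, freport, imodel, scored = build_cohort_data(
        table, dictionary, seed=config.seed, **build_kwargs
    )
    if config.sensitivity and config.sensitivity != "none":
        scan = run_sensitivity(cohort, config, config.sensitivity)
    else:
        scan = run_enwas(cohort, config)
    return PipelineResult(
        scan=scan, cohort=cohort, harmonized=harm,
        filter_report=freport, imputation=imodel, outcome=scored,
    )
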