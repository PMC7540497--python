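"""Dataset-level exclusion cascade for exposures and subjects.

Three filters are applied in a fixed order, each with a strict ">" boundary:

1. drop variables where more than 95% of respondents gave the same answer
   (near-constant variables carry rare, inflatable effects);
2. drop subjects with more than 60% missingness over the remaining variables;
3. drop variables that still have over 50% missing data.

Modal share is computed among nonmissing respondents; missingness is handled
only by the missingness filters. All thresholds are configurable so the same
robustness sweep the design allows can be re-run.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class FilterReport:
    """Audit of the exclusion cascade: what was dropped, when, and why."""

    thresholds: dict = field(default_factory=dict)
    dropped_constant: list = field(default_factory=list)
    dropped_sparse_vars: list = field(default_factory=list)
    dropped_subjects: list = field(default_factory=list)
    steps: list = field(default_factory=list)  # (step, before, after) shape tuples

    def record_step(self, step: str, before: tuple, after: tuple) -> None:
        self.steps.append({"step": step, "before": list(before), "after": list(after)})

    def validate(self) -> None:
        for s in self.steps:
            if s["step"] == "constancy":
                assert s["before"][1] - s["after"][1] == len(self.dropped_constant)
            elif s["step"] == "subjects":
                assert s["before"][0] - s["after"][0] == len(self.dropped_subjects)
            elif s["step"] == "variables":
                assert s["before"][1] - s["after"][1] == len(self.dropped_sparse_vars)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "thresholds": self.thresholds,
                    "dropped_constant": list(map(str, self.dropped_constant)),
                    "dropped_sparse_vars": list(map(str, self.dropped_sparse_vars)),
                    "dropped_subjects": [str(s) for s in self.dropped_subjects],
                    "steps": self.steps,
                },
                indent=1,
            )
        )


def _modal_share(col: pd.Series) -> float:
    nonmissing = col.dropna()
    if len(nonmissing) == 0:
        return 1.0
    return nonmissing.value_counts().iloc[0] / len(nonmissing)


def drop_low_information(
    table: pd.DataFrame,
    constancy_threshold: float = 0.95,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop variables whose modal answer covers more than the threshold share."""
    report = report or FilterReport()
    report.thresholds["constancy"] = constancy_threshold
    before = table.shape
    dropped = [c for c in table.columns if _modal_share(table[c]) > constancy_threshold]
    out = table.drop(columns=dropped)
    report.dropped_constant = dropped
    report.record_step("constancy", before, out.shape)
    return out, report


def drop_sparse_subjects(
    table: pd.DataFrame,
    subject_threshold: float = 0.60,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop subjects missing more than the threshold share of variables."""
    report = report or FilterReport()
    report.thresholds["subjects"] = subject_threshold
    before = table.shape
    missing_share = table.isna().mean(axis=1)
    dropped = table.index[missing_share > subject_threshold]
    out = table.drop(index=dropped)
    report.dropped_subjects = list(dropped)
    report.record_step("subjects", before, out.shape)
    return out, report


def drop_sparse_variables(
    table: pd.DataFrame,
    variable_threshold: float = 0.50,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop variables with more than the threshold share missing."""
    report = report or FilterReport()
    report.thresholds["variables"] = variable_threshold
    before = table.shape
    missing_share = table.isna().mean(axis=0)
    dropped = list(missing_share.index[missing_share > variable_threshold])
    out = table.drop(columns=dropped)
    report.dropped_sparse_vars = dropped
    report.record_step("variables", before, out.shape)
    return out, report


def apply_qc_cascade(
    table: pd.DataFrame,
    constancy_threshold: float = 0.95,
    subject_threshold: float = 0.60,
    variable_threshold: float = 0.50,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade (constancy -> subjects -> variables) in order."""
    report = FilterReport()
    table, report = drop_low_information(table, constancy_threshold, report)
    table, report = drop_sparse_subjects(table, subject_threshold, report)
    table, report = drop_sparse_variables(table, variable_threshold, report)
    report.validate()
    return table, report
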