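"""Scoring of the 18-item short-form SRS outcome.

Each item is parent-rated 0 ("never true") to 3 ("almost always true").
A subject's record is excluded when over 25% of items are missing;
otherwise the mean item score is the mean of the nonmissing items, the
weighted total is 18 x that mean (so fully observed subjects recover the
plain item sum), and the regression outcome is the square root of the mean
item score, which symmetrizes the right-skewed score distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

N_ITEMS = 18
MAX_MISSING = 0.25


@dataclass
class OutcomeRecord:
    subject: object
    n_items_present: int
    excluded: bool
    mean_item_score: float  # NaN when excluded
    weighted_total: float
    y: float  # sqrt(mean item score); NaN when excluded


def score_srs(items: pd.DataFrame, max_missing: float = MAX_MISSING) -> pd.DataFrame:
    """Score an 18-column item matrix into outcome columns.

    Returns a frame indexed like `items` with columns ``n_items_present``,
    ``excluded``, ``mean_item_score``, ``weighted_total`` and ``y``.
    Item values must be in {0, 1, 2, 3} or missing.
    """
    if items.shape[1] != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} item columns, got {items.shape[1]}")
    values = items.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    bad = observed & (~np.isin(values, [0.0, 1.0, 2.0, 3.0]))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"item value {values[r, c]!r} outside 0..3 "
            f"(subject {items.index[r]!r}, item {items.columns[c]!r})"
        )
    n_present = observed.sum(axis=1)
    missing_share = 1.0 - n_present / N_ITEMS
    excluded = missing_share > max_missing
    with np.errstate(invalid="ignore"):
        mean_score = np.nansum(values, axis=1) / np.where(n_present > 0, n_present, np.nan)
    mean_score = np.where(excluded, np.nan, mean_score)
    out = pd.DataFrame(
        {
            "n_items_present": n_present,
            "excluded": excluded,
            "mean_item_score": mean_score,
            "weighted_total": N_ITEMS * mean_score,
            "y": np.sqrt(mean_score),
        },
        index=items.index,
    )
    return out


def score_srs_record(item_values, subject=None, max_missing: float = MAX_MISSING) -> OutcomeRecord:
    """Score a single subject's 18 item values (scalar-record convenience)."""
    frame = pd.DataFrame([list(item_values)], index=[subject])
    row = score_srs(frame, max_missing=max_missing).iloc[0]
    return OutcomeRecord(
        subject=subject,
        n_items_present=int(row["n_items_present"]),
        excluded=bool(row["excluded"]),
        mean_item_score=float(row["mean_item_score"]),
        weighted_total=float(row["weighted_total"]),
        y=float(row["y"]),
    )


def attach_outcome(
    table: pd.DataFrame, item_prefix: str = "srs_", max_missing: float = MAX_MISSING
) -> pd.DataFrame:
    """Score the SRS item columns of a cohort table and append derived columns."""
    item_cols = [c for c in table.columns if c.startswith(item_prefix)]
    scored = score_srs(table[item_cols], max_missing=max_missing)
    out = table.copy()
    for col in scored.columns:
        out[col] = scored[col]
    return out
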