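"""Presentation artifacts: Manhattan plots, correlation heatmap, tables.

Every figure and table is a pure function of a results table (plus a plot
spec), so artifacts regenerate byte-identically from saved results.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Default domain palette (10 topical domains).
DEFAULT_COLORS = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass
class PlotSpec:
    alpha: float = 0.05
    domain_order: list[str] | None = None
    colors: list[str] = field(default_factory=lambda: list(DEFAULT_COLORS))
    raw_p_axis: bool = False  # y-axis on raw p instead of FDR-adjusted p
    fmt: str = "png"


def _adjusted_threshold(p_raw: np.ndarray, p_adj: np.ndarray, t: float) -> float:
    """Position of a raw-scale threshold on the adjusted-p axis.

    Uses the empirical monotone raw -> adjusted step map: the smallest
    adjusted p among variables with raw p >= t. A variable with raw p
    exactly t therefore sits exactly on the line, and a variable is above
    the line iff its raw p is below t.
    """
    order = np.argsort(p_raw)
    p_raw, p_adj = p_raw[order], np.minimum.accumulate(p_adj[order][::-1])[::-1]
    at_or_above = p_raw >= t
    if at_or_above.any():
        return float(p_adj[at_or_above][0])
    return min(1.0, t * len(p_raw))  # extrapolate past the largest observed p


def manhattan_plot(
    results: pd.DataFrame,
    spec: PlotSpec | None = None,
    path: str | Path | None = None,
    stage: str | None = None,
) -> plt.Figure:
    """One point per tested variable, colored by domain, with the three
    significance threshold lines (green uncorrected 0.05, red FDR 0.05,
    purple Bonferroni 0.05)."""
    spec = spec or PlotSpec()
    if stage is None:
        stage = results["stage"].iloc[0]
    df = results[results["stage"] == stage].drop_duplicates("variable")
    if df.empty:
        raise ValidationError("no results to plot")
    domains = spec.domain_order or list(dict.fromkeys(df["domain"]))
    unknown = set(df["domain"]) - set(domains)
    if unknown:
        raise ValidationError(f"unknown domain labels: {sorted(unknown)}")
    df = df.copy()
    df["_dom_i"] = df["domain"].map({d: i for i, d in enumerate(domains)})
    df = df.sort_values(["_dom_i", "variable"], kind="mergesort").reset_index(drop=True)

    p_raw = df["p_joint"].to_numpy(float)
    p_adj = df["p_fdr"].to_numpy(float)
    m = len(df)
    floor = np.finfo(float).tiny
    if spec.raw_p_axis:
        yvals = -np.log10(np.maximum(p_raw, floor))
        lines = {
            "green": -np.log10(spec.alpha),
            "red": -np.log10(_bh_raw_cutoff(p_raw, spec.alpha)),
            "purple": -np.log10(spec.alpha / m),
        }
    else:
        yvals = -np.log10(np.maximum(p_adj, floor))
        lines = {
            "green": -np.log10(max(_adjusted_threshold(p_raw, p_adj, spec.alpha), floor)),
            "red": -np.log10(spec.alpha),
            "purple": -np.log10(
                max(_adjusted_threshold(p_raw, p_adj, spec.alpha / m), floor)
            ),
        }

    fig, ax = plt.subplots(figsize=(12, 4.5))
    for i, dom in enumerate(domains):
        sub = df[df["domain"] == dom]
        ax.scatter(sub.index, yvals[sub.index], s=8,
                   color=spec.colors[i % len(spec.colors)], label=dom)
    for color, yline in lines.items():
        ax.axhline(yline, color=color, lw=1)
    ax.set_xlabel("variable (grouped by domain)")
    ax.set_ylabel("-log10 p" if spec.raw_p_axis else "-log10 FDR-adjusted p")
    ax.set_title(f"{stage} stage: {m} variables")
    ax.legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata=_stable_metadata(Path(path).suffix))
    return fig


def _bh_raw_cutoff(p_raw: np.ndarray, alpha: float) -> float:
    m = len(p_raw)
    ps = np.sort(p_raw)
    passed = ps <= alpha * np.arange(1, m + 1) / m
    if passed.any():
        return float(ps[np.flatnonzero(passed)[-1]])
    return alpha / m


def _stable_metadata(suffix: str) -> dict | None:
    # strip the creation date so regeneration is byte-identical
    if suffix.lower() == ".svg":
        return {"Date": None}
    return None


def numeric_coding(table: pd.DataFrame) -> pd.DataFrame:
    """Code a mixed-type table numerically (category labels -> sorted codes)."""
    out = {}
    for c in table.columns:
        col = table[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            labels = sorted(col.dropna().astype(str).unique())
            lut = {lbl: float(i) for i, lbl in enumerate(labels)}
            out[c] = col.astype(str).map(lut).where(col.notna(), np.nan)
        else:
            out[c] = pd.to_numeric(col, errors="coerce")
    return pd.DataFrame(out, index=table.index)


def covariance_heatmap(
    table: pd.DataFrame,
    domains: dict[str, str] | None = None,
    path: str | Path | None = None,
) -> tuple[plt.Figure, pd.DataFrame]:
    """Pairwise-complete correlation heatmap, variables ordered by domain.

    Red is positive, blue negative (diverging palette, fixed [-1, 1] range).
    Returns the figure and the correlation matrix.
    """
    if table.shape[1] < 2:
        raise ValidationError("need at least two variables")
    cols = list(table.columns)
    if domains:
        order = list(dict.fromkeys(domains.values()))
        cols = sorted(cols, key=lambda c: (order.index(domains.get(c, order[0])), cols.index(c)))
    corr = numeric_coding(table[cols]).corr(method="pearson", min_periods=2)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="correlation")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("pairwise-complete correlation (domain order)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata=_stable_metadata(Path(path).suffix))
    return fig, corr


def nonresponse_comparison(
    included: pd.DataFrame, excluded: pd.DataFrame, compare_on: list[str]
) -> pd.DataFrame:
    """Compare included vs excluded subjects on the listed variables.

    Continuous variables get group means, mean difference and a two-sided
    t-test p; categoricals get modal-level proportions, their difference and
    a chi-square p over the full contingency table.
    """
    if len(included) == 0 or len(excluded) == 0:
        raise ValidationError("both groups must be nonempty")
    rows = []
    for var in compare_on:
        a, b = included[var].dropna(), excluded[var].dropna()
        if a.dtype == object or b.dtype == object:
            a, b = a.astype(str), b.astype(str)
            levels = sorted(set(a) | set(b))
            ca = a.value_counts().reindex(levels, fill_value=0)
            cb = b.value_counts().reindex(levels, fill_value=0)
            tbl = np.array([ca.to_numpy(), cb.to_numpy()])
            keep = tbl.sum(axis=0) > 0
            p = float(stats.chi2_contingency(tbl[:, keep])[1]) if keep.sum() > 1 else 1.0
            modal = ca.idxmax()
            ga, gb = ca[modal] / len(a), cb[modal] / len(b)
            rows.append({"variable": var, "kind": "categorical",
                         "included": ga, "excluded": gb,
                         "difference": ga - gb, "p": p,
                         "note": f"proportion {modal!r}"})
        else:
            t, p = stats.ttest_ind(a.astype(float), b.astype(float), equal_var=False)
            rows.append({"variable": var, "kind": "continuous",
                         "included": float(a.mean()), "excluded": float(b.mean()),
                         "difference": float(a.mean() - b.mean()), "p": float(p),
                         "note": "mean"})
    return pd.DataFrame(rows)


def counts_table(reports: dict[str, object]) -> pd.DataFrame:
    """Tabulate per-configuration significant-variable counts.

    Rows: one per analysis configuration (plus per-domain rows for any
    report carrying domain counts); columns: total, p<0.05 and
    FDR-significant counts for the discovery and test stages.
    """
    rows = []
    for name, report in reports.items():
        sc = report.stage_counts
        disc = sc.get("discovery") or sc.get("combined") or {}
        test = sc.get("test") or {}
        rows.append({
            "analysis": name,
            "disc_total": disc.get("total", 0),
            "disc_p<0.05": disc.get("p<0.05", 0),
            "disc_fdr": disc.get("fdr", 0),
            "test_total": test.get("total", 0),
            "test_p<0.05": test.get("p<0.05", 0),
            "test_fdr": test.get("fdr", 0),
        })
        if report.domain_counts is not None:
            dc = report.domain_counts
            for dom in dict.fromkeys(dc["domain"]):
                d = dc[(dc["stage"].isin(["discovery", "combined"])) & (dc["domain"] == dom)]
                t = dc[(dc["stage"] == "test") & (dc["domain"] == dom)]
                rows.append({
                    "analysis": f"{name}:{dom}",
                    "disc_total": int(d["tested"].sum()),
                    "disc_p<0.05": int(d["p<0.05"].sum()),
                    "disc_fdr": int(d["fdr"].sum()),
                    "test_total": int(t["tested"].sum()) if len(t) else 0,
                    "test_p<0.05": int(t["p<0.05"].sum()) if len(t) else 0,
                    "test_fdr": int(t["fdr"].sum()) if len(t) else 0,
                })
    return pd.DataFrame(rows)
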