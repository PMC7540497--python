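"""Rule-based harmonization of dictionary-annotated questionnaire variables.

Raw cohort variables are transformed into analysis-ready form by a fixed,
auditable per-variable algorithm:

1. conditional (skip-logic) questions are merged into their parent question,
   so e.g. "Have you ever smoked?" + "Do you still smoke?" become one
   variable with levels Never smoked / Past smoker / Current smoker;
2. "Do not know"-style answers, which carry no information, become missing;
3. sparsely populated or lopsided category sets are collapsed to three
   informative levels, and residual sparse categories are pooled.

Every transformation appends an audit record (a JSON-serializable dict) that
maps raw labels to harmonized labels, so the harmonized values can be
reconstructed deterministically from the raw values (`replay_audit`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionary import CONTINUOUS, ORDERED, UNORDERED, DataDictionary, VariableRecord
from .errors import ClassificationError, DictionaryError

DEFAULT_LOPSIDED = 0.5
DEFAULT_CENTERED = 0.4
DEFAULT_SPARSE = 0.05


@dataclass
class HarmonizedVariable:
    """An analysis-ready variable plus the audit trail that produced it."""

    name: str
    domain: str
    var_type: str
    values: pd.Series
    levels: list[str] | None = None
    audit: list[dict] = field(default_factory=list)

    @property
    def observed_levels(self) -> list[str]:
        observed = set(self.values.dropna().astype(str))
        if self.levels:
            return [lvl for lvl in self.levels if lvl in observed]
        return sorted(observed)


def classify_variable(var: VariableRecord) -> tuple[str, bool]:
    """Return the variable's type label and whether it had to be inferred.

    Declared types are returned as-is. Otherwise: numeric values with more
    than 10 distinct levels are continuous, declared (ordered) level lists
    give an ordered categorical, and anything else is unordered. Mixing
    numeric and text values without a declaration is an error.
    """
    if var.var_type is not None:
        return var.var_type, False
    nonmissing = var.values.dropna()
    nonmissing = nonmissing[~nonmissing.astype(str).isin(var.dont_know_labels)]
    if len(nonmissing) == 0:
        return (ORDERED if var.levels else UNORDERED), True
    numeric = pd.to_numeric(nonmissing, errors="coerce")
    n_num = numeric.notna().sum()
    if 0 < n_num < len(nonmissing):
        raise ClassificationError(
            f"{var.name}: mixed numeric/text values without a declared type"
        )
    if n_num == len(nonmissing) and numeric.nunique() > 10:
        return CONTINUOUS, True
    if var.levels:
        return ORDERED, True
    return UNORDERED, True


def merge_conditional(
    parent: VariableRecord,
    child: VariableRecord,
    labels: dict[str, str] | None = None,
) -> HarmonizedVariable:
    """Merge a conditional question into its parent question.

    The combined variable has one level per non-gate parent answer and one
    level per child answer within the gate branch (named ``"gate:child"`` by
    default; `labels` may rename any combined level). Subjects missing the
    parent, or inside the gate but missing the child, are missing.
    """
    if child.parent != parent.name:
        raise DictionaryError(f"{child.name}: parent is not {parent.name!r}")
    gate = str(child.parent_gate)
    parent_levels = [str(x) for x in (parent.levels or parent.observed_levels)]
    if gate not in parent_levels:
        raise DictionaryError(
            f"{child.name}: gate {gate!r} is not a level of {parent.name!r}"
        )
    child_levels = [str(x) for x in (child.levels or child.observed_levels)]
    labels = labels or {}

    nongate_map = {
        lvl: labels.get(lvl, lvl) for lvl in parent_levels if lvl != gate
    }
    gate_map = {
        lvl: labels.get(f"{gate}:{lvl}", f"{gate}:{lvl}") for lvl in child_levels
    }

    p = parent.values.astype("object").where(parent.values.notna(), np.nan)
    c = child.values.astype("object").where(child.values.notna(), np.nan)
    p_str = p.astype(str).where(p.notna(), np.nan)
    c_str = c.astype(str).where(c.notna(), np.nan)

    merged = pd.Series(np.nan, index=parent.values.index, dtype="object")
    nongate_mask = p.notna() & (p_str != gate)
    merged[nongate_mask] = p_str[nongate_mask].map(nongate_map)
    gate_mask = p.notna() & (p_str == gate) & c.notna()
    merged[gate_mask] = c_str[gate_mask].map(gate_map)

    # Ordered semantics survive the merge only in the binary-parent case
    # (e.g. Never < Past < Current); otherwise the result is unordered.
    if len(parent_levels) == 2 and child.var_type == ORDERED:
        var_type = ORDERED
    else:
        var_type = UNORDERED
    merged_levels = list(nongate_map.values()) + list(gate_map.values())

    audit = [
        {
            "op": "merge_conditional",
            "variable": parent.name,
            "parent": parent.name,
            "child": child.name,
            "gate": gate,
            "nongate_map": nongate_map,
            "gate_map": gate_map,
        }
    ]
    return HarmonizedVariable(
        name=parent.name,
        domain=parent.domain,
        var_type=var_type,
        values=merged,
        levels=merged_levels,
        audit=audit,
    )


def _as_harmonized(var: VariableRecord | HarmonizedVariable) -> HarmonizedVariable:
    if isinstance(var, HarmonizedVariable):
        return var
    var_type, inferred = classify_variable(var)
    audit = []
    if inferred:
        audit.append({"op": "classify_inferred", "variable": var.name, "type": var_type})
    return HarmonizedVariable(
        name=var.name,
        domain=var.domain,
        var_type=var_type,
        values=var.values,
        levels=[str(x) for x in var.levels] if var.levels else None,
        audit=audit,
    )


def recode_dont_know(
    var: VariableRecord | HarmonizedVariable,
    dont_know_labels: frozenset | set | None = None,
) -> HarmonizedVariable:
    """Recode "no information" answers (e.g. "Do not know") as missing."""
    dk = set(
        dont_know_labels
        if dont_know_labels is not None
        else getattr(var, "dont_know_labels", frozenset())
    )
    hv = _as_harmonized(var)
    if not dk:
        return hv
    values = hv.values.copy()
    present = values.astype(str).isin(dk) & values.notna()
    values[present] = np.nan
    levels = [lvl for lvl in hv.levels if lvl not in dk] if hv.levels else None
    if hv.var_type == CONTINUOUS:
        values = pd.to_numeric(values, errors="coerce")
    audit = hv.audit + [
        {"op": "dk_recode", "variable": hv.name, "map": {lbl: None for lbl in sorted(dk)}}
    ]
    return HarmonizedVariable(hv.name, hv.domain, hv.var_type, values, levels, audit)


def _joined(levels: list[str]) -> str:
    return "+".join(levels)


def _shares(values: pd.Series, levels: list[str]) -> dict[str, float]:
    counts = values.dropna().astype(str).value_counts()
    total = counts.sum()
    return {lvl: (counts.get(lvl, 0) / total if total else 0.0) for lvl in levels}


def _apply_map(hv: HarmonizedVariable, mapping: dict[str, str], new_levels: list[str],
               rule: str) -> HarmonizedVariable:
    values = hv.values.copy()
    mask = values.notna()
    values[mask] = values[mask].astype(str).map(lambda v: mapping.get(v, v))
    audit = hv.audit + [
        {"op": "collapse", "variable": hv.name, "rule": rule, "map": mapping}
    ]
    return HarmonizedVariable(hv.name, hv.domain, hv.var_type, values, new_levels, audit)


def collapse_categories(
    var: HarmonizedVariable,
    lopsided_threshold: float = DEFAULT_LOPSIDED,
    centered_threshold: float = DEFAULT_CENTERED,
    sparse_threshold: float = DEFAULT_SPARSE,
) -> HarmonizedVariable:
    """Collapse uninformative category patterns to at most three levels.

    Rules are applied in a fixed order:

    a. ordered with >= 4 levels whose terminal category holds at least
       `lopsided_threshold` of responses -> terminal / adjacent band / rest;
    b. ordered with >= 5 levels whose middle category is modal and holds at
       least `centered_threshold` -> left of middle / middle / right;
    c. any category below `sparse_threshold` is merged into its nearest
       neighbor (ordered) or a pooled "other" level (unordered), repeatedly.
    """
    if var.var_type == CONTINUOUS:
        return var
    hv = var
    levels = hv.observed_levels
    if len(levels) < 2:
        return hv

    # rule a: lopsided ordered scale
    if hv.var_type == ORDERED and len(levels) >= 4:
        shares = _shares(hv.values, levels)
        first, last = shares[levels[0]], shares[levels[-1]]
        side = None
        if first >= lopsided_threshold and first >= last:
            side = "left"
        elif last >= lopsided_threshold:
            side = "right"
        if side is not None:
            ordered = levels if side == "left" else levels[::-1]
            band_n = (len(levels) - 1) // 2
            terminal, band, rest = ordered[0], ordered[1 : 1 + band_n], ordered[1 + band_n :]
            if side == "right":
                band, rest = band[::-1], rest[::-1]
            groups = [[terminal], band, rest] if side == "left" else [rest, band, [terminal]]
            mapping = {lvl: _joined(g) for g in groups for lvl in g}
            new_levels = [_joined(g) for g in groups]
            hv = _apply_map(hv, mapping, new_levels, "lopsided")
            levels = hv.observed_levels

    # rule b: center-heavy ordered scale
    if hv.var_type == ORDERED and len(levels) >= 5:
        shares = _shares(hv.values, levels)
        k = len(levels)
        mid_candidates = [k // 2] if k % 2 else [k // 2 - 1, k // 2]
        mid = max(mid_candidates, key=lambda i: shares[levels[i]])
        mid_share = shares[levels[mid]]
        if mid_share >= centered_threshold and mid_share == max(shares.values()):
            groups = [levels[:mid], [levels[mid]], levels[mid + 1 :]]
            mapping = {lvl: _joined(g) for g in groups for lvl in g}
            hv = _apply_map(hv, mapping, [_joined(g) for g in groups], "centered")
            levels = hv.observed_levels

    # rule c: pool sparse categories until none remain (or only 2 levels)
    while True:
        levels = hv.observed_levels
        if len(levels) <= 2:
            break
        shares = _shares(hv.values, levels)
        sparse = [lvl for lvl in levels if shares[lvl] < sparse_threshold]
        if not sparse:
            break
        target = min(sparse, key=lambda lvl: (shares[lvl], levels.index(lvl)))
        if hv.var_type == ORDERED:
            i = levels.index(target)
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(levels)]
            j = min(neighbors, key=lambda j: (shares[levels[j]], j))
            lo, hi = sorted((i, j))
            merged_label = _joined([levels[lo], levels[hi]])
            mapping = {levels[lo]: merged_label, levels[hi]: merged_label}
            new_levels = levels[:lo] + [merged_label] + levels[hi + 1 :]
        else:
            pool = [lvl for lvl in sparse if lvl != "other"]
            if not pool:  # "other" itself sparse: absorb the smallest remaining level
                rest = [lvl for lvl in levels if lvl != "other"]
                pool = [min(rest, key=lambda lvl: (shares[lvl], levels.index(lvl)))]
            mapping = {lvl: "other" for lvl in pool}
            new_levels = [lvl for lvl in levels if lvl not in pool]
            if "other" not in new_levels:
                new_levels.append("other")
        hv = _apply_map(hv, mapping, new_levels, "sparse")
    return hv


def replay_audit(audit: list[dict], raw: pd.DataFrame) -> pd.Series:
    """Recompute a variable's harmonized values from raw columns via its audit.

    The audit is the authoritative record: replaying it must reproduce the
    harmonized values exactly (round-trip property).
    """
    values: pd.Series | None = None
    var_name = None
    for entry in audit:
        op = entry["op"]
        if op == "merge_conditional":
            gate = entry["gate"]
            p = raw[entry["parent"]]
            c = raw[entry["child"]]
            p_str = p.astype(str).where(p.notna(), np.nan)
            c_str = c.astype(str).where(c.notna(), np.nan)
            values = pd.Series(np.nan, index=raw.index, dtype="object")
            nongate = p.notna() & (p_str != gate)
            values[nongate] = p_str[nongate].map(entry["nongate_map"])
            g = p.notna() & (p_str == gate) & c.notna()
            values[g] = c_str[g].map(entry["gate_map"])
            var_name = entry["parent"]
        elif op == "classify_inferred":
            var_name = entry["variable"]
        elif op in ("dk_recode", "collapse"):
            if values is None:
                var_name = entry["variable"]
                values = raw[var_name].copy()
            mask = values.notna()
            mapping = entry["map"]
            values[mask] = values[mask].astype(str).map(
                lambda v: mapping[v] if v in mapping else v
            )
            values = values.where(values.notna(), np.nan)
        else:  # pragma: no cover - future ops
            raise ValueError(f"unknown audit op {op!r}")
    if values is None:
        values = raw[var_name].copy() if var_name else None
    if values is None:
        raise ValueError("empty audit with no variable reference")
    return values


@dataclass
class HarmonizeResult:
    """Harmonized exposure table plus per-variable metadata and audit log."""

    data: pd.DataFrame
    variables: dict[str, HarmonizedVariable]
    audit: list[dict]

    def to_dictionary(self) -> DataDictionary:
        """Dictionary describing the harmonized (post-transformation) variables."""
        entries = {}
        for name, hv in self.variables.items():
            entries[name] = {
                "name": name,
                "domain": hv.domain,
                "type": hv.var_type,
                "levels": list(hv.levels) if hv.levels else None,
            }
        return DataDictionary(entries)

    def write_audit(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for rec in self.audit:
                fh.write(json.dumps(rec) + "\n")


def harmonize_table(
    table: pd.DataFrame,
    dd: DataDictionary,
    lopsided_threshold: float = DEFAULT_LOPSIDED,
    centered_threshold: float = DEFAULT_CENTERED,
    sparse_threshold: float = DEFAULT_SPARSE,
) -> HarmonizeResult:
    """Run the full harmonization pipeline over every dictionary variable.

    Order: conditional merges (deepest chains first), then "Do not know"
    recoding (so gate answers of "Do not know" propagate to missing), then
    category collapsing. Idempotent: harmonizing the harmonized output with
    its derived dictionary is a no-op.
    """
    dd.check_parents()

    def depth(name: str) -> int:
        d, cur = 0, dd.entries[name].get("parent")
        while cur is not None:
            d, cur = d + 1, dd.entries[cur].get("parent")
        return d

    records = {name: dd.record(name, table[name]) for name in dd}
    children = sorted(
        (n for n in dd if records[n].parent is not None), key=depth, reverse=True
    )
    merged: dict[str, HarmonizedVariable] = {}
    dk_labels = {n: set(records[n].dont_know_labels) for n in dd}
    consumed: set[str] = set()
    for child_name in children:
        rec = records[child_name]
        parent_name = rec.parent
        if parent_name in merged:
            prev = merged[parent_name]
            parent_rec = VariableRecord(
                name=prev.name, domain=prev.domain, var_type=prev.var_type,
                values=prev.values, levels=prev.levels,
            )
            prior_audit = prev.audit
        else:
            parent_rec = records[parent_name]
            prior_audit = []
        hv = merge_conditional(parent_rec, rec)
        hv.audit = prior_audit + hv.audit
        merged[parent_name] = hv
        consumed.add(child_name)
        gate = str(rec.parent_gate)
        dk_labels[parent_name] = (
            {lbl for lbl in dk_labels[parent_name] if lbl != gate}
            | {f"{gate}:{lbl}" for lbl in dk_labels[child_name]}
        )

    variables: dict[str, HarmonizedVariable] = {}
    audit_log: list[dict] = []
    for name in dd:
        if name in consumed:
            continue
        base = merged.get(name, records[name])
        hv = recode_dont_know(base, frozenset(dk_labels[name]))
        if hv.var_type == CONTINUOUS:
            hv.values = pd.to_numeric(hv.values, errors="coerce")
        else:
            hv = collapse_categories(
                hv, lopsided_threshold, centered_threshold, sparse_threshold
            )
        variables[name] = hv
        audit_log.extend(hv.audit)

    data = pd.DataFrame({name: hv.values for name, hv in variables.items()},
                        index=table.index)
    return HarmonizeResult(data=data, variables=variables, audit=audit_log)
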