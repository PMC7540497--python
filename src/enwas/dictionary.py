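"""Data-dictionary driven variable records and file IO.

A cohort is a subjects x variables table (CSV/TSV) accompanied by a data
dictionary (JSON or YAML) with one entry per variable::

    {name, domain, type, levels, parent, parent_gate, dont_know_labels}

``levels`` is the declared label set; for ordered categoricals its order is
the category order. Conditional (skip-logic) questions declare a ``parent``
and the ``parent_gate`` answer that triggers them.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DictionaryError

UNORDERED = "unordered_categorical"
ORDERED = "ordered_categorical"
CONTINUOUS = "continuous"
VAR_TYPES = (UNORDERED, ORDERED, CONTINUOUS)

#: Default cell contents treated as missing when reading cohort tables.
MISSING_SENTINELS = ("", "NA")


@dataclass
class VariableRecord:
    """One raw exposure column plus its dictionary metadata."""

    name: str
    domain: str
    var_type: str | None
    values: pd.Series
    levels: list[str] | None = None
    parent: str | None = None
    parent_gate: str | None = None
    dont_know_labels: frozenset = frozenset()

    def validate(self) -> None:
        if self.var_type is not None and self.var_type not in VAR_TYPES:
            raise DictionaryError(f"{self.name}: unknown type {self.var_type!r}")
        if self.var_type == CONTINUOUS and self.levels:
            raise DictionaryError(f"{self.name}: continuous variable declares levels")
        if self.parent is not None and self.parent_gate is None:
            raise DictionaryError(f"{self.name}: parent set without parent_gate")
        if self.var_type in (UNORDERED, ORDERED) and self.levels:
            observed = set(self.values.dropna().astype(str))
            extra = observed - set(map(str, self.levels)) - set(self.dont_know_labels)
            if extra:
                raise DictionaryError(
                    f"{self.name}: observed values {sorted(extra)} outside declared levels"
                )

    @property
    def observed_levels(self) -> list[str]:
        """Declared levels restricted to those observed, keeping declared order."""
        observed = set(self.values.dropna().astype(str))
        if self.levels:
            return [lvl for lvl in self.levels if str(lvl) in observed]
        return sorted(observed)


@dataclass
class DataDictionary:
    """Ordered collection of per-variable dictionary entries."""

    entries: dict[str, dict] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> dict:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def record(self, name: str, values: pd.Series) -> VariableRecord:
        """Bind a dictionary entry to a column of observations."""
        e = self.entries[name]
        return VariableRecord(
            name=name,
            domain=e.get("domain", "unknown"),
            var_type=e.get("type"),
            values=values,
            levels=list(e["levels"]) if e.get("levels") else None,
            parent=e.get("parent"),
            parent_gate=e.get("parent_gate"),
            dont_know_labels=frozenset(e.get("dont_know_labels") or ()),
        )

    def check_parents(self) -> None:
        """Raise on dangling or cyclic conditional-parent links."""
        for name, e in self.entries.items():
            parent = e.get("parent")
            if parent is None:
                continue
            if parent not in self.entries:
                raise DictionaryError(f"{name}: parent {parent!r} not in dictionary")
            seen = {name}
            cur = parent
            while cur is not None:
                if cur in seen:
                    raise DictionaryError(f"cyclic parent links through {name!r}")
                seen.add(cur)
                cur = self.entries[cur].get("parent")

    @property
    def domains(self) -> list[str]:
        out: list[str] = []
        for e in self.entries.values():
            d = e.get("domain", "unknown")
            if d not in out:
                out.append(d)
        return out


def load_dictionary(path: str | Path) -> DataDictionary:
    """Read a JSON or YAML data dictionary (list of entries or name-keyed map)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if isinstance(raw, dict):
        entries = {name: dict(e, name=name) for name, e in raw.items()}
    else:
        entries = {e["name"]: dict(e) for e in raw}
    dd = DataDictionary(entries)
    dd.check_parents()
    return dd


def save_dictionary(dd: DataDictionary, path: str | Path) -> None:
    path = Path(path)
    payload = list(dd.entries.values())
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_cohort(
    path: str | Path,
    missing_sentinels: tuple[str, ...] = MISSING_SENTINELS,
) -> pd.DataFrame:
    """Read a cohort CSV/TSV with a header row of variable names."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(
        path, sep=sep, na_values=list(missing_sentinels), keep_default_na=False
    )
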