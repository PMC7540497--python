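"""Harmonization: conditional merges, don't-know recoding, collapsing, audit replay."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enwas
from enwas.errors import ClassificationError, DictionaryError
from enwas.harmonize import replay_audit


class TestMergeConditional:
    def test_smoking_example_labels(self, smoking_records):
        parent, child = smoking_records
        merged = enwas.merge_conditional(
            parent, child,
            labels={"No": "Never smoked", "Yes:No": "Past smoker",
                    "Yes:Yes": "Current smoker"},
        )
        assert list(merged.values)[:3] == ["Never smoked", "Current smoker", "Past smoker"]
        assert merged.levels == ["Never smoked", "Past smoker", "Current smoker"]

    def test_parent_missing_propagates(self, smoking_records):
        merged = enwas.merge_conditional(*smoking_records)
        assert pd.isna(merged.values.iloc[3])

    def test_gate_open_child_missing_is_missing(self, smoking_records):
        merged = enwas.merge_conditional(*smoking_records)
        assert pd.isna(merged.values.iloc[4])  # parent Yes, child unanswered

    def test_bad_gate_level_raises(self, smoking_records):
        parent, child = smoking_records
        bad = enwas.VariableRecord(
            name=child.name, domain=child.domain, var_type=child.var_type,
            values=child.values, levels=child.levels,
            parent=parent.name, parent_gate="Maybe",
        )
        with pytest.raises(DictionaryError):
            enwas.merge_conditional(parent, bad)

    def test_no_merged_value_contradicts_parent(self, smoking_records):
        # brute-force cross-tabulation on the fixture
        parent, child = smoking_records
        merged = enwas.merge_conditional(parent, child)
        for i in parent.values.index:
            p, c, m = parent.values[i], child.values[i], merged.values[i]
            if pd.isna(p):
                assert pd.isna(m)
            elif p != "Yes":
                assert m == str(p)
            elif pd.isna(c):
                assert pd.isna(m)
            else:
                assert m == f"Yes:{c}"

    def test_cyclic_parent_links_raise(self):
        dd = enwas.DataDictionary({
            "a": {"name": "a", "domain": "d", "type": enwas.UNORDERED,
                  "levels": ["x", "y"], "parent": "b", "parent_gate": "x"},
            "b": {"name": "b", "domain": "d", "type": enwas.UNORDERED,
                  "levels": ["x", "y"], "parent": "a", "parent_gate": "x"},
        })
        with pytest.raises(DictionaryError):
            dd.check_parents()


class TestRecodeDontKnow:
    def test_dont_know_becomes_missing(self):
        var = enwas.VariableRecord(
            name="bw_recall", domain="parental_health", var_type=enwas.UNORDERED,
            values=pd.Series(["Yes", "No", "Do not know"]),
            levels=["Yes", "No"], dont_know_labels=frozenset({"Do not know"}),
        )
        out = enwas.recode_dont_know(var)
        assert list(out.values[:2]) == ["Yes", "No"]
        assert pd.isna(out.values[2])
        assert "Do not know" not in (out.levels or [])

    def test_without_labels_is_identity(self):
        var = enwas.VariableRecord(
            name="v", domain="d", var_type=enwas.UNORDERED,
            values=pd.Series(["a", "b"]), levels=["a", "b"],
        )
        out = enwas.recode_dont_know(var)
        assert list(out.values) == ["a", "b"]

    def test_all_dont_know_becomes_all_missing(self):
        var = enwas.VariableRecord(
            name="v", domain="d", var_type=enwas.UNORDERED,
            values=pd.Series(["Do not know"] * 4),
            levels=["a"], dont_know_labels=frozenset({"Do not know"}),
        )
        out = enwas.recode_dont_know(var)
        assert out.values.isna().all()


def _ordered_var(counts: dict[str, int]) -> enwas.HarmonizedVariable:
    values = pd.Series(
        [lvl for lvl, k in counts.items() for _ in range(k)], dtype=object
    )
    return enwas.HarmonizedVariable(
        name="v", domain="d", var_type=enwas.ORDERED,
        values=values, levels=list(counts),
    )


class TestCollapseCategories:
    def test_lopsided_rule(self):
        var = _ordered_var({"Never": 70, "Rarely": 15, "Sometimes": 10, "Often": 5})
        out = enwas.collapse_categories(var, lopsided_threshold=0.5)
        assert out.levels == ["Never", "Rarely", "Sometimes+Often"]

    def test_centered_rule(self):
        var = _ordered_var({"SD": 5, "D": 15, "N": 60, "A": 15, "SA": 5})
        out = enwas.collapse_categories(var, centered_threshold=0.4)
        assert out.levels == ["SD+D", "N", "A+SA"]

    def test_sparse_rule_unordered(self):
        values = pd.Series(["A"] * 96 + ["B"] * 2 + ["C"] * 2, dtype=object)
        var = enwas.HarmonizedVariable(
            name="v", domain="d", var_type=enwas.UNORDERED,
            values=values, levels=["A", "B", "C"],
        )
        out = enwas.collapse_categories(var, sparse_threshold=0.05)
        assert set(out.levels) == {"A", "other"}
        assert (out.values == "other").sum() == 4

    def test_single_level_passes_through(self):
        var = _ordered_var({"only": 10})
        out = enwas.collapse_categories(var)
        assert list(out.values.unique()) == ["only"]

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=60), min_size=2, max_size=7),
        thresholds=st.tuples(
            st.floats(0.3, 0.9), st.floats(0.3, 0.6), st.floats(0.01, 0.2)
        ),
    )
    def test_collapse_properties(self, counts, thresholds):
        if sum(counts) == 0:
            counts[0] = 1
        levels = [f"L{i}" for i in range(len(counts))]
        var = _ordered_var(dict(zip(levels, counts)))
        out = enwas.collapse_categories(var, *thresholds)
        observed_in = [l for l, k in zip(levels, counts) if k > 0]
        # never increases the number of levels
        assert len(out.observed_levels) <= max(len(observed_in), 1)
        # equal raw values always map to the same harmonized value
        mapping = dict(zip(var.values, out.values))
        assert all(mapping[raw] == new for raw, new in zip(var.values, out.values))


class TestClassifyVariable:
    @pytest.mark.parametrize(
        "values,levels,vtype,expected",
        [
            (["dutch", "nonwestern"], ["dutch", "nonwestern"], enwas.UNORDERED,
             enwas.UNORDERED),
            (["low", "high"], ["low", "middle", "high"], enwas.ORDERED, enwas.ORDERED),
            (list(np.linspace(2500, 4500, 30)), None, enwas.CONTINUOUS,
             enwas.CONTINUOUS),
        ],
    )
    def test_declared_types_returned(self, values, levels, vtype, expected):
        var = enwas.VariableRecord(
            name="v", domain="d", var_type=vtype,
            values=pd.Series(values), levels=levels,
        )
        assert enwas.classify_variable(var) == (expected, False)

    def test_numeric_many_values_inferred_continuous(self):
        var = enwas.VariableRecord(
            name="bw", domain="d", var_type=None,
            values=pd.Series(np.arange(20, dtype=float)),
        )
        label, inferred = enwas.classify_variable(var)
        assert label == enwas.CONTINUOUS and inferred

    def test_declared_levels_inferred_ordered(self):
        var = enwas.VariableRecord(
            name="edu", domain="d", var_type=None,
            values=pd.Series(["low", "high", "low"]), levels=["low", "middle", "high"],
        )
        assert enwas.classify_variable(var) == (enwas.ORDERED, True)

    def test_mixed_values_raise(self):
        var = enwas.VariableRecord(
            name="v", domain="d", var_type=None,
            values=pd.Series(["1", "2", "many"]),
        )
        with pytest.raises(ClassificationError):
            enwas.classify_variable(var)


class TestPipelineProperties:
    def test_audit_replay_roundtrip(self, small_cohort):
        """Replaying each variable's audit on the raw table reproduces the
        harmonized values exactly."""
        raw = small_cohort.table
        result = enwas.harmonize_table(
            raw[[c for c in raw.columns if c in small_cohort.dictionary]],
            small_cohort.dictionary,
        )
        assert result.audit  # the generator plants work for every path
        for name, hv in result.variables.items():
            if not hv.audit:
                continue
            replayed = replay_audit(hv.audit, raw)
            expected = hv.values
            if hv.var_type == enwas.CONTINUOUS:
                replayed = pd.to_numeric(replayed, errors="coerce")
                assert np.allclose(
                    replayed.fillna(-1).to_numpy(dtype=float),
                    expected.fillna(-1).to_numpy(dtype=float),
                )
            else:
                assert (replayed.fillna("<NA>") == expected.fillna("<NA>")).all(), name

    def test_idempotence(self, small_cohort):
        """Harmonizing the harmonized output with its derived dictionary is a no-op."""
        raw = small_cohort.table
        first = enwas.harmonize_table(
            raw[[c for c in raw.columns if c in small_cohort.dictionary]],
            small_cohort.dictionary,
        )
        second = enwas.harmonize_table(first.data, first.to_dictionary())
        for name in first.data.columns:
            a, b = first.data[name], second.data[name]
            if first.variables[name].var_type == enwas.CONTINUOUS:
                assert np.allclose(
                    pd.to_numeric(a, errors="coerce").fillna(-1),
                    pd.to_numeric(b, errors="coerce").fillna(-1),
                )
            else:
                assert (a.fillna("<NA>").astype(str) == b.fillna("<NA>").astype(str)).all()
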