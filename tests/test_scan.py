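"""Per-variable models, split, multiplicity adjustment, two-stage scan."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enwas
from enwas.errors import ConfigError, DegenerateFitError, RankDeficiencyError
from enwas.scan import Contrast, _single_stage_scan  # noqa: F401


def _no_covariates(index):
    return pd.DataFrame(index=index)


class TestFitExposureModel:
    def test_exact_line(self):
        y = pd.Series([1.0, 3.0, 5.0, 7.0])
        x = pd.Series([0.0, 1.0, 2.0, 3.0])
        r = enwas.fit_exposure_model(y, x, enwas.CONTINUOUS, _no_covariates(y.index))
        assert r.contrasts[0].B == pytest.approx(2.0, abs=1e-10)
        assert r.b_intercept == pytest.approx(1.0, abs=1e-10)

    def test_worked_five_row_table(self):
        # normal equations by hand: Sxy=8, Sxx=10 -> slope 0.8, intercept 0.6
        y = pd.Series([2.0, 1.0, 4.0, 3.0, 5.0])
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        r = enwas.fit_exposure_model(y, x, enwas.CONTINUOUS, _no_covariates(y.index))
        assert r.contrasts[0].B == pytest.approx(0.8, abs=1e-10)
        assert r.b_intercept == pytest.approx(0.6, abs=1e-10)

    def test_null_slope_within_sampling_error(self):
        rng = np.random.default_rng(12)
        n = 2000
        y = pd.Series(rng.standard_normal(n))
        x = pd.Series(rng.standard_normal(n))
        r = enwas.fit_exposure_model(y, x, enwas.CONTINUOUS, _no_covariates(y.index))
        se = (r.contrasts[0].ci_high - r.contrasts[0].ci_low) / (2 * 1.96)
        assert abs(r.contrasts[0].B) < 4 * se

    def test_ordered_integer_score_contrast(self):
        x = pd.Series(["low", "middle", "high", "low", "high", "middle"] * 10)
        y = pd.Series(
            x.map({"low": 0.0, "middle": 1.0, "high": 2.0})
            + np.random.default_rng(0).normal(0, 0.01, 60)
        )
        r = enwas.fit_exposure_model(
            y, x, enwas.ORDERED, _no_covariates(y.index), levels=["low", "middle", "high"]
        )
        assert len(r.contrasts) == 1
        assert r.contrasts[0].label == "low to high"
        assert r.contrasts[0].B == pytest.approx(1.0, abs=0.01)

    def test_unordered_joint_f_and_modal_reference(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.choice(["a", "b", "c"], 300, p=[0.2, 0.5, 0.3]))
        y = pd.Series(x.map({"a": 0.0, "b": 0.0, "c": 1.0}) + rng.normal(0, 0.2, 300))
        r = enwas.fit_exposure_model(y, x, enwas.UNORDERED, _no_covariates(y.index))
        labels = [c.label for c in r.contrasts]
        assert labels == ["a vs b", "c vs b"]  # b is modal -> reference
        assert r.p_joint < 1e-10
        assert all(c.ci_low <= c.B <= c.ci_high for c in r.contrasts)

    def test_complete_case_restriction(self):
        y = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        x = pd.Series([1.0, np.nan, 3.0, 4.0, 5.0, 6.0])
        r = enwas.fit_exposure_model(y, x, enwas.CONTINUOUS, _no_covariates(y.index))
        assert r.n == 4

    def test_constant_exposure_raises(self):
        y = pd.Series([1.0, 2.0, 3.0])
        x = pd.Series(["a", "a", "a"])
        with pytest.raises(DegenerateFitError):
            enwas.fit_exposure_model(y, x, enwas.UNORDERED, _no_covariates(y.index))

    def test_collinear_exposure_raises(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.standard_normal(50))
        cov = pd.DataFrame({"c1": rng.standard_normal(50)})
        x = pd.Series(2.0 * cov["c1"])  # exactly collinear with the covariate
        with pytest.raises(RankDeficiencyError):
            enwas.fit_exposure_model(y, x, enwas.CONTINUOUS, cov)


class TestQuadraticScreen:
    def test_pure_quadratic_detected(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.standard_normal(500))
        y = pd.Series((x - x.mean()) ** 2)
        p = enwas.screen_quadratic(y, x, _no_covariates(y.index))
        assert p < 1e-20

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = pd.Series(rng.standard_normal(200))
            y = pd.Series(0.5 * x + rng.standard_normal(200))
            hits += enwas.screen_quadratic(y, x, _no_covariates(y.index)) < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.04)

    def test_categorical_exposure_has_no_quadratic(self, small_cohort):
        cfg = enwas.ScanConfig(seed=0, quadratic_screen=True)
        res = enwas.run_pipeline(small_cohort.table, small_cohort.dictionary, cfg)
        cat = res.scan.results[res.scan.results["var_type"] != enwas.CONTINUOUS]
        assert cat["p_quadratic"].isna().all()


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        adj = enwas.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "fdr_bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_identity(self):
        for method in ("fdr_bh", "bonferroni"):
            np.testing.assert_allclose(enwas.adjust_pvalues([0.03], method), [0.03])

    def test_bonferroni_multiplication(self):
        adj = enwas.adjust_pvalues([1e-4] + [0.5] * 919, "bonferroni")
        assert adj[0] == pytest.approx(0.092)

    def test_empty_vector(self):
        assert enwas.adjust_pvalues([], "fdr_bh").size == 0

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_adjusted_never_below_raw(self, ps):
        for method in ("fdr_bh", "bonferroni"):
            adj = enwas.adjust_pvalues(ps, method)
            assert (adj >= np.asarray(ps) - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()


class TestSplitCohort:
    def _data(self, n):
        idx = pd.RangeIndex(n)
        return enwas.CohortData(
            exposures=pd.DataFrame({"v": np.zeros(n)}, index=idx),
            meta={"v": enwas.VariableMeta("d", enwas.CONTINUOUS, None)},
            covariates=pd.DataFrame(index=idx),
            y=pd.Series(np.zeros(n), index=idx),
        )

    def test_sizes_and_partition(self):
        disc, test = enwas.split_cohort(self._data(100), 0.75, seed=0)
        assert (disc.n, test.n) == (75, 25)
        assert set(disc.y.index) | set(test.y.index) == set(range(100))
        assert set(disc.y.index) & set(test.y.index) == set()

    def test_deterministic_for_seed(self):
        d1, _ = enwas.split_cohort(self._data(100), 0.75, seed=42)
        d2, _ = enwas.split_cohort(self._data(100), 0.75, seed=42)
        assert list(d1.y.index) == list(d2.y.index)

    def test_rounding_rule(self):
        disc, test = enwas.split_cohort(self._data(3841), 0.75, seed=1)
        assert disc.n == 2881  # round(3841 * 0.75) = round(2880.75)
        assert test.n == 960

    def test_too_small_raises(self):
        with pytest.raises(ConfigError):
            enwas.split_cohort(self._data(1))


class TestRunEnwas:
    def test_same_seed_identical_results(self, small_cohort):
        cfg = enwas.ScanConfig(seed=5, quadratic_screen=False)
        r1 = enwas.run_pipeline(small_cohort.table, small_cohort.dictionary, cfg)
        r2 = enwas.run_pipeline(small_cohort.table, small_cohort.dictionary, cfg)
        assert r1.scan.results.to_csv() == r2.scan.results.to_csv()

    def test_test_stage_total_equals_discovery_fdr_count(self, small_cohort):
        cfg = enwas.ScanConfig(seed=5, quadratic_screen=False)
        res = enwas.run_pipeline(small_cohort.table, small_cohort.dictionary, cfg)
        counts = res.scan.report.stage_counts
        assert counts["test"]["total"] == counts["discovery"]["fdr"]

    def test_per_variable_n_bounded_by_stage_size(self, small_cohort):
        cfg = enwas.ScanConfig(seed=5, quadratic_screen=False)
        res = enwas.run_pipeline(small_cohort.table, small_cohort.dictionary, cfg)
        disc_n = int(round(0.75 * res.cohort.n))
        disc = res.scan.results[res.scan.results["stage"] == "discovery"]
        assert (disc["n"] <= disc_n).all()

    def test_missing_covariate_raises(self, small_cohort):
        cohort, *_ = enwas.build_cohort_data(small_cohort.table, small_cohort.dictionary)
        cfg = enwas.ScanConfig(covariate_set="extended8")
        cohort.covariates = cohort.covariates.drop(columns=["birth_weight"])
        with pytest.raises(ConfigError):
            enwas.run_enwas(cohort, cfg)

    def test_planted_effect_survives_both_stages(self):
        spec = enwas.SyntheticSpec(
            n_subjects=2500,
            domains=(("parental_health", 6), ("family_rearing", 6)),
            planted_effects=(enwas.PlantedEffect("family_rearing_001", 0.15),),
            n_conditional_pairs=0, n_dont_know=0, seed=21,
        )
        gen = enwas.generate(spec)
        cfg = enwas.ScanConfig(seed=8, quadratic_screen=False)
        res = enwas.run_pipeline(gen.table, gen.dictionary, cfg)
        assert "family_rearing_001" in res.scan.report.survivors


class TestSensitivity:
    def test_exclude_asd_without_cases_is_noop(self, small_spec):
        spec = dataclasses.replace(small_spec, asd_rate=0.0)
        gen = enwas.generate(spec)
        cohort, *_ = enwas.build_cohort_data(gen.table, gen.dictionary, seed=0)
        cfg = enwas.ScanConfig(seed=3, quadratic_screen=False)
        main = enwas.run_enwas(cohort, cfg)
        sens = enwas.run_sensitivity(cohort, cfg, "exclude_asd")
        pd.testing.assert_frame_equal(main.results, sens.results)

    def test_dutch_only_is_single_combined_stage(self, small_cohort):
        cohort, *_ = enwas.build_cohort_data(
            small_cohort.table, small_cohort.dictionary, seed=0
        )
        cfg = enwas.ScanConfig(seed=3, quadratic_screen=False)
        res = enwas.run_sensitivity(cohort, cfg, "dutch_only")
        assert set(res.results["stage"]) == {"combined"}
        n_dutch = int(cohort.flags["dutch_parents"].sum())
        assert (res.results["n"] <= n_dutch).all()

    def test_gsi_adjustment_drops_parental_domains(self, small_cohort):
        cohort, *_ = enwas.build_cohort_data(
            small_cohort.table, small_cohort.dictionary, seed=0
        )
        cfg = enwas.ScanConfig(seed=3, quadratic_screen=False)
        res = enwas.run_sensitivity(cohort, cfg, "gsi_adjusted")
        assert not set(res.results["domain"]) & set(enwas.scan.GSI_EXCLUDED_DOMAINS)

    def test_unknown_mode_raises(self, small_cohort):
        cohort, *_ = enwas.build_cohort_data(
            small_cohort.table, small_cohort.dictionary, seed=0
        )
        with pytest.raises(ConfigError):
            enwas.run_sensitivity(cohort, enwas.ScanConfig(), "bootstrap")
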