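"""Statistical engine: enumeration oracles for the permutation test,
robust-adjustment recovery, subgroup construction, FDR arithmetic."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equisense import stats
from equisense.stats import (
    AnalysisConfig,
    adjust_covariates,
    adjust_fdr,
    build_subgroups,
    cohens_d,
    cohens_d_from_stats,
    percent_difference,
    permutation_test,
    rank_sum_test,
    run_equivalence,
    select_first_valid,
)
from equisense.types import SchemaError


def exact_permutation_p(sub, ref, statistic=np.mean):
    """Independent oracle: exhaustive enumeration of all splits."""
    pooled = np.concatenate([sub, ref])
    n1 = len(sub)
    obs = abs(statistic(sub) - statistic(ref))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        d = abs(statistic(pooled[mask]) - statistic(pooled[~mask]))
        count += d >= obs - 1e-12
        total += 1
    return count / total


class TestSelectFirstValid:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "test_type",
                                           "run_index", "valid",
                                           "feature_name", "value"])

    def test_second_bundle_used_when_first_invalid(self):
        rows = []
        for run, valid in ((0, False), (1, True)):
            for t in ("IPS", "IPS_DD", "PT", "SBT", "UTT"):
                v = valid or t != "PT"  # run 0: PT invalid
                rows.append(("P1", t, run, v, "f", 10.0 + run))
        sel = select_first_valid(self.make_table(rows))
        assert len(sel) == 5
        assert (sel.value == 11.0).all()

    def test_walk_contributes_independently(self):
        rows = [("P1", "MWT2", 0, True, "step_count", 200.0),
                ("P1", "IPS", 0, False, "correct_responses", 40.0)]
        sel = select_first_valid(self.make_table(rows))
        assert list(sel.test_type) == ["MWT2"]

    def test_partial_bundle_contributes_nothing(self):
        """A run where one bundled test is invalid supplies no bundled
        features at all."""
        rows = [("P1", t, 0, t != "UTT", "f", 1.0)
                for t in ("IPS", "IPS_DD", "PT", "SBT", "UTT")]
        sel = select_first_valid(self.make_table(rows))
        assert sel.empty

    def test_no_valid_sessions_excluded(self):
        rows = [("P1", "MWT2", 0, False, "step_count", 1.0)]
        assert select_first_valid(self.make_table(rows)).empty


class TestAdjustCovariates:
    def cohort(self, n, rng):
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "age": rng.integers(18, 80, n),
            "sex": rng.choice(["female", "male"], n),
            "ms_status": rng.choice(["MS", "non-MS"], n),
        })

    def test_null_covariates_leave_values_nearly_unchanged(self, rng):
        n = 1000
        cohort = self.cohort(n, rng)
        feats = pd.DataFrame({"participant_id": cohort.participant_id,
                              "test_type": "IPS",
                              "value": rng.normal(50, 10, n)})
        adj = adjust_covariates(feats, cohort)
        assert np.mean(np.abs(adj.adjusted_value - adj.value)) < 1.5

    def test_age_effect_removed(self, rng):
        n = 1000
        cohort = self.cohort(n, rng)
        feats = pd.DataFrame({"participant_id": cohort.participant_id,
                              "test_type": "IPS",
                              "value": 0.5 * cohort.age
                              + rng.normal(0, 3, n)})
        adj = adjust_covariates(feats, cohort)
        r = np.corrcoef(adj.adjusted_value, cohort.age)[0, 1]
        assert abs(r) < 0.05
        # native scale preserved
        assert adj.adjusted_value.mean() == pytest.approx(
            feats.value.mean(), rel=0.05)

    def test_outlier_robust_slope(self, rng):
        """With 5% gross outliers, the Huber slope stays within 3 SE of
        the clean-data OLS oracle."""
        n = 1000
        age = rng.integers(18, 80, n).astype(float)
        y_clean = 0.5 * age + rng.normal(0, 3, n)
        ols_slope = np.polyfit(age, y_clean, 1)[0]
        y = y_clean.copy()
        out_idx = rng.choice(n, n // 20, replace=False)
        y[out_idx] += rng.choice([-1, 1], out_idx.size) * 100
        slope, se = stats.fit_robust_slope(y, age)
        assert abs(slope - ols_slope) < 3 * se

    def test_missing_covariates_dropped(self, rng):
        cohort = self.cohort(10, rng)
        cohort.loc[0, "age"] = np.nan
        feats = pd.DataFrame({"participant_id": cohort.participant_id,
                              "test_type": "IPS",
                              "value": np.arange(10.0)})
        adj = adjust_covariates(feats, cohort)
        assert len(adj) == 9
        assert "P0" not in set(adj.participant_id)


class TestBuildSubgroups:
    def cohort(self):
        rows = []
        for i in range(50):
            rows.append((f"A{i}", "iOS", "iOS 12", "iPhone X",
                         "smartphone"))
        for i in range(30):
            rows.append((f"B{i}", "iOS", "iOS 13", "iPhone 8",
                         "smartphone"))
        for i in range(19):
            rows.append((f"C{i}", "Android", "Android 9", "Pixel 3",
                         "smartphone"))
        for i in range(25):
            rows.append((f"D{i}", "Android", "Android 10", "Galaxy S9",
                         "smartphone"))
        return pd.DataFrame(rows, columns=["participant_id", "os_platform",
                                           "os_version", "device_model",
                                           "device_class"])

    def test_small_subgroup_excluded_everywhere(self):
        parts = build_subgroups(self.cohort(), "device_model")
        assert "Pixel 3" not in parts
        for label, (members, reference) in parts.items():
            assert not any(pid.startswith("C") for pid in reference)

    def test_two_subgroup_symmetry(self):
        parts = build_subgroups(self.cohort(), "os_platform")
        # Android has 44 >= 20, iOS 80 >= 20
        assert parts["iOS"][1] == parts["Android"][0]
        assert parts["Android"][1] == parts["iOS"][0]

    def test_version_category_restricted_to_platform(self):
        parts = build_subgroups(self.cohort(), "ios_version")
        all_ids = set().union(*(m | r for m, r in parts.values()))
        assert all(pid[0] in "AB" for pid in all_ids)

    def test_single_qualifying_subgroup_yields_no_comparisons(self):
        parts = build_subgroups(self.cohort(), "android_version",
                                AnalysisConfig(min_subgroup_n=30))
        assert parts == {}

    def test_unknown_category_rejected(self):
        with pytest.raises(SchemaError):
            build_subgroups(self.cohort(), "carrier")


class TestPermutationTest:
    def test_degenerate_identical_values(self):
        cfg = AnalysisConfig(n_permutations=200, seed=1)
        res = permutation_test(np.ones(5), np.ones(8), cfg)
        assert res.observed_diff == 0.0
        assert res.p_unadjusted == 1.0

    def test_monte_carlo_matches_enumeration(self, rng):
        """MC p within 3 binomial SEs of the exhaustive-enumeration p
        for group sizes with C(n, n1) <= 5000."""
        B = 5000
        for n1, n2 in ((3, 2), (5, 5), (6, 6), (7, 7), (4, 9)):
            sub = rng.normal(0, 1, n1)
            ref = rng.normal(0.5, 1, n2)
            exact = exact_permutation_p(sub, ref)
            cfg = AnalysisConfig(n_permutations=B, seed=11)
            res = permutation_test(sub, ref, cfg)
            se = np.sqrt(exact * (1 - exact) / B)
            assert abs(res.p_unadjusted - exact) <= 3 * se + 2 / B, \
                (n1, n2, res.p_unadjusted, exact)

    def test_spec_example_three_vs_two(self):
        """(1,2,3) vs (4,5): the exact p over all 10 splits."""
        sub, ref = np.array([1., 2., 3.]), np.array([4., 5.])
        exact = exact_permutation_p(sub, ref)
        cfg = AnalysisConfig(n_permutations=4000, seed=5)
        res = permutation_test(sub, ref, cfg)
        assert abs(res.p_unadjusted - exact) < 3 * np.sqrt(
            exact * (1 - exact) / 4000) + 1e-3

    def test_huge_shift_hits_addone_floor(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, 500)
        sub = rng.normal(10, 1, 50)
        cfg = AnalysisConfig(n_permutations=10_000, seed=2)
        res = permutation_test(sub, ref, cfg)
        assert res.p_unadjusted == pytest.approx(1 / 10_001)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        sub, ref = rng.normal(0, 1, 20), rng.normal(0, 1, 60)
        cfg = AnalysisConfig(n_permutations=500, seed=7)
        a = permutation_test(sub, ref, cfg)
        b = permutation_test(sub, ref, cfg)
        assert a.p_unadjusted == b.p_unadjusted
        np.testing.assert_array_equal(a.null_diffs, b.null_diffs)

    def test_median_statistic(self, rng):
        sub = rng.normal(0, 1, 15)
        ref = rng.normal(0, 1, 45)
        cfg = AnalysisConfig(n_permutations=500, statistic="median", seed=3)
        res = permutation_test(sub, ref, cfg)
        assert res.observed_diff == pytest.approx(
            np.median(sub) - np.median(ref))
        assert 0 < res.p_unadjusted <= 1

    def test_null_ci_covers_null_observations(self, rng):
        """Under exchangeability the observed |diff| falls inside the
        95% permutation interval about 95% of the time."""
        cfg = AnalysisConfig(n_permutations=400, seed=0)
        inside = 0
        n_sim = 1200
        for i in range(n_sim):
            pooled = rng.normal(0, 1, 60)
            sub, ref = pooled[:20], pooled[20:]
            res = permutation_test(sub, ref, cfg,
                                   np.random.default_rng(i))
            inside += res.ci_low <= abs(res.observed_diff) <= res.ci_high
        assert inside / n_sim == pytest.approx(0.95, abs=0.02)


class TestEffectSizes:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(0, 1, 30)
        assert cohens_d(x, x) == 0.0

    def test_unit_pooled_sd_definition(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = a + 1.0
        d = cohens_d(a, b)
        assert d == pytest.approx(1.0 / a.std(ddof=1))

    def test_published_platform_comparison(self):
        """Printed group summaries for the processing-speed test give
        d = 0.12 at two decimals."""
        d = cohens_d_from_stats(734, 63.1, 11.2, 341, 61.8, 10.3)
        assert round(d, 2) == 0.12

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(SchemaError):
            cohens_d(np.ones(3), np.full(3, 2.0))

    def test_percent_difference_examples(self):
        assert percent_difference(5.0, 5.0) == 0.0
        assert round(percent_difference(195.9, 191.9), 1) == 2.1
        assert round(percent_difference(63.1, 61.8), 1) == 2.1

    def test_percent_difference_zero_reference(self):
        with pytest.raises(SchemaError):
            percent_difference(1.0, 0.0)


class TestFdr:
    def test_single_p_identity(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        adj = adjust_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, 0.05)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_dominance_and_bounds(self, ps):
        adj = adjust_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestRankSum:
    def test_fully_separated_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        assert rank_sum_test(a, b) == pytest.approx(2 / 70)

    def test_exact_and_asymptotic_agree_at_n10(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.3, 1, 10)
        from scipy.stats import mannwhitneyu
        exact = mannwhitneyu(a, b, alternative="two-sided",
                             method="exact").pvalue
        approx = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02
        # package picks asymptotic at combined n=20
        assert rank_sum_test(a, b) == pytest.approx(approx)

    def test_symmetric_small_sample(self, rng):
        a = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert rank_sum_test(a, b) > 0.5


class TestRunEquivalence:
    def adjusted_null(self, n, seed):
        from equisense.synth import SimulationConfig, generate_feature_table
        cfg = SimulationConfig(n_participants=n, seed=seed)
        cohort, table = generate_feature_table(cfg)
        adj = adjust_covariates(table, cohort)
        return adj, cohort

    def test_null_cohort_mostly_nonsignificant(self):
        adj, cohort = self.adjusted_null(800, 21)
        cfg = AnalysisConfig(n_permutations=400,
                             categories=("os_platform",), seed=1)
        out = run_equivalence(adj, cohort, cfg)
        assert len(out) == 12  # 6 tests x 2 platform subgroups
        assert (out.p_unadjusted < 0.05).mean() < 0.25
        assert (out.p_adjusted >= out.p_unadjusted - 1e-12).all()

    def test_mean_and_median_sign_agreement(self):
        """For symmetric noise the two statistics point the same way on
        clearly shifted subgroups."""
        from equisense.synth import SimulationConfig, generate_feature_table
        cfg = SimulationConfig(n_participants=800, seed=22)
        cohort, table = generate_feature_table(
            cfg, shifts={("PT", "Android"): -5.0})
        adj = adjust_covariates(table, cohort)
        res = {}
        for statistic in ("mean", "median"):
            acfg = AnalysisConfig(n_permutations=300,
                                  categories=("os_platform",),
                                  statistic=statistic, seed=2)
            out = run_equivalence(adj, cohort, acfg)
            row = out[(out.test_type == "PT")
                      & (out.subgroup == "Android")].iloc[0]
            res[statistic] = row.mean_subgroup - row.mean_reference
        assert np.sign(res["mean"]) == np.sign(res["median"])

    def test_family_is_category_by_test(self):
        adj, cohort = self.adjusted_null(600, 23)
        cfg = AnalysisConfig(n_permutations=200,
                             categories=("ios_version",), seed=3)
        out = run_equivalence(adj, cohort, cfg)
        for test, grp in out.groupby("test_type"):
            np.testing.assert_allclose(
                grp.p_adjusted,
                adjust_fdr(grp.p_unadjusted.to_numpy()))

    def test_requires_adjusted_features(self):
        with pytest.raises(SchemaError):
            run_equivalence(pd.DataFrame({"value": [1.0]}),
                            pd.DataFrame(), AnalysisConfig())
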