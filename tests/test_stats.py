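"""Group, paired, correlation, and FDR statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netswitch.stats import (
    Cohort,
    ancova_group_effect,
    bh_fdr,
    paired_t,
    partial_pearson,
    run_study_stats,
    spearman,
    two_sample_t_summary,
)
from netswitch.synthetic import PlantedDesign, generate_cohort
from netswitch.connectivity import SlidingWindowConfig


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.statistic_kind == "t"

    def test_antisymmetric_in_swap(self, rng):
        pre, post = rng.normal(size=10), rng.normal(size=10)
        assert paired_t(pre, post).statistic == pytest.approx(
            -paired_t(post, pre).statistic
        )

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))


class TestTwoSampleFromSummary:
    def test_pooled_matches_published_depression_score_row(self):
        """Recomputing t from the printed group means/SDs: 10.58+-6.68 (n=24)
        vs 4.04+-4.65 (n=26) gives the published t = 4.044."""
        res = two_sample_t_summary(24, 10.58, 6.68, 26, 4.04, 4.65, "pooled")
        assert round(res.statistic, 3) == 4.044
        assert res.df == 48
        assert res.p < 0.001

    def test_equal_means_give_zero(self):
        assert two_sample_t_summary(10, 5.0, 1.0, 12, 5.0, 2.0).statistic == 0.0

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        a = two_sample_t_summary(15, 1.2, 0.8, 15, 0.9, 0.8, "pooled")
        b = two_sample_t_summary(15, 1.2, 0.8, 15, 0.9, 0.8, "welch")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.df == pytest.approx(b.df, abs=1e-9)

    def test_degenerate_sds_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            two_sample_t_summary(5, 1.0, 0.0, 5, 2.0, 0.0)


class TestSpearman:
    def test_monotone_pair_is_one(self):
        x = np.array([1.0, 3.0, 4.0, 10.0, 20.0])
        assert spearman(x, np.exp(x / 10)).statistic == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_exact_permutation_p_for_tiny_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 5.0, 4.0]
        exact = spearman(x, y, method="exact")
        # 5! = 120 permutations; count |rho| >= 0.9 by direct enumeration
        from itertools import permutations

        count = 0
        for perm in permutations(y):
            r = sps.spearmanr(x, perm).statistic
            if abs(r) >= abs(exact.statistic) - 1e-12:
                count += 1
        assert exact.p == pytest.approx(count / 120)
        with pytest.raises(ValueError, match="n <= 10"):
            spearman(np.arange(12.0), np.arange(12.0), method="exact")


class TestPartialPearson:
    def test_reduces_to_plain_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_pearson(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_covariate_determined_outcome_gives_zero(self, rng):
        z = rng.normal(size=(40, 2))
        x = rng.normal(size=40)
        y = 3 * z[:, 0] - z[:, 1] + 0.5
        assert partial_pearson(x, y, z).statistic == pytest.approx(0.0, abs=1e-7)

    def test_matches_recursive_formula(self, rng):
        """Residual-based partial r equals the textbook recursion to 1e-10."""

        def recursive_partial(x, y, z):
            if z.shape[1] == 0:
                return sps.pearsonr(x, y).statistic
            last, rest = z[:, -1], z[:, :-1]
            rxy = recursive_partial(x, y, rest)
            rxz = recursive_partial(x, last, rest)
            ryz = recursive_partial(y, last, rest)
            return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

        x, y = rng.normal(size=10), rng.normal(size=10)
        z = rng.normal(size=(10, 3))
        expected = recursive_partial(x, y, z)
        res = partial_pearson(x, y, z)
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.df == 10 - 3 - 2


class TestAncova:
    def test_identical_outcomes_give_zero_f(self, rng):
        """Groups with identical outcome/covariate patterns: no group effect."""
        outcome = np.tile([1.0, 2.0, 3.0, 1.5, 2.5, 3.5], 2)
        group = ["dependent"] * 6 + ["control"] * 6
        cov = np.tile(rng.normal(size=(6, 3)), (2, 1))
        res = ancova_group_effect(outcome, group, cov)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_independent_normal_equations(self, rng):
        """Six-subject toy: F agrees with a from-scratch least-squares solve."""
        outcome = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        group = ["a", "a", "a", "b", "b", "b"]
        cov = np.array([[0.1], [0.4], [0.2], [0.3], [0.6], [0.5]])
        res = ancova_group_effect(outcome, group, cov, covariate_names=["c1"])

        g = np.array([0.0, 0, 0, 1, 1, 1])
        xf = np.column_stack([np.ones(6), cov[:, 0], g])
        xr = xf[:, :2]

        def rss(x):
            beta = np.linalg.solve(x.T @ x, x.T @ outcome)
            e = outcome - x @ beta
            return e @ e

        f_expected = (rss(xr) - rss(xf)) / (rss(xf) / (6 - 3))
        assert res.statistic == pytest.approx(f_expected, abs=1e-10)
        assert res.df == (1, 3)

    def test_f_equals_squared_pooled_t_without_covariates(self, rng):
        a, b = rng.normal(size=12), rng.normal(loc=0.6, size=14)
        outcome = np.concatenate([a, b])
        group = ["x"] * 12 + ["y"] * 14
        res = ancova_group_effect(
            outcome, group, np.empty((26, 0)), covariate_names=[]
        )
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t**2, abs=1e-10)

    def test_constant_covariate_named_in_error(self, rng):
        outcome = rng.normal(size=10)
        group = ["a"] * 5 + ["b"] * 5
        cov = np.column_stack([rng.normal(size=10), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="education"):
            ancova_group_effect(outcome, group, cov, ["age", "education"])


class TestBhFdr:
    def test_worked_step_up_example(self):
        adj = bh_fdr([0.01, 0.02, 0.04, 0.05])
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_single_and_tied_inputs_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_never_decreases_and_respects_order(self, rng):
        p = rng.uniform(size=40)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def small_cohort(effect=0.0, seed=0, levels=("global",), n=(8, 8)):
    design = PlantedDesign.static(n_nodes=12, n_modules=2, n_volumes=240)
    return generate_cohort(
        n,
        {"dependent": design, "control": design},
        effect=effect,
        seed=seed,
        window=SlidingWindowConfig(),
        events_mean=6,
        events_sd=2,
        levels=levels,
        outcome_noise_sd=0.004,
    )


class TestRunStudyStats:
    def test_subnetwork_level_has_six_fdr_values_per_family(self):
        cohort = small_cohort(levels=("global", "subnetwork"), seed=3)
        table = run_study_stats(cohort, "subnetwork")
        for _, sub in table.groupby("test"):
            assert len(sub) == 6
            assert sub["p_fdr"].notna().all()
        glob = run_study_stats(cohort, "global")
        assert glob["p_fdr"].isna().all()

    def test_planted_effect_detected_by_whole_sample_paired_t(self):
        cohort = small_cohort(effect=0.01, seed=5, n=(12, 13))
        table = run_study_stats(cohort, "global")
        row = table[table["test"] == "paired_all"].iloc[0]
        assert row["statistic"] > 0
        assert row["p"] < 0.05

    def test_null_cohorts_rarely_significant(self):
        ps = []
        for seed in range(12):
            table = run_study_stats(small_cohort(effect=0.0, seed=seed), "global")
            ps.append(table[table["test"] == "paired_all"]["p"].iloc[0])
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_invariant_to_subject_order(self):
        cohort = small_cohort(seed=7)
        table1 = run_study_stats(cohort, "global")
        shuffled = Cohort(
            subjects=cohort.subjects.iloc[::-1],
            outcomes=cohort.outcomes.iloc[::-1],
        )
        table2 = run_study_stats(shuffled, "global")
        merged = table1.merge(table2, on=["test", "outcome"], suffixes=("_a", "_b"))
        assert np.allclose(merged["statistic_a"], merged["statistic_b"], atol=1e-10)

    def test_missing_scan_excluded_and_reported(self):
        cohort = small_cohort(seed=9)
        dropped = cohort.outcomes.drop(index=[(cohort.subjects.index[0], "post")])
        table = run_study_stats(
            Cohort(subjects=cohort.subjects, outcomes=dropped), "global"
        )
        assert cohort.subjects.index[0] in table.attrs["excluded_subjects"]
        assert table[table["test"] == "paired_all"]["n"].iloc[0] == len(cohort.subjects) - 1
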