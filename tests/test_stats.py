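"""Comparison suite: chi-square, t, Mann–Whitney, normality, ICC, AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from renalct import phantom, stats


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        res = stats.pearson_chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_symmetry_under_transpose_and_permutation(self):
        t = np.array([[48, 7], [26, 24]])
        base = stats.pearson_chi_square(t).statistic
        assert stats.pearson_chi_square(t.T).statistic == pytest.approx(base)
        assert stats.pearson_chi_square(t[::-1]).statistic == pytest.approx(base)
        assert stats.pearson_chi_square(t[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            stats.pearson_chi_square([[0, 0], [5, 3]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            stats.pearson_chi_square([[1.5, 2], [3, 4]])


class TestPooledT:
    def test_summary_and_raw_paths_agree(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 25)
        raw = stats.pooled_t(x, y)
        summ = stats.pooled_t_from_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)
        assert raw.df == x.size + y.size - 2

    def test_equal_means_give_zero(self):
        res = stats.pooled_t_from_summary(5.0, 1.0, 10, 5.0, 3.0, 12)
        assert res.statistic == pytest.approx(0.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            stats.pooled_t_from_summary(1, 1, 1, 2, 1, 5)


def _brute_force_mwu_p(x, y):
    """Exact two-sided p by enumerating label assignments, counting pairs."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return min(u, len(xs) * len(ys) - u)

    u_obs = u_stat(range(n1))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        hits += u_stat(idx) <= u_obs + 1e-9
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples_give_zero_z(self):
        x = np.arange(10.0)
        res = stats.mann_whitney_z(x, x, method="asymptotic")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_complete_separation_reaches_no_tie_maximum(self):
        x = np.arange(100, 108.0)
        y = np.arange(0, 6.0)
        res = stats.mann_whitney_z(x, y, method="asymptotic")
        n1, n2 = len(x), len(y)
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert res.extras["u"] == n1 * n2
        assert abs(res.statistic) == pytest.approx(n1 * n2 / 2 / sigma)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_sample_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(0, 13.0))[:6]
        y = rng.permutation(np.arange(20, 33.0) + 0.5)[:5]
        res = stats.mann_whitney_z(x, y)  # auto -> exact for small tie-free
        assert res.extras["method"] == "exact"
        assert res.p_value == pytest.approx(_brute_force_mwu_p(x, y), abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            stats.mann_whitney_z([1.0, 1.0], [1.0, 1.0, 1.0])


class TestNormalityCheck:
    def test_normal_samples_usually_pass(self):
        flags = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(10, 2, size=150)
            flags.append(stats.ks_normality(x)[2])
        assert np.mean(flags) >= 0.90  # 1 - alpha with binomial slack

    def test_heavy_skew_detected(self):
        x = np.random.default_rng(1).lognormal(0.0, 1.0, size=200)
        stat, p, ok = stats.ks_normality(x)
        assert not ok and p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.ks_normality(np.full(20, 3.0))


class TestDispatch:
    def test_categorical_goes_to_chi_square(self, published_cohort):
        res = stats.compare_groups(published_cohort, "gender")
        assert res.test == "chi-square"

    def test_normal_feature_goes_to_t(self, published_cohort):
        res = stats.compare_groups(published_cohort, "AVT_PCP_1")
        assert res.test == "pooled-t"

    def test_skewed_feature_goes_to_mann_whitney(self, published_cohort):
        df = published_cohort[["label"]].copy()
        rng = np.random.default_rng(5)
        df["skewed"] = rng.lognormal(0, 1.2, size=len(df))
        res = stats.compare_groups(df, "skewed")
        assert res.test == "mann-whitney"

    def test_missing_class_rejected(self, published_cohort):
        solo = published_cohort[published_cohort.label == "ccRCC"]
        with pytest.raises(ValueError):
            stats.compare_groups(solo, "AVT_PCP_1")


class TestICC:
    def test_identical_observers_give_one(self):
        vals = np.random.default_rng(0).normal(100, 20, size=30)
        assert stats.icc_agreement(np.c_[vals, vals]) == 1.0

    def test_equal_variance_components_give_half(self):
        # noise variance == between-lesion variance -> ICC ~ 0.5
        rng = np.random.default_rng(7)
        truth = rng.normal(0, 10, size=3000)
        obs = np.c_[truth + rng.normal(0, 10, 3000),
                    truth + rng.normal(0, 10, 3000)]
        assert stats.icc_agreement(obs) == pytest.approx(0.5, abs=0.05)

    def test_observer_simulation_reaches_good_agreement_band(self):
        # calibrated reading noise is small next to between-lesion spread
        cfg = phantom.CohortConfig(seed=2)
        truth = phantom.simulate_cohort(cfg).set_index("lesion_id")[
            ["AVT_CMP_1"]]
        reps = phantom.simulate_observer_measurements(
            truth, noise_sd=5.0, n_observers=2, seed=3)
        wide = reps.pivot_table(index="lesion_id", columns="observer",
                                values="value")
        icc = stats.icc_agreement(wide.to_numpy())
        assert 0.75 < icc <= 1.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            stats.icc_agreement(np.ones((5, 1)))
        with pytest.raises(ValueError):
            stats.icc_agreement(np.ones((2, 2)))


class TestROC:
    def test_perfect_separation(self):
        r = stats.roc_auc([1, 2, 3, 10, 11, 12],
                          ["AML.wovf"] * 3 + ["ccRCC"] * 3)
        assert r.auc == 1.0 and r.ci_upper <= 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=3000)
        labels = np.where(rng.random(3000) < 0.5, "ccRCC", "AML.wovf")
        assert stats.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_four_point_example_matches_pair_counting(self):
        scores = np.array([1, 2, 3, 4.0])
        labels = np.array(["AML.wovf", "AML.wovf", "ccRCC", "ccRCC"])
        # brute force over the 2x2 score pairs
        pos = scores[labels == "ccRCC"]
        neg = scores[labels != "ccRCC"]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert stats.roc_auc(scores, labels).auc == pytest.approx(brute)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_u_over_n1n2(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1, 1, 40)  # positive-class scores
        y = rng.normal(0, 1, 25)
        labels = np.r_[["ccRCC"] * 40, ["AML.wovf"] * 25]
        res = stats.mann_whitney_z(x, y, method="asymptotic")
        auc = stats.roc_auc(np.r_[x, y], labels).auc
        assert auc == pytest.approx(res.extras["u"] / (40 * 25), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_auc([1, 2, 3], ["ccRCC"] * 3)

    def test_inverted_marker_is_oriented(self):
        # lower scores in the positive class: AUC reported >= 0.5, flagged
        r = stats.roc_auc([10, 11, 12, 1, 2, 3],
                          ["AML.wovf"] * 3 + ["ccRCC"] * 3)
        assert r.auc == 1.0 and r.direction == "less"
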