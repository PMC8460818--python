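"""Statistical layer checked against brute-force enumeration oracles,
hand arithmetic and closed-form expectations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from periglioma.stats_survival import (cohens_d, cohens_d_paired, cox_ph,
                                       fdr_adjust, km_median_split,
                                       kruskal_wallis, mann_whitney_u,
                                       spearman_corr, wilcoxon_signed_rank,
                                       zscore_vs_controls)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def exact_spearman_p(x, y):
    """Two-sided permutation p over all n! orderings of y's ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, perm)[0, 1])
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def exact_mannwhitney_p(a, b):
    """Two-sided p over all C(n_a+n_b, n_a) group labelings."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    obs = u_stat(range(na))
    mean_u = na * (len(pooled) - na) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        if abs(u_stat(idx) - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def exact_wilcoxon_p(diffs):
    """Two-sided exact p (doubled smaller tail of the positive-rank sum,
    capped at 1) over all 2^n sign assignments of |differences|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    le = ge = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        le += w <= obs + 1e-12
        ge += w >= obs - 1e-12
        total += 1
    return min(1.0, 2.0 * min(le, ge) / total)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        res = spearman_corr([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert res.statistic == pytest.approx(1.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 120)

    def test_reversal_rho_minus_one(self):
        res = spearman_corr([1, 2, 3, 4], [9, 6, 4, 1])
        assert res.statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = spearman_corr(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_spearman_p(x, y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_nonfinite_pairs_dropped(self):
        res = spearman_corr([1, 2, 3, 4, 5, np.nan],
                            [1, 2, 3, 4, 5, 100.0])
        assert res.n == (5,)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [5, 6, 7, 8])
        assert res.statistic == 0.0  # U of the first (smaller-valued) group
        assert res.method == "exact"

    def test_identical_groups_p_near_one(self):
        res = mann_whitney_u([1, 2, 3, 4], [1.5, 2.5, 3.5, 0.5])
        assert res.p_value > 0.5

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=4)
        res = mann_whitney_u(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_large_samples_use_asymptotic(self, rng):
        res = mann_whitney_u(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "asymptotic"


class TestWilcoxon:
    def test_all_positive_differences_n6(self):
        a = np.array([5.0, 6, 7, 8, 9, 10])
        b = a - np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 64)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", [7, 8])
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = a + rng.normal(size=8) * 0.8
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_wilcoxon_p(a - b))

    def test_null_p_values_approximately_uniform(self, rng):
        ps = [wilcoxon_signed_rank(rng.normal(size=9),
                                   np.zeros(9)).p_value
              for _ in range(400)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)
        assert np.mean(np.array(ps) < 0.05) < 0.1

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_signed_rank([1.0], [0.5])

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)


class TestKruskalWallis:
    def test_three_singletons_hand_value(self):
        # ranks 1,2,3; H = 12/(3*4) * sum (r_i - 2)^2 * 1 = 2
        res = kruskal_wallis([1.0], [5.0], [9.0])
        assert res.statistic == pytest.approx(2.0)

    def test_two_group_consistency_with_mann_whitney(self, rng):
        # without ties, H equals the squared standardized U statistic
        a, b = rng.normal(size=8), rng.normal(size=11)
        h = kruskal_wallis(a, b).statistic
        u = mann_whitney_u(a, b).statistic
        na, nb = len(a), len(b)
        z2 = (u - na * nb / 2) ** 2 / (na * nb * (na + nb + 1) / 12)
        assert h == pytest.approx(z2)

    def test_type_one_error_near_nominal(self, rng):
        hits = 0
        reps = 600
        for _ in range(reps):
            g = [rng.normal(size=10) for _ in range(3)]
            hits += kruskal_wallis(*g).p_value < 0.05
        assert abs(hits / reps - 0.05) < 0.03

    def test_identical_observations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([2.0, 2.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# effect sizes, z-scores, FDR
# ---------------------------------------------------------------------------

class TestEffectSizes:
    def test_one_pooled_sd_difference_is_d_one(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 1, 2000)
        assert cohens_d(b, a) == pytest.approx(1.0, abs=0.1)

    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_hand_formula_fixture(self):
        a, b = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        sp = math.sqrt(((3 - 1) * 4.0 + (3 - 1) * 1.0) / 4)
        assert cohens_d(a, b) == pytest.approx((4.0 - 2.0) / sp)

    def test_paired_effect_size(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        b = a - np.array([1.0, 2.0, 1.0, 2.0])
        d = a - b
        assert cohens_d_paired(a, b) == pytest.approx(
            d.mean() / d.std(ddof=1))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestFdr:
    def test_benjamini_hochberg_step_up(self):
        reject, adj = fdr_adjust([0.01, 0.02, 0.04])
        assert reject.all()
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones_none_rejected(self):
        reject, _ = fdr_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_test_reduces_to_alpha(self):
        assert fdr_adjust([0.049])[0][0]
        assert not fdr_adjust([0.051])[0][0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestZScores:
    def test_patient_at_control_mean_is_zero(self):
        z = zscore_vs_controls([3.0], [1.0, 3.0, 5.0])
        assert z[0] == 0.0

    def test_one_control_sd_above_is_one(self):
        controls = [1.0, 2.0, 3.0, 4.0]
        sd = np.std(controls, ddof=1)
        z = zscore_vs_controls([2.5 + sd], controls)
        assert z[0] == pytest.approx(1.0)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore_vs_controls([1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _survival_frame(rng, n=120, beta=0.0):
    z = rng.normal(size=n)
    lam = 0.02 * np.exp(beta * z)
    t = rng.exponential(1 / lam)
    c = rng.exponential(80, size=n)
    return pd.DataFrame({"time_weeks": np.minimum(t, c),
                         "event": t <= c,
                         "activity_z": z,
                         "age": rng.normal(44, 10, n),
                         "grade": rng.choice([2.0, 3.0, 4.0], size=n)})


class TestCox:
    def test_estimates_and_ci_structure(self, rng):
        df = _survival_frame(rng, beta=0.7)
        est = cox_ph(df, ["activity_z", "age", "grade"])
        he = est["activity_z"]
        assert he.ci_95[0] < he.hazard_ratio < he.ci_95[1]
        assert he.hazard_ratio > 1.0
        assert he.n_events == int(df["event"].sum())

    def test_all_censored_rejected(self, rng):
        df = _survival_frame(rng)
        df["event"] = False
        with pytest.raises(ValueError, match="no events"):
            cox_ph(df, ["activity_z"])


class TestKaplanMeier:
    def test_no_events_curves_stay_at_one(self, rng):
        df = pd.DataFrame({"time_weeks": rng.uniform(1, 50, 10),
                           "event": [False] * 10})
        curves, thr = km_median_split(df, np.arange(10))
        for c in curves.values():
            assert np.allclose(c.to_numpy(), 1.0)

    def test_product_limit_steps_match_hand_oracle(self):
        # high group: 4 subjects, events at distinct times 1 < 2 < 3 < 4
        df = pd.DataFrame({"time_weeks": [1.0, 2.0, 3.0, 4.0,
                                          9.0, 9.0, 9.0, 9.0],
                           "event": [True] * 4 + [False] * 4})
        act = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        curves, thr = km_median_split(df, act)
        high = curves["high"]
        # S(t) after k-th of 4 distinct events is 1 - k/4
        for t, expected in [(1.0, 0.75), (2.0, 0.5), (3.0, 0.25),
                            (4.0, 0.0)]:
            assert high.loc[t].iloc[0] == pytest.approx(expected)

    def test_identical_activity_split_rejected(self, rng):
        df = pd.DataFrame({"time_weeks": rng.uniform(1, 50, 6),
                           "event": [True] * 6})
        with pytest.raises(ValueError, match="degenerate"):
            km_median_split(df, np.ones(6))
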