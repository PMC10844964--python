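import itertools

import numpy as np
import pytest
from scipy import stats as sps

from spatialtme.stats import (
    band_covariate,
    km_curve,
    km_logrank,
    logrank,
    median_split,
    spearman,
    spearman_screen,
    threshold_split,
    wilcoxon_rank_sum,
)
from spatialtme.io_tables import SurvivalRecord
from spatialtme.synthetic import make_profile

import pandas as pd


class TestWilcoxonRankSum:
    def test_exact_separated_groups(self):
        # oracle: of the C(6,3)=20 rank splits only (1,2,3) and (4,5,6)
        # are at least as extreme, so p = 2/20 = 0.1
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], family_size=1)
        assert res.method == "exact"
        assert res.p_raw == pytest.approx(0.1)

    def test_exact_enumeration_oracle(self, rng):
        # independent full-enumeration oracle on random data without ties
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        res = wilcoxon_rank_sum(a, b)
        ranks = sps.rankdata(a + b)
        n_a = len(a)
        mean_u = len(a) * len(b) / 2
        obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        count = total = 0
        for comb in itertools.combinations(range(len(ranks)), n_a):
            u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
            if abs(u - mean_u) >= abs(obs - mean_u) - 1e-12:
                count += 1
            total += 1
        assert res.p_raw == pytest.approx(count / total)

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_raw == 1.0

    def test_bonferroni_arithmetic(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], family_size=4)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 4))
        res2 = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], family_size=100)
        assert res2.p_adjusted == 1.0

    def test_normal_approximation_matches_scipy(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "normal"
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, p = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_five_point_example_exact_permutation(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(0.8)
        # oracle: enumerate all 120 permutations of y
        rx = np.asarray(x, dtype=float)
        count = total = 0
        for perm in itertools.permutations(y):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= 0.8 - 1e-12:
                count += 1
            total += 1
        assert total == 120
        assert p == pytest.approx(count / total)

    def test_constant_input_flagged_not_raised(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_screen_shape_and_flags(self, rng):
        n = 20
        df = pd.DataFrame(
            {"f1": rng.normal(size=n), "f2": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        )
        out = pd.DataFrame(
            {"event": rng.integers(0, 2, n), "time": rng.exponential(10, n)},
            index=df.index,
        )
        res = spearman_screen(df, out)
        assert len(res) == 4
        assert (res["p_adjusted"] >= res["p"] - 1e-12).all()
        assert (res["p_adjusted"] <= 1.0 + 1e-12).all()

    def test_screen_constant_column_nan(self):
        idx = ["P1", "P2", "P3", "P4"]
        feats = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]}, index=idx)
        out = pd.DataFrame({"event": [0, 1, 0, 1]}, index=idx)
        res = spearman_screen(feats, out)
        assert np.isnan(res["rho"].iloc[0])


class TestSplits:
    def test_even_median_split(self):
        hi, lo = median_split({"A": 1, "B": 2, "C": 3, "D": 4})
        assert set(hi) == {"C", "D"} and set(lo) == {"A", "B"}

    def test_tie_at_median_goes_lo(self):
        hi, lo = median_split({"A": 1, "B": 2, "C": 3})
        assert set(hi) == {"C"} and set(lo) == {"A", "B"}

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            hi, lo = median_split({"A": 1.0, "B": 1.0})
        assert hi == [] and set(lo) == {"A", "B"}

    def test_threshold_zero_split(self):
        hi, lo = threshold_split({"A": 0.0, "B": 0.0, "C": 1.7}, threshold=0.0)
        assert set(hi) == {"C"} and set(lo) == {"A", "B"}


def hand_logrank(times_a, times_b):
    """Oracle: 2x2 table accumulation at every event time (all events)."""
    all_t = sorted(set(times_a) | set(times_b))
    o_minus_e = var = 0.0
    for t in all_t:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        n = na + nb
        da = times_a.count(t)
        db = times_b.count(t)
        d = da + db
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKmLogrank:
    def test_km_no_censoring_equals_empirical(self):
        times = [5.0, 1.0, 3.0, 2.0, 4.0]
        t, s = km_curve(times, [True] * 5)
        for ti, si in zip(t[1:], s[1:]):
            emp = np.mean(np.asarray(times) > ti)
            assert si == pytest.approx(emp)

    def test_km_nonincreasing_starts_at_one(self, rng):
        times = rng.exponential(10, 30)
        events = rng.uniform(size=30) < 0.7
        t, s = km_curve(times, events)
        assert t[0] == 0.0 and s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_km_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(10, 50)
        events = rng.uniform(size=50) < 0.6
        t, s = km_curve(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for ti, si in zip(t, s):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-9
            )

    def test_identical_groups_chi2_zero(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        chi2, p, _ = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_event_fixture_matches_hand_tables(self):
        a = [2.0, 4.0, 6.0]
        b = [1.0, 3.0, 5.0]
        chi2, p, ome = logrank(a, [True] * 3, b, [True] * 3)
        oracle = hand_logrank(a, b)
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(float(sps.chi2.sf(oracle, 1)))

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        ta = rng.exponential(10, 40)
        ea = rng.uniform(size=40) < 0.7
        tb = rng.exponential(15, 35)
        eb = rng.uniform(size=35) < 0.7
        chi2, p, _ = logrank(ta, ea, tb, eb)
        ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_flagged_undefined(self):
        chi2, p, _ = logrank([1.0, 2.0], [False, False], [3.0], [False])
        assert chi2 == 0.0 and np.isnan(p)

    def test_label_swap_invariance(self, rng):
        ta = list(rng.exponential(10, 20))
        ea = list(rng.uniform(size=20) < 0.8)
        tb = list(rng.exponential(5, 20))
        eb = list(rng.uniform(size=20) < 0.8)
        c1, p1, o1 = logrank(ta, ea, tb, eb)
        c2, p2, o2 = logrank(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2)
        assert p1 == pytest.approx(p2)
        assert o1 == pytest.approx(-o2)

    def test_km_logrank_wrapper(self):
        recs = [
            SurvivalRecord(f"P{i}", t, True)
            for i, t in enumerate([2.0, 4.0, 6.0, 1.0, 3.0, 5.0])
        ]
        split = km_logrank(recs, ["P0", "P1", "P2"], ["P3", "P4", "P5"])
        assert split.logrank_chi2 == pytest.approx(
            hand_logrank([2.0, 4.0, 6.0], [1.0, 3.0, 5.0])
        )
        assert split.km_hi[1][0] == 1.0


class TestBandCovariate:
    def profiles(self):
        edges = [-50.0, 0.0, 50.0, 100.0]  # centers -25, 25, 75
        return {"P1": make_profile(edges, [1.0, 2.0, 3.0])}

    def test_lookup(self):
        cov = band_covariate(self.profiles(), 75.0)
        assert cov["P1"] == pytest.approx(3.0)

    def test_off_grid_band_lists_centers(self):
        with pytest.raises(ValueError, match=r"-25\.0, 25\.0, 75\.0"):
            band_covariate(self.profiles(), 50.0)
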