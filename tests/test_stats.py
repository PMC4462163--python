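import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from wholegrain import (
    DiaryOccasion,
    Participant,
    estimate_all,
    expand_by_weight,
    kruskal_wallis,
    linear_trend,
    mann_whitney,
    summarize,
    weighted_quantile,
)

# ---------------------------------------------------------------------------
# Weighted quantiles


class TestWeightedQuantile:
    def test_cumulative_weight_definition(self):
        # cumulative normalised weights 0.25, 0.5, 1.0 -> first >= 0.5 is 20
        assert weighted_quantile([10, 20, 30], [1, 1, 2], 0.5) == 20

    def test_equal_weights_odd_n_is_sample_median(self):
        vals = [7.0, 1.0, 5.0, 3.0, 9.0]
        assert weighted_quantile(vals, [1] * 5, 0.5) == np.median(vals)

    def test_boundaries(self):
        vals, w = [4.0, 8.0, 15.0], [2.0, 1.0, 0.5]
        assert weighted_quantile(vals, w, 0.0) == 4.0
        assert weighted_quantile(vals, w, 1.0) == 15.0

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_quantile([], [], 0.5)
        with pytest.raises(ValueError):
            weighted_quantile([1.0], [0.0], 0.5)
        with pytest.raises(ValueError):
            weighted_quantile([1.0], [1.0], 1.5)

    @settings(derandomize=True, max_examples=150)
    @given(
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.integers(1, 4)), min_size=1, max_size=12
        ),
        q=st.floats(0, 1),
    )
    def test_integer_weights_equal_expanded_sample(self, data, q):
        """Weighted type-1 quantile == type-1 quantile of the expanded sample."""
        vals = [v for v, _ in data]
        wts = [w for _, w in data]
        expanded = np.sort(expand_by_weight(vals, wts))
        k = max(int(math.ceil(q * expanded.size)) - 1, 0)
        assert weighted_quantile(vals, wts, q) == expanded[k]


# ---------------------------------------------------------------------------
# Mann-Whitney


def _enumeration_oracle(x, y):
    """Exact two-sided p by direct pairwise counting over all assignments.

    Independent of the implementation's midrank path: for every way of
    labelling the pooled values as x, U is recomputed by comparing every
    (x, y) pair directly.
    """
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mu = nx * (len(pooled) - nx) / 2.0
    u_obs = u_of(tuple(range(nx)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        if abs(u_of(idx) - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments
        assert res.meta["exact"]

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_is_pairwise_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 6, size=rng.integers(2, 7)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(2, 7)).astype(float)
            res = mann_whitney(x, y)
            brute = sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y
            )
            assert res.statistic == pytest.approx(brute)

    def test_exact_p_matches_enumeration_for_all_small_layouts(self):
        """Exhaustive over sample-size splits with total n <= 8, incl. ties."""
        rng = np.random.default_rng(23)
        for n in range(2, 9):
            for nx in range(1, n):
                for pool in ("continuous", "tied"):
                    if pool == "continuous":
                        vals = rng.normal(size=n)
                    else:
                        vals = rng.integers(0, 3, size=n).astype(float)
                    x, y = vals[:nx], vals[nx:]
                    res = mann_whitney(x, y)
                    u_oracle, p_oracle = _enumeration_oracle(x, y)
                    assert res.statistic == pytest.approx(u_oracle)
                    assert res.p_value == pytest.approx(p_oracle), (n, nx, pool)

    def test_large_sample_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1.0, size=25)
        res = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_hand_rank_closed_form(self):
        # ranks 1..6, group mean ranks 1.5/3.5/5.5 -> H = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)
        assert res.meta["df"] == 2

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        groups = [rng.integers(0, 8, size=m).astype(float) for m in (7, 9, 11)]
        res = kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_two_groups_consistent_with_mann_whitney_z(self):
        """No ties, two groups: H equals the squared Mann-Whitney z-score."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=14)
        y = rng.normal(0.8, 1.0, size=12)
        h = kruskal_wallis([x, y]).statistic
        z = mann_whitney(x, y).meta["z"]
        assert h == pytest.approx(z**2)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=m) for m in (5, 8, 6)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_all_identical_values(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


# ---------------------------------------------------------------------------
# Linear trend


class TestLinearTrend:
    def test_perfect_fit(self):
        res = linear_trend([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(1.0)
        assert res.meta["se"] == 0.0
        assert res.p_value == 0.0

    def test_constant_response(self):
        res = linear_trend([5, 5, 5, 5], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_closed_form_slope_on_random_fixture(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 9, size=40).astype(float)
        y = 0.7 * x + rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, size=40)
        res = linear_trend(y, x, w)
        xbar = np.sum(w * x) / np.sum(w)
        ybar = np.sum(w * y) / np.sum(w)
        slope = np.sum(w * (x - xbar) * (y - ybar)) / np.sum(w * (x - xbar) ** 2)
        assert res.statistic == pytest.approx(slope)

    def test_matches_statsmodels_wls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        x = rng.integers(1, 10, size=60).astype(float)
        y = 0.4 * x + rng.normal(size=60)
        w = rng.uniform(0.2, 3.0, size=60)
        res = linear_trend(y, x, w)
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert res.statistic == pytest.approx(fit.params[1])
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_single_band_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([1, 2], [3, 3])


# ---------------------------------------------------------------------------
# Stratified summaries


def _fixture_population(small_registry):
    participants = [
        Participant("M1", 30, "male", 1, 1.0, 4, 8.0),
        Participant("M2", 40, "male", 2, 1.0, 4, 10.0),
        Participant("F1", 35, "female", 3, 1.0, 4, 8.0),
        Participant("F2", 50, "female", None, 2.0, 4, 8.0),
        Participant("F3", 16, "female", 6, 1.0, 4, 7.0),
    ]
    occasions = [
        DiaryOccasion("M1", 1, "F_BREAD", 200.0),   # 120 g WG -> 30 g/d
        DiaryOccasion("M2", 1, "F_CEREAL", 100.0),  # 40 g -> 10 g/d
        DiaryOccasion("F1", 1, "F_BREAD", 100.0),   # 60 g -> 15 g/d
        DiaryOccasion("F2", 1, "F_BREAD", 400.0),   # 240 g -> 60 g/d
        # F3 consumes nothing
    ]
    return participants, occasions


class TestSummarize:
    def test_hand_computed_weighted_medians_by_sex(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        by_sex = {
            s.stratum: s for s in summarize(intakes, participants, by="sex")
        }
        # males: values 30, 10 equal weights -> type-1 median = 10
        assert by_sex["male"].median == 10.0
        # females: values (15 w1), (60 w2), (0 w1): cum 0.25 (0), 0.5 (15), 1.0 (60)
        assert by_sex["female"].median == 15.0
        assert by_sex["female"].q75 == 60.0
        assert by_sex["female"].minimum == 0.0 and by_sex["female"].maximum == 60.0
        # non-consumers: F3 (weight 1 of total 4) -> 25 %
        assert by_sex["female"].percent_nonconsumers == pytest.approx(25.0)

    def test_all_zero_intakes(self, small_registry):
        participants, _ = _fixture_population(small_registry)
        intakes = estimate_all([], participants, small_registry)
        for s in summarize(intakes, participants, by="adult_child"):
            assert s.median == 0.0
            assert s.percent_nonconsumers == 100.0

    def test_missing_nssec_excluded_only_from_nssec_strata(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        nssec_n = sum(s.n for s in summarize(intakes, participants, by="nssec"))
        sex_n = sum(s.n for s in summarize(intakes, participants, by="sex"))
        assert nssec_n == 4  # F2 has no NS-SEC
        assert sex_n == 5

    def test_energy_adjusted_values_used(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        by_sex = {
            s.stratum: s
            for s in summarize(intakes, participants, by="sex", energy_adjusted=True)
        }
        # M1: 30 g/d at 8 MJ -> 37.5; M2: 10 g/d at 10 MJ -> 10
        assert by_sex["male"].median == 10.0
        assert by_sex["male"].maximum == pytest.approx(37.5)

    def test_age_bands_and_ordering(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        labels = [s.stratum for s in summarize(intakes, participants, by="age_band")]
        assert labels == ["13-17", "25-34", "35-44", "45-54"]

    def test_unknown_stratum_variable(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        with pytest.raises(ValueError, match="unknown stratum"):
            summarize(intakes, participants, by="height")

    def test_invariants_q25_le_median_le_q75(self, small_registry):
        participants, occasions = _fixture_population(small_registry)
        intakes = estimate_all(occasions, participants, small_registry)
        for by in ("sex", "age_band", "nssec", "adult_child"):
            for s in summarize(intakes, participants, by=by):
                assert s.minimum <= s.q25 <= s.median <= s.q75 <= s.maximum
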