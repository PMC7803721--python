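import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from strokedti.errors import DesignError, ParameterError
from strokedti.stats import (
    correlate,
    group_time_test,
    holm_sidak_ttests,
    kruskal_dunn,
    mann_whitney,
    slope_compare,
    split_plot_anova,
    validate_study_table,
)


def holm_sidak_oracle(raw):
    """Hand-applied step-down formula: sorted p_(i) ->
    1 - (1 - p_(i))^(m - i), cumulative max."""
    raw = np.asarray(raw, float)
    m = len(raw)
    order = np.argsort(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - raw[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


class TestHolmSidak:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        res = holm_sidak_ttests([(a, a.copy())])
        assert res[0].p_raw == pytest.approx(1.0)
        assert res[0].p_adj == pytest.approx(1.0)

    def test_single_pair_unadjusted(self):
        rng = np.random.default_rng(0)
        res = holm_sidak_ttests([(rng.normal(size=5), rng.normal(1, 1, 6))])
        assert res[0].p_adj == pytest.approx(res[0].p_raw)

    def test_three_pairs_match_hand_formula(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.normal(0, 1, 6), rng.normal(d, 1, 6)) for d in (2.5, 1.5, 0.1)]
        res = holm_sidak_ttests(pairs)
        raw = [r.p_raw for r in res]
        adj = holm_sidak_oracle(raw)
        for r, a in zip(res, adj):
            assert r.p_adj == pytest.approx(a, rel=1e-9)
            assert r.p_adj >= r.p_raw - 1e-15

    @given(hst.lists(hst.floats(0.001, 0.999), min_size=2, max_size=6),
           hst.integers(0, 5))
    def test_adjustment_monotone_in_raw_p(self, raw, bump_idx):
        """Increasing any raw p never decreases any adjusted p."""
        raw = np.asarray(raw)
        bump_idx = bump_idx % len(raw)
        bumped = raw.copy()
        bumped[bump_idx] = min(0.9999, bumped[bump_idx] * 1.5)
        a0, a1 = holm_sidak_oracle(raw), holm_sidak_oracle(bumped)
        assert np.all(a1 >= a0 - 1e-12)


class TestSplitPlot:
    def test_all_equal_gives_p_one(self):
        g = [np.full((3, 4), 2.0), np.full((4, 4), 2.0)]
        res = split_plot_anova(g)
        assert res.p_interaction == 1.0 and res.f_interaction == 0.0

    def test_matches_pingouin_mixed_anova(self):
        """Independent oracle: pingouin's split-plot (mixed) ANOVA."""
        import pingouin as pg

        rng = np.random.default_rng(8)
        arrays = [rng.normal(0, 1, (5, 4)), rng.normal(0.8, 1, (4, 4))]
        res = split_plot_anova(arrays)
        rows = []
        for gi, arr in enumerate(arrays):
            for si in range(arr.shape[0]):
                for di in range(arr.shape[1]):
                    rows.append({"subject": f"g{gi}s{si}", "group": f"g{gi}",
                                 "day": di, "value": arr[si, di]})
        df = pd.DataFrame(rows)
        aov = pg.mixed_anova(df, dv="value", within="day", subject="subject",
                             between="group").set_index("Source")
        assert res.f_group == pytest.approx(aov.loc["group", "F"], rel=1e-8)
        assert res.p_group == pytest.approx(aov.loc["group", "p_unc"], rel=1e-8)
        assert res.f_day == pytest.approx(aov.loc["day", "F"], rel=1e-8)
        assert res.f_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-8)
        assert res.p_interaction == pytest.approx(aov.loc["Interaction", "p_unc"],
                                                  rel=1e-8)


def make_table(group_arrays, days, measure="m"):
    rows = []
    for gi, arr in enumerate(group_arrays):
        for si in range(arr.shape[0]):
            for di, day in enumerate(days):
                rows.append({"subject_id": f"g{gi}s{si}", "group": f"g{gi}",
                             "day": day, "measure": measure, "value": arr[si, di]})
    return pd.DataFrame(rows)


class TestGroupTimeTest:
    def test_flat_data_nothing_significant(self):
        table = make_table([np.full((3, 3), 1.0), np.full((3, 3), 1.0)], [1, 2, 3])
        res = group_time_test(table, "m", ["g0", "g1"], [1, 2, 3])
        assert len(res) == 3  # gate closed: no contrasts emitted
        assert all(r.p_adj == 1.0 for r in res)

    def test_late_shift_detected_with_gated_contrasts(self):
        rng = np.random.default_rng(3)
        g0 = rng.normal(0, 0.2, (5, 4))
        g1 = rng.normal(0, 0.2, (5, 4))
        g1[:, 2:] += 3.0  # shift at late days only
        res = group_time_test(make_table([g0, g1], [1, 2, 3, 4]),
                              "m", ["g0", "g1"], [1, 2, 3, 4])
        by = {r.comparison: r for r in res}
        assert by["m: group x day"].significant
        assert by["m day 3: g0 vs g1"].significant
        assert not by["m day 1: g0 vs g1"].significant

    def test_contrasts_bonferroni_adjusted(self):
        rng = np.random.default_rng(4)
        g0, g1 = rng.normal(0, 1, (4, 3)), rng.normal(3, 1, (4, 3))
        res = group_time_test(make_table([g0, g1], [1, 2, 3]),
                              "m", ["g0", "g1"], [1, 2, 3])
        contrasts = [r for r in res if "vs" in r.comparison]
        assert contrasts
        for r in contrasts:
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * len(contrasts)))

    def test_missing_group_rejected(self):
        table = make_table([np.zeros((3, 3))], [1, 2, 3])
        with pytest.raises(DesignError):
            group_time_test(table, "m", ["g0", "missing"], [1, 2, 3])

    def test_unbalanced_uses_mixed_model(self):
        rng = np.random.default_rng(5)
        table = make_table([rng.normal(0, 1, (4, 3)), rng.normal(0, 1, (4, 3))],
                           [1, 2, 3])
        table = table.drop(table[(table.subject_id == "g0s0")
                                 & (table.day == 3)].index)
        res = group_time_test(table, "m", ["g0", "g1"], [1, 2, 3])
        assert res[0].test.startswith("mixed-effects")
        assert all(0 <= r.p_raw <= 1 for r in res)

    def test_duplicate_rows_rejected(self):
        table = make_table([np.zeros((2, 2)), np.zeros((2, 2))], [1, 2])
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError):
            validate_study_table(dup)


def kruskal_oracle(samples):
    """Tie-corrected H from first principles."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    offsets = np.cumsum([0] + [len(s) for s in samples])
    h = 12.0 / (n * (n + 1)) * sum(
        len(s) * ranks[offsets[k]:offsets[k + 1]].mean() ** 2
        for k, s in enumerate(samples)
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_dunn([np.ones(4), np.ones(4), np.ones(4)])
        assert res[0].statistic == 0.0 and res[0].p_raw == 1.0

    def test_h_matches_hand_ranked_oracle(self):
        samples = [np.array([1.0, 5.0, 8.0, 2.0]),
                   np.array([3.0, 3.0, 7.0, 9.0]),
                   np.array([4.0, 6.0, 2.0, 10.0])]
        res = kruskal_dunn(samples)
        assert res[0].statistic == pytest.approx(kruskal_oracle(samples), rel=1e-10)

    def test_shifted_group_flagged_only(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        c = rng.normal(12, 1, 8)
        res = kruskal_dunn([a, b, c], labels=["a", "b", "c"])
        by = {r.comparison: r for r in res if r.test == "dunn"}
        assert by["a vs c"].significant and by["b vs c"].significant
        assert not by["a vs b"].significant

    def test_dunn_gated_on_omnibus(self):
        rng = np.random.default_rng(7)
        res = kruskal_dunn([rng.normal(size=4) for _ in range(3)])
        if res[0].p_raw >= 0.05:
            assert len(res) == 1  # no post hoc without a significant omnibus


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert mann_whitney(a, a.copy()).p_raw == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        res = mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_u_equals_pairwise_comparison_count(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=5)
        res = mann_whitney(a, b)
        u_oracle = sum(
            (x < y) + 0.5 * (x == y) for x, y in itertools.product(a, b))
        # scipy reports U for the first sample = #(a > b) pairs
        assert res.statistic == pytest.approx(len(a) * len(b) - u_oracle)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, r2, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_four_point_toy_is_point_eight(self):
        r, r2, p = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert r2 == pytest.approx(0.64, abs=1e-12)
        assert 0 < p <= 1

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = [correlate(rng.normal(size=50), rng.normal(size=50))[2]
              for _ in range(200)]
        # crude uniformity check on the null distribution
        assert 0.25 < np.mean(ps) < 0.75
        assert (np.array(ps) < 0.05).mean() < 0.12

    def test_spearman_on_monotone(self):
        x = np.arange(1.0, 11)
        r, _, _ = correlate(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSlopeCompare:
    def test_identical_series_equal_slopes(self):
        days = np.array([1.0, 7, 14, 28])
        vals = 2 + 0.5 * days
        slopes, p = slope_compare({"a": (days, vals), "b": (days, vals.copy())})
        assert slopes["a"] == pytest.approx(slopes["b"])
        assert p == pytest.approx(1.0)

    def test_different_slopes_detected(self):
        rng = np.random.default_rng(2)
        days = np.tile([1.0, 7, 14, 21, 28], 4)
        a = 0 * days + rng.normal(0, 0.01, days.size)
        b = 1 * days + rng.normal(0, 0.01, days.size)
        slopes, p = slope_compare({"a": (days, a), "b": (days, b)})
        assert p < 1e-3
        assert slopes["b"] - slopes["a"] == pytest.approx(1.0, abs=0.01)

    def test_pooled_slope_equals_per_group_ols(self):
        rng = np.random.default_rng(3)
        days = np.array([1.0, 3, 7, 14, 21, 28])
        series = {g: (days, rng.normal(size=days.size)) for g in ("a", "b")}
        slopes, _ = slope_compare(series)
        for g, (d, v) in series.items():
            assert slopes[g] == pytest.approx(np.polyfit(d, v, 1)[0])
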