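"""Recovery statistics, deciles, ranks, differential mCH, binned curves."""

import numpy as np
import pandas as pd
import pytest

from methcross.crosstalk import (
    apply_delta_filters,
    binned_scatter,
    crossing_point,
    decile_partition,
    decile_summary,
    diff_methylation,
    expression_join,
    filter_te_genes,
    rank_percentile,
    recovery_efficiency,
    relative_rank_comparison,
)


def series(d):
    return pd.Series(d, dtype=float)


class TestFilterAndEfficiency:
    def test_threshold_in_both_references(self):
        wt = series({"a": 0.25, "b": 0.25, "c": 0.05})
        met1 = series({"a": 0.15, "b": 0.05, "c": 0.2})
        kept = filter_te_genes(wt, met1, "CHG", 0.1)
        assert list(kept) == ["a"]

    def test_missing_region_excluded(self):
        kept = filter_te_genes(series({"a": 0.3, "b": 0.3}), series({"a": 0.3}), "CHG")
        assert list(kept) == ["a"]

    @pytest.mark.parametrize("f1, bg, expected", [(0.30, 0.30, 1.0), (0.0, 0.30, 0.0), (0.36, 0.30, 1.2)])
    def test_efficiency_ratio(self, f1, bg, expected):
        assert recovery_efficiency(f1, bg) == pytest.approx(expected)

    def test_zero_background_is_contract_violation(self):
        with pytest.raises(ValueError, match="filter_te_genes"):
            recovery_efficiency(0.2, 0.0)

    def test_self_recovery_is_exactly_one(self):
        rng = np.random.default_rng(1)
        lv = series({f"r{i}": v for i, v in enumerate(rng.uniform(0.11, 0.9, 50))})
        kept = filter_te_genes(lv, lv, "CHG")
        eff = recovery_efficiency(lv.loc[kept], lv.loc[kept])
        assert (eff == 1.0).all()


class TestDeciles:
    def test_distinct_levels_equal_sizes(self):
        lv = series({f"r{i:02d}": i / 20 for i in range(20)})
        assign = decile_partition(lv)
        assert assign.groupby("decile").size().tolist() == [2] * 10

    def test_all_ties_still_balanced(self):
        lv = series({f"r{i:02d}": 0.5 for i in range(23)})
        assign = decile_partition(lv)
        sizes = assign.groupby("decile").size()
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_regions_suggests_override(self):
        with pytest.raises(ValueError, match="n_quantiles"):
            decile_partition(series({"a": 0.1, "b": 0.2}))

    def test_decile_means_nondecreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lv = series({f"r{i:03d}": v for i, v in enumerate(rng.uniform(0, 1, 137))})
            assign = decile_partition(lv)
            means = (
                assign.assign(level=lv.loc[assign["region_id"]].to_numpy())
                .groupby("decile")["level"].mean()
            )
            assert (np.diff(means.to_numpy()) >= -1e-12).all()

    def test_consistent_with_rank_percentile(self):
        rng = np.random.default_rng(9)
        lv = series({f"r{i:03d}": v for i, v in enumerate(rng.uniform(0, 1, 200))})
        assign = decile_partition(lv).set_index("region_id")["decile"]
        ranks = rank_percentile(lv)
        implied = np.ceil(10 * ranks).astype(int).clip(lower=1)
        assert (assign.reindex(ranks.index) == implied).all()

    def test_summary_quartiles_match_order_statistics(self):
        rng = np.random.default_rng(3)
        lv = series({f"r{i:03d}": v for i, v in enumerate(rng.uniform(0, 1, 100))})
        assign = decile_partition(lv)
        summ = decile_summary(assign, {"x": lv}).set_index("decile")
        for decile, grp in assign.groupby("decile"):
            vals = lv.loc[grp["region_id"]].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            row = summ.loc[decile]
            assert (row["q1"], row["median"], row["q3"]) == pytest.approx((q1, med, q3))
            assert row["whisker_lo"] == vals[vals >= q1 - 1.5 * iqr].min()
            assert row["whisker_hi"] == vals[vals <= q3 + 1.5 * iqr].max()

    def test_constant_levels_collapse_quartiles(self):
        lv = series({f"r{i:02d}": 0.3 for i in range(20)})
        summ = decile_summary(decile_partition(lv), {"x": lv})
        assert (summ[["q1", "median", "q3"]].to_numpy() == 0.3).all()


class TestRankPercentile:
    def test_extremes_and_ties(self):
        lv = series({"lo": 0.0, "mid": 0.5, "hi": 1.0})
        r = rank_percentile(lv)
        assert r["lo"] < r["mid"] < r["hi"]
        assert r["lo"] == pytest.approx(0.5 / 3) and r["hi"] == pytest.approx(2.5 / 3)
        tied = rank_percentile(series({"a": 0.2, "b": 0.2, "c": 0.2}))
        assert (tied == 0.5).all()

    def test_monotone_invariance(self):
        rng = np.random.default_rng(4)
        lv = series({f"r{i}": v for i, v in enumerate(rng.uniform(0, 1, 60))})
        pd.testing.assert_series_equal(rank_percentile(lv), rank_percentile(2 * lv))

    def test_relative_rank_constructed_shift(self):
        rng = np.random.default_rng(5)
        ids = [f"r{i:03d}" for i in range(200)]
        a = series(dict(zip(ids, rng.uniform(0, 1, 200))))
        b = series(dict(zip(ids, rng.uniform(0, 1, 200))))
        subset = a.sort_values().index[-50:]  # top quartile of A, uniform in B
        res = relative_rank_comparison(subset, a, b)
        assert res["median_rank_diff"] > 0 and res["p"] < 0.01

    def test_full_set_has_zero_median_difference(self):
        rng = np.random.default_rng(6)
        ids = [f"r{i:03d}" for i in range(101)]
        a = series(dict(zip(ids, rng.uniform(0, 1, 101))))
        b = a.sample(frac=1, random_state=0)  # same values, reshuffled over ids
        res = relative_rank_comparison(ids, a, b)
        assert abs(res["median_rank_diff"]) < 0.05

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relative_rank_comparison([], series({"a": 1.0}), series({"a": 1.0}))


def _counts(meths, totals, ids=None):
    ids = ids or [f"R{i}" for i in range(len(meths))]
    return pd.DataFrame({"n_meth": meths, "n_total": totals}, index=pd.Index(ids, name="region_id"))


class TestDiffMethylation:
    def test_identical_groups_are_null(self):
        reps = [_counts([10, 40], [100, 100]), _counts([12, 38], [100, 100])]
        res = diff_methylation(reps, [f.copy() for f in reps])
        assert (res["delta"].abs() < 1e-12).all()
        assert (res["p"] > 0.95).all()

    def test_extreme_separation_is_significant(self):
        ga = [_counts([0], [100]), _counts([1], [100])]
        gb = [_counts([100], [100]), _counts([99], [100])]
        res = diff_methylation(ga, gb)
        assert res["q"].iloc[0] < 1e-6
        assert res["delta"].iloc[0] == pytest.approx(0.995, abs=0.01)

    def test_group_swap_flips_delta_and_preserves_p(self):
        rng = np.random.default_rng(12)
        n = 40
        totals = rng.poisson(200, n)
        ga = [_counts(rng.binomial(totals, 0.3), totals) for _ in range(2)]
        gb = [_counts(rng.binomial(totals, 0.4), totals) for _ in range(2)]
        fwd = diff_methylation(ga, gb)
        rev = diff_methylation(gb, ga)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-6)

    def test_all_zero_group_skipped(self):
        ga = [_counts([5, 0], [50, 0]), _counts([5, 0], [50, 0])]
        gb = [_counts([5, 10], [50, 50]), _counts([5, 10], [50, 50])]
        res = diff_methylation(ga, gb)
        assert not res.loc["R1", "tested"]
        assert np.isnan(res.loc["R1", "p"])

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="single replicate"):
            diff_methylation([_counts([5], [50])], [_counts([10], [50])])


class TestDeltaFilters:
    def _results(self):
        return pd.DataFrame(
            {"delta": [0.15, 0.15], "statistic": [30.0, 30.0], "p": [1e-7, 1e-7],
             "q": [1e-6, 1e-6], "tested": True},
            index=pd.Index(["kept", "met1_driven"], name="region_id"),
        )

    def test_met1_driven_changes_excluded(self):
        wt = series({"kept": 0.30, "met1_driven": 0.30})
        met1 = series({"kept": 0.25, "met1_driven": 0.10})  # |diff| 0.05 vs 0.2
        f1 = series({"kept": 0.10, "met1_driven": 0.10})
        mf1 = series({"kept": 0.25, "met1_driven": 0.25})
        out = apply_delta_filters(self._results(), wt, met1, f1, mf1, context="CHG")
        assert bool(out.loc["kept", "pass_delta_filters"])
        assert not bool(out.loc["met1_driven", "pass_delta_filters"])


class TestBinnedScatter:
    def _linear(self, slope=0.5, n=500):
        rng = np.random.default_rng(2)
        mcg = series({f"r{i:03d}": v for i, v in enumerate(rng.uniform(0, 1, n))})
        return mcg, slope * mcg

    def test_linear_relation_recovered(self):
        mcg, mchg = self._linear()
        curve = binned_scatter(mcg, mchg, bin_size=50)
        fitted = np.polyfit(curve["mcg_mean"], curve["mchg_mean"], 1)[0]
        assert fitted == pytest.approx(0.5, rel=1e-6)

    def test_crossing_analytic(self):
        mcg, mchg = self._linear()
        curve = binned_scatter(mcg, mchg, bin_size=50)
        assert crossing_point(curve, 0.1) == pytest.approx(0.2, abs=0.01)

    def test_curve_below_query_gives_nan(self):
        mcg, mchg = self._linear(slope=0.04)
        curve = binned_scatter(mcg, mchg, bin_size=50)
        assert np.isnan(crossing_point(curve, 0.1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binned_scatter(series({}), series({}))


class TestExpressionJoin:
    def test_pseudocount_arithmetic(self):
        lv = series({f"r{i:02d}": i / 20 for i in range(20)})
        assign = decile_partition(lv)
        expr = pd.DataFrame({"region_id": lv.index, "genotype": "WT", "rpkm": 0.0})
        expr.loc[expr.index[:10], "rpkm"] = 1.0
        out = expression_join(expr, assign)
        vals = set(np.round(out["median"].unique(), 3))
        assert vals <= {round(np.log2(0.001), 3), round(np.log2(1.001), 3)}
        assert round(np.log2(0.001), 3) == -9.966

    def test_missing_regions_dropped(self):
        lv = series({f"r{i:02d}": i / 20 for i in range(20)})
        assign = decile_partition(lv)
        expr = pd.DataFrame({"region_id": lv.index[:10], "genotype": "WT", "rpkm": 1.0})
        out = expression_join(expr, assign)
        assert out["n"].sum() == 10
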