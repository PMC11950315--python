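"""Model ranking, point scheme, selection threshold and R² utility."""

import numpy as np
import pandas as pd
import pytest

from urbanheat import (award_points, comprehensive_rank,
                       cumulative_and_select, deviations, r_squared)
from urbanheat.selection import means_to_long, score_models


def dev_frame(entries):
    return pd.DataFrame(entries,
                        columns=["model_id", "city_id", "index_name",
                                 "deviation"])


class TestDeviations:
    def _long(self, rows, with_model=True):
        cols = (["model_id"] if with_model else []) + \
            ["city_id", "index_name", "value"]
        return pd.DataFrame(rows, columns=cols)

    def test_absolute_difference(self):
        mod = self._long([["m1", "a", "hwn_tasmax", 3.2]])
        ref = self._long([["a", "hwn_tasmax", 2.5]], with_model=False)
        out = deviations(mod, ref)
        assert out["deviation"].iloc[0] == pytest.approx(0.7)

    def test_equal_means_give_zero_table(self):
        mod = self._long([["m1", "a", "hwn_tasmax", 2.0],
                          ["m1", "b", "hwtd_tasmax", 5.0]])
        ref = self._long([["a", "hwn_tasmax", 2.0],
                          ["b", "hwtd_tasmax", 5.0]], with_model=False)
        assert (deviations(mod, ref)["deviation"] == 0).all()

    def test_missing_reference_intensity_propagates(self):
        mod = self._long([["m1", "a", "hwmt_tasmax", 31.0]])
        ref = self._long([["a", "hwmt_tasmax", np.nan]], with_model=False)
        assert deviations(mod, ref)["deviation"].isna().all()

    def test_coverage_mismatch_rejected(self):
        mod = self._long([["m1", "a", "hwn_tasmax", 3.0]])
        ref = self._long([["b", "hwn_tasmax", 2.0]], with_model=False)
        with pytest.raises(ValueError, match="hwn_tasmax"):
            deviations(mod, ref)


class TestComprehensiveRank:
    def test_single_index_sort_order(self):
        dev = dev_frame([["A", "c", "hwn", 0.1], ["B", "c", "hwn", 0.5],
                         ["C", "c", "hwn", 0.2]])
        assert comprehensive_rank(dev, "c") == {"A": 1, "C": 2, "B": 3}

    def test_zero_deviation_dominates(self):
        rows = []
        for idx in ("hwn", "hwtd", "hwld", "hwmt", "hht"):
            rows += [["A", "c", idx, 0.0], ["B", "c", idx, 1.0],
                     ["C", "c", idx, 0.5]]
        assert comprehensive_rank(dev_frame(rows), "c")["A"] == 1

    def test_ties_broken_by_model_id(self):
        rows = []
        for idx in ("hwn", "hwtd"):
            rows += [["B", "c", idx, 0.3], ["A", "c", idx, 0.3]]
        assert comprehensive_rank(dev_frame(rows), "c") == {"A": 1, "B": 2}

    def test_missing_index_dropped_with_reduced_divisor(self):
        # model A: ranks (1, missing) -> avg 1; model B: (2, 1) -> avg 1.5
        dev = dev_frame([["A", "c", "hwn", 0.1], ["B", "c", "hwn", 0.5],
                         ["A", "c", "hwmt", np.nan], ["B", "c", "hwmt", 0.2]])
        assert comprehensive_rank(dev, "c") == {"A": 1, "B": 2}

    def test_all_missing_rejected(self):
        dev = dev_frame([["A", "c", "hwmt", np.nan],
                         ["B", "c", "hwmt", np.nan]])
        with pytest.raises(ValueError):
            comprehensive_rank(dev, "c")


class TestPoints:
    @pytest.mark.parametrize("rank,n,expected", [
        (1, 29, 29), (29, 29, 1), (2, 3, 2)])
    def test_linear_scale(self, rank, n, expected):
        assert award_points(rank, n) == expected

    @pytest.mark.parametrize("rank", [0, 30, -1])
    def test_out_of_range_rejected(self, rank):
        with pytest.raises(ValueError):
            award_points(rank, 29)

    def test_points_conserved_within_city(self):
        dev = dev_frame([[m, "c", "hwn", d] for m, d in
                         zip("ABCDE", [0.5, 0.1, 0.9, 0.3, 0.7])])
        ranks = comprehensive_rank(dev, "c")
        total = sum(award_points(r, 5) for r in ranks.values())
        assert total == 5 * 6 // 2


class TestCumulativeAndSelect:
    def _points(self, score_by_model, n_cities):
        rows = []
        for m, total in score_by_model.items():
            per_city = total // n_cities
            rem = total - per_city * n_cities
            for c in range(n_cities):
                rows.append([m, f"c{c}", per_city + (1 if c < rem else 0)])
        return pd.DataFrame(rows, columns=["model_id", "city_id", "points"])

    def test_perfect_model_scores_1450(self):
        pts = pd.DataFrame([["best", f"c{c}", 29] for c in range(50)],
                           columns=["model_id", "city_id", "points"])
        scores = cumulative_and_select(pts, 50, 29, 0.5)
        assert scores[0].cumulative_score == 1450

    def test_threshold_is_725_for_50x29(self):
        pts = self._points({"m": 725}, 50)
        scores = cumulative_and_select(pts, 50, 29, 0.5)
        assert not scores[0].selected  # must strictly surpass 725

    def test_strict_selection_filter(self):
        pts = pd.concat([self._points({"a": 800}, 50),
                         self._points({"b": 726}, 50),
                         self._points({"c": 700}, 50)])
        scores = cumulative_and_select(pts, 50, 29, 0.5)
        assert {s.model_id for s in scores if s.selected} == {"a", "b"}
        assert [s.model_id for s in scores] == ["a", "b", "c"]  # sorted desc

    def test_city_coverage_required(self):
        pts = pd.DataFrame([["m", "c0", 3]],
                           columns=["model_id", "city_id", "points"])
        with pytest.raises(ValueError):
            cumulative_and_select(pts, 2, 1, 0.5)

    def test_invariant_to_city_ordering(self):
        pts = self._points({"a": 40, "b": 30}, 10)
        shuffled = pts.sample(frac=1, random_state=0)
        s1 = cumulative_and_select(pts, 10, 5, 0.5)
        s2 = cumulative_and_select(shuffled, 10, 5, 0.5)
        assert [(s.model_id, s.cumulative_score, s.selected) for s in s1] == \
               [(s.model_id, s.cumulative_score, s.selected) for s in s2]


class TestScoreModels:
    def test_biased_models_rank_below_accurate_ones(self):
        rows = []
        for var in ("tasmax", "tasmin"):
            for city in ("a", "b", "c"):
                base = {"hwn": 3.0, "hwtd": 10.0, "hwld": 5.0,
                        "hwmt": 33.0, "hht": 36.0}
                rows.append(dict(city_id=city, model_id="REF",
                                 scenario="reference", diurnal_var=var,
                                 **base))
                for m, bias in (("good", 0.1), ("bad", 2.0)):
                    rows.append(dict(
                        city_id=city, model_id=m, scenario="historical",
                        diurnal_var=var,
                        **{k: v + bias for k, v in base.items()}))
        scores = score_models(pd.DataFrame(rows))
        assert scores[0].model_id == "good"
        assert scores[0].cumulative_score == 3 * 2  # rank 1 in 3 cities of 2

    def test_means_to_long_builds_ten_components(self):
        df = pd.DataFrame([
            dict(city_id="a", model_id="m", scenario="historical",
                 diurnal_var=v, hwn=1, hwtd=2, hwld=3, hwmt=4.0, hht=5.0)
            for v in ("tasmax", "tasmin")])
        long = means_to_long(df)
        assert len(long) == 10
        assert set(long["index_name"]) == {
            f"{n}_{v}" for n in ("hwn", "hwtd", "hwld", "hwmt", "hht")
            for v in ("tasmax", "tasmin")}


class TestRSquared:
    def test_identical_series(self):
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert r_squared(a, 2 * a + 3) == pytest.approx(1.0)

    def test_worked_example(self):
        # r = 11 / sqrt(5 * 29) = 0.91339..., r^2 = 0.83428...
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 8]) == pytest.approx(
            121.0 / 145.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r1, r2 = r_squared(a, b), r_squared(b, a)
        assert r1 == pytest.approx(r2)
        assert 0.0 <= r1 <= 1.0

    def test_pairwise_deletion(self):
        a = [1.0, 2.0, np.nan, 4.0, 5.0]
        b = [2.0, 4.0, 6.0, np.nan, 10.0]
        assert r_squared(a, b) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            r_squared([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_flagged_not_zero(self):
        out = r_squared([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(out)
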