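"""Land-cover classification, availability, selection ratios, exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import MultiPoint, Point, Polygon

from frugitrack.habitat import (
    CATEGORIES,
    GridLandCover,
    OutOfExtentError,
    PolygonLandCover,
    availability_circle,
    composition,
    fisher_exact_rxc,
    holm_bonferroni,
    selection_ratios,
)

CODE = {c: i for i, c in enumerate(CATEGORIES)}


def half_half_map(n=100, cell=10.0, left="natural", right="pasture"):
    """Vertical split: `left` category west of the midline, `right` east."""
    codes = np.full((n, n), CODE[right], dtype=int)
    codes[:, : n // 2] = CODE[left]
    return GridLandCover(codes, 0.0, 0.0, cell)


class TestClassifyPoint:
    def test_interior_points(self):
        m = half_half_map()
        assert m.classify_point(100.0, 500.0) == "natural"
        assert m.classify_point(900.0, 500.0) == "pasture"

    def test_cell_corner_uses_half_open_convention(self):
        m = half_half_map()
        # (500, 500) is exactly the corner of the first pasture cell
        assert m.classify_point(500.0, 500.0) == "pasture"
        assert m.classify_point(499.999, 500.0) == "natural"

    def test_outside_extent_raises(self):
        with pytest.raises(OutOfExtentError):
            half_half_map().classify_point(-1.0, 0.0)

    def test_random_points_split_evenly_on_balanced_map(self, rng):
        m = half_half_map()
        pts = rng.uniform(0, 1000, size=(1000, 2))
        cats = m.classify_points(pts)
        n_nat = int((cats == "natural").sum())
        # binomial(1000, 0.5): 3 sigma ~ 47
        assert abs(n_nat - 500) < 3 * math.sqrt(1000 * 0.25)

    def test_polygon_map_boundary_goes_to_first_feature(self):
        sq1 = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        sq2 = Polygon([(10, 0), (20, 0), (20, 10), (10, 10)])
        m = PolygonLandCover([(sq1, "natural"), (sq2, "farmland")])
        assert m.classify_point(10.0, 5.0) == "natural"
        m2 = PolygonLandCover([(sq2, "farmland"), (sq1, "natural")])
        assert m2.classify_point(10.0, 5.0) == "farmland"


class TestAvailabilityCircle:
    def test_single_roost_square_mcp(self):
        sq = Polygon([(-100, -100), (100, -100), (100, 100), (-100, 100)])
        center, radius = availability_circle([(0.0, 0.0)], sq)
        assert center == (0.0, 0.0)
        assert radius == pytest.approx(100 * math.sqrt(2))

    def test_multiple_roosts_use_mean_center(self):
        sq = Polygon([(-100, -100), (100, -100), (100, 100), (-100, 100)])
        center, _ = availability_circle([(0.0, 0.0), (10.0, 0.0)], sq)
        assert center == (5.0, 0.0)

    def test_radius_reaches_every_vertex(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        roost = pts.mean(axis=0)
        center, radius = availability_circle([tuple(roost)], hull)
        for v in hull.exterior.coords:
            assert radius >= math.dist(center, v) - 1e-9

    def test_empty_roosts_invalid(self):
        with pytest.raises(ValueError):
            availability_circle([], Polygon([(0, 0), (1, 0), (1, 1)]))


class TestComposition:
    def test_circle_on_straight_boundary_splits_evenly(self):
        m = half_half_map()
        circle = Point(500.0, 500.0).buffer(200.0, quad_segs=256)
        comp = composition(circle, m)
        assert comp["natural"] == pytest.approx(0.5, abs=1e-3)
        assert comp["pasture"] == pytest.approx(0.5, abs=1e-3)

    def test_region_inside_one_patch(self):
        m = half_half_map()
        comp = composition(Point(200.0, 500.0).buffer(100.0), m)
        assert comp["natural"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        m = half_half_map()
        for _ in range(5):
            c = Point(rng.uniform(200, 800, 2)).buffer(rng.uniform(50, 150))
            assert sum(composition(c, m).values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_monte_carlo_point_sampling(self, rng):
        codes = rng.integers(0, 5, size=(40, 40))
        m = GridLandCover(codes, 0.0, 0.0, 25.0)
        circle = Point(480.0, 510.0).buffer(230.0, quad_segs=256)
        comp = m.composition(circle)
        # oracle: 1e5 uniform points in the circle via rejection sampling
        pts = rng.uniform(circle.bounds[0], circle.bounds[2], size=(400_000, 2))
        pts[:, 1] = rng.uniform(circle.bounds[1], circle.bounds[3], 400_000)
        d = np.hypot(pts[:, 0] - 480.0, pts[:, 1] - 510.0)
        pts = pts[d <= 230.0][:100_000]
        cats = m.classify_points(pts)
        for c in CATEGORIES:
            assert comp[c] == pytest.approx((cats == c).mean(), abs=0.01)

    def test_polygon_map_composition(self):
        sq = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        m = PolygonLandCover([(sq, "natural")], background="pasture",
                             extent=(0, 0, 200, 100))
        region = Polygon([(50, 0), (150, 0), (150, 100), (50, 100)])
        comp = m.composition(region)
        assert comp["natural"] == pytest.approx(0.5)
        assert comp["pasture"] == pytest.approx(0.5)


class TestSelectionRatios:
    def test_use_equal_to_availability_gives_unit_ratios(self):
        avail = pd.DataFrame({"natural": [0.4] * 3, "pasture": [0.6] * 3},
                             index=list("abc"))
        used = pd.DataFrame({"natural": [40] * 3, "pasture": [60] * 3},
                            index=list("abc"))
        res = selection_ratios(used, avail)
        assert res.table["wi"].to_numpy() == pytest.approx([1.0, 1.0])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_even_availability_ratio_arithmetic(self):
        avail = pd.DataFrame({"a": [0.5] * 3, "b": [0.5] * 3}, index=list("xyz"))
        used = pd.DataFrame({"a": [75] * 3, "b": [25] * 3}, index=list("xyz"))
        res = selection_ratios(used, avail)
        assert res.table["wi"].to_numpy() == pytest.approx([1.5, 0.5])

    def test_chi2_df_counts_available_categories_per_animal(self):
        avail = pd.DataFrame({"a": [0.5, 0.6], "b": [0.5, 0.4], "c": [0.0, 0.0]},
                             index=["j1", "j2"])
        used = pd.DataFrame({"a": [10, 20], "b": [10, 5], "c": [0, 0]},
                            index=["j1", "j2"])
        res = selection_ratios(used, avail)
        assert res.df == 2  # (2-1) + (2-1)

    def test_lower_ci_truncated_at_zero(self, rng):
        avail = pd.DataFrame(rng.dirichlet(np.ones(3), size=4),
                             columns=list("abc"), index=range(4))
        used = pd.DataFrame(rng.integers(0, 4, size=(4, 3)) * [1, 1, 0] + [[5, 5, 1]],
                            columns=list("abc"), index=range(4))
        res = selection_ratios(used, avail)
        assert (res.table["ci_low"] >= 0).all()

    def test_zero_availability_with_use_warns(self):
        avail = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 0.0]}, index=[1, 2])
        used = pd.DataFrame({"a": [9, 10], "b": [1, 0]}, index=[1, 2])
        with pytest.warns(UserWarning, match="zero availability"):
            selection_ratios(used, avail)


def _fisher_bruteforce_2xc(table):
    """Enumerate all first rows compatible with the margins (independent oracle)."""
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(axis=1), table.sum(axis=0)

    def prob(t):
        num = sum(math.lgamma(v + 1) for v in rows) + \
            sum(math.lgamma(v + 1) for v in cols)
        den = math.lgamma(t.sum() + 1) + sum(math.lgamma(v + 1) for v in t.flat)
        return math.exp(num - den)

    p_obs = prob(table)
    total = 0.0
    ranges = [range(min(rows[0], c) + 1) for c in cols]
    for first in itertools.product(*ranges):
        if sum(first) != rows[0]:
            continue
        t = np.array([first, cols - np.array(first)])
        if (t < 0).any():
            continue
        p = prob(t)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestFisherExact:
    def test_2x2_matches_scipy(self, rng):
        for _ in range(25):
            t = rng.integers(0, 13, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_rxc(t).p
            ref = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_small_tables_match_bruteforce(self, rng):
        assert fisher_exact_rxc([[3, 1], [1, 3]]).p == pytest.approx(
            _fisher_bruteforce_2xc([[3, 1], [1, 3]]))
        for _ in range(10):
            t = rng.integers(0, 7, size=(2, 3))
            if t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_rxc(t).p == pytest.approx(
                _fisher_bruteforce_2xc(t), abs=1e-12)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[5, 5, 5], [5, 5, 5]]).p == pytest.approx(1.0)

    def test_empty_column_dropped(self):
        with_zero = fisher_exact_rxc([[3, 0, 1], [1, 0, 3]])
        without = fisher_exact_rxc([[3, 1], [1, 3]])
        assert with_zero.p == pytest.approx(without.p)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1.5, 2], [3, 4]])

    def test_monte_carlo_fallback_close_to_exact(self):
        t = [[8, 2, 5], [3, 7, 4]]
        exact = fisher_exact_rxc(t).p
        mc = fisher_exact_rxc(t, budget=10, n_mc=20_000, seed=3)
        assert mc.method == "monte-carlo"
        assert mc.p == pytest.approx(exact, abs=4 * mc.se + 1e-4)

    def test_null_p_values_are_uniform(self, rng):
        """Calibration: p under the null is superuniform/uniform (KS at 1%)."""
        ps = []
        for _ in range(150):
            t = rng.multinomial(15, [1 / 3] * 3, size=2)
            if t.sum(axis=1).min() == 0:
                continue
            ps.append(fisher_exact_rxc(t).p)
        # discrete test: compare against uniform, generous alpha
        assert stats.kstest(ps, "uniform").pvalue > 0.01 or np.mean(ps) > 0.45


class TestHolm:
    def test_five_small_pvalues_all_rejected(self):
        reject, thresh = holm_bonferroni([0.0005] * 5, alpha=0.05)
        assert reject.all()
        assert thresh.min() == pytest.approx(0.01)  # 0.05 / 5

    def test_single_test_plain_alpha(self):
        reject, thresh = holm_bonferroni([0.04])
        assert reject[0] and thresh[0] == pytest.approx(0.05)

    def test_step_down_sequence(self):
        reject, thresh = holm_bonferroni([0.011, 0.02, 0.9], alpha=0.05)
        assert list(reject) == [True, True, False]
        assert thresh == pytest.approx([0.05 / 3, 0.05 / 2, 0.05])

    def test_rejections_form_prefix_of_sorted_list(self, rng):
        p = rng.uniform(0, 1, 8)
        reject, _ = holm_bonferroni(p)
        order = np.argsort(p)
        seen_retain = False
        for idx in order:
            if not reject[idx]:
                seen_retain = True
            assert not (seen_retain and reject[idx])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])
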