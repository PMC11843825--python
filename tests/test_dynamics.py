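"""Kernel densities, kernel class regions, hulls, overlaps, trajectories."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from burndyn.dynamics import (
    ClassRegion,
    DegenerateHullError,
    class_regions,
    convex_hull,
    discrimination_table,
    kde,
    kernel_region,
    overlap,
    overlap_iou,
    trajectories,
)
from burndyn.reference import BurnClass
from burndyn.secondary import PS2


def brute_force_hull(pts):
    """O(n^3) supporting-line oracle: a point pair is a hull edge iff all
    other points lie on one side."""
    n = len(pts)
    edges = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = pts[i], pts[j]
            cross = [
                (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                for k, p in enumerate(pts)
                if k not in (i, j)
            ]
            if all(c >= -1e-12 for c in cross):
                edges.add((i, j))
    verts = {i for i, _ in edges}
    return {tuple(np.round(pts[i], 12)) for i in verts}


class TestKde:
    def test_point_mass_concentrates_in_its_cell(self):
        pts = [(0.305, 0.715)] * 10
        grid = kde(pts, bandwidth=0.01, n=50)
        peak = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        # nearest cell centres at n=50: col 15 (x=0.31), row 35 (y=0.71)
        assert peak == (35, 15)

    def test_density_normalised_on_grid(self, rng):
        pts = rng.uniform(0, 1, (200, 2))
        grid = kde(pts, n=64)
        assert grid.values.sum() * grid.cell_area == pytest.approx(1.0, abs=1e-6)
        assert np.all(grid.values >= 0)

    def test_uniform_sample_is_nearly_flat_with_wide_bandwidth(self, rng):
        pts = rng.uniform(0, 1, (10_000, 2))
        grid = kde(pts, bandwidth=0.5, n=40)
        assert grid.values.max() / grid.values.min() < 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kde([(0.5, 0.5)] * 4)


class TestKernelRegion:
    def test_near_total_mass_covers_support(self, rng):
        pts = rng.uniform(0.4, 0.6, (100, 2))
        grid = kde(pts, bandwidth=0.05, n=40)
        cells = kernel_region(grid, 0.999)
        mass = grid.values[cells[:, 0], cells[:, 1]].sum() * grid.cell_area
        assert mass >= 0.999

    def test_matches_greedy_oracle(self, rng):
        pts = rng.normal(0.5, 0.08, (300, 2)).clip(0, 1)
        grid = kde(pts, n=50)
        cells = kernel_region(grid, 0.5)
        # independent greedy oracle over sorted cells
        flat = sorted(
            ((v, i) for i, v in enumerate(grid.values.ravel())),
            key=lambda t: (-t[0], t[1]),
        )
        acc, chosen = 0.0, []
        for v, i in flat:
            chosen.append(i)
            acc += v * grid.cell_area
            if acc >= 0.5:
                break
        expected = {tuple(np.unravel_index(i, grid.values.shape)) for i in chosen}
        assert {tuple(c) for c in cells} == expected

    def test_single_peak_region_is_connected_block(self, rng):
        pts = rng.normal(0.5, 0.05, (500, 2)).clip(0, 1)
        grid = kde(pts, n=40)
        cells = kernel_region(grid, 0.5)
        cellset = {tuple(c) for c in cells}
        # connectivity by flood fill from the densest cell
        start = tuple(cells[0])
        seen = {start}
        frontier = [start]
        while frontier:
            r, c = frontier.pop()
            for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if nb in cellset and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert seen == cellset

    def test_two_equal_peaks_split_mass(self, rng):
        a = rng.normal(0.2, 0.03, (500, 2)).clip(0, 1)
        b = rng.normal(0.8, 0.03, (500, 2)).clip(0, 1)
        grid = kde(np.vstack([a, b]), n=50)
        cells = kernel_region(grid, 0.4)
        xs = (cells[:, 1] + 0.5) / 50
        assert (xs < 0.5).any() and (xs > 0.5).any()

    def test_mass_bounds(self, rng):
        grid = kde(rng.uniform(0, 1, (50, 2)), n=20)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                kernel_region(grid, bad)


class TestConvexHull:
    def test_square_corners_exclude_interior_point(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)]
        hull = convex_hull(pts)
        assert len(hull) == 4
        assert {tuple(v) for v in hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}
        # CCW from lowest-then-leftmost
        assert tuple(hull[0]) == (0, 0)
        area = Polygon(hull).area
        assert area == pytest.approx(1.0)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 1, (20, 2))
            hull = convex_hull(pts)
            expected = brute_force_hull(pts)
            assert {tuple(np.round(v, 12)) for v in hull} == expected

    def test_ccw_orientation(self, rng):
        pts = rng.uniform(0, 1, (15, 2))
        hull = convex_hull(pts)
        signed = 0.0
        for i in range(len(hull)):
            x1, y1 = hull[i]
            x2, y2 = hull[(i + 1) % len(hull)]
            signed += x1 * y2 - x2 * y1
        assert signed > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateHullError):
            convex_hull([(0, 0), (1, 1)])
        with pytest.raises(DegenerateHullError):
            convex_hull([(0, 0), (0.5, 0.5), (1, 1)])


class TestOverlap:
    def _rect(self, x0, y0, x1, y1, cls=BurnClass.C2A, day=0):
        hull = np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], float)
        return ClassRegion(cls, day, PS2, hull, 1.0)

    def test_self_overlap_is_one(self):
        a = self._rect(0.1, 0.1, 0.6, 0.8)
        assert overlap(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = self._rect(0.0, 0.0, 0.2, 0.2)
        b = self._rect(0.5, 0.5, 0.9, 0.9, BurnClass.C3)
        assert overlap(a, b) == 0.0

    def test_half_square_analytic_case(self):
        a = self._rect(0.0, 0.0, 0.5, 1.0)            # left half
        b = self._rect(0.25, 0.0, 0.75, 1.0, BurnClass.C2B1)
        assert overlap(a, b) == pytest.approx(0.5)
        assert overlap(b, a) == pytest.approx(0.5)
        # asymmetry with unequal areas
        c = self._rect(0.0, 0.0, 0.25, 1.0, BurnClass.C2B2)
        assert overlap(c, a) == pytest.approx(1.0)
        assert overlap(a, c) == pytest.approx(0.5)

    def test_iou_variant_symmetric(self):
        a = self._rect(0.0, 0.0, 0.5, 1.0)
        b = self._rect(0.25, 0.0, 0.75, 1.0, BurnClass.C2B1)
        assert overlap_iou(a, b) == overlap_iou(b, a) == pytest.approx(1 / 3)

    def test_mismatched_day_rejected(self):
        a = self._rect(0, 0, 1, 1, day=0)
        b = self._rect(0, 0, 1, 1, BurnClass.C3, day=1)
        with pytest.raises(ValueError):
            overlap(a, b)


class TestClassRegions:
    def _table(self, clouds):
        rows = []
        for cls, pts in clouds.items():
            for i, (x, y) in enumerate(pts):
                rows.append(
                    {
                        "segment_id": f"{cls}_{i}",
                        "day": 0,
                        "true_class": cls,
                        "v2": x,
                        "flow2": y,
                        "v1": x,
                        "xrate": y,
                    }
                )
        return pd.DataFrame(rows)

    def test_separated_clouds_give_disjoint_hulls(self, rng):
        a = rng.normal(0.2, 0.05, (60, 2)).clip(0, 1)
        b = rng.normal(0.8, 0.05, (60, 2)).clip(0, 1)
        table = self._table({"2a": a, "3": b})
        regs = class_regions(table, 0, PS2)
        assert set(regs) == {BurnClass.C2A, BurnClass.C3}
        assert overlap(regs[BurnClass.C2A], regs[BurnClass.C3]) == 0.0

    def test_identical_clouds_give_nearly_identical_hulls(self, rng):
        pts = rng.normal(0.5, 0.05, (80, 2)).clip(0, 1)
        table = self._table({"2b1": pts, "2b2": pts.copy()})
        regs = class_regions(table, 0, PS2, grid_n=100)
        h1 = regs[BurnClass.C2B1].hull
        h2 = regs[BurnClass.C2B2].hull
        d = max(
            max(min(np.linalg.norm(v - w) for w in h2) for v in h1),
            max(min(np.linalg.norm(v - w) for w in h1) for v in h2),
        )
        assert d < 2.0 / 100  # two cell widths

    def test_underpopulated_class_omitted(self, rng):
        table = self._table({"2a": rng.uniform(0, 1, (10, 2)), "3": [(0.5, 0.5)] * 3})
        regs = class_regions(table, 0, PS2)
        assert BurnClass.C3 not in regs
        assert BurnClass.C2A in regs

    def test_hull_contains_every_kernel_region_cell(self, rng):
        from burndyn.dynamics import DEFAULT_MASS, kde as kde_fn, kernel_region

        pts = rng.normal(0.5, 0.07, (80, 2)).clip(0, 1)
        table = self._table({"2a": pts})
        regs = class_regions(table, 0, PS2, grid_n=80)
        grid = kde_fn(pts, n=80)
        cells = kernel_region(grid, DEFAULT_MASS)
        poly = regs[BurnClass.C2A].polygon().buffer(1e-9)
        centers = (cells[:, ::-1] + 0.5) / 80
        assert all(poly.covers(Point(x, y)) for x, y in centers)


class TestDiscrimination:
    def test_identical_regions_summary_one(self):
        hull = np.array([(0.1, 0.1), (0.5, 0.1), (0.5, 0.5), (0.1, 0.5)])
        regs = {
            c: ClassRegion(c, 0, PS2, hull.copy(), 1.0)
            for c in BurnClass
        }
        mat, summary = discrimination_table(regs)
        assert summary == pytest.approx(1.0)
        assert np.all(np.diag(mat.to_numpy()) == 1.0)

    def test_disjoint_regions_summary_zero(self):
        regs = {}
        for i, c in enumerate(BurnClass):
            x0 = 0.05 + 0.25 * i
            hull = np.array(
                [(x0, 0.1), (x0 + 0.1, 0.1), (x0 + 0.1, 0.3), (x0, 0.3)]
            )
            regs[c] = ClassRegion(c, 0, PS2, hull, 1.0)
        _, summary = discrimination_table(regs)
        assert summary == 0.0


class TestTrajectories:
    def test_four_day_segment_gives_four_points(self, scenarios):
        trs = trajectories(scenarios["trajectory_demo"], PS2)
        assert len(trs) == 4  # one per class
        assert all(len(t.days) == 4 for t in trs)
        classes = {t.burn_class for t in trs}
        assert classes == set(BurnClass)

    def test_single_day_segment_excluded(self):
        df = pd.DataFrame(
            {
                "segment_id": ["a", "b", "b"],
                "day": [0, 0, 3],
                "true_class": ["2a", "2b1", "2b1"],
                "v2": [0.1, 0.2, 0.4],
                "flow2": [0.1, 0.1, 0.3],
                "v1": 0.1,
                "xrate": 0.1,
            }
        )
        trs = trajectories(df, PS2)
        assert [t.segment_id for t in trs] == ["b"]
        np.testing.assert_allclose(trs[0].displacement(), [0.2, 0.2])

    def test_mean_class_trajectories_follow_their_dynamics(self, scenarios):
        trs = {t.burn_class: t for t in trajectories(scenarios["trajectory_demo"], PS2)}
        d2b1 = trs[BurnClass.C2B1].displacement()
        assert d2b1[0] > 0 and d2b1[1] > 0  # hyperemic drift up-right
        d3 = trs[BurnClass.C3].displacement()
        assert d3[0] <= 0 and d3[1] <= 0  # declining full-thickness
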