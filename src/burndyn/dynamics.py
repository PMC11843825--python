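"""Class-distribution analysis in the 2-D parameter spaces.

Per class and day, the point cloud in PS_1 or PS_2 is turned into a kernel
density on the unit square, the highest-density cells capturing a configured
probability mass form the *kernel class region*, and its convex hull is the
abstracted class area. Pairwise directional overlaps of the hulls quantify
class discrimination per day; per-segment day-to-day tracks give the
segment trajectories.

Numerical choices: an isotropic Gaussian kernel with a per-cloud Silverman
bandwidth (floored at 0.02), density renormalised on the grid after
truncation at the unit-square boundary, highest-density cells selected in
row-major order on ties, hull vertices returned counter-clockwise starting
from the lowest-then-leftmost vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .reference import CLASS_ORDER, BurnClass
from .secondary import PS1, PS2, ParamPoint

__all__ = [
    "DensityGrid",
    "ClassRegion",
    "SegmentTrajectory",
    "DegenerateHullError",
    "kde",
    "kernel_region",
    "convex_hull",
    "class_regions",
    "overlap",
    "overlap_iou",
    "discrimination_table",
    "trajectories",
    "silverman_bandwidth",
]

DEFAULT_GRID_N = 200
DEFAULT_MASS = 0.68
BANDWIDTH_FLOOR = 0.02


class DegenerateHullError(ValueError):
    """Fewer than three distinct non-collinear points."""


@dataclass(frozen=True)
class DensityGrid:
    """Kernel density on an n x n grid over the unit square.

    ``values[i, j]`` is the density at cell centre (x_j, y_i); cell-sum times
    cell area is 1 within 1e-6.
    """

    space: str
    values: np.ndarray
    n: int

    @property
    def cell_area(self) -> float:
        return (1.0 / self.n) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.n) + 0.5) / self.n
        return np.meshgrid(c, c)  # (X, Y), values[i, j] at (c[j], c[i])


@dataclass(frozen=True)
class ClassRegion:
    """Convex-hull abstraction of a kernel class region."""

    burn_class: BurnClass
    day: int
    space: str
    hull: np.ndarray  # (k, 2) CCW vertices in the unit square
    mass_captured: float

    def polygon(self) -> Polygon:
        return Polygon(self.hull)


@dataclass(frozen=True)
class SegmentTrajectory:
    """Per-day parameter-space track of one segment (>= 2 observed days)."""

    segment_id: str
    burn_class: BurnClass
    space: str
    days: tuple
    points: np.ndarray  # (len(days), 2)

    def displacement(self) -> np.ndarray:
        return self.points[-1] - self.points[0]


def _points_array(points) -> np.ndarray:
    arr = np.array(
        [[p.x, p.y] if isinstance(p, ParamPoint) else p for p in points], float
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be 2-D")
    return arr


def silverman_bandwidth(pts: np.ndarray, floor: float = BANDWIDTH_FLOOR) -> float:
    """Isotropic Silverman rule for 2-D data, floored."""
    n = pts.shape[0]
    sd = float(np.mean(np.std(pts, axis=0)))
    h = sd * n ** (-1.0 / 6.0)
    return max(h, floor)


def kde(
    points,
    bandwidth: float | None = None,
    n: int = DEFAULT_GRID_N,
    space: str = PS2,
) -> DensityGrid:
    """Gaussian-kernel density of parameter points on the unit square."""
    pts = _points_array(points)
    if pts.shape[0] < 5:
        raise ValueError(f"need >= 5 points for a density, got {pts.shape[0]}")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    c = (np.arange(n) + 0.5) / n
    dx = (c[None, :] - pts[:, 0][:, None]) / bandwidth  # (m, n)
    dy = (c[None, :] - pts[:, 1][:, None]) / bandwidth
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    vals = ky.T @ kx  # (n_y, n_x)
    total = vals.sum() * (1.0 / n) ** 2
    if total <= 0:
        raise ValueError("density vanished on the grid")
    return DensityGrid(space=space, values=vals / total, n=n)


def kernel_region(density: DensityGrid, mass: float = DEFAULT_MASS) -> np.ndarray:
    """Highest-density cells capturing at least ``mass`` probability.

    Returns (k, 2) integer cell indices (row, col), selected densest-first
    with row-major order breaking ties.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    flat = density.values.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order]) * density.cell_area
    k = int(np.searchsorted(csum, mass)) + 1
    k = min(k, flat.size)
    chosen = order[:k]
    return np.column_stack(np.unravel_index(chosen, density.values.shape))


def convex_hull(points) -> np.ndarray:
    """Convex hull vertices, CCW from the lowest-then-leftmost vertex."""
    pts = _points_array(points)
    if pts.shape[0] < 3:
        raise DegenerateHullError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate hull: {exc}") from exc
    verts = pts[hull.vertices]  # scipy returns CCW order in 2-D
    start = np.lexsort((verts[:, 0], verts[:, 1]))[0]
    return np.roll(verts, -start, axis=0)


def class_regions(
    table: pd.DataFrame,
    day: int,
    space: str = PS2,
    mass: float = DEFAULT_MASS,
    grid_n: int = DEFAULT_GRID_N,
    bandwidth: float | None = None,
    min_points: int = 5,
    label_col: str = "true_class",
) -> dict[BurnClass, ClassRegion]:
    """Abstracted class areas for one day and space.

    ``table`` needs columns ``label_col``, ``day`` and the space's
    coordinates. Classes with fewer than ``min_points`` points that day are
    omitted (the returned dict simply lacks them).
    """
    xcol, ycol = ("v1", "xrate") if space == PS1 else ("v2", "flow2")
    out: dict[BurnClass, ClassRegion] = {}
    sub = table[table["day"] == day]
    for cls in CLASS_ORDER:
        pts = sub.loc[sub[label_col] == cls.value, [xcol, ycol]].to_numpy(float)
        if pts.shape[0] < min_points:
            continue
        density = kde(pts, bandwidth=bandwidth, n=grid_n, space=space)
        cells = kernel_region(density, mass)
        centers = (cells[:, ::-1] + 0.5) / grid_n  # (col, row) -> (x, y)
        try:
            hull = convex_hull(centers)
        except DegenerateHullError:
            continue
        captured = float(
            density.values[cells[:, 0], cells[:, 1]].sum() * density.cell_area
        )
        out[cls] = ClassRegion(
            burn_class=cls, day=day, space=space, hull=hull, mass_captured=captured
        )
    return out


def overlap(a: ClassRegion, b: ClassRegion) -> float:
    """Directional hull overlap area(a & b) / area(a), in [0, 1].

    Asymmetric on purpose: it measures how much of class a's area is covered
    by class b.
    """
    if a.space != b.space or a.day != b.day:
        raise ValueError("overlap requires regions from the same day and space")
    pa, pb = a.polygon(), b.polygon()
    if pa.area == 0:
        return 0.0
    return float(min(1.0, pa.intersection(pb).area / pa.area))


def overlap_iou(a: ClassRegion, b: ClassRegion) -> float:
    """Symmetric intersection-over-union variant."""
    pa, pb = a.polygon(), b.polygon()
    u = pa.union(pb).area
    return float(pa.intersection(pb).area / u) if u > 0 else 0.0


def discrimination_table(
    regions: dict[BurnClass, ClassRegion]
) -> tuple[pd.DataFrame, float]:
    """Pairwise overlap matrix (rows = a, cols = b) and its mean off-diagonal.

    Missing classes yield NaN rows/columns; the summary averages the defined
    off-diagonal entries. Low summary = well-discriminated classes.
    """
    names = [c.value for c in CLASS_ORDER]
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in CLASS_ORDER:
        if a not in regions:
            continue
        for b in CLASS_ORDER:
            if b not in regions:
                continue
            mat.loc[a.value, b.value] = (
                1.0 if a is b else overlap(regions[a], regions[b])
            )
    off = mat.to_numpy()[~np.eye(4, dtype=bool)]
    summary = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return mat, summary


def trajectories(
    table: pd.DataFrame, space: str = PS2, label_col: str = "true_class"
) -> list[SegmentTrajectory]:
    """Per-segment mean trajectories across days (segments with >= 2 days)."""
    xcol, ycol = ("v1", "xrate") if space == PS1 else ("v2", "flow2")
    out = []
    for sid, grp in table.groupby("segment_id", sort=True):
        per_day = grp.groupby("day")[[xcol, ycol]].mean().sort_index()
        if len(per_day) < 2:
            continue
        cls = BurnClass(grp[label_col].iloc[0])
        out.append(
            SegmentTrajectory(
                segment_id=str(sid),
                burn_class=cls,
                space=space,
                days=tuple(int(d) for d in per_day.index),
                points=per_day.to_numpy(float),
            )
        )
    return out
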