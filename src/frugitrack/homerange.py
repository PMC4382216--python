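"""Home-range estimation: percent MCP, fixed k-LoCoH isopleths, geometry.

Two estimators are provided.  The *percent minimum convex polygon* (MCP)
peels the fraction of fixes farthest from the point cloud's centroid and
takes the convex hull of the rest; at 95% it is the conventional measure of
total home range.  The *fixed k local convex hull* (k-LoCoH) estimator
builds one small hull around every fix from its k-1 nearest neighbours and
unions hulls in order of increasing area until a target fraction of fixes
is covered; its 50% isopleth delineates focal foraging areas and respects
hard habitat boundaries far better than a single global hull.

Home-range shape is summarised by the isoperimetric compactness ratio
4*pi*A/P^2 (1 for a circle, near 0 for elongated, linear ranges).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import GeometryCollection, MultiPoint, MultiPolygon, Polygon
from shapely.ops import unary_union

from .telemetry import Track

__all__ = [
    "DegenerateGeometryError",
    "InsufficientDataError",
    "HomeRangeResult",
    "DailyRange",
    "mcp",
    "locoh_k_from_n",
    "locoh_hulls",
    "locoh_isopleth",
    "count_focus_areas",
    "compactness_ratio",
    "daily_ranges",
    "home_range",
]


class DegenerateGeometryError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class HomeRangeResult:
    """Per-bat home-range summary: MCPs, LoCoH isopleth, geometry."""

    bat_id: str
    mcp95: Polygon
    mcp100: Polygon
    locoh_k: int
    isopleth50: list[Polygon]
    n_fixes: int
    compactness: float

    @property
    def hr_tot_ha(self) -> float:
        """Total home range in hectares (area of the 95% MCP)."""
        return self.mcp95.area / 1e4

    @property
    def n_focus_areas(self) -> int:
        return len(self.isopleth50)


@dataclass
class DailyRange:
    """95% MCP of one six-hour observation session."""

    bat_id: str
    session_id: int
    area: float  # m^2
    polygon: Polygon
    composition: dict[str, float] | None = None

    @property
    def log_area(self) -> float:
        return math.log(self.area)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array-like")
    return pts


def mcp(points, level: float = 95.0) -> Polygon:
    """Percent minimum convex polygon.

    Retains the ``ceil(level/100 * n)`` points closest to the arithmetic
    centroid of *all* points (single-pass peeling, ties broken by input
    order) and returns their convex hull.  ``level=100`` contains every
    input point.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("MCP needs at least 3 points")
    if not (0 < level <= 100):
        raise ValueError("level must be in (0, 100]")
    m = math.ceil(level / 100.0 * n)
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    order = np.lexsort((np.arange(n), d))  # distance, then input index
    kept = pts[np.sort(order[:m])]
    hull = MultiPoint(kept).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise DegenerateGeometryError("kept points are collinear or coincident")
    return hull


def locoh_k_from_n(n: int, rounding: str = "round") -> int:
    """Neighbourhood size rule k = sqrt(n) for the fixed-k LoCoH.

    ``rounding`` is ``"round"`` (half-up, default) or ``"floor"``.  The
    result is clamped to [3, n].  Fewer than 9 fixes cannot support a
    meaningful local-hull estimate.
    """
    if n < 9:
        raise InsufficientDataError("need at least 9 fixes for k-LoCoH")
    root = math.sqrt(n)
    k = math.floor(root) if rounding == "floor" else math.floor(root + 0.5)
    return max(3, min(k, n))


def _neighbour_order(pts: np.ndarray, i: int) -> np.ndarray:
    """Indices of all points by distance from point i; ties by input index."""
    d = np.hypot(*(pts - pts[i]).T)
    return np.lexsort((np.arange(len(pts)), d))


def locoh_hulls(points, k: int, include_root: bool = True) -> list:
    """One local convex hull per point from it and its nearest neighbours.

    With ``include_root`` (default) a hull uses k points total: the root
    point plus its k-1 nearest neighbours.  The alternative convention
    (k neighbours plus the root, k+1 points) is selected by
    ``include_root=False``.  Duplicate or collinear neighbourhoods yield
    degenerate (zero-area) geometries, which are retained so that their
    points still count as covered.
    """
    pts = _as_points(points)
    n = len(pts)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n < k:
        raise InsufficientDataError("need at least k points")
    size = k if include_root else k + 1
    size = min(size, n)
    hulls = []
    for i in range(n):
        idx = _neighbour_order(pts, i)[:size]
        hulls.append(MultiPoint(pts[idx]).convex_hull)
    return hulls


def locoh_isopleth(
    points,
    k: int,
    fraction: float = 0.5,
    include_root: bool = True,
) -> list[Polygon]:
    """Fixed-k LoCoH isopleth: disjoint components covering ``fraction`` of fixes.

    Hulls are sorted by ascending area (ties by root-point index) and
    unioned in that order until the union covers at least ``fraction * n``
    of the input points.  Returns the disjoint polygonal components of the
    union (touching polygons merge).
    """
    pts = _as_points(points)
    n = len(pts)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    hulls = locoh_hulls(pts, k, include_root=include_root)
    order = sorted(range(n), key=lambda i: (hulls[i].area, i))
    target = fraction * n
    pt_geoms = shapely.points(pts)

    union = None
    for rank, i in enumerate(order):
        union = hulls[i] if union is None else union.union(hulls[i])
        covered = int(np.count_nonzero(shapely.covers(union, pt_geoms)))
        if covered >= target:
            break
    return _polygonal_components(union)


def _polygonal_components(geom) -> list[Polygon]:
    if geom is None or geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom] if geom.area > 0 else []
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        out = []
        for g in geom.geoms:
            out.extend(_polygonal_components(g))
        return out
    return []  # points/lines from degenerate hulls carry no area


def count_focus_areas(isopleth: list[Polygon], merge_radius: float = 0.0) -> int:
    """Number of strictly disjoint components of an isopleth.

    Touching polygons are merged before counting.  ``merge_radius`` > 0
    additionally merges components closer than that distance (default off).
    """
    if not isopleth:
        return 0
    if merge_radius > 0:
        merged = unary_union([p.buffer(merge_radius / 2) for p in isopleth])
    else:
        merged = unary_union(isopleth)
    return len(_polygonal_components(merged))


def compactness_ratio(polygon: Polygon) -> float:
    """Isoperimetric quotient 4*pi*A/P^2 of a polygon, in (0, 1].

    Equals the polygon's area divided by the area of the circle with the
    same perimeter; 1 only in the circle limit, lower for more linear
    shapes.  Scale-invariant.
    """
    area, perim = polygon.area, polygon.length
    if area <= 0 or perim <= 0:
        raise DegenerateGeometryError("degenerate polygon")
    return 4.0 * math.pi * area / perim ** 2


def daily_ranges(track: Track, level: float = 95.0) -> list[DailyRange]:
    """95% MCP of each observation session of a track.

    Sessions with fewer than 3 usable fixes are skipped with a warning.
    """
    out = []
    for sid in range(len(track.sessions)):
        fixes = track.session_fixes(sid)
        pts = np.array([f.position for f in fixes], dtype=float).reshape(-1, 2)
        try:
            poly = mcp(pts, level=level)
        except DegenerateGeometryError:
            warnings.warn(
                f"bat {track.bat_id} session {sid}: fewer than 3 usable fixes, skipped"
            )
            continue
        out.append(DailyRange(track.bat_id, sid, poly.area, poly))
    return out


def home_range(
    track: Track,
    mcp_level: float = 95.0,
    locoh_fraction: float = 0.5,
    k_rounding: str = "round",
    include_root: bool = True,
) -> HomeRangeResult:
    """Full per-bat home-range summary from a deduplicated track."""
    pts = track.positions()
    m95 = mcp(pts, level=mcp_level)
    m100 = mcp(pts, level=100.0)
    k = locoh_k_from_n(len(pts), rounding=k_rounding)
    iso = locoh_isopleth(pts, k, fraction=locoh_fraction, include_root=include_root)
    return HomeRangeResult(
        bat_id=track.bat_id,
        mcp95=m95,
        mcp100=m100,
        locoh_k=k,
        isopleth50=iso,
        n_fixes=len(pts),
        compactness=compactness_ratio(m95),
    )
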