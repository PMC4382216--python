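"""Land-cover classification, availability, and habitat-selection inference.

Space is classified into five structural land-cover categories — natural
forest, degraded forest, farmland, pasture and urban — from either a
categorical grid or a set of category-labelled polygons.  Habitat available
to each bat is the composition of a circle around its day roost reaching to
the far edge of its 95% MCP; habitat used is the set of fixes inside its
50% LoCoH focus areas.  Use versus availability is tested with Manly
selection ratios under design III (use and availability measured per
individual), with simultaneous Bonferroni confidence intervals, and
near-versus-far focus-area composition is compared with exact r x c
Fisher tests under a Holm (sequential Bonferroni) correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.special import gammaln
from shapely.geometry import Point, Polygon

__all__ = [
    "CATEGORIES",
    "OutOfExtentError",
    "LandCoverMap",
    "GridLandCover",
    "PolygonLandCover",
    "availability_circle",
    "composition",
    "SelectionResult",
    "selection_ratios",
    "FisherResult",
    "fisher_exact_rxc",
    "holm_bonferroni",
]

#: the five structural land-cover categories, in fixed order
CATEGORIES = ("natural", "degraded", "farmland", "pasture", "urban")


class OutOfExtentError(ValueError):
    pass


class LandCoverMap:
    """Interface: a categorical planar map queryable by point and by region."""

    categories = CATEGORIES

    def classify_point(self, x: float, y: float) -> str:
        raise NotImplementedError

    def classify_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return np.array([self.classify_point(x, y) for x, y in pts])

    def composition(self, region) -> dict[str, float]:
        raise NotImplementedError


class GridLandCover(LandCoverMap):
    """Regular grid of category codes.

    ``codes`` is an (nrows, ncols) integer array indexing :data:`CATEGORIES`,
    with row 0 the *southern* (bottom) row.  A cell owns the half-open square
    [x, x+cell) x [y, y+cell), which makes point classification deterministic
    on cell edges.
    """

    def __init__(self, codes: np.ndarray, xll: float, yll: float, cellsize: float):
        codes = np.asarray(codes, dtype=int)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if not ((codes >= 0) & (codes < len(CATEGORIES))).all():
            raise ValueError("category codes out of range")
        self.codes = codes
        self.xll = float(xll)
        self.yll = float(yll)
        self.cellsize = float(cellsize)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nr, nc = self.codes.shape
        return (self.xll, self.yll,
                self.xll + nc * self.cellsize, self.yll + nr * self.cellsize)

    def classify_point(self, x: float, y: float) -> str:
        col = math.floor((x - self.xll) / self.cellsize)
        row = math.floor((y - self.yll) / self.cellsize)
        nr, nc = self.codes.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise OutOfExtentError(f"point ({x}, {y}) outside map extent")
        return CATEGORIES[self.codes[row, col]]

    def classify_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        col = np.floor((pts[:, 0] - self.xll) / self.cellsize).astype(int)
        row = np.floor((pts[:, 1] - self.yll) / self.cellsize).astype(int)
        nr, nc = self.codes.shape
        if ((row < 0) | (row >= nr) | (col < 0) | (col >= nc)).any():
            raise OutOfExtentError("point outside map extent")
        return np.array(CATEGORIES, dtype=object)[self.codes[row, col]]

    def composition(self, region) -> dict[str, float]:
        """Exact per-category area fractions of a region (cells clipped)."""
        x0, y0, x1, y1 = region.bounds
        ex0, ey0, ex1, ey1 = self.extent
        cs = self.cellsize
        c0 = max(0, math.floor((x0 - self.xll) / cs))
        r0 = max(0, math.floor((y0 - self.yll) / cs))
        nr, nc = self.codes.shape
        c1 = min(nc - 1, math.floor((x1 - self.xll) / cs))
        r1 = min(nr - 1, math.floor((y1 - self.yll) / cs))
        if c1 < c0 or r1 < r0:
            raise OutOfExtentError("region fully outside map extent")

        rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                                 indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        xs = self.xll + cols * cs
        ys = self.yll + rows * cs
        boxes = shapely.box(xs, ys, xs + cs, ys + cs)
        # cells fully inside need no clipping; only boundary cells do
        inside = shapely.contains(region, boxes)
        areas = np.where(inside, cs * cs, 0.0)
        edge = ~inside & shapely.intersects(region, boxes)
        if edge.any():
            areas[edge] = shapely.area(shapely.intersection(region, boxes[edge]))
        total = areas.sum()
        if total <= 0:
            raise OutOfExtentError("region fully outside map extent")
        out = {}
        codes = self.codes[rows, cols]
        for i, cat in enumerate(CATEGORIES):
            out[cat] = float(areas[codes == i].sum() / total)
        return out


class PolygonLandCover(LandCoverMap):
    """Category-labelled polygons over a declared background category.

    ``features`` is a list of ``(polygon, category)`` pairs; polygons are
    assumed disjoint.  A boundary point resolves to the first-listed feature
    covering it; points in no feature take the background category.
    """

    def __init__(self, features: list[tuple[Polygon, str]],
                 background: str = "pasture",
                 extent: tuple[float, float, float, float] | None = None):
        for _, cat in features:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        if background not in CATEGORIES:
            raise ValueError(f"unknown category {background!r}")
        self.features = list(features)
        self.background = background
        if extent is None and features:
            bounds = np.array([p.bounds for p, _ in features])
            extent = (bounds[:, 0].min(), bounds[:, 1].min(),
                      bounds[:, 2].max(), bounds[:, 3].max())
        self.extent = extent

    def classify_point(self, x: float, y: float) -> str:
        pt = Point(x, y)
        for poly, cat in self.features:
            if poly.covers(pt):
                return cat
        if self.extent is not None:
            x0, y0, x1, y1 = self.extent
            if not (x0 <= x <= x1 and y0 <= y <= y1):
                raise OutOfExtentError(f"point ({x}, {y}) outside map extent")
        return self.background

    def composition(self, region) -> dict[str, float]:
        total = region.area
        if total <= 0:
            raise OutOfExtentError("empty region")
        out = dict.fromkeys(CATEGORIES, 0.0)
        for poly, cat in self.features:
            out[cat] += region.intersection(poly).area
        covered = sum(out.values())
        out[self.background] += max(0.0, total - covered)
        return {c: v / total for c, v in out.items()}


def availability_circle(roosts, mcp95: Polygon) -> tuple[tuple[float, float], float]:
    """Availability circle around the day roost(s).

    Center is the single roost, or the mean of the roost coordinates when a
    bat used several (a degenerate-hull-safe center of the roost cluster);
    radius is the maximum distance from the center to any vertex of the
    bat's 95% MCP, so the circle reaches the far edge of the home range.
    """
    roosts = np.asarray(roosts, dtype=float).reshape(-1, 2)
    if len(roosts) == 0:
        raise ValueError("empty roost list")
    center = roosts.mean(axis=0)
    verts = np.asarray(mcp95.exterior.coords)
    radius = float(np.hypot(*(verts - center).T).max())
    return (float(center[0]), float(center[1])), radius


def composition(region, landcover: LandCoverMap) -> dict[str, float]:
    """Per-category area fractions of a region (circle or polygon)."""
    return landcover.composition(region)


@dataclass
class SelectionResult:
    """Manly design-III selection ratios with simultaneous Bonferroni CIs."""

    table: pd.DataFrame  # index: category; columns: wi, se, ci_low, ci_high
    chi2: float
    df: int
    p: float
    alpha: float


def selection_ratios(
    used: pd.DataFrame,
    available: pd.DataFrame,
    alpha: float = 0.05,
    quantile: str = "t",
) -> SelectionResult:
    """Population-level selection ratios from per-animal use and availability.

    ``used`` holds per-bat fix counts by category (rows: bats, columns:
    categories); ``available`` holds per-bat availability proportions with
    the same shape, each row summing to 1.  Under design III the pooled
    ratio for category i is

        w_i = sum_j u_ij / sum_j u_+j * pi_ij

    (u_+j the bat j total, pi_ij its availability).  Its standard error is
    the ratio-of-totals estimator treating bats as sampling units.
    Simultaneous (1 - alpha) Bonferroni intervals use the alpha/(2 I)
    quantile with I the number of categories available to the population;
    because the standard error is estimated from few animals, the default
    quantile is Student t with (n_animals - 1) degrees of freedom, which
    restores near-nominal simultaneous coverage at telemetry-sized samples.
    ``quantile="normal"`` reproduces the classical large-sample z
    construction.  Negative lower limits are truncated to 0.  The global
    log-likelihood chi-square compares observed counts u_ij with expected
    u_+j * pi_ij, on sum_j (I_j - 1) degrees of freedom where I_j counts
    the categories with nonzero availability for bat j.
    """
    used = used.astype(float)
    available = available.reindex(index=used.index, columns=used.columns)
    if used.shape != available.shape:
        raise ValueError("used and available must share shape")
    if len(used) < 2:
        raise ValueError("design III needs at least 2 animals")
    u = used.to_numpy()
    pi = available.to_numpy()
    if (u.sum(axis=1) <= 0).any():
        raise ValueError("every animal must have a positive total use count")
    if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("availability proportions must sum to 1 per animal")

    zero_avail_use = (pi == 0) & (u > 0)
    if zero_avail_use.any():
        warnings.warn("use recorded in a category with zero availability; "
                      "those cells are excluded from the chi-square")

    u_tot = u.sum(axis=1)  # per bat
    expected = u_tot[:, None] * pi
    denom = expected.sum(axis=0)  # per category
    with np.errstate(divide="ignore", invalid="ignore"):
        wi = np.where(denom > 0, u.sum(axis=0) / np.where(denom > 0, denom, 1.0), np.nan)

    # ratio-of-totals variance over animals
    n = len(u)
    resid = u - wi[None, :] * expected
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(denom > 0,
                       n / (n - 1) * (resid ** 2).sum(axis=0) / np.where(denom > 0, denom, 1.0) ** 2,
                       np.nan)
    se = np.sqrt(var)

    n_avail = int((pi.sum(axis=0) > 0).sum())
    if quantile == "normal":
        z = stats.norm.isf(alpha / (2 * n_avail))
    elif quantile == "t":
        z = stats.t.isf(alpha / (2 * n_avail), n - 1)
    else:
        raise ValueError("quantile must be 't' or 'normal'")
    ci_low = np.maximum(0.0, wi - z * se)
    ci_high = wi + z * se

    mask = (u > 0) & (pi > 0)
    chi2 = float(2.0 * (u[mask] * np.log(u[mask] / expected[mask])).sum())
    df = int(((pi > 0).sum(axis=1) - 1).sum())
    p = float(stats.chi2.sf(chi2, df))

    table = pd.DataFrame(
        {"wi": wi, "se": se, "ci_low": ci_low, "ci_high": ci_high},
        index=pd.Index(used.columns, name="category"),
    )
    return SelectionResult(table=table, chi2=chi2, df=df, p=p, alpha=alpha)


@dataclass
class FisherResult:
    p: float
    method: str  # exact | monte-carlo
    se: float | None = None

    def __float__(self) -> float:
        return self.p


def _table_logprob(t: np.ndarray) -> float:
    # multivariate hypergeometric mass given both margins
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(t + 1).sum())


def fisher_exact_rxc(
    table,
    budget: int = 10_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Exact conditional test of independence for an r x c count table.

    The p-value is the total multivariate-hypergeometric probability of all
    tables with the observed margins whose probability does not exceed that
    of the observed table (within a relative tolerance of 1e-7).  All-zero
    columns are dropped first.  When the enumeration would visit more than
    ``budget`` tables, a seeded Monte-Carlo estimate over ``n_mc`` sampled
    tables is returned instead, with its standard error.
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    t = t[:, t.sum(axis=0) > 0]
    t = t[t.sum(axis=1) > 0, :]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return FisherResult(p=1.0, method="exact")

    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    log_obs = _table_logprob(t)
    tol = 1e-7

    acc = 0.0
    count = 0
    r, c = t.shape

    def enumerate_tables(row: int, remaining_cols: np.ndarray, filled: list) -> bool:
        """Accumulate the p-value; return False if the budget is exceeded."""
        nonlocal acc, count
        if row == r - 1:
            count += 1
            if count > budget:
                return False
            full = np.array(filled + [remaining_cols])
            lp = _table_logprob(full)
            if lp <= log_obs + tol:
                acc += math.exp(lp)
            return True
        # enumerate compositions of rows[row] bounded by remaining_cols
        target = rows[row]

        def rec(j: int, left: int, cells: list) -> bool:
            if j == c - 1:
                if left > remaining_cols[c - 1]:
                    return True
                return enumerate_tables(
                    row + 1,
                    remaining_cols - np.array(cells + [left]),
                    filled + [np.array(cells + [left])],
                )
            lo = max(0, left - int(remaining_cols[j + 1:].sum()))
            hi = min(int(remaining_cols[j]), left)
            for v in range(lo, hi + 1):
                if not rec(j + 1, left - v, cells + [v]):
                    return False
            return True

        return rec(0, int(target), [])

    if enumerate_tables(0, cols.copy(), []):
        return FisherResult(p=min(1.0, acc), method="exact")

    # Monte-Carlo fallback: shuffle column labels, split by row totals
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(c), cols)
    splits = np.cumsum(rows)[:-1]
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        sim = np.array([np.bincount(part, minlength=c)
                        for part in np.split(labels, splits)])
        if _table_logprob(sim) <= log_obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p=p, method="monte-carlo", se=se)


def holm_bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down (sequential Bonferroni) multiple-testing correction.

    The i-th smallest p-value is compared with alpha/(m - i + 1); testing
    stops at the first retention, so rejections form a prefix of the sorted
    list.  Returns ``(reject, threshold)`` aligned with the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    thresh = np.empty(m, dtype=float)
    alive = True
    for rank, idx in enumerate(order):
        thresh[idx] = alpha / (m - rank)
        if alive and p[idx] <= thresh[idx]:
            reject[idx] = True
        else:
            alive = False
    return reject, thresh
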