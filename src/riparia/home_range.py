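"""Home-range estimation: MCP, kernel utilization distributions, contours.

Two estimators are provided, matching standard telemetry practice:

* **MCP95** — the convex hull of the 95% of relocations closest to the fix
  centroid (arithmetic mean), with area in hectares.
* **Kernel UD** — a bivariate-Gaussian kernel density on a square grid using
  the normal-reference ("ad hoc") bandwidth href, with K95/K75/K50 isopleth
  regions extracted by accumulating cells in descending density order.

An area-accumulation curve (area against days of data) checks whether the
estimate has saturated before trusting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

from .landcover import mask_to_multipolygon
from .telemetry import Trajectory

__all__ = [
    "UtilizationDistribution",
    "HomeRangeEstimate",
    "DegenerateGeometryError",
    "mcp",
    "href_bandwidth",
    "kernel_ud",
    "ud_contour",
    "area_accumulation",
]

M2_PER_HA = 1e4

#: Default UD grid resolution (m); matches the 5 m imagery grid.
DEFAULT_CELL_SIZE = 5.0

#: Grid margin around the fixes, in bandwidths.
GRID_MARGIN_H = 3.0


class DegenerateGeometryError(ValueError):
    """Fixes are collinear/coincident; the estimator has no area."""


@dataclass
class HomeRangeEstimate:
    """One home-range polygon with its area."""

    bird_id: str
    estimator: str  # MCP95, K95, K75, K50 (or MCP<retention>)
    polygon: BaseGeometry | None
    area_ha: float
    parameter: float  # retention fraction (MCP) or bandwidth h in m (kernel)


@dataclass
class UtilizationDistribution:
    """Kernel density of space use on a square grid (integrates to one).

    ``density[i, j]`` (per m^2) is the cell whose centre is
    ``(x0 + (j+0.5) dx, y0 + (i+0.5) dx)`` with ``dx = cell_size``.
    """

    x0: float
    y0: float
    cell_size: float
    density: np.ndarray
    h: float
    bird_id: str = "bird"

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def _as_xy(fixes) -> np.ndarray:
    if isinstance(fixes, Trajectory):
        return fixes.xy
    arr = np.asarray(fixes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("fixes must be an (n, 2) coordinate array or a Trajectory")
    return arr


def _bird_id(fixes, default: str = "bird") -> str:
    return fixes.bird_id if isinstance(fixes, Trajectory) else default


def mcp(fixes, retention: float = 0.95, bird_id: str | None = None) -> HomeRangeEstimate:
    """Minimum convex polygon on the centroid-nearest ``retention`` fraction.

    The distance threshold is the empirical ``retention`` quantile (linear
    interpolation) of centroid distances; points exactly at the threshold
    are retained.  Area is returned in hectares.
    """
    xy = _as_xy(fixes)
    if len(xy) < 3:
        raise ValueError("MCP needs at least three fixes")
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must lie in (0, 1]")
    centroid = xy.mean(axis=0)
    d = np.hypot(*(xy - centroid).T)
    thr = np.quantile(d, retention)
    kept = xy[d <= thr]
    hull = MultiPoint(kept).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0.0:
        raise DegenerateGeometryError("retained fixes are collinear or coincident")
    name = "MCP95" if abs(retention - 0.95) < 1e-12 else f"MCP{retention:g}"
    return HomeRangeEstimate(
        bird_id or _bird_id(fixes), name, hull, hull.area / M2_PER_HA, retention
    )


def href_bandwidth(fixes) -> float:
    """Normal-reference ("ad hoc") kernel bandwidth.

    ``h = sqrt((var(x) + var(y)) / 2) * n^(-1/6)`` with the unbiased
    (n - 1) variance — the standard bivariate reference bandwidth for
    telemetry kernels.
    """
    xy = _as_xy(fixes)
    n = len(xy)
    if n < 2:
        raise ValueError("href needs at least two fixes")
    v = xy.var(axis=0, ddof=1)
    if v.sum() <= 0.0:
        raise ValueError("fixes have zero spread; href undefined")
    return float(np.sqrt(v.mean()) * n ** (-1.0 / 6.0))


def kernel_ud(
    fixes,
    h: float | None = None,
    cell_size: float = DEFAULT_CELL_SIZE,
    grid: tuple[float, float, int, int] | None = None,
    bird_id: str | None = None,
) -> UtilizationDistribution:
    """Bivariate-Gaussian kernel utilization distribution.

    ``UD(cell) = (1/n) sum_i N2(||cell - fix_i||; h)``, evaluated exactly via
    the separable x/y structure of the Gaussian and renormalized so the grid
    integrates to one.  The default grid is the fix bounding box padded by
    three bandwidths; a user grid (x0, y0, nx, ny) must cover that box.
    """
    xy = _as_xy(fixes)
    if h is None:
        h = href_bandwidth(xy)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pad = GRID_MARGIN_H * h
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    if grid is None:
        x0, y0 = lo
        nx = int(np.ceil((hi[0] - x0) / cell_size))
        ny = int(np.ceil((hi[1] - y0) / cell_size))
    else:
        x0, y0, nx, ny = grid
        if x0 > lo[0] or y0 > lo[1] or x0 + nx * cell_size < hi[0] or y0 + ny * cell_size < hi[1]:
            raise ValueError("grid too small: must cover fixes plus a 3h margin")
    cx = x0 + (np.arange(nx) + 0.5) * cell_size
    cy = y0 + (np.arange(ny) + 0.5) * cell_size
    # separable exact evaluation: density = Gy.T @ Gx / (n 2 pi h^2)
    gx = np.exp(-0.5 * ((cx[None, :] - xy[:, 0][:, None]) / h) ** 2)
    gy = np.exp(-0.5 * ((cy[None, :] - xy[:, 1][:, None]) / h) ** 2)
    dens = (gy.T @ gx) / (len(xy) * 2.0 * np.pi * h**2)
    mass = dens.sum() * cell_size**2
    if mass <= 0:
        raise ValueError("all density mass fell outside the grid")
    dens /= mass
    return UtilizationDistribution(
        float(x0), float(y0), cell_size, dens, float(h), bird_id or _bird_id(fixes)
    )


def ud_contour(
    ud: UtilizationDistribution, level: float, polygonize: bool = True
) -> HomeRangeEstimate:
    """Smallest UD region holding ``level`` of the use mass.

    Cells are accumulated in descending density order (ties broken by cell
    index) until their mass reaches ``level``; the region's area is cell
    count times cell area, and its boundary is polygonized on request.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mask = contour_mask(ud, level)
    k = int(mask.sum())
    poly = mask_to_multipolygon(mask, ud.x0, ud.y0, ud.cell_size) if polygonize else None
    return HomeRangeEstimate(
        ud.bird_id, f"K{int(round(level * 100))}", poly, k * ud.cell_area / M2_PER_HA, ud.h
    )


def contour_mask(ud: UtilizationDistribution, level: float) -> np.ndarray:
    """Boolean cell mask of the ``level`` isopleth region (grid shape).

    Cells are taken in descending density order (stable ties) until their
    cumulative mass reaches ``level``; a tiny relative slack keeps exact-tie
    accumulations (e.g. a uniform UD) from spilling into one extra cell.
    """
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order]) * ud.cell_area
    target = level * ud.total_mass() * (1.0 - 1e-12)
    k = int(np.searchsorted(csum, target, side="left")) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[: min(k, flat.size)]] = True
    return mask.reshape(ud.density.shape)


@dataclass
class AccumulationCurve:
    """Home-range area against days of data, with saturation flags."""

    table: pd.DataFrame  # columns: days_used, mcp95_ha, k95_ha
    saturated_mcp: bool
    saturated_k95: bool


def area_accumulation(
    traj: Trajectory,
    retention: float = 0.95,
    level: float = 0.95,
    cell_size: float = DEFAULT_CELL_SIZE,
    saturation_tol: float = 0.05,
) -> AccumulationCurve:
    """Estimate MCP95 and K95 areas on the first k days, for k = 2..D.

    The saturation flag is set when the final day adds less than
    ``saturation_tol`` of the final area — the sample-size check applied
    before trusting a home-range estimate.
    """
    days = pd.to_datetime(pd.Series(traj.times)).dt.normalize()
    uniq = days.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two days of fixes")
    rows = []
    for k in range(2, len(uniq) + 1):
        sel = days.isin(uniq[:k]).to_numpy()
        xy = traj.xy[sel]
        a_mcp = mcp(xy, retention, bird_id=traj.bird_id).area_ha
        ud = kernel_ud(xy, cell_size=cell_size, bird_id=traj.bird_id)
        a_k = ud_contour(ud, level, polygonize=False).area_ha
        rows.append({"days_used": k, "mcp95_ha": a_mcp, "k95_ha": a_k})
    tab = pd.DataFrame(rows)

    def saturated(col: str) -> bool:
        final = tab[col].iloc[-1]
        if len(tab) < 2 or final <= 0:
            return False
        return abs(final - tab[col].iloc[-2]) < saturation_tol * final

    return AccumulationCurve(tab, saturated("mcp95_ha"), saturated("k95_ha"))
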