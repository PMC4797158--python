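"""Multispectral band arithmetic: TOA reflectance, vegetation indices,
distance rasters.

The imagery model is a 5-band stack (Blue, Green, Red, RedEdge, NIR) on a
square metric grid, 5 m cells by default.  Radiance is converted to
top-of-atmosphere (TOA) reflectance with sensor-supplied coefficients, seven
vegetation indices are derived from the reflectance bands, and Euclidean
distance-to-feature rasters (river, mixed thicket, settlements) quantify the
spatial configuration of preferred habitat for the suitability models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .landcover import LandCoverMap

#: Spectral bands expected on input, in order.
SPECTRAL_BANDS: tuple[str, ...] = ("Blue", "Green", "Red", "RedEdge", "NIR")

#: The seven vegetation indices, as (name, formula description).
INDEX_NAMES: tuple[str, ...] = (
    "NDVI",     # (NIR - Red) / (NIR + Red)
    "REGNDVI",  # red-edge green NDVI: (RedEdge - Green) / (RedEdge + Green)
    "GNDVI",    # (NIR - Green) / (NIR + Green)
    "NDRE",     # (NIR - RedEdge) / (NIR + RedEdge)
    "GCM",      # chlorophyll green model: NIR / Green - 1
    "GRM",      # chlorophyll red-edge model: NIR / RedEdge - 1
    "RENDVI",   # red-edge NDVI: (RedEdge - Red) / (RedEdge + Red)
)


@dataclass
class RasterStack:
    """Co-registered named bands on one square grid.

    Rows are indexed south-to-north: ``bands[name][i, j]`` is the cell whose
    centre is at ``(x0 + (j + 0.5) * cell_size, y0 + (i + 0.5) * cell_size)``.
    ``valid`` is a boolean mask shared by all bands (False = nodata).
    """

    x0: float
    y0: float
    cell_size: float
    bands: dict[str, np.ndarray]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs: str | None = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("all bands must share one grid")
        if self.valid is None:
            self.valid = np.ones(self.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.shape
        return (self.x0, self.y0, self.x0 + nx * self.cell_size, self.y0 + ny * self.cell_size)

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, each of grid shape."""
        ny, nx = self.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing planar points; clipped to grid."""
        ny, nx = self.shape
        j = np.clip(((np.asarray(x) - self.x0) // self.cell_size).astype(int), 0, nx - 1)
        i = np.clip(((np.asarray(y) - self.y0) // self.cell_size).astype(int), 0, ny - 1)
        return i, j

    def with_bands(self, new: dict[str, np.ndarray], valid: np.ndarray | None = None) -> "RasterStack":
        bands = dict(self.bands)
        bands.update(new)
        v = self.valid if valid is None else (self.valid & valid)
        return RasterStack(self.x0, self.y0, self.cell_size, bands, v, self.crs)


def toa_reflectance(
    stack: RasterStack,
    coefficients: dict[str, dict[str, float]],
    sun_elevation_deg: float,
    earth_sun_distance_au: float = 1.0,
) -> RasterStack:
    """Convert radiance bands to top-of-atmosphere reflectance.

    ``reflectance = radiance * scale * pi * d^2 / (esun * cos(zenith))``
    with per-band ``scale`` (radiometric scale factor) and ``esun``
    (exo-atmospheric solar irradiance), solar zenith = 90 deg - elevation,
    and Earth-Sun distance ``d`` in AU.  Output clipped to [0, 1].

    Coefficients come from the imagery product metadata; there are no
    universal defaults, so a missing band raises with instructions.
    """
    zenith = math.radians(90.0 - sun_elevation_deg)
    cosz = math.cos(zenith)
    if cosz < 1e-6:
        raise ValueError("solar zenith at or beyond 90 degrees; cannot normalize illumination")
    out: dict[str, np.ndarray] = {}
    for name in SPECTRAL_BANDS:
        if name not in stack.bands:
            continue
        if name not in coefficients or not {"scale", "esun"} <= set(coefficients[name]):
            raise ValueError(
                f"missing TOA coefficients for band {name!r}: supply "
                "{'scale': radiometric scale, 'esun': solar irradiance} from the product metadata"
            )
        c = coefficients[name]
        refl = stack.bands[name] * c["scale"] * math.pi * earth_sun_distance_au**2 / (c["esun"] * cosz)
        out[name] = np.clip(refl, 0.0, 1.0)
    # carry through any non-spectral bands untouched
    for name, arr in stack.bands.items():
        if name not in out:
            out[name] = arr
    return RasterStack(stack.x0, stack.y0, stack.cell_size, out, stack.valid.copy(), stack.crs)


def _nd(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized difference (a-b)/(a+b) and its validity mask."""
    denom = a + b
    ok = denom != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(ok, (a - b) / np.where(ok, denom, 1.0), np.nan)
    return v, ok


def _ratio(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = b != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(ok, a / np.where(ok, b, 1.0) - 1.0, np.nan)
    return v, ok


def vegetation_indices(stack: RasterStack) -> RasterStack:
    """Append the seven vegetation index bands to a reflectance stack.

    Cells with a zero denominator (or already nodata) become nodata in the
    returned stack; nodata propagates, never fabricates index values.
    """
    missing = [b for b in SPECTRAL_BANDS if b not in stack.bands]
    if missing:
        raise ValueError(f"reflectance bands missing: {missing}")
    G, R = stack.band("Green"), stack.band("Red")
    RE, NIR = stack.band("RedEdge"), stack.band("NIR")
    new: dict[str, np.ndarray] = {}
    ok = np.ones(stack.shape, dtype=bool)
    for name, (v, m) in {
        "NDVI": _nd(NIR, R),
        "REGNDVI": _nd(RE, G),
        "GNDVI": _nd(NIR, G),
        "NDRE": _nd(NIR, RE),
        "GCM": _ratio(NIR, G),
        "GRM": _ratio(NIR, RE),
        "RENDVI": _nd(RE, R),
    }.items():
        new[name] = v
        ok &= m
    return stack.with_bands(new, valid=ok)


def distance_raster(
    lc: LandCoverMap,
    target: str | BaseGeometry,
    grid: RasterStack,
) -> RasterStack:
    """Euclidean distance (m) from each cell centre to the nearest target.

    ``target`` may be ``"river"`` (the river polyline), ``"settlement"``
    (settlement points, falling back to settlement polygons), any polygon
    class name such as ``"mixed"``, or an explicit shapely geometry.
    Distance is zero inside target polygons.
    """
    if isinstance(target, BaseGeometry):
        geom = target
        name = "target"
    elif target == "river":
        geom, name = lc.river, "river"
    elif target == "settlement":
        if lc.settlement_points:
            geom = unary_union(lc.settlement_points)
            poly = lc.polygons.get("settlement")
            if poly is not None and not poly.is_empty:
                geom = unary_union([geom, poly])
        else:
            geom = lc.polygons.get("settlement")
        name = "settlement"
    else:
        geom = lc.polygons.get(target)
        name = str(target)
    if geom is None or geom.is_empty:
        raise ValueError(f"target geometry {target!r} is empty")
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, geom).reshape(grid.shape)
    return RasterStack(grid.x0, grid.y0, grid.cell_size, {f"dist_{name}": d},
                       grid.valid.copy(), grid.crs)
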