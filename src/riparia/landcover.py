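"""Land-cover map container shared across the pipeline.

A :class:`LandCoverMap` holds the polygonal habitat mosaic of a river-centred
study area in a projected, metric CRS: non-overlapping class polygons, the
river polyline, optional roads, and settlement points.  The class schema
follows the field protocol for East African riparian mosaics: indigenous
thicket, mixed thicket (indigenous invaded by *Lantana camara*), pure
*L. camara* thicket, low- and high-growing crops, and settlements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

#: Polygonal habitat classes, in river-priority order (thicket classes first).
POLYGON_CLASSES: tuple[str, ...] = (
    "indigenous",
    "mixed",
    "lantana",
    "crops_low",
    "crops_high",
    "settlement",
)

#: Every feature class accepted in a land-cover GeoJSON.
ALL_CLASSES: tuple[str, ...] = POLYGON_CLASSES + ("river", "road")


@dataclass
class LandCoverMap:
    """Polygonal land-cover mosaic with river line and settlement points.

    Parameters
    ----------
    extent
        (xmin, ymin, xmax, ymax) in metres.
    polygons
        Mapping habitat class -> (Multi)Polygon.  Classes absent from the map
        are simply missing keys (or empty geometries).
    river
        River centre line.
    settlement_points
        Point locations of homesteads (the polygonal ``settlement`` class may
        coexist; points are the survey's point layer).
    roads
        Optional road/path polylines.
    class_grid, cell_size
        Optional rasterized class labels (row 0 = south edge) produced by the
        synthetic generator; used as a fast point-class lookup.
    """

    extent: tuple[float, float, float, float]
    polygons: dict[str, BaseGeometry]
    river: LineString
    settlement_points: list[Point] = field(default_factory=list)
    roads: list[LineString] = field(default_factory=list)
    class_grid: np.ndarray | None = None
    cell_size: float | None = None

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must be a non-degenerate rectangle")
        unknown = set(self.polygons) - set(POLYGON_CLASSES)
        if unknown:
            raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")

    @property
    def area_m2(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)

    def class_at(self, x: float, y: float) -> str | None:
        """Habitat class containing (x, y), or None if unmapped."""
        if self.class_grid is not None and self.cell_size is not None:
            xmin, ymin, xmax, ymax = self.extent
            if not (xmin <= x < xmax and ymin <= y < ymax):
                return None
            j = int((x - xmin) // self.cell_size)
            i = int((y - ymin) // self.cell_size)
            ny, nx = self.class_grid.shape
            i, j = min(i, ny - 1), min(j, nx - 1)
            idx = int(self.class_grid[i, j])
            return POLYGON_CLASSES[idx] if idx >= 0 else None
        pt = Point(x, y)
        for cls, geom in self.polygons.items():
            if geom is not None and not geom.is_empty and geom.intersects(pt):
                return cls
        return None

    def classes_at(self, xy: np.ndarray) -> list[str | None]:
        """Vectorized :meth:`class_at` over an (n, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float)
        if self.class_grid is not None and self.cell_size is not None:
            return [self.class_at(x, y) for x, y in xy]
        # STRtree point-in-polygon for maps without a label grid
        classes: list[str | None] = [None] * len(xy)
        pts = shapely.points(xy[:, 0], xy[:, 1])
        for cls, geom in self.polygons.items():
            if geom is None or geom.is_empty:
                continue
            hit = shapely.intersects(geom, pts)
            for k in np.flatnonzero(hit):
                if classes[k] is None:
                    classes[k] = cls
        return classes


def mask_to_multipolygon(mask: np.ndarray, x0: float, y0: float, cell: float) -> MultiPolygon:
    """Union of grid-cell boxes where ``mask`` is True (rows run south→north).

    Rows are run-length encoded into horizontal strips before the union, so
    large masks polygonize quickly.
    """
    boxes = []
    for i in range(mask.shape[0]):
        row = np.ascontiguousarray(mask[i], dtype=bool)
        if not row.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            boxes.append(
                shapely.box(x0 + start * cell, y0 + i * cell, x0 + stop * cell, y0 + (i + 1) * cell)
            )
    merged = shapely.unary_union(boxes) if boxes else MultiPolygon([])
    return ensure_multipolygon(merged)


def ensure_multipolygon(geom: BaseGeometry) -> MultiPolygon:
    """Coerce a polygonal geometry to MultiPolygon, dropping slivers."""
    if geom.is_empty:
        return MultiPolygon([])
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return MultiPolygon(polys)
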