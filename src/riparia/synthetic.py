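"""Synthetic river-valley landscapes, imagery and bird tracks.

The generator emulates the study system the pipeline is built for: a
semi-arid river valley whose riparian thickets (indigenous, mixed, and pure
*Lantana camara*) hug the river inside a few-hundred-metre buffer, embedded
in a mosaic of low and high crops with scattered settlements.  On top of the
landscape it simulates

* a 5-band multispectral reflectance raster with class-conditional spectra,
* habitat-biased correlated-random-walk bird tracks fixed every 10 minutes,
* paired observer compass bearings with Gaussian angular noise.

Every generator funnels all randomness through one seeded
:class:`numpy.random.Generator`, so equal seeds give bit-identical output.

Default parameters are the study conditions: the class mix follows the
mapped composition of the real valley (thicket ~30% of the assessed area,
dominated by *L. camara*; crops the remainder; settlements ~4%), and the
per-habitat step-length means are the reported movement speeds
(143.9 m/10 min in *L. camara*, 402.8 in low crops, 315.1 in high crops,
299.8 in mixed thicket).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

from .landcover import POLYGON_CLASSES, LandCoverMap, mask_to_multipolygon
from .remote_sensing import SPECTRAL_BANDS, RasterStack
from .telemetry import Trajectory, build_trajectory

__all__ = [
    "LandscapeSpec",
    "MovementSpec",
    "SpectralSpec",
    "generate_landscape",
    "generate_track",
    "generate_bearings",
    "generate_raster",
]

#: Target area fraction per class (remainder = crops_high background).
#: Mirrors the mapped composition of the study valley.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "indigenous": 0.018,
    "mixed": 0.065,
    "lantana": 0.283,
    "crops_low": 0.094,
    "settlement": 0.043,
}

#: Mean step length (m per 10 min) by habitat class.  Thicket classes are
#: slow (foraging), open crops fast (transit).  Values for lantana, crops_low,
#: crops_high and mixed are the reported per-habitat movement speeds; the two
#: classes without a reported speed (rarely visited) borrow the nearest
#: structural analogue: indigenous thicket moves like mixed thicket,
#: settlements like high crops.
DEFAULT_STEP_MEANS: dict[str, float] = {
    "lantana": 143.9,
    "crops_low": 402.8,
    "crops_high": 315.1,
    "mixed": 299.8,
    "indigenous": 299.8,
    "settlement": 315.1,
}

#: Class-conditional mean reflectance per band (Blue, Green, Red, RedEdge,
#: NIR; unitless 0-1).  Plausible vegetation/soil spectra; lantana carries a
#: distinct green / red-edge signature so the spectral sub-model has signal.
DEFAULT_SPECTRA: dict[str, tuple[float, float, float, float, float]] = {
    "indigenous": (0.030, 0.060, 0.040, 0.150, 0.450),
    "mixed":      (0.035, 0.070, 0.050, 0.180, 0.420),
    "lantana":    (0.040, 0.110, 0.050, 0.260, 0.500),
    "crops_low":  (0.060, 0.100, 0.090, 0.200, 0.350),
    "crops_high": (0.050, 0.090, 0.070, 0.220, 0.400),
    "settlement": (0.150, 0.170, 0.200, 0.220, 0.250),
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic river-valley mosaic."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 2000.0)
    cell_size: float = 10.0
    river_amplitude: float = 150.0
    river_wavelength: float = 900.0
    river_phase: float = 0.0
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    buffer_width: float = 400.0
    mosaic: float = 0.35  # corridor interleaving: 0 = solid thicket band
    n_patches: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        unknown = set(self.class_mix) - set(POLYGON_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class_mix fractions sum to {total:.3f} > 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix fractions must be non-negative")


@dataclass(frozen=True)
class MovementSpec:
    """Correlated-random-walk parameters for one simulated bird."""

    step_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STEP_MEANS))
    step_cv: float = 0.6          # gamma coefficient of variation
    kappa: float = 1.0            # von Mises turning-angle concentration
    river_attraction: float = 0.0  # 0 = free CRW, 1 = head straight to river
    habitat_preference: dict[str, float] | None = None  # selection weights
    n_candidates: int = 7         # candidate headings when selecting habitat
    fix_interval_min: float = 10.0
    n_fixes: int = 500
    start: tuple[float, float] | None = None  # default: a point on the river
    start_time: str = "2014-08-08T07:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.step_means.values()):
            raise ValueError("step-length means must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.0 <= self.river_attraction <= 1.0:
            raise ValueError("river_attraction must lie in [0, 1]")


@dataclass(frozen=True)
class SpectralSpec:
    """Class-conditional reflectance model for the synthetic imagery."""

    class_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA)
    )
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, means in self.class_means.items():
            if len(means) != len(SPECTRAL_BANDS):
                raise ValueError(f"{cls}: need {len(SPECTRAL_BANDS)} band means")
            if any(not 0.0 <= m <= 1.0 for m in means):
                raise ValueError(f"{cls}: band means must lie in [0, 1]")


# ---------------------------------------------------------------------------
# landscape


def river_polyline(spec: LandscapeSpec) -> LineString:
    """Sinusoidal river centre line running west-east across the extent."""
    xmin, ymin, xmax, ymax = spec.extent
    ymid = 0.5 * (ymin + ymax)
    xs = np.linspace(xmin, xmax, max(64, int((xmax - xmin) / spec.cell_size) + 1))
    ys = ymid + spec.river_amplitude * np.sin(
        2.0 * math.pi * (xs - xmin) / spec.river_wavelength + spec.river_phase
    )
    return LineString(np.column_stack([xs, ys]))


def generate_landscape(spec: LandscapeSpec) -> LandCoverMap:
    """Generate a river-centred habitat mosaic.

    Voronoi-seeded patches are relabelled by distance-to-river priority: the
    thicket classes claim the river-nearest patches (concentrating them
    inside ``buffer_width``), crops_low and settlement patches are scattered
    over the remainder, and crops_high is the background matrix.  With
    ``mosaic`` > 0 the priority distance is jittered, interleaving
    agricultural plots into the corridor — the fine-grained river mosaic of
    the study system.  Realized class fractions track the targets to within
    roughly one patch.
    """
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = spec.extent
    nx = int(round((xmax - xmin) / spec.cell_size))
    ny = int(round((ymax - ymin) / spec.cell_size))
    n_cells = nx * ny
    river = river_polyline(spec)

    # Voronoi patches on the cell grid
    seeds = np.column_stack(
        [rng.uniform(xmin, xmax, spec.n_patches), rng.uniform(ymin, ymax, spec.n_patches)]
    )
    xs = xmin + (np.arange(nx) + 0.5) * spec.cell_size
    ys = ymin + (np.arange(ny) + 0.5) * spec.cell_size
    X, Y = np.meshgrid(xs, ys)
    _, patch_of_cell = cKDTree(seeds).query(np.column_stack([X.ravel(), Y.ravel()]))
    patch_of_cell = patch_of_cell.reshape(ny, nx)

    # patch -> mean distance to river, ascending (river-priority order)
    cell_river_dist = shapely.distance(
        shapely.points(X.ravel(), Y.ravel()), river
    ).reshape(ny, nx)
    patch_sizes = np.bincount(patch_of_cell.ravel(), minlength=spec.n_patches)
    patch_dist = np.full(spec.n_patches, np.inf)
    occupied = patch_sizes > 0
    sums = np.bincount(
        patch_of_cell.ravel(), weights=cell_river_dist.ravel(), minlength=spec.n_patches
    )
    patch_dist[occupied] = sums[occupied] / patch_sizes[occupied]
    # mosaic: jitter the priority distance so agricultural plots interleave
    # with thicket inside the corridor (jitter scale << buffer keeps the
    # thicket classes concentrated near the river)
    if spec.mosaic > 0:
        jitter = rng.exponential(spec.mosaic * spec.buffer_width * 0.5, spec.n_patches)
        priority = patch_dist + jitter
    else:
        priority = patch_dist
    order = np.argsort(priority, kind="stable")

    thicket = ("indigenous", "mixed", "lantana")
    quota = {c: spec.class_mix.get(c, 0.0) * n_cells for c in POLYGON_CLASSES}
    filled = {c: 0 for c in POLYGON_CLASSES}
    label = np.full(spec.n_patches, POLYGON_CLASSES.index("crops_high"), dtype=np.int8)

    # thicket classes take the priority-nearest patches, drawn in proportion
    # to their remaining quota so each class concentrates near the river
    remaining = [p for p in order if occupied[p]]
    idx = 0
    while idx < len(remaining):
        want = [c for c in thicket if filled[c] < quota[c]]
        if not want:
            break
        p = remaining[idx]
        idx += 1
        size = patch_sizes[p]
        # a patch is only assigned where it will not overshoot the class
        # quota by more than half its size, keeping realized fractions tight
        fits = [c for c in want if size <= 2.0 * (quota[c] - filled[c])]
        if not fits:
            continue  # patch stays agricultural; a smaller one may fit later
        weights = np.array([quota[c] - filled[c] for c in fits])
        cls = rng.choice(fits, p=weights / weights.sum())
        label[p] = POLYGON_CLASSES.index(cls)
        filled[cls] += size

    # crops_low and settlement scattered over the rest
    rest = remaining[idx:] + [p for p in remaining[:idx]
                              if label[p] == POLYGON_CLASSES.index("crops_high")]
    rng.shuffle(rest)  # in-place, seeded
    for cls in ("crops_low", "settlement"):
        k = 0
        while k < len(rest) and filled[cls] < quota[cls]:
            p = rest[k]
            size = patch_sizes[p]
            if (label[p] == POLYGON_CLASSES.index("crops_high")
                    and size <= 2.0 * (quota[cls] - filled[cls])):
                label[p] = POLYGON_CLASSES.index(cls)
                filled[cls] += size
            k += 1

    class_grid = label[patch_of_cell]

    polygons = {}
    for ci, cls in enumerate(POLYGON_CLASSES):
        if spec.class_mix.get(cls, None) == 0.0 and cls != "crops_high":
            continue
        mask = class_grid == ci
        if mask.any():
            polygons[cls] = mask_to_multipolygon(mask, xmin, ymin, spec.cell_size)

    settlement_points = []
    si = POLYGON_CLASSES.index("settlement")
    for p in np.flatnonzero((label == si) & occupied):
        cells = patch_of_cell == p
        settlement_points.append(Point(float(X[cells].mean()), float(Y[cells].mean())))

    return LandCoverMap(
        extent=spec.extent,
        polygons=polygons,
        river=river,
        settlement_points=settlement_points,
        class_grid=class_grid,
        cell_size=spec.cell_size,
    )


# ---------------------------------------------------------------------------
# movement


def _bounded_step(
    pos: np.ndarray, heading: float, length: float,
    xmin: float, ymin: float, xmax: float, ymax: float,
) -> tuple[float, float]:
    """Endpoint of a step reflected at the extent edge.

    The heading component pointing out of the extent is mirrored and the
    full step length re-applied, so step lengths are preserved exactly
    (folding the endpoint instead would shorten boundary steps and bias the
    recovered step-length distributions).
    """
    dx, dy = math.sin(heading), math.cos(heading)
    for _ in range(4):
        ex, ey = pos[0] + length * dx, pos[1] + length * dy
        if xmin <= ex <= xmax and ymin <= ey <= ymax:
            return ex, ey
        if ex < xmin or ex > xmax:
            dx = -dx
        if ey < ymin or ey > ymax:
            dy = -dy
    # step longer than the extent itself: clamp as a last resort
    return min(max(ex, xmin), xmax), min(max(ey, ymin), ymax)


def generate_track(lc: LandCoverMap, spec: MovementSpec) -> Trajectory:
    """Simulate a habitat-biased correlated random walk over a landscape.

    Step lengths are gamma-distributed with the mean of the habitat class at
    the current position (CV fixed); headings follow a von Mises correlated
    walk, blended toward the nearest river point with weight
    ``river_attraction``.  With ``habitat_preference`` set, each step draws
    ``n_candidates`` candidate headings and picks one with probability
    proportional to the preference weight of the destination's habitat class
    — a resource-selection walk that concentrates space use in preferred
    classes.  Tracks reflect off the extent boundary, keeping ``n_fixes``
    constant.  Fixes are exactly ``fix_interval_min`` apart.
    """
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = lc.extent
    if spec.start is None:
        start = lc.river.interpolate(0.5, normalized=True)
        pos = np.array([start.x, start.y])
    else:
        pos = np.array(spec.start, dtype=float)
        if not (xmin <= pos[0] <= xmax and ymin <= pos[1] <= ymax):
            raise ValueError("start point outside landscape extent")
    cv2 = spec.step_cv**2
    shape_k = 1.0 / cv2
    heading = rng.uniform(0.0, 2.0 * math.pi)
    fallback_mean = float(np.mean(list(spec.step_means.values())))
    xy = np.empty((spec.n_fixes, 2))
    xy[0] = pos
    def blend_to_river(h: float) -> float:
        if spec.river_attraction <= 0.0:
            return h
        near = nearest_points(Point(pos), lc.river)[1]
        to_river = math.atan2(near.x - pos[0], near.y - pos[1])
        w = spec.river_attraction
        vx = (1 - w) * math.sin(h) + w * math.sin(to_river)
        vy = (1 - w) * math.cos(h) + w * math.cos(to_river)
        return math.atan2(vx, vy) if (vx, vy) != (0.0, 0.0) else h

    pref = spec.habitat_preference
    for t in range(1, spec.n_fixes):
        cls = lc.class_at(pos[0], pos[1])
        mean = spec.step_means.get(cls, fallback_mean) if cls else fallback_mean
        length = rng.gamma(shape_k, mean * cv2)
        n_cand = spec.n_candidates if pref else 1
        turns = (
            rng.vonmises(0.0, spec.kappa, n_cand)
            if spec.kappa > 0
            else rng.uniform(-math.pi, math.pi, n_cand)
        )
        cands = []
        for turn in turns:
            h = blend_to_river(heading + turn)
            cands.append(_bounded_step(pos, h, length, xmin, ymin, xmax, ymax))
        if pref:
            weights = np.array(
                [max(pref.get(lc.class_at(cx, cy) or "", 1.0), 1e-9) for cx, cy in cands]
            )
            pick = rng.choice(n_cand, p=weights / weights.sum())
        else:
            pick = 0
        nx_r, ny_r = cands[pick]
        heading = math.atan2(nx_r - pos[0], ny_r - pos[1])
        pos = np.array([nx_r, ny_r])
        xy[t] = pos
    times = pd.date_range(
        spec.start_time, periods=spec.n_fixes, freq=pd.Timedelta(minutes=spec.fix_interval_min)
    )
    df = pd.DataFrame({"bird_id": f"sim{spec.seed}", "timestamp": times,
                       "x": xy[:, 0], "y": xy[:, 1]})
    return build_trajectory(df)


# ---------------------------------------------------------------------------
# bearings


def generate_bearings(
    track: Trajectory,
    observer_a: tuple[float, float],
    observer_b: tuple[float, float],
    noise_sd_deg: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit one simultaneous bearing pair per fix of a track.

    Azimuths are the true observer-to-bird azimuths plus Gaussian noise in
    degrees, wrapped to [0, 360).  Returns the paired-bearings table schema
    consumed by :func:`riparia.telemetry.triangulate_bearing_table`.
    """
    ax, ay = observer_a
    bx, by = observer_b
    if (ax, ay) == (bx, by):
        raise ValueError("observers must not be co-located")
    rng = np.random.default_rng(seed)
    x, y = track.xy[:, 0], track.xy[:, 1]
    az_a = np.degrees(np.arctan2(x - ax, y - ay)) % 360.0
    az_b = np.degrees(np.arctan2(x - bx, y - by)) % 360.0
    if noise_sd_deg > 0:
        az_a = (az_a + rng.normal(0.0, noise_sd_deg, len(x))) % 360.0
        az_b = (az_b + rng.normal(0.0, noise_sd_deg, len(x))) % 360.0
    return pd.DataFrame(
        {
            "bird_id": track.bird_id,
            "timestamp": track.times,
            "obs_a_x": ax,
            "obs_a_y": ay,
            "obs_a_az": az_a,
            "obs_b_x": bx,
            "obs_b_y": by,
            "obs_b_az": az_b,
        }
    )


# ---------------------------------------------------------------------------
# bundled suitability scenario

#: River-buffer composition for the suitability scenario: thicket ~12% of
#: the corridor landscape (the buffer-scale share, unlike the ~30% of the
#: small detailed-mapping area), plus crops and scattered settlements.
SDM_CLASS_MIX: dict[str, float] = {
    "indigenous": 0.01,
    "mixed": 0.03,
    "lantana": 0.08,
    "crops_low": 0.10,
    "settlement": 0.04,
}

#: Relative habitat-selection weights of a thicket specialist: strong
#: preference for L. camara, weak tolerance of other thicket, avoidance of
#: open crops and settlements.
SDM_PREFERENCE: dict[str, float] = {
    "lantana": 1.0,
    "mixed": 0.1,
    "indigenous": 0.1,
    "crops_low": 0.05,
    "crops_high": 0.02,
    "settlement": 0.01,
}


def sdm_scenario(
    seed: int = 0,
    n_birds: int = 4,
    n_fixes: int = 400,
    noise_sd: float = 0.02,
) -> tuple[LandCoverMap, RasterStack, list[Trajectory]]:
    """Seeded scenario for the habitat-suitability chain.

    A 2 x 2 km river-corridor landscape with the buffer-scale thicket share,
    a spectrally distinct lantana signature, and ``n_birds`` thicket
    specialists whose walks select lantana near the river.  Returns the
    land-cover map, the reflectance stack and the tracks; the pooled fixes
    are the presence records for the masked suitability models.
    """
    lc = generate_landscape(LandscapeSpec(seed=seed, class_mix=dict(SDM_CLASS_MIX)))
    stack = generate_raster(lc, SpectralSpec(seed=seed + 1, noise_sd=noise_sd))
    tracks = [
        generate_track(
            lc,
            MovementSpec(
                n_fixes=n_fixes,
                river_attraction=0.05,
                habitat_preference=dict(SDM_PREFERENCE),
                n_candidates=12,
                seed=seed * 100 + i,
            ),
        )
        for i in range(n_birds)
    ]
    return lc, stack, tracks


# ---------------------------------------------------------------------------
# imagery


def generate_raster(lc: LandCoverMap, spec: SpectralSpec) -> RasterStack:
    """Render a 5-band reflectance raster from the class grid.

    Each cell draws ``Normal(class mean, noise_sd)`` per band, truncated to
    [0, 1].  Requires a landscape generated by :func:`generate_landscape`
    (i.e. one that carries its class grid).
    """
    if lc.class_grid is None or lc.cell_size is None:
        raise ValueError("land-cover map carries no class grid; generate it synthetically")
    rng = np.random.default_rng(spec.seed)
    grid = lc.class_grid
    bands: dict[str, np.ndarray] = {}
    means = np.zeros((len(POLYGON_CLASSES), len(SPECTRAL_BANDS)))
    for ci, cls in enumerate(POLYGON_CLASSES):
        means[ci] = spec.class_means.get(cls, (0.5,) * len(SPECTRAL_BANDS))
    for bi, band in enumerate(SPECTRAL_BANDS):
        base = means[grid, bi]
        if spec.noise_sd > 0:
            base = base + rng.normal(0.0, spec.noise_sd, grid.shape)
        bands[band] = np.clip(base, 0.0, 1.0)
    xmin, ymin, _, _ = lc.extent
    return RasterStack(xmin, ymin, lc.cell_size, bands)
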