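"""File formats, configuration and the end-to-end pipeline driver.

Vector data travel as GeoJSON FeatureCollections (each feature carrying a
``class`` property from the land-cover schema and a top-level ``crs`` name),
rasters as multi-band TIFF with the grid geometry in a JSON description tag,
tables as CSV with ISO-8601 timestamps.  All coordinates are planar metres
in a user-declared projected CRS; geographic inputs must be projected before
they reach this package.

:func:`run_pipeline` chains the stages — simulate (optional), triangulate,
filter, home ranges, habitat preference, movement, site fidelity, vegetation
indices, habitat suitability — and writes a manifest recording every
artifact with the parameters and seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import linemerge, unary_union

from . import fidelity as fid
from . import habitat as hab
from . import home_range as hr
from . import remote_sensing as rs
from . import suitability as suit
from . import synthetic as syn
from . import telemetry as tel
from .landcover import ALL_CLASSES, POLYGON_CLASSES, LandCoverMap, ensure_multipolygon

log = logging.getLogger("riparia")

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE = 0, 2, 3

STAGES = (
    "simulate",
    "triangulate",
    "homerange",
    "preference",
    "movement",
    "fidelity",
    "indices",
    "suitability",
)


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = EXIT_STAGE):
        super().__init__(message)
        self.exit_code = exit_code


# ---------------------------------------------------------------------------
# vector I/O


def write_landcover(lc: LandCoverMap, path: str | Path, crs: str = "local-metric") -> None:
    """Write a land-cover map as one GeoJSON FeatureCollection."""
    features = []
    for cls, geom in lc.polygons.items():
        features.append({"type": "Feature", "properties": {"class": cls},
                         "geometry": mapping(geom)})
    features.append({"type": "Feature", "properties": {"class": "river"},
                     "geometry": mapping(lc.river)})
    for r in lc.roads:
        features.append({"type": "Feature", "properties": {"class": "road"},
                         "geometry": mapping(r)})
    for p in lc.settlement_points:
        features.append({"type": "Feature", "properties": {"class": "settlement"},
                         "geometry": mapping(p)})
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "bbox": list(lc.extent[:2]) + list(lc.extent[2:]),
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_landcover(path: str | Path) -> LandCoverMap:
    """Read and validate a land-cover GeoJSON.

    Every feature must carry a ``class`` property from the schema; invalid
    polygons are repaired (make-valid) with a logged count; unknown classes
    or a missing CRS declaration raise descriptive errors.
    """
    doc = json.loads(Path(path).read_text())
    if "crs" not in doc:
        raise PipelineError(
            f"{path}: no 'crs' member; declare the projected metric CRS of the file",
            EXIT_VALIDATION,
        )
    polys: dict[str, list] = {}
    rivers: list[LineString] = []
    roads: list[LineString] = []
    settlement_pts: list[Point] = []
    repaired = 0
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        cls = props.get("class")
        if cls is None:
            raise PipelineError(f"{path}: feature {i} has no 'class' property", EXIT_VALIDATION)
        if cls not in ALL_CLASSES:
            raise PipelineError(f"{path}: feature {i} has unknown class {cls!r}", EXIT_VALIDATION)
        geom = shape(feat["geometry"])
        if geom.geom_type in ("Polygon", "MultiPolygon"):
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
                repaired += 1
            polys.setdefault(cls, []).append(geom)
        elif geom.geom_type in ("LineString", "MultiLineString"):
            lines = [geom] if geom.geom_type == "LineString" else list(geom.geoms)
            (rivers if cls == "river" else roads).extend(lines)
        elif geom.geom_type == "Point":
            settlement_pts.append(geom)
    if repaired:
        log.warning("%s: repaired %d invalid polygon(s)", path, repaired)
    if not rivers:
        raise PipelineError(f"{path}: no river feature", EXIT_VALIDATION)
    river = linemerge(unary_union(rivers)) if len(rivers) > 1 else rivers[0]
    if river.geom_type != "LineString":
        river = max(river.geoms, key=lambda g: g.length)
    polygons = {cls: ensure_multipolygon(unary_union(gs)) for cls, gs in polys.items()}
    geoms = list(polygons.values()) + [river]
    xmin = min(g.bounds[0] for g in geoms)
    ymin = min(g.bounds[1] for g in geoms)
    xmax = max(g.bounds[2] for g in geoms)
    ymax = max(g.bounds[3] for g in geoms)
    return LandCoverMap((xmin, ymin, xmax, ymax), polygons, river, settlement_pts, roads)


def write_homerange_geojson(estimates, path: str | Path, crs: str = "local-metric") -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"bird_id": e.bird_id, "estimator": e.estimator,
                           "area_ha": e.area_ha, "parameter": e.parameter},
            "geometry": mapping(e.polygon),
        }
        for e in estimates
        if e.polygon is not None
    ]
    doc = {"type": "FeatureCollection",
           "crs": {"type": "name", "properties": {"name": crs}}, "features": features}
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# raster I/O (multi-band TIFF; grid geometry in a JSON description tag)


def write_raster(stack: rs.RasterStack, path: str | Path) -> None:
    names = list(stack.bands)
    data = np.stack([stack.bands[n] for n in names]).astype(np.float32)
    data[:, ~stack.valid] = np.nan
    meta = {"x0": stack.x0, "y0": stack.y0, "cell_size": stack.cell_size,
            "bands": names, "crs": stack.crs or "local-metric"}
    tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps(meta))


def read_raster(path: str | Path) -> rs.RasterStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    bands = {n: data[i].astype(float) for i, n in enumerate(meta["bands"])}
    valid = np.all([np.isfinite(b) for b in bands.values()], axis=0)
    return rs.RasterStack(meta["x0"], meta["y0"], meta["cell_size"], bands, valid, meta.get("crs"))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BirdConfig:
    bird_id: str
    species: str
    movement: dict = field(default_factory=dict)
    observers: list | None = None  # [[ax, ay], [bx, by]]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serializable to/from JSON."""

    output_dir: str = "riparia_out"
    crs: str = "local-metric"
    seed: int = 0
    # inputs: either synthetic simulation or file paths
    simulate: bool = True
    landscape: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    birds: list = field(default_factory=list)  # list of BirdConfig/dicts
    bearings_csv: str | None = None
    fixes_csv: str | None = None
    landcover_geojson: str | None = None
    raster_tif: str | None = None
    # stage parameters
    max_observer_dist: float = 1000.0
    retention: float = 0.95
    kernel_cell_size: float = 5.0
    h_override: float | None = None
    max_gap_min: float = 10.0
    buffer_m: float | None = None
    n_sims: int = 1000
    rwm_cell_size: float = 20.0
    reg: float = 1.0
    percentile: float = 10.0
    n_random: int = 200
    n_replicates: int = 10
    bearing_noise_sd_deg: float = 2.0
    skip: list = field(default_factory=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}", EXIT_VALIDATION)
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def bird_configs(self) -> list[BirdConfig]:
        return [b if isinstance(b, BirdConfig) else BirdConfig(**b) for b in self.birds]


def _validate(cfg: PipelineConfig) -> None:
    bad = set(cfg.skip) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stages in skip: {sorted(bad)}", EXIT_VALIDATION)
    if not cfg.simulate:
        if (cfg.bearings_csv is None) == (cfg.fixes_csv is None):
            raise PipelineError(
                "exactly one of bearings_csv / fixes_csv must be supplied", EXIT_VALIDATION
            )
        for p, stage in [(cfg.landcover_geojson, "preference"), (cfg.raster_tif, "indices")]:
            if stage not in cfg.skip and p is None:
                raise PipelineError(f"stage {stage!r} enabled but its input is missing",
                                    EXIT_VALIDATION)
        for p in (cfg.bearings_csv, cfg.fixes_csv, cfg.landcover_geojson, cfg.raster_tif):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}", EXIT_VALIDATION)
    if ("suitability" not in cfg.skip) and (not cfg.simulate) and cfg.raster_tif is None:
        raise PipelineError("suitability stage needs a raster", EXIT_VALIDATION)
    if not isinstance(cfg.seed, int):
        raise PipelineError("seed must be an integer", EXIT_VALIDATION)


# ---------------------------------------------------------------------------
# pipeline


def _default_birds(seed: int) -> list[BirdConfig]:
    """The bundled synthetic cohort: 4 species, thicket-loving birds."""
    birds = []
    species = ["tephronotus", "rubiginosus", "insularis", "hindei"]
    for i, sp in enumerate(species):
        birds.append(
            BirdConfig(
                bird_id=f"{sp[:2].upper()}{i + 1}",
                species=sp,
                movement={"n_fixes": 300, "river_attraction": 0.35,
                          "seed": seed * 1000 + i},
            )
        )
    return birds


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Every artifact is re-derivable from the config and seed alone.  A stage
    failure raises :class:`PipelineError`; the partial manifest is still
    written to ``output_dir/manifest.json``.
    """
    _validate(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": cfg.seed, "artifacts": {}, "stages_run": []}

    def record(name: str, path: Path, **params) -> None:
        manifest["artifacts"][name] = {"path": str(path), **params}

    def done(stage: str) -> None:
        manifest["stages_run"].append(stage)

    try:
        lc = None
        stack = None
        trajs: dict[str, tel.Trajectory] = {}
        species_of: dict[str, str] = {}
        fixes_df = None

        if cfg.simulate and "simulate" not in cfg.skip:
            lspec = syn.LandscapeSpec(**{"seed": cfg.seed, **cfg.landscape})
            lc = syn.generate_landscape(lspec)
            sspec = syn.SpectralSpec(**{"seed": cfg.seed + 1, **cfg.spectral})
            stack = syn.generate_raster(lc, sspec)
            write_landcover(lc, out / "landcover.geojson", cfg.crs)
            record("landcover", out / "landcover.geojson", seed=cfg.seed)
            write_raster(stack, out / "reflectance.tif")
            record("reflectance", out / "reflectance.tif", seed=cfg.seed + 1)
            birds = cfg.bird_configs() or _default_birds(cfg.seed)
            bearing_frames = []
            xmin, ymin, xmax, ymax = lc.extent
            for b in birds:
                mspec = syn.MovementSpec(**b.movement)
                tr = syn.generate_track(lc, mspec)
                tr.bird_id = b.bird_id
                obs = b.observers or [
                    [0.45 * (xmin + xmax), 0.5 * (ymin + ymax)],
                    [0.55 * (xmin + xmax), 0.5 * (ymin + ymax)],
                ]
                bf = syn.generate_bearings(tr, tuple(obs[0]), tuple(obs[1]),
                                           cfg.bearing_noise_sd_deg, seed=mspec.seed + 7)
                bf["bird_id"] = b.bird_id
                bearing_frames.append(bf)
                species_of[b.bird_id] = b.species
            bearings = pd.concat(bearing_frames, ignore_index=True)
            bearings.to_csv(out / "bearings.csv", index=False)
            record("bearings", out / "bearings.csv", noise_sd_deg=cfg.bearing_noise_sd_deg)
            done("simulate")
        else:
            if cfg.landcover_geojson:
                lc = read_landcover(cfg.landcover_geojson)
            if cfg.raster_tif:
                stack = read_raster(cfg.raster_tif)
            bearings = pd.read_csv(cfg.bearings_csv) if cfg.bearings_csv else None
            if cfg.fixes_csv:
                fixes_df = pd.read_csv(cfg.fixes_csv, parse_dates=["timestamp"])
            for b in cfg.bird_configs():
                species_of[b.bird_id] = b.species

        if "triangulate" not in cfg.skip and bearings is not None:
            rows = []
            removed_total = 0
            for bird, grp in bearings.groupby("bird_id"):
                fixes = tel.triangulate_bearing_table(grp, str(bird))
                kept, removed = tel.filter_fixes(fixes, cfg.max_observer_dist)
                removed_total += removed
                rows.extend(
                    {"bird_id": f.bird_id, "timestamp": f.timestamp, "x": f.x, "y": f.y,
                     "dist_a": f.dist_a, "dist_b": f.dist_b, "valid": f.valid}
                    for f in kept
                )
            fixes_df = pd.DataFrame(rows)
            fixes_df.to_csv(out / "fixes.csv", index=False)
            record("fixes", out / "fixes.csv",
                   max_observer_dist=cfg.max_observer_dist, removed=removed_total)
            done("triangulate")

        if fixes_df is None or fixes_df.empty:
            raise PipelineError("no fixes available after triangulation/filtering")
        for bird, grp in fixes_df.groupby("bird_id"):
            trajs[str(bird)] = tel.build_trajectory(grp, str(bird))

        uds: dict[str, hr.UtilizationDistribution] = {}
        k75: dict[str, hr.HomeRangeEstimate] = {}
        if "homerange" not in cfg.skip:
            est_rows, estimates = [], []
            for bird, tr in trajs.items():
                m = hr.mcp(tr, cfg.retention)
                h = cfg.h_override or hr.href_bandwidth(tr)
                ud = hr.kernel_ud(tr, h=h, cell_size=cfg.kernel_cell_size)
                uds[bird] = ud
                for level in (0.95, 0.75, 0.50):
                    e = hr.ud_contour(ud, level)
                    if level == 0.75:
                        k75[bird] = e
                    estimates.append(e)
                    est_rows.append({"bird_id": bird, "estimator": e.estimator,
                                     "area_ha": round(e.area_ha, 2), "h": round(h, 2)})
                estimates.append(m)
                est_rows.append({"bird_id": bird, "estimator": m.estimator,
                                 "area_ha": round(m.area_ha, 2), "h": np.nan})
            pd.DataFrame(est_rows).to_csv(out / "homeranges.csv", index=False)
            record("homeranges", out / "homeranges.csv",
                   retention=cfg.retention, cell_size=cfg.kernel_cell_size)
            write_homerange_geojson(estimates, out / "homeranges.geojson", cfg.crs)
            record("homerange_polygons", out / "homeranges.geojson")
            done("homerange")

        if "preference" not in cfg.skip and lc is not None and k75:
            avail, _ = hab.habitat_fractions(shapely.box(*lc.extent), lc)
            used = {}
            for bird, est in k75.items():
                fr, _ = hab.habitat_fractions(est.polygon, lc)
                used[bird] = fr
            jt = hab.jacobs_table(used, avail)
            jt.to_csv(out / "jacobs.csv", index=False)
            record("jacobs", out / "jacobs.csv")
            tests = []
            for cls, grp in jt.groupby("class"):
                vals = grp["D"].dropna()
                try:
                    s, p = hab.sign_test(vals.tolist())
                except ValueError:
                    s, p = np.nan, np.nan
                tests.append({"class": cls, "mean_D": vals.mean(), "s": s, "p": p})
            pd.DataFrame(tests).to_csv(out / "jacobs_tests.csv", index=False)
            record("jacobs_tests", out / "jacobs_tests.csv")
            comp = hab.landscape_composition(lc, cfg.buffer_m)
            comp.to_csv(out / "composition.csv", index=False)
            record("composition", out / "composition.csv", buffer_m=cfg.buffer_m)
            done("preference")

        if "movement" not in cfg.skip and lc is not None:
            frames = [hab.movement_by_habitat(tr, lc, cfg.max_gap_min)
                      for tr in trajs.values()]
            mv = pd.concat(frames, ignore_index=True)
            mv.to_csv(out / "movement.csv", index=False)
            record("movement", out / "movement.csv", max_gap_min=cfg.max_gap_min)
            hab.movement_summary(mv).to_csv(out / "movement_summary.csv", index=False)
            record("movement_summary", out / "movement_summary.csv")
            if species_of and "homerange" not in cfg.skip:
                areas = pd.read_csv(out / "homeranges.csv")
                areas["species"] = areas["bird_id"].map(species_of)
                lines = []
                for est, grp in areas.groupby("estimator"):
                    groups = [g["area_ha"].to_numpy()
                              for _, g in grp.groupby("species") if len(g) >= 2]
                    if len(groups) >= 2:
                        f, d1, d2, p = hab.one_way_anova(groups, transform="auto")
                        lines.append(f"{est}: F({d1},{d2}) = {f:.2f}, p = {p:.3f}")
                (out / "anova.txt").write_text("\n".join(lines) + "\n")
                record("anova", out / "anova.txt")
            done("movement")

        if "fidelity" not in cfg.skip:
            results = []
            for bi, (bird, tr) in enumerate(sorted(trajs.items())):
                res = fid.rwm_simulate(tr, n_sims=cfg.n_sims, seed=cfg.seed + 101 * bi,
                                       cell_size=cfg.rwm_cell_size)
                results.extend(res.values())
            rep = fid.rwm_report(results)
            rep.to_csv(out / "rwm.csv", index=False)
            record("rwm", out / "rwm.csv", n_sims=cfg.n_sims,
                   fidelity_fraction=rep.attrs["fidelity_fraction"])
            done("fidelity")

        index_stack = None
        if "indices" not in cfg.skip and stack is not None:
            index_stack = rs.vegetation_indices(stack)
            write_raster(index_stack, out / "indices.tif")
            record("indices", out / "indices.tif")
            done("indices")

        if "suitability" not in cfg.skip:
            if stack is None or lc is None:
                raise PipelineError("suitability stage needs a raster and a land-cover map")
            if index_stack is None:
                index_stack = rs.vegetation_indices(stack)
            grid = index_stack
            d_river = rs.distance_raster(lc, "river", grid)
            d_mixed = rs.distance_raster(lc, "mixed", grid) if "mixed" in lc.polygons else None
            d_settle = rs.distance_raster(lc, "settlement", grid)
            pooled = np.vstack([tr.xy for tr in trajs.values()])
            chain = suit.build_mask(pooled, d_river, reg=cfg.reg,
                                    percentile=cfg.percentile, seed=cfg.seed + 11)
            lant_raster, lant_model = suit.lantana_model(
                lc, index_stack, n_random=cfg.n_random, reg=cfg.reg, seed=cfg.seed + 13
            )
            bands = dict(index_stack.bands)
            bands["lantana_prob"] = lant_raster
            bands["dist_settlement"] = next(iter(d_settle.bands.values()))
            if d_mixed is not None:
                bands["dist_mixed"] = next(iter(d_mixed.bands.values()))
            pred_stack = rs.RasterStack(grid.x0, grid.y0, grid.cell_size, bands,
                                        grid.valid, grid.crs)
            predictor_bands = list(rs.INDEX_NAMES) + ["lantana_prob", "dist_settlement"]
            if d_mixed is not None:
                predictor_bands.append("dist_mixed")
            rows = [{"model": "lantana", "train_auc": np.nan, "test_auc": np.nan,
                     "threshold": np.nan,
                     **lant_model.contributions().round(1).to_dict()}]
            by_species: dict[str, list[str]] = {}
            for bird, sp in species_of.items():
                by_species.setdefault(sp, []).append(bird)
            if not by_species:
                by_species = {"pooled": list(trajs)}
            for sp, bird_ids in by_species.items():
                xy = np.vstack([trajs[b].xy for b in bird_ids if b in trajs])
                model = suit.fit_species_model(
                    xy, chain, pred_stack, predictor_bands, species=sp, reg=cfg.reg,
                    n_replicates=cfg.n_replicates, percentile=cfg.percentile,
                    seed=cfg.seed + 17,
                )
                pred = rs.RasterStack(grid.x0, grid.y0, grid.cell_size,
                                      {"suitability": model.mean_prediction},
                                      np.isfinite(model.mean_prediction), grid.crs)
                write_raster(pred, out / f"suitability_{sp}.tif")
                record(f"suitability_{sp}", out / f"suitability_{sp}.tif",
                       seed=cfg.seed + 17)
                rows.append({"model": sp, "train_auc": round(model.mean_train_auc, 3),
                             "test_auc": round(model.mean_test_auc, 3),
                             "threshold": round(model.threshold, 3),
                             **model.contributions.round(1).to_dict()})
            pd.DataFrame(rows).to_csv(out / "suitability_summary.csv", index=False)
            record("suitability_summary", out / "suitability_summary.csv",
                   reg=cfg.reg, n_replicates=cfg.n_replicates)
            done("suitability")

        return manifest
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
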