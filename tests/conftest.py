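"""Shared fixtures: small synthetic landscapes, rasters and tracks.

Everything is generated at test time from fixed seeds; heavier artifacts are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import riparia as rp
from riparia.telemetry import build_trajectory

#: Per-individual home-range areas (ha) and fix counts of the 14-bird
#: telemetry cohort (four species), used as worked-example inputs.
COHORT = {
    "species": ["tephronotus"] * 6 + ["rubiginosus"] * 2 + ["insularis"] * 3 + ["hindei"] * 3,
    "n_fixes": [298, 225, 211, 202, 628, 561, 527, 346, 289, 211, 147, 819, 623, 501],
    "mcp95": [37.87, 33.90, 35.05, 18.07, 54.94, 75.88, 57.74, 63.02,
              50.58, 16.39, 58.57, 92.57, 68.39, 75.60],
    "k95": [52.05, 48.62, 70.06, 29.45, 53.53, 71.55, 65.26, 71.79,
            61.38, 31.29, 89.64, 77.58, 70.68, 72.72],
    "k75": [10.63, 10.08, 21.09, 6.50, 12.56, 16.16, 11.35, 19.33,
            12.92, 8.28, 37.01, 15.32, 15.81, 12.77],
    "k50": [3.92, 4.74, 7.53, 2.60, 5.29, 6.15, 3.78, 7.59,
            4.85, 3.22, 15.63, 5.75, 5.58, 3.93],
}


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    return pd.DataFrame(COHORT)


@pytest.fixture(scope="session")
def landscape() -> rp.LandCoverMap:
    """Default-composition 2 x 2 km landscape, seed 1."""
    return rp.generate_landscape(rp.LandscapeSpec(seed=1))


@pytest.fixture(scope="session")
def raster(landscape) -> rp.RasterStack:
    return rp.generate_raster(landscape, rp.SpectralSpec(seed=2))


@pytest.fixture(scope="session")
def track(landscape) -> rp.Trajectory:
    return rp.generate_track(
        landscape, rp.MovementSpec(n_fixes=500, river_attraction=0.3, seed=3)
    )


@pytest.fixture(scope="session")
def sdm(request):
    """The chained suitability scenario (landscape, raster, tracks, fit)."""
    lc, stack, tracks = rp.sdm_scenario(seed=1)
    pooled = np.vstack([t.xy for t in tracks])
    result = rp.chained_suitability(lc, stack, pooled, species="thicket_specialist", seed=1)
    return {"lc": lc, "stack": stack, "tracks": tracks, "pooled": pooled, **result}


def make_crw(seed: int, n_steps: int = 100, mean_step: float = 150.0,
             kappa: float = 1.0) -> rp.Trajectory:
    """Unconstrained correlated random walk with gamma steps."""
    r = np.random.default_rng(seed)
    L = r.gamma(2.0, mean_step / 2.0, n_steps)
    T = np.degrees(r.vonmises(0.0, kappa, n_steps - 1))
    h0 = r.uniform(0, 360)
    h = h0 + np.concatenate([[0.0], np.cumsum(T)])
    xy = np.zeros((n_steps + 1, 2))
    xy[1:, 0] = np.cumsum(L * np.sin(np.deg2rad(h)))
    xy[1:, 1] = np.cumsum(L * np.cos(np.deg2rad(h)))
    t = pd.date_range("2015-01-01", periods=n_steps + 1, freq="10min")
    return build_trajectory(
        pd.DataFrame({"bird_id": f"crw{seed}", "timestamp": t, "x": xy[:, 0], "y": xy[:, 1]})
    )


def make_confined(seed: int, n_steps: int = 120, mean_step: float = 150.0,
                  radius_pull: float = 0.9) -> rp.Trajectory:
    """Site-faithful track: substantial steps but headings pulled to a centre."""
    r = np.random.default_rng(seed)
    pos = np.zeros(2)
    xy = [pos.copy()]
    heading = r.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        L = r.gamma(2.0, mean_step / 2.0)
        to_centre = np.arctan2(-pos[0], -pos[1])
        turn = r.vonmises(0.0, 1.0)
        free = heading + turn
        vx = (1 - radius_pull) * np.sin(free) + radius_pull * np.sin(to_centre)
        vy = (1 - radius_pull) * np.cos(free) + radius_pull * np.cos(to_centre)
        heading = np.arctan2(vx, vy)
        pos = pos + L * np.array([np.sin(heading), np.cos(heading)])
        xy.append(pos.copy())
    xy = np.asarray(xy)
    t = pd.date_range("2015-01-01", periods=n_steps + 1, freq="10min")
    return build_trajectory(
        pd.DataFrame({"bird_id": f"conf{seed}", "timestamp": t, "x": xy[:, 0], "y": xy[:, 1]})
    )
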