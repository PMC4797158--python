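"""Habitat preference, per-habitat movement, and landscape composition.

Preference is quantified with the Jacobs selectivity index

    D = (r - p) / (r + p - 2 r p),

where ``r`` is the proportion of a habitat used (core-area K75 intersected
with the land-cover map) and ``p`` the proportion available in the study
area; D runs from -1 (total avoidance) through 0 (no interaction) to +1
(absolute preference).  Cohort-level preference per habitat is tested with
the exact sign test against a median of zero.

Movement behaviour is summarized as step distances normalized to
m per 10 min, attributed to the habitat class of the step's start fix by
point-in-polygon lookup; habitats with fewer than ~50 samples are flagged.
Between-species differences in home-range size use a one-way ANOVA with an
optional log(x+1) transform when a Shapiro-Wilk test rejects residual
normality.  The richer mixed-effects analyses are left to external
statistics packages: this module emits the tidy long table they need.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .landcover import POLYGON_CLASSES, LandCoverMap
from .telemetry import Trajectory

__all__ = [
    "habitat_fractions",
    "jacobs_index",
    "sign_test",
    "movement_by_habitat",
    "movement_summary",
    "one_way_anova",
    "landscape_composition",
    "composition_percentages",
    "jacobs_table",
]

#: Minimum per-habitat sample size for movement contrasts.
MIN_MOVEMENT_SAMPLES = 50


def habitat_fractions(
    region: BaseGeometry, lc: LandCoverMap
) -> tuple[dict[str, float], float]:
    """Area fraction of each habitat class within a region.

    Returns ``(fractions, unmapped)`` where ``unmapped`` is the region share
    covered by no class polygon.  Region and map must share a metric CRS.
    """
    if region is None or region.is_empty or region.area <= 0:
        raise ValueError("region is empty")
    total = region.area
    fractions: dict[str, float] = {}
    for cls, geom in lc.polygons.items():
        if geom is None or geom.is_empty:
            continue
        inter = region.intersection(geom)
        if not inter.is_empty and inter.area > 0:
            fractions[cls] = inter.area / total
    return fractions, max(0.0, 1.0 - sum(fractions.values()))


def jacobs_index(r: float, p: float) -> float:
    """Jacobs selectivity index D = (r - p) / (r + p - 2 r p).

    ``r`` = proportion used, ``p`` = proportion available, both in [0, 1].
    Returns NaN for the undefined corners r = p = 0 and r = p = 1 (0/0).
    """
    if not (0.0 <= r <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("r and p must lie in [0, 1]")
    # boundary cases resolve exactly: the formula simplifies algebraically
    if r == p:
        return math.nan if r in (0.0, 1.0) else 0.0
    if r == 1.0 or p == 0.0:
        return 1.0
    if r == 0.0 or p == 1.0:
        return -1.0
    d = (r - p) / (r + p - 2.0 * r * p)
    return min(1.0, max(-1.0, d))


def sign_test(values: Sequence[float], mu: float = 0.0) -> tuple[int, float]:
    """Exact two-sided sign test against a hypothesized median.

    Values equal to ``mu`` are dropped (the standard exact convention).
    Returns ``(s, p)`` with ``s`` the count of values above ``mu`` and ``p``
    the exact binomial two-sided p-value at success probability 1/2.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    nonzero = arr[arr != mu]
    n = len(nonzero)
    if n == 0:
        raise ValueError("all values equal the hypothesized median; sign test undefined")
    s = int((nonzero > mu).sum())
    p = stats.binomtest(s, n, 0.5, alternative="two-sided").pvalue
    return s, float(p)


def movement_by_habitat(
    traj: Trajectory, lc: LandCoverMap, max_gap_min: float = 10.0
) -> pd.DataFrame:
    """Per-step movement distances attributed to the start fix's habitat.

    Steps with a time gap larger than ``max_gap_min`` are excluded so the
    m per 10 min unit stays exact; remaining distances are normalized by
    ``length * 10 / dt``.  Fixes outside all class polygons are labelled
    ``"unmapped"`` (excluded from per-class tests downstream).

    Returns columns ``bird_id, habitat, dist_per_10min``.
    """
    ok = traj.dt_min <= max_gap_min + 1e-9
    starts = traj.xy[:-1][ok]
    dist10 = traj.step_lengths[ok] * 10.0 / traj.dt_min[ok]
    classes = lc.classes_at(starts)
    return pd.DataFrame(
        {
            "bird_id": traj.bird_id,
            "habitat": [c if c is not None else "unmapped" for c in classes],
            "dist_per_10min": dist10,
        }
    )


def movement_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat n, mean, and standard error, with a low-sample flag."""
    g = samples[samples["habitat"] != "unmapped"].groupby("habitat")["dist_per_10min"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["low_n"] = out["n"] <= MIN_MOVEMENT_SAMPLES
    return out


def one_way_anova(
    groups: Sequence[Sequence[float]], transform: str = "none"
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA across groups of home-range areas.

    ``transform``: ``"none"``, ``"log1p"``, or ``"auto"`` which applies
    log(x+1) only when a Shapiro-Wilk test rejects normality of the
    group-centred residuals at alpha = 0.05.  Returns (F, df1, df2, p).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if transform == "auto":
        resid = np.concatenate([g - g.mean() for g in gs])
        transform = "log1p" if stats.shapiro(resid).pvalue < 0.05 else "none"
    if transform == "log1p":
        gs = [np.log1p(g) for g in gs]
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if all(np.ptp(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1:
        raise ValueError("zero variance everywhere; ANOVA undefined")
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = len(gs) - 1, n - len(gs)
    if ss_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def landscape_composition(
    lc: LandCoverMap, buffer_m: float | None = None
) -> pd.DataFrame:
    """Class areas (ha) and percentages of the assessed area.

    With ``buffer_m`` the assessment is clipped to a buffer around the river
    polyline (the field protocol's river corridor); otherwise every mapped
    polygon counts.  Percentages are of the summed mapped area, not the
    bounding extent, and sum to 100.
    """
    clip = lc.river.buffer(buffer_m) if buffer_m is not None else None
    rows = []
    for cls in POLYGON_CLASSES:
        geom = lc.polygons.get(cls)
        if geom is None or geom.is_empty:
            continue
        g = geom.intersection(clip) if clip is not None else geom
        if not g.is_empty and g.area > 0:
            rows.append({"class": cls, "ha": g.area / 1e4})
    tab = pd.DataFrame(rows)
    if tab.empty:
        return pd.DataFrame(columns=["class", "ha", "pct"])
    tab["pct"] = 100.0 * tab["ha"] / tab["ha"].sum()
    return tab


def composition_percentages(areas_ha: dict[str, float]) -> pd.DataFrame:
    """Percent composition from a table of absolute class areas (ha)."""
    total = sum(areas_ha.values())
    if total <= 0:
        raise ValueError("total area must be positive")
    return pd.DataFrame(
        [{"class": k, "ha": v, "pct": 100.0 * v / total} for k, v in areas_ha.items()]
    )


def jacobs_table(
    used_fractions: dict[str, dict[str, float]],
    available: dict[str, float],
) -> pd.DataFrame:
    """Per-bird, per-class Jacobs indices from used/available fractions.

    ``used_fractions`` maps bird_id -> {class: r}; ``available`` maps
    class -> p over the study area.  Classes missing from a bird's usage get
    r = 0 (available but unused).  Returns columns bird_id, class, r, p, D.
    """
    rows = []
    for bird, used in used_fractions.items():
        for cls, p in available.items():
            r = used.get(cls, 0.0)
            rows.append(
                {"bird_id": bird, "class": cls, "r": r, "p": p, "D": jacobs_index(r, p)}
            )
    return pd.DataFrame(rows)
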