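"""Presence-background habitat suitability in the maxent tradition.

The model is the Gibbs / maximum-entropy density over background cells,

    q_lambda(x) = exp(lambda . f(x)) / sum_bg exp(lambda . f(x')),

fitted by minimizing the L1-regularized negative log-likelihood of the
presence cells.  Features are linear, quadratic and pairwise-product terms
of background-standardized predictors.  Raw output sums to one over the
background; the logistic output applies the standard transform with default
prevalence 0.5 (``c r / (1 + c r)`` with ``c = exp(H)``, H the entropy of
the raw distribution).

The chained study design is reproduced:

1. :func:`build_mask` — a pre-model with distance-to-river as the single
   predictor, trained inside the MCP of the pooled fixes, binarized at the
   10-percentile training-omission threshold, becomes a spatial mask.
2. :func:`lantana_model` — a spectral sub-model of *Lantana camara* cover
   from the seven vegetation indices; its logistic probabilities become a
   predictor.
3. :func:`fit_species_model` — per-species models inside the mask using the
   vegetation indices, the lantana probability, and distances to mixed
   thicket and settlements, evaluated over 10 random 70/30 presence splits
   by ranked AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata
from shapely.geometry import MultiPoint

from .landcover import LandCoverMap
from .remote_sensing import INDEX_NAMES, RasterStack

__all__ = [
    "FeatureExpansion",
    "MaxentModel",
    "MaskChain",
    "SuitabilityModel",
    "fit_maxent",
    "evaluate_auc",
    "auc_from_scores",
    "omission_threshold",
    "build_mask",
    "lantana_model",
    "fit_species_model",
    "chained_suitability",
]

#: Hard cap on |lambda| guarding against separation.
LAMBDA_CAP = 50.0


class FeatureExpansion:
    """Linear + quadratic + pairwise-product features of standardized predictors.

    Standardization constants (mean, sd) come from the background sample and
    are applied identically to presences and background.  Predictors with
    zero background spread are dropped.
    """

    def __init__(self, predictor_names: list[str], linear=True, quadratic=True, product=True):
        self.input_names = list(predictor_names)
        self.linear, self.quadratic, self.product = linear, quadratic, product
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None
        self.names: list[str] = []
        self.feature_owners: list[dict[str, float]] = []  # predictor -> share

    def fit(self, background: np.ndarray) -> "FeatureExpansion":
        bg = np.asarray(background, dtype=float)
        self.mean_ = bg.mean(axis=0)
        self.sd_ = bg.std(axis=0)
        self.keep_ = self.sd_ > 0
        kept = [n for n, k in zip(self.input_names, self.keep_) if k]
        self.names, self.feature_owners = [], []
        if self.linear:
            for n in kept:
                self.names.append(n)
                self.feature_owners.append({n: 1.0})
        if self.quadratic:
            for n in kept:
                self.names.append(f"{n}^2")
                self.feature_owners.append({n: 1.0})
        if self.product:
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    self.names.append(f"{kept[i]}*{kept[j]}")
                    self.feature_owners.append({kept[i]: 0.5, kept[j]: 0.5})
        return self

    @property
    def kept_predictors(self) -> list[str]:
        return [n for n, k in zip(self.input_names, self.keep_) if k]

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("expansion not fitted")
        X = np.asarray(X, dtype=float)
        z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        parts = []
        if self.linear:
            parts.append(z)
        if self.quadratic:
            parts.append(z**2)
        if self.product:
            k = z.shape[1]
            prods = [z[:, i] * z[:, j] for i in range(k) for j in range(i + 1, k)]
            if prods:
                parts.append(np.column_stack(prods))
        return np.column_stack(parts) if parts else np.empty((len(X), 0))


@dataclass
class MaxentModel:
    """A fitted Gibbs density over a background sample."""

    expansion: FeatureExpansion
    lam: np.ndarray
    reg: float
    log_z: float  # log sum over background of exp(lambda . f)
    entropy: float  # entropy of the raw background distribution
    feature_gain: np.ndarray  # per-feature |gain| attribution
    capped: bool = False

    def linear_score(self, X: np.ndarray) -> np.ndarray:
        return self.expansion.transform(X) @ self.lam

    def raw(self, X: np.ndarray) -> np.ndarray:
        """exp(lambda.f)/Z; sums to one over the fitting background."""
        return np.exp(self.linear_score(X) - self.log_z)

    def logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic output at default prevalence 0.5: c r / (1 + c r), c=e^H."""
        cr = np.exp(self.linear_score(X) - self.log_z + self.entropy)
        return cr / (1.0 + cr)

    def contributions(self) -> pd.Series:
        """Percent contribution per predictor (sums to 100)."""
        share: dict[str, float] = {n: 0.0 for n in self.expansion.kept_predictors}
        for g, owners in zip(self.feature_gain, self.expansion.feature_owners):
            for pred, w in owners.items():
                share[pred] += w * g
        total = sum(share.values())
        if total <= 0:
            n = max(len(share), 1)
            return pd.Series({k: 100.0 / n for k in share})
        return pd.Series({k: 100.0 * v / total for k, v in share.items()})


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    predictor_names: list[str] | None = None,
    reg: float = 1.0,
    expansion: FeatureExpansion | None = None,
    seed: int = 0,
) -> MaxentModel:
    """Fit the L1-regularized Gibbs density of presences over background.

    Minimizes ``logsumexp_bg(lambda.f) - mean_pres(lambda.f)
    + sum_j reg_j |lambda_j|`` with ``reg_j = reg * sd_j / sqrt(n_pres)``
    (sd over background features), via an a-b split of lambda under
    L-BFGS-B with box bounds — penalized likelihood identical to the
    classical maxent formulation.  Unbounded coefficients (separation) are
    capped at +-50 with ``capped=True``.
    """
    P = np.atleast_2d(np.asarray(presence_X, dtype=float))
    B = np.atleast_2d(np.asarray(background_X, dtype=float))
    if len(P) < 1:
        raise ValueError("need at least one presence")
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(B.shape[1])]
    if not (np.isfinite(P).all() and np.isfinite(B).all()):
        raise ValueError("non-finite predictor values in training cells")
    if expansion is None:
        expansion = FeatureExpansion(predictor_names).fit(B)
    Fp = expansion.transform(P)
    Fb = expansion.transform(B)
    k = Fb.shape[1]
    if k == 0:  # all predictors constant: the entropy-maximal uniform model
        lam = np.zeros(0)
        log_z = float(np.log(len(B)))
        return MaxentModel(expansion, lam, reg, log_z, log_z, np.zeros(0))
    fbar_p = Fp.mean(axis=0)
    sd_b = Fb.std(axis=0)
    reg_j = reg * np.where(sd_b > 0, sd_b, 1.0) / np.sqrt(len(P))

    def objective(ab: np.ndarray):
        lam = ab[:k] - ab[k:]
        eta = Fb @ lam
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        grad_lam = w @ Fb - fbar_p
        val = lz - fbar_p @ lam + reg_j @ (ab[:k] + ab[k:])
        grad = np.concatenate([grad_lam + reg_j, -grad_lam + reg_j])
        return val, grad

    x0 = np.zeros(2 * k)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, LAMBDA_CAP)] * (2 * k),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    lam = res.x[:k] - res.x[k:]
    capped = bool(np.any(np.abs(lam) >= LAMBDA_CAP - 1e-6))
    eta_b = Fb @ lam
    log_z = float(logsumexp(eta_b))
    w = np.exp(eta_b - log_z)
    entropy = float(-(w * np.log(np.clip(w, 1e-300, None))).sum())
    fbar_b = w @ Fb
    gain = np.abs(lam * (fbar_p - fbar_b))
    return MaxentModel(expansion, lam, reg, log_z, entropy, gain, capped)


def auc_from_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC of presence vs background scores, ties counted 0.5."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if len(pos) < 1 or len(neg) < 1:
        raise ValueError("need at least one score on each side")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def evaluate_auc(model: MaxentModel, test_X: np.ndarray, background_X: np.ndarray) -> float:
    """AUC of model scores at test presences against a background sample."""
    return auc_from_scores(model.linear_score(np.atleast_2d(test_X)),
                           model.linear_score(np.atleast_2d(background_X)))


def omission_threshold(predictions: np.ndarray, percentile: float = 10.0) -> float:
    """Training-omission threshold: the largest value retaining >= (100-p)%.

    ``t`` is the prediction value such that at least ``100 - percentile``
    percent of the training-presence predictions are >= t; reclassification
    declares a cell present when its prediction >= t.
    """
    v = np.sort(np.asarray(predictions, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("no predictions")
    k = int(np.floor(n * percentile / 100.0))
    return float(v[min(k, n - 1)])


# ---------------------------------------------------------------------------
# chained study design


@dataclass
class MaskChain:
    """Distance-to-river pre-model reclassified into a training mask."""

    model: MaxentModel
    mask: np.ndarray  # bool, grid shape; True = inside training domain
    background_mcp: shapely.Geometry
    threshold: float
    grid: RasterStack


def _cells_of_points(stack: RasterStack, xy: np.ndarray) -> np.ndarray:
    """Deduplicated (row, col) cells containing the points."""
    i, j = stack.cell_index(xy[:, 0], xy[:, 1])
    return np.unique(np.column_stack([i, j]), axis=0)


def _band_matrix(stack: RasterStack, bands: list[str], rows, cols) -> np.ndarray:
    return np.column_stack([stack.band(b)[rows, cols] for b in bands])


def build_mask(
    pooled_xy: np.ndarray,
    river_distance: RasterStack,
    reg: float = 1.0,
    percentile: float = 10.0,
    seed: int = 0,
) -> MaskChain:
    """Pre-model mask: MCP background, distance-to-river single predictor.

    The background is every grid cell whose centre lies inside the 100% MCP
    of the pooled fixes of all birds; the fitted logistic surface is
    binarized at the training-omission threshold to form the mask used by
    the species models.
    """
    pooled_xy = np.asarray(pooled_xy, dtype=float)
    hull = MultiPoint(pooled_xy).convex_hull
    if hull.area <= 0:
        raise ValueError("pooled fixes are degenerate; MCP has no area")
    band = next(iter(river_distance.bands))
    X, Y = river_distance.cell_centers()
    inside = shapely.contains_xy(hull, X.ravel(), Y.ravel()).reshape(river_distance.shape)
    inside &= river_distance.valid
    rows, cols = np.nonzero(inside)
    if rows.size == 0:
        raise ValueError("no background cells inside the pooled MCP")
    Bg = _band_matrix(river_distance, [band], rows, cols)
    pres_cells = _cells_of_points(river_distance, pooled_xy)
    ok = inside[pres_cells[:, 0], pres_cells[:, 1]]
    pres_cells = pres_cells[ok]
    P = _band_matrix(river_distance, [band], pres_cells[:, 0], pres_cells[:, 1])
    model = fit_maxent(P, Bg, ["dist_river"], reg=reg, seed=seed)
    pred_pres = model.logistic(P)
    t = omission_threshold(pred_pres, percentile)
    mask = np.zeros(river_distance.shape, dtype=bool)
    mask[rows, cols] = model.logistic(Bg) >= t
    return MaskChain(model, mask, hull, t, river_distance)


def _sample_in_polygons(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a (multi)polygon by bbox rejection sampling."""
    xmin, ymin, xmax, ymax = geom.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 64)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        hit = shapely.contains_xy(geom, xs, ys)
        pts.extend(zip(xs[hit], ys[hit]))
    return np.asarray(pts[:n])


def lantana_model(
    lc: LandCoverMap,
    index_stack: RasterStack,
    n_random: int = 200,
    reg: float = 1.0,
    seed: int = 0,
    bands: tuple[str, ...] = INDEX_NAMES,
    background_size: int = 10000,
) -> tuple[np.ndarray, MaxentModel]:
    """Spectral sub-model of *L. camara* cover.

    Presences are ``n_random`` points sampled uniformly within the mapped
    lantana polygons; the background is a seeded sample of valid study-area
    cells; predictors are the vegetation-index bands.  Returns the logistic
    probability raster (grid shape, NaN where invalid) — used downstream as
    an environmental predictor — and the fitted model.
    """
    if n_random < 10:
        raise ValueError("need at least 10 random presence records")
    geom = lc.polygons.get("lantana")
    if geom is None or geom.is_empty:
        raise ValueError("no lantana polygons in the land-cover map")
    rng = np.random.default_rng(seed)
    pts = _sample_in_polygons(geom, n_random, rng)
    pi, pj = index_stack.cell_index(pts[:, 0], pts[:, 1])
    valid_rows, valid_cols = np.nonzero(index_stack.valid)
    if valid_rows.size > background_size:
        pick = rng.choice(valid_rows.size, background_size, replace=False)
        valid_rows, valid_cols = valid_rows[pick], valid_cols[pick]
    bands = [b for b in bands]
    P = _band_matrix(index_stack, bands, pi, pj)
    Bg = _band_matrix(index_stack, bands, valid_rows, valid_cols)
    keep = np.isfinite(P).all(axis=1)
    P = P[keep]
    keepb = np.isfinite(Bg).all(axis=1)
    Bg = Bg[keepb]
    model = fit_maxent(P, Bg, bands, reg=reg, seed=seed)
    out = np.full(index_stack.shape, np.nan)
    vr, vc = np.nonzero(index_stack.valid)
    Xall = _band_matrix(index_stack, bands, vr, vc)
    fin = np.isfinite(Xall).all(axis=1)
    out[vr[fin], vc[fin]] = model.logistic(Xall[fin])
    return out, model


@dataclass
class SuitabilityModel:
    """Replicate-averaged species suitability model."""

    species: str
    replicates: pd.DataFrame  # replicate, train_auc, test_auc, threshold
    mean_prediction: np.ndarray  # grid shape; NaN outside the mask
    threshold: float  # mean replicate training-omission threshold
    contributions: pd.Series  # percent per predictor, sums to 100
    n_presence_cells: int
    redraws: int
    seed: int

    @property
    def mean_train_auc(self) -> float:
        return float(self.replicates["train_auc"].mean())

    @property
    def mean_test_auc(self) -> float:
        return float(self.replicates["test_auc"].mean())


def chained_suitability(
    lc: LandCoverMap,
    reflectance: RasterStack,
    species_xy: np.ndarray,
    species: str = "species",
    reg: float = 1.0,
    n_random: int = 200,
    n_replicates: int = 10,
    percentile: float = 10.0,
    seed: int = 0,
    background_size: int = 4000,
) -> dict:
    """Run the full chained design for one species group.

    Computes vegetation indices and distance rasters, builds the
    distance-to-river mask from the pooled fixes, fits the lantana spectral
    sub-model, and fits the final masked species model on the seven indices,
    the lantana probability, and the distances to mixed thicket and
    settlements.  Returns a dict with keys ``mask`` (:class:`MaskChain`),
    ``lantana_raster``, ``lantana_model`` and ``model``
    (:class:`SuitabilityModel`).
    """
    from .remote_sensing import distance_raster, vegetation_indices

    idx = vegetation_indices(reflectance)
    d_river = distance_raster(lc, "river", idx)
    chain = build_mask(np.asarray(species_xy, float), d_river, reg=reg,
                       percentile=percentile, seed=seed + 11)
    lant_raster, lant_model = lantana_model(lc, idx, n_random=n_random,
                                            reg=reg, seed=seed + 13)
    bands = dict(idx.bands)
    bands["lantana_prob"] = lant_raster
    bands["dist_settlement"] = next(iter(distance_raster(lc, "settlement", idx).bands.values()))
    predictor_bands = list(INDEX_NAMES) + ["lantana_prob", "dist_settlement"]
    if "mixed" in lc.polygons and not lc.polygons["mixed"].is_empty:
        bands["dist_mixed"] = next(iter(distance_raster(lc, "mixed", idx).bands.values()))
        predictor_bands.append("dist_mixed")
    stack = RasterStack(idx.x0, idx.y0, idx.cell_size, bands, idx.valid, idx.crs)
    model = fit_species_model(
        np.asarray(species_xy, float), chain, stack, predictor_bands, species=species,
        reg=reg, n_replicates=n_replicates, percentile=percentile, seed=seed + 17,
        background_size=background_size,
    )
    return {"mask": chain, "lantana_raster": lant_raster,
            "lantana_model": lant_model, "model": model,
            "predictor_stack": stack, "predictor_bands": predictor_bands}


def fit_species_model(
    species_xy: np.ndarray,
    mask_chain: MaskChain,
    predictor_stack: RasterStack,
    predictor_bands: list[str],
    species: str = "species",
    reg: float = 1.0,
    n_replicates: int = 10,
    train_fraction: float = 0.7,
    percentile: float = 10.0,
    seed: int = 0,
    background_size: int = 10000,
) -> SuitabilityModel:
    """Final per-species model inside the distance-to-river mask.

    Presence cells (deduplicated, one per grid cell) are split 70/30 into
    training and evaluation folds for each of ``n_replicates`` seeded
    replicates; a replicate whose test fold would hold fewer than 4
    presences is redrawn (counted in ``redraws``).  The background is the
    mask's cell set (seeded subsample above ``background_size``).  Reported
    per replicate: training and test AUC and the training-omission
    threshold; the prediction raster is the mean of the replicate logistic
    surfaces and is NaN outside the mask.
    """
    mask = mask_chain.mask & predictor_stack.valid
    fin = np.ones(predictor_stack.shape, dtype=bool)
    for b in predictor_bands:
        fin &= np.isfinite(predictor_stack.band(b))
    mask = mask & fin
    species_xy = np.asarray(species_xy, dtype=float)
    cells = _cells_of_points(predictor_stack, species_xy)
    inside = mask[cells[:, 0], cells[:, 1]]
    cells = cells[inside]
    n_p = len(cells)
    if n_p < 10:
        raise ValueError(f"only {n_p} presence cells inside the mask; need >= 10")
    rng = np.random.default_rng(seed)
    rows_all, cols_all = np.nonzero(mask)
    rows, cols = rows_all, cols_all
    if rows.size > background_size:
        pick = rng.choice(rows.size, background_size, replace=False)
        rows, cols = rows[pick], cols[pick]
    Bg = _band_matrix(predictor_stack, predictor_bands, rows, cols)
    Ball = _band_matrix(predictor_stack, predictor_bands, rows_all, cols_all)
    expansion = FeatureExpansion(predictor_bands).fit(Bg)
    Pall = _band_matrix(predictor_stack, predictor_bands, cells[:, 0], cells[:, 1])

    reps, redraws = [], 0
    pred_sum = np.zeros(rows_all.size)
    contrib_sum: pd.Series | None = None
    for r in range(n_replicates):
        # Bernoulli 70/30 split; redraw (logged) until the test fold holds
        # at least 4 presences and the training fold is non-empty
        while True:
            is_train = rng.random(n_p) < train_fraction
            if is_train.sum() >= 1 and (~is_train).sum() >= 4:
                break
            redraws += 1
            if redraws > 100:
                raise ValueError("cannot form a test fold with >= 4 presences")
        train, test = np.flatnonzero(is_train), np.flatnonzero(~is_train)
        model = fit_maxent(Pall[train], Bg, predictor_bands, reg=reg,
                           expansion=expansion, seed=seed + r)
        s_bg = model.linear_score(Bg)
        train_auc = auc_from_scores(model.linear_score(Pall[train]), s_bg)
        test_auc = auc_from_scores(model.linear_score(Pall[test]), s_bg)
        logi_train = model.logistic(Pall[train])
        t = omission_threshold(logi_train, percentile)
        reps.append({"replicate": r, "train_auc": train_auc, "test_auc": test_auc,
                     "threshold": t})
        pred_sum += model.logistic(Ball)
        c = model.contributions()
        contrib_sum = c if contrib_sum is None else contrib_sum.add(c, fill_value=0.0)

    rep_tab = pd.DataFrame(reps)
    mean_pred = np.full(predictor_stack.shape, np.nan)
    mean_pred[rows_all, cols_all] = pred_sum / n_replicates
    contrib = contrib_sum / n_replicates
    contrib = 100.0 * contrib / contrib.sum()
    return SuitabilityModel(
        species=species,
        replicates=rep_tab,
        mean_prediction=mean_pred,
        threshold=float(rep_tab["threshold"].mean()),
        contributions=contrib,
        n_presence_cells=n_p,
        redraws=redraws,
        seed=seed,
    )
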