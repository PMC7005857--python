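"""Presence-background maximum-entropy niche modelling.

Protocol: spatially thin the presences on a grid whose cell size is 10% of
the longest inter-point great-circle distance, subsample 80% of the thinned
records, draw ten background points per presence from the convex hull of the
presences buffered by 10% of that same distance, fit a Gibbs distribution
over background cells whose feature expectations match the presence feature
means (standardised linear + quadratic features, L1 regularisation), average
three such runs, binarise at the maximum sensitivity + specificity threshold,
and clip the binary range to the buffered hull.

The fit minimises::

    -mean_presence(w . f)  +  log sum_background exp(w . f)  +  beta * ||w||_1

which at the optimum bounds every feature-expectation mismatch by ``beta``
(the defining box constraint of an L1-regularised maximum-entropy model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from shapely.geometry import MultiPoint

from .geo import haversine_km, km_to_degrees
from .types import ClimateStack, GridSpec


class TooFewRecords(ValueError):
    """A taxon has fewer presence records than the modelling minimum."""


# ------------------------------------------------------------------ geometry

def longest_interpoint_distance(lats, lons) -> float:
    """Maximum pairwise great-circle distance (km) over the points."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        raise ValueError("insufficient points: need at least 2")
    best = 0.0
    for i in range(lats.size - 1):
        d = haversine_km(lats[i], lons[i], lats[i + 1:], lons[i + 1:])
        best = max(best, float(np.max(d)))
    return best


@dataclass(frozen=True)
class ThinningGrid:
    """Square thinning grid aligned to the raster origin."""
    cell_deg: float
    x0: float
    y0: float

    def cell_index(self, lons, lats):
        cx = np.floor((np.asarray(lons) - self.x0) / self.cell_deg).astype(int)
        cy = np.floor((np.asarray(lats) - self.y0) / self.cell_deg).astype(int)
        return cx, cy

    @classmethod
    def from_points(cls, lats, lons, raster_grid: GridSpec, thin_frac=0.1):
        km = longest_interpoint_distance(lats, lons)
        deg = km_to_degrees(thin_frac * km, float(np.mean(lats)))
        if deg <= 0:
            raise ValueError("thinning cell size must be positive")
        return cls(cell_deg=deg, x0=raster_grid.xll, y0=raster_grid.yll)


@dataclass
class HullRegion:
    """Convex hull of the presences, buffered by ``buffer_frac`` of the
    longest inter-point distance (converted to degrees at the mean latitude)."""
    hull: object
    buffered: object
    buffer_deg: float

    @classmethod
    def from_points(cls, lats, lons, buffer_frac=0.1):
        km = longest_interpoint_distance(lats, lons)
        deg = km_to_degrees(buffer_frac * km, float(np.mean(lats)))
        hull = MultiPoint(list(zip(lons, lats))).convex_hull
        return cls(hull=hull, buffered=hull.buffer(deg), buffer_deg=deg)


def resample_presences(lats, lons, grid: ThinningGrid, keep_frac=0.8, seed=0):
    """Spatial thinning then random subsampling; returns selected indices.

    Stage 1 keeps one record, uniformly at random, per occupied thinning
    cell; stage 2 keeps ``ceil(keep_frac * n_thinned)`` of those without
    replacement. Deterministic given the seed.
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    cx, cy = grid.cell_index(lons, lats)
    cells = {}
    for i in range(len(cx)):
        cells.setdefault((int(cx[i]), int(cy[i])), []).append(i)
    thinned = np.array(sorted(int(rng.choice(idx)) for idx in cells.values()))
    k = int(np.ceil(keep_frac * thinned.size))
    return np.sort(rng.choice(thinned, size=k, replace=False))


def sample_background(hull_region: HullRegion, stack: ClimateStack,
                      n_presence: int, ratio: int = 10, seed: int = 0):
    """Uniform background draw over data cells inside the buffered hull.

    Returns (lons, lats) of ``ratio * n_presence`` sampled cell centres
    (drawn with replacement across the eligible cells, which keeps the
    per-cell density uniform).
    """
    import shapely

    rng = np.random.default_rng(seed)
    grid = stack.grid
    lon, lat = grid.center_grids()
    ok = stack.data_mask.ravel()
    inside = shapely.contains_xy(hull_region.buffered, lon.ravel(), lat.ravel())
    eligible = np.nonzero(ok & inside)[0]
    if eligible.size == 0:
        raise ValueError("buffered hull contains no data cells")
    n = ratio * n_presence
    if eligible.size < n:
        warnings.warn(f"only {eligible.size} eligible cells for {n} background "
                      "points; sampling with replacement")
    pick = rng.choice(eligible, size=n, replace=True)
    return lon.ravel()[pick], lat.ravel()[pick]


# --------------------------------------------------------------------- model

@dataclass
class NicheModel:
    variables: list
    weights: np.ndarray          # one per feature (linear then quadratic)
    beta: float
    lin_mean: np.ndarray
    lin_sd: np.ndarray
    quad_mean: np.ndarray
    quad_sd: np.ndarray
    meta: dict = field(default_factory=dict)

    def features(self, env: np.ndarray) -> np.ndarray:
        """Standardised linear + quadratic features of raw env values."""
        z = (env - self.lin_mean) / self.lin_sd
        q = (z * z - self.quad_mean) / self.quad_sd
        return np.hstack([z, q])

    def raw_score(self, env: np.ndarray) -> np.ndarray:
        """Unnormalised log-suitability ``w . f``."""
        return self.features(env) @ self.weights


def fit_maxent(presence_env: np.ndarray, background_env: np.ndarray,
               beta: float = 0.05, max_iter: int = 500) -> NicheModel:
    """Fit the penalised maximum-entropy model.

    ``presence_env`` and ``background_env`` are raw (n, d) climate matrices.
    Features are standardised against the background sample. The L1 term is
    handled by the positive/negative split ``w = u - v`` with box bounds,
    solved by L-BFGS-B; at the optimum every feature expectation under the
    fitted Gibbs distribution matches the presence mean to within ``beta``.
    """
    presence_env = np.asarray(presence_env, dtype=float)
    background_env = np.asarray(background_env, dtype=float)
    if presence_env.shape[0] < 5:
        raise TooFewRecords("need at least 5 presence rows")
    if background_env.shape[0] < presence_env.shape[0]:
        raise ValueError("background must be at least as large as presence")

    lin_mean = background_env.mean(axis=0)
    lin_sd = background_env.std(axis=0)
    lin_sd[lin_sd == 0] = 1.0
    zb = (background_env - lin_mean) / lin_sd
    quad = zb * zb
    quad_mean = quad.mean(axis=0)
    quad_sd = quad.std(axis=0)
    quad_sd[quad_sd == 0] = 1.0

    model = NicheModel(variables=[], weights=None, beta=beta,
                       lin_mean=lin_mean, lin_sd=lin_sd,
                       quad_mean=quad_mean, quad_sd=quad_sd)
    Fp = model.features(presence_env)
    Fb = model.features(background_env)
    # the Gibbs support is background + presence samples (the standard Maxent
    # convention); without the presence rows the objective is unbounded when
    # the presence feature mean falls outside the background feature hull
    Fs = np.vstack([Fb, Fp])
    p_mean = Fp.mean(axis=0)
    d = Fp.shape[1]

    def objective(x):
        u, v = x[:d], x[d:]
        w = u - v
        s = Fs @ w
        lse = logsumexp(s)
        pb = np.exp(s - lse)
        grad_w = -p_mean + Fs.T @ pb
        f = -p_mean @ w + lse + beta * (u.sum() + v.sum())
        return f, np.concatenate([grad_w + beta, -grad_w + beta])

    x0 = np.zeros(2 * d)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * d),
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    w = res.x[:d] - res.x[d:]
    s = Fs @ w
    pb = np.exp(s - logsumexp(s))
    gap = np.abs(Fs.T @ pb - p_mean)
    if not res.success and gap.max() > beta + 1e-4:
        raise RuntimeError(
            f"maxent fit did not converge: max feature gap {gap.max():.3g}")
    model.weights = w
    model.meta = {"n_presence": presence_env.shape[0],
                  "n_background": background_env.shape[0],
                  "kkt_gap": float(gap.max()), "niter": int(res.nit)}
    return model


def predict(model: NicheModel, stack: ClimateStack, variables, clip=None):
    """Continuous suitability raster in [0, 1] (max-normalised over the clip).

    Cells outside the clip polygon or without data are nodata.
    """
    import shapely

    for v in variables:
        if v not in stack.layers:
            raise ValueError(f"stack is missing model variable {v}")
    grid = stack.grid
    lon, lat = grid.center_grids()
    ok = stack.data_mask.copy()
    if clip is not None:
        inside = shapely.contains_xy(clip, lon.ravel(), lat.ravel()
                                     ).reshape(lon.shape)
        ok &= inside
    env = np.stack([stack.layers[v][ok] for v in variables], axis=1)
    score = model.raw_score(env)
    s = np.exp(score - score.max())
    out = np.full(lon.shape, grid.nodata)
    out[ok] = s / s.max()
    return out


def threshold_max_ss(presence_scores, background_scores) -> float:
    """Suitability cut-off maximising sensitivity + specificity.

    Candidates are the distinct observed scores; sensitivity counts presences
    with score >= tau, specificity counts background with score < tau; ties
    are broken toward the smallest candidate.
    """
    ps = np.asarray(presence_scores, dtype=float)
    bs = np.asarray(background_scores, dtype=float)
    if ps.size == 0 or bs.size == 0:
        raise ValueError("both score lists must be non-empty")
    cands = np.unique(np.concatenate([ps, bs]))
    best_tau, best_val = None, -np.inf
    for tau in cands:  # ascending: first maximum wins the tie-break
        val = (ps >= tau).mean() + (bs < tau).mean()
        if val > best_val + 1e-12:
            best_val, best_tau = val, float(tau)
    return best_tau


# ------------------------------------------------------------------ protocol

@dataclass
class NicheConfig:
    n_runs: int = 3
    keep_frac: float = 0.8
    bg_ratio: int = 10
    beta: float = 0.05
    min_records: int = 5
    thin_frac: float = 0.1
    buffer_frac: float = 0.1
    variables: tuple = ("BIO1", "BIO12")
    seed: int = 0


@dataclass
class SuitabilityMap:
    continuous: np.ndarray
    tau: float
    binary: np.ndarray
    hull: HullRegion
    grid: GridSpec
    models: list = field(default_factory=list)


def run_protocol(records, stack: ClimateStack, config: NicheConfig | None = None
                 ) -> SuitabilityMap:
    """Full per-taxon protocol: thin, fit ``n_runs`` models, average, binarise.

    ``records`` are the cleaned presences of one taxon. The threshold is
    computed on the averaged raster, scoring all cleaned presences against a
    dedicated background sample.
    """
    cfg = config or NicheConfig()
    lats = np.array([r.lat for r in records], dtype=float)
    lons = np.array([r.lon for r in records], dtype=float)
    if lats.size < cfg.min_records:
        raise TooFewRecords(
            f"{lats.size} records < min_model_records={cfg.min_records}")
    grid = ThinningGrid.from_points(lats, lons, stack.grid, cfg.thin_frac)
    hull = HullRegion.from_points(lats, lons, cfg.buffer_frac)
    variables = list(cfg.variables)

    rasters, models = [], []
    for run in range(cfg.n_runs):
        sel = resample_presences(lats, lons, grid, cfg.keep_frac,
                                 seed=np.random.SeedSequence((cfg.seed, 100 + run)))
        p_env = stack.values_at(lons[sel], lats[sel], variables)
        p_env = p_env[~np.isnan(p_env).any(axis=1)]
        blon, blat = sample_background(hull, stack, max(len(p_env), 1),
                                       cfg.bg_ratio,
                                       seed=np.random.SeedSequence((cfg.seed, 200 + run)))
        b_env = stack.values_at(blon, blat, variables)
        model = fit_maxent(p_env, b_env, cfg.beta)
        model.variables = variables
        model.meta["run"] = run
        models.append(model)
        rasters.append(predict(model, stack, variables, clip=hull.buffered))

    nodata = stack.grid.nodata
    stackd = np.stack(rasters)
    valid = np.all(stackd != nodata, axis=0)
    continuous = np.full(rasters[0].shape, nodata)
    continuous[valid] = stackd[:, valid].mean(axis=0)

    # threshold on the averaged raster: all cleaned presences vs a dedicated
    # background draw
    prow, pcol = stack.grid.cell_of(lons, lats)
    pin = prow >= 0
    pscores = continuous[prow[pin], pcol[pin]]
    pscores = pscores[pscores != nodata]
    blon, blat = sample_background(hull, stack, max(lats.size, 1), cfg.bg_ratio,
                                   seed=np.random.SeedSequence((cfg.seed, 999)))
    brow, bcol = stack.grid.cell_of(blon, blat)
    bscores = continuous[brow, bcol]
    bscores = bscores[bscores != nodata]
    tau = threshold_max_ss(pscores, bscores)

    binary = np.where((continuous != nodata) & (continuous >= tau), 1, 0)
    return SuitabilityMap(continuous=continuous, tau=tau, binary=binary,
                          hull=hull, grid=stack.grid, models=models)
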