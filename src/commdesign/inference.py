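"""Regularized gLV parameter estimation with prior chaining and
parametric-bootstrap posterior ensembles.

The fitting objective combines endpoint community data ("single"
observations, where only the 48-h composition was measured), monoculture
time series ("dynamic" observations, up-weighted by ``w``), and an L2
penalty on prior-standardized deviations:

    phi(theta) = sum_single (X_exp - X_model)^2
               + w * sum_dynamic (X_exp - X_model)^2
               + lambda * sum_j ((theta_j - mu_j) / sd_j)^2

The MAP estimate minimizes phi subject to a_ii < 0.  Posterior uncertainty
is represented by an ensemble of refits on data perturbed with zero-mean
Gaussian noise scaled by the replicate standard deviations (a parametric
bootstrap).  The ensemble's per-parameter mean/sd become the prior for the
next model update (prior chaining M1 -> M2 -> M3).

Monoculture trajectories are evaluated with the exact logistic closed form;
endpoint communities use the vectorized RK4 integrator from
:mod:`commdesign.glv`, with the cost and its finite-difference gradient for
all parameter directions computed in a single batched integration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .glv import (
    DEFAULT_INOCULUM_OD,
    DEFAULT_T_END,
    GLVParameters,
    SpeciesRegistry,
    simulate_batch_parameter_sets,
)

__all__ = [
    "PriorSpec",
    "DynamicObservation",
    "SingleObservation",
    "TrainingData",
    "InferenceConfig",
    "ParameterEnsemble",
    "standard_prior",
    "fit_map",
    "sample_posterior_ensemble",
    "posterior_to_prior",
    "observed_pair_mask",
    "select_lambda",
    "cost_at",
    "InferenceError",
]

logger = logging.getLogger(__name__)

DIAG_UPPER_BOUND = -1e-4
SD_FLOOR = 1e-3


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal prior per parameter, in packed order (r then a,
    row-major)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("prior mean and sd must be matching vectors")
        if np.any(sd <= 0):
            raise ValueError("prior sd must be strictly positive")


def standard_prior(n_species: int) -> PriorSpec:
    """The uninformed starting prior: every parameter ~ N(0, 1)."""
    p = n_species + n_species * n_species
    return PriorSpec(np.zeros(p), np.ones(p))


@dataclass(frozen=True)
class DynamicObservation:
    """Monoculture time series: mean OD and replicate sd at each time."""

    species: str
    t: np.ndarray
    x: np.ndarray
    sd: np.ndarray
    x0: float = DEFAULT_INOCULUM_OD

    def __post_init__(self) -> None:
        for name in ("t", "x", "sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.x.shape == self.sd.shape):
            raise ValueError("t, x, sd must have matching shapes")
        if np.any(self.x < 0) or np.any(self.sd < 0):
            raise ValueError("abundances and sds must be non-negative")


@dataclass(frozen=True)
class SingleObservation:
    """Endpoint community composition: mean abundance vector (zeros for
    absent species) and replicate sd, at ``t_end`` hours."""

    members: frozenset[str]
    x: np.ndarray
    sd: np.ndarray
    t_end: float = DEFAULT_T_END
    x0_total: float = DEFAULT_INOCULUM_OD

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.x < 0) or np.any(self.sd < 0):
            raise ValueError("abundances and sds must be non-negative")


@dataclass(frozen=True)
class TrainingData:
    dynamic: tuple[DynamicObservation, ...]
    single: tuple[SingleObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dynamic", tuple(self.dynamic))
        object.__setattr__(self, "single", tuple(self.single))

    def validate(self, registry: SpeciesRegistry) -> None:
        for d in self.dynamic:
            registry.index(d.species)
        for s in self.single:
            if s.x.size != registry.n_species:
                raise ValueError("single observation length must match registry")
            for m in s.members:
                registry.index(m)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the MAP/ensemble fit.

    lambda_l2 : prior-deviation penalty weight (lambda).
    dynamic_weight : weight w on the monoculture time-series residuals.
    n_ensemble : number of bootstrap members (member 0 is the plain MAP).
    noise_scale : multiplier on replicate sd for bootstrap perturbations.
    sim_dt : RK4 step (h) used inside the cost function.
    n_starts : multi-start count for the MAP fit (prior mean, previous MAP
        when available, jittered prior mean).
    """

    lambda_l2: float = 0.01
    dynamic_weight: float = 10.0
    n_ensemble: int = 100
    noise_scale: float = 1.0
    seed: int = 0
    sim_dt: float = 0.5
    n_starts: int = 3
    maxiter: int = 400

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be >= 0")
        if self.dynamic_weight <= 0:
            raise ValueError("dynamic_weight must be > 0")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")


@dataclass(frozen=True)
class ParameterEnsemble:
    members: tuple[GLVParameters, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("ensemble must be non-empty")
        n = members[0].n_species
        if any(m.n_species != n for m in members):
            raise ValueError("ensemble members must be dimensionally identical")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_species(self) -> int:
        return self.members[0].n_species

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(B, N) growth rates and (B, N, N) interaction matrices."""
        r = np.stack([m.r for m in self.members])
        a = np.stack([m.a for m in self.members])
        return r, a


# -- parameter packing -------------------------------------------------------

def pack(params: GLVParameters) -> np.ndarray:
    return np.concatenate([params.r, params.a.ravel()])


def unpack(theta: np.ndarray, n: int) -> GLVParameters:
    return GLVParameters(theta[:n], theta[n:].reshape(n, n))


def _diag_indices(n: int) -> np.ndarray:
    return n + np.arange(n) * (n + 1)


# -- cost --------------------------------------------------------------------

def _logistic(t, x0, r, a):
    """Closed-form monoculture gLV solution of dx/dt = x (r + a x).

    Uses the overflow-safe form X = K x0 / (x0 + (K - x0) e^{-rt}) with
    K = -r/a, and the r -> 0 limit x0 / (1 - a x0 t).
    """
    t = np.asarray(t, dtype=float)
    out = np.empty(np.broadcast_shapes(t.shape, np.shape(r)), dtype=float)
    r, a, x0 = np.broadcast_to(r, out.shape), np.broadcast_to(a, out.shape), np.broadcast_to(x0, out.shape)
    t = np.broadcast_to(t, out.shape)
    small = np.abs(r) < 1e-10
    with np.errstate(over="ignore", invalid="ignore"):
        K = np.where(small, 1.0, -r / np.where(a == 0, -1e-300, a))
        e = np.exp(np.clip(-r * t, -500.0, 500.0))
        gen = K * x0 / (x0 + (K - x0) * e)
        lim = x0 / (1.0 - a * x0 * t)
    out[:] = np.where(small, lim, gen)
    return np.maximum(out, 0.0)


class _CostBundle:
    """Precomputed arrays for fast batched cost evaluation."""

    def __init__(self, data: TrainingData, registry: SpeciesRegistry, cfg: InferenceConfig):
        n = registry.n_species
        self.n = n
        self.cfg = cfg
        # endpoint communities
        self.X0 = np.zeros((len(data.single), n))
        self.Xobs = np.zeros_like(self.X0)
        for i, s in enumerate(data.single):
            idx = registry.indices(s.members)
            self.X0[i, idx] = s.x0_total / len(s.members)
            self.Xobs[i] = s.x
        self.t_end = data.single[0].t_end if data.single else DEFAULT_T_END
        # monoculture time series, flattened
        self.dyn_sp = np.array([registry.index(d.species) for d in data.dynamic], dtype=int)
        self.dyn_t = [d.t for d in data.dynamic]
        self.dyn_x = [d.x for d in data.dynamic]
        self.dyn_x0 = np.array([d.x0 for d in data.dynamic])

    def residuals_batch(self, theta_batch: np.ndarray, prior: PriorSpec) -> np.ndarray:
        """Weighted residual vectors (one per row of ``theta_batch``) whose
        squared sum equals phi; all rows evaluated in one batched
        integration."""
        B = theta_batch.shape[0]
        n = self.n
        r = theta_batch[:, :n]
        a = theta_batch[:, n:].reshape(B, n, n)
        parts = []
        if self.X0.shape[0]:
            Xend = simulate_batch_parameter_sets(
                r, a, self.X0, t_end=self.t_end, dt=self.cfg.sim_dt
            )
            parts.append((Xend - self.Xobs[None]).reshape(B, -1))
        sw = np.sqrt(self.cfg.dynamic_weight)
        for k, sp in enumerate(self.dyn_sp):
            xm = _logistic(
                self.dyn_t[k][None, :], self.dyn_x0[k], r[:, sp : sp + 1], a[:, sp, sp][:, None]
            )
            parts.append(sw * (xm - self.dyn_x[k][None, :]))
        z = (theta_batch - prior.mean[None]) / prior.sd[None]
        parts.append(np.sqrt(self.cfg.lambda_l2) * z)
        return np.concatenate(parts, axis=1)

    def cost_batch(self, theta_batch: np.ndarray, prior: PriorSpec) -> np.ndarray:
        """phi for each row of ``theta_batch``."""
        res = self.residuals_batch(theta_batch, prior)
        return (res**2).sum(axis=1)

    def residuals_and_jac(self, theta: np.ndarray, prior: PriorSpec, eps: float = 1e-7):
        """Residual vector and forward-difference Jacobian, both from a
        single batched integration over all parameter directions."""
        P = theta.size
        batch = np.tile(theta, (P + 1, 1))
        steps = eps * (1.0 + np.abs(theta))
        batch[1:] += np.diag(steps)
        res = self.residuals_batch(batch, prior)
        jac = (res[1:] - res[0][None, :]) / steps[:, None]
        return res[0], jac.T


def cost_at(
    params: GLVParameters,
    data: TrainingData,
    prior: PriorSpec,
    registry: SpeciesRegistry,
    cfg: InferenceConfig | None = None,
) -> float:
    """The joint weighted cost phi at a given parameter set."""
    cfg = cfg or InferenceConfig()
    bundle = _CostBundle(data, registry, cfg)
    return float(bundle.cost_batch(pack(params)[None, :], prior)[0])


# -- MAP fit -----------------------------------------------------------------

def _project_feasible(theta: np.ndarray, n: int, diag_cap: float = -0.05) -> np.ndarray:
    theta = theta.copy()
    di = _diag_indices(n)
    theta[di] = np.minimum(theta[di], diag_cap)
    return theta


def _fit_theta(
    bundle: _CostBundle,
    prior: PriorSpec,
    cfg: InferenceConfig,
    starts: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    n = bundle.n
    P = n + n * n
    lb = np.full(P, -np.inf)
    ub = np.full(P, np.inf)
    ub[_diag_indices(n)] = DIAG_UPPER_BOUND

    # cache: trust-region solvers evaluate fun and jac at the same point
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def fun_jac(th):
        key = th.tobytes()
        if key not in cache:
            cache.clear()
            cache[key] = bundle.residuals_and_jac(th, prior)
        return cache[key]

    best: tuple[np.ndarray, float] | None = None
    for x0 in starts:
        res = least_squares(
            lambda th: fun_jac(th)[0],
            np.clip(_project_feasible(x0, n), lb, ub),
            jac=lambda th: fun_jac(th)[1],
            bounds=(lb, ub),
            method="trf",
            max_nfev=cfg.maxiter,
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
        )
        cost = float(2.0 * res.cost)  # least_squares reports 0.5 * sum of squares
        if not np.isfinite(cost):
            raise InferenceError(f"optimizer diverged (final cost {cost})")
        if res.status <= 0:
            logger.debug("optimizer stopped early: %s", res.message)
        cand = (res.x, cost)
        if (
            best is None
            or cand[1] < best[1] - 1e-12
            or (abs(cand[1] - best[1]) <= 1e-12
                and np.linalg.norm(cand[0]) < np.linalg.norm(best[0]))
        ):
            best = cand
    assert best is not None
    return best


def _make_starts(
    prior: PriorSpec, cfg: InferenceConfig, n: int, previous_map: np.ndarray | None, rng
) -> list[np.ndarray]:
    starts = [prior.mean.copy()]
    if previous_map is not None:
        starts.append(previous_map.copy())
    while len(starts) < cfg.n_starts:
        starts.append(prior.mean + 0.1 * prior.sd * rng.standard_normal(prior.mean.size))
    return starts[: max(cfg.n_starts, 1)]


def fit_map(
    data: TrainingData,
    prior: PriorSpec,
    cfg: InferenceConfig,
    registry: SpeciesRegistry,
    previous_map: GLVParameters | None = None,
) -> GLVParameters:
    """MAP estimate: minimize the joint weighted cost subject to a_ii < 0."""
    if not data.dynamic and not data.single:
        raise InferenceError("training data is empty")
    data.validate(registry)
    n = registry.n_species
    if prior.mean.size != n + n * n:
        raise ValueError("prior dimension must equal N + N^2")
    obs = np.concatenate(
        [d.x for d in data.dynamic] + [s.x for s in data.single]
    )
    if np.all(obs == 0):
        raise InferenceError("degenerate training data: all observations are zero")

    rng = np.random.default_rng(cfg.seed)
    bundle = _CostBundle(data, registry, cfg)
    prev = pack(previous_map) if previous_map is not None else None
    theta, _ = _fit_theta(bundle, prior, cfg, _make_starts(prior, cfg, n, prev, rng))
    return unpack(theta, n)


# -- bootstrap ensemble ------------------------------------------------------

def _perturb(data: TrainingData, noise_scale: float, rng) -> TrainingData:
    dyn = tuple(
        replace(d, x=np.maximum(d.x + noise_scale * d.sd * rng.standard_normal(d.x.shape), 0.0))
        for d in data.dynamic
    )
    sing = tuple(
        replace(s, x=np.maximum(s.x + noise_scale * s.sd * rng.standard_normal(s.x.shape), 0.0))
        for s in data.single
    )
    return TrainingData(dyn, sing)


def _data_equal(a: TrainingData, b: TrainingData) -> bool:
    return all(
        np.array_equal(da.x, db.x) for da, db in zip(a.dynamic, b.dynamic)
    ) and all(np.array_equal(sa.x, sb.x) for sa, sb in zip(a.single, b.single))


def sample_posterior_ensemble(
    data: TrainingData,
    prior: PriorSpec,
    cfg: InferenceConfig,
    registry: SpeciesRegistry,
) -> ParameterEnsemble:
    """Parametric-bootstrap posterior: member 0 is the unperturbed MAP;
    members 1..n-1 are MAP refits on noise-perturbed data (sd = noise_scale
    x replicate sd, truncated at 0), warm-started from the MAP."""
    rng = np.random.default_rng(cfg.seed)
    map_params = fit_map(data, prior, cfg, registry)
    map_theta = pack(map_params)
    bundle0 = _CostBundle(data, registry, cfg)

    members = [map_params]
    failures = 0
    member_cfg = replace(cfg, n_starts=1, maxiter=max(100, cfg.maxiter // 2))
    for m in range(1, cfg.n_ensemble):
        pdata = _perturb(data, cfg.noise_scale, rng)
        if _data_equal(pdata, data):
            # zero noise (all sd = 0 or noise_scale = 0): the refit optimum
            # is the MAP itself, so skip the redundant optimization
            members.append(map_params)
            continue
        try:
            bundle = _CostBundle(pdata, registry, member_cfg)
            theta, _ = _fit_theta(bundle, prior, member_cfg, [map_theta])
            members.append(unpack(theta, registry.n_species))
        except InferenceError as exc:  # pragma: no cover - rare
            failures += 1
            logger.warning("ensemble member %d failed: %s", m, exc)
    if cfg.n_ensemble > 1 and failures > 0.2 * cfg.n_ensemble:
        raise InferenceError(
            f"{failures}/{cfg.n_ensemble} ensemble members failed to fit"
        )
    provenance = {
        "lambda_l2": cfg.lambda_l2,
        "dynamic_weight": cfg.dynamic_weight,
        "noise_scale": cfg.noise_scale,
        "seed": cfg.seed,
        "n_requested": cfg.n_ensemble,
        "n_failures": failures,
    }
    return ParameterEnsemble(tuple(members), provenance)


def posterior_to_prior(ens: ParameterEnsemble, sd_floor: float = SD_FLOOR) -> PriorSpec:
    """Per-parameter mean/sd across ensemble members, for prior chaining."""
    thetas = np.stack([pack(m) for m in ens.members])
    mean = thetas.mean(axis=0)
    if len(ens) == 1:
        warnings.warn("single-member ensemble: prior sd set to the floor everywhere")
        sd = np.full(mean.shape, sd_floor)
    else:
        sd = np.maximum(thetas.std(axis=0, ddof=0), sd_floor)
    return PriorSpec(mean, sd)


def observed_pair_mask(data: TrainingData, registry: SpeciesRegistry) -> np.ndarray:
    """(N, N) boolean: True where a_ij is informed by the data, i.e. species
    i and j co-occurred in some training community (diagonals via
    monocultures)."""
    n = registry.n_species
    mask = np.zeros((n, n), dtype=bool)
    for d in data.dynamic:
        i = registry.index(d.species)
        mask[i, i] = True
    for s in data.single:
        idx = registry.indices(s.members)
        mask[np.ix_(idx, idx)] = True
    return mask


def select_lambda(
    data: TrainingData,
    prior: PriorSpec,
    cfg: InferenceConfig,
    registry: SpeciesRegistry,
    grid: np.ndarray | None = None,
    holdout_frac: float = 0.2,
) -> float:
    """Coarse lambda selection: hold out a fraction of endpoint communities,
    fit at each grid value, and pick the largest lambda within 5% of the best
    held-out endpoint SSE (strongest regularization that still fits)."""
    if grid is None:
        grid = np.logspace(-4, 1, 6)
    rng = np.random.default_rng(cfg.seed)
    n_single = len(data.single)
    if n_single < 5:
        raise InferenceError("need at least 5 endpoint communities to select lambda")
    idx = rng.permutation(n_single)
    n_hold = max(1, int(round(holdout_frac * n_single)))
    hold, train = idx[:n_hold], idx[n_hold:]
    train_data = TrainingData(data.dynamic, tuple(data.single[i] for i in train))
    hold_data = [data.single[i] for i in hold]

    sses = []
    for lam in grid:
        params = fit_map(train_data, prior, replace(cfg, lambda_l2=float(lam)), registry)
        bundle = _CostBundle(
            TrainingData((), tuple(hold_data)), registry, replace(cfg, lambda_l2=0.0)
        )
        sses.append(bundle.cost_batch(pack(params)[None], prior)[0])
    sses = np.asarray(sses)
    ok = sses <= 1.05 * sses.min()
    return float(np.max(np.asarray(grid)[ok]))
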