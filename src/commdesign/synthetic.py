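"""Ground-truth generation and emulated community experiments.

This module produces synthetic datasets with the statistical structure the
analysis pipeline assumes: a species pool whose pairwise growth interactions
are predominantly negative (about half the off-diagonal coefficients below
-0.05 h^-1 OD^-1 and only a few percent above +0.05, mirroring the inferred
interaction network of the emulated system), gLV-governed growth from a
small equal-split inoculum to a 48-h endpoint, sequencing-style
compositional measurement (multinomial read counts at Poisson depth,
converted back to absolute abundance via a noisy OD600), and growth-coupled
butyrate production through the sparse interaction regression.  Occasional
contaminated samples exercise the QC rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glv import (
    DEFAULT_INOCULUM_OD,
    DEFAULT_T_END,
    GLVParameters,
    SpeciesRegistry,
    default_registry,
    simulate_endpoints_batch,
    simulate_batch_parameter_sets,
)
from .inference import (
    DynamicObservation,
    SingleObservation,
    TrainingData,
)
from .production import ProductionModel, predict_butyrate

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_registry",
    "generate_ground_truth",
    "simulate_experiment",
    "monoculture_timeseries",
    "training_data_from_tables",
    "standard_fixture",
]

#: thresholds classifying an interaction as negative/positive (h^-1 OD^-1)
INTERACTION_THRESHOLD = 0.05

MONO_TIME_GRID = np.array([0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults emulate the 25-species / 5-producer system: 49.8% of
    off-diagonal growth interactions negative and 1.7% positive at the
    +-0.05 h^-1 OD^-1 thresholds, 5% multiplicative replicate noise on OD
    and metabolite measurements, and sequencing depth around 20,000 reads.
    """

    n_species: int = 25
    n_bp: int = 5
    frac_negative_interactions: float = 0.498
    frac_positive_interactions: float = 0.017
    interaction_scale: float = 0.6
    growth_rate_range: tuple[float, float] = (0.15, 0.65)
    production_sparsity: int = 10
    od_noise_cv: float = 0.05
    metabolite_noise_cv: float = 0.05
    read_depth_mean: float = 20000.0
    contamination_rate: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fn, fp = self.frac_negative_interactions, self.frac_positive_interactions
        if not (0 <= fn <= 1 and 0 <= fp <= 1 and fn + fp <= 1):
            raise ValueError("interaction fractions must lie in [0,1] and sum <= 1")
        if self.read_depth_mean <= 0:
            raise ValueError("read_depth_mean must be positive")


@dataclass(frozen=True)
class GroundTruth:
    glv: GLVParameters
    production: ProductionModel
    registry: SpeciesRegistry


def make_registry(n_species: int, n_bp: int) -> SpeciesRegistry:
    """Registry for a generated pool.  The full default pool is used when
    dimensions match; smaller pools take a prefix that always includes the
    producers AC and ER first."""
    if n_species == 25 and n_bp == 5:
        return default_registry()
    full = default_registry()
    bp_sorted = sorted(full.butyrate_producers)
    others = [s for s in full.species_ids if s not in full.butyrate_producers]
    if n_bp > len(bp_sorted) or n_species - n_bp > len(others):
        ids = [f"S{i:02d}" for i in range(n_species)]
        bp = frozenset(ids[:n_bp])
        return SpeciesRegistry(tuple(ids), bp)
    ids = bp_sorted[:n_bp] + others[: n_species - n_bp]
    order = [s for s in full.phylo_order if s in set(ids)]
    return SpeciesRegistry(tuple(sorted(ids)), frozenset(bp_sorted[:n_bp]), tuple(order))


def generate_ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Draw a gLV parameter set and a sparse production model.

    Off-diagonal interactions fall in three classes drawn per entry:
    negative (uniform in [-interaction_scale, -0.05]), positive (uniform in
    [0.05, interaction_scale/2]), or near-neutral (uniform in [-0.05, 0.05]),
    with class probabilities from the config.  Diagonals are set from
    realistic carrying capacities (K ~ U(0.3, 1.2) OD600, a_ii = -r_i / K_i).
    """
    rng = np.random.default_rng(cfg.seed)
    registry = make_registry(cfg.n_species, cfg.n_bp)
    n = cfg.n_species

    lo, hi = cfg.growth_rate_range
    r = rng.uniform(lo, hi, size=n)
    K = rng.uniform(0.3, 1.2, size=n)
    a = np.zeros((n, n))
    np.fill_diagonal(a, -r / K)

    classes = rng.choice(
        3,
        size=(n, n),
        p=[
            cfg.frac_negative_interactions,
            cfg.frac_positive_interactions,
            1 - cfg.frac_negative_interactions - cfg.frac_positive_interactions,
        ],
    )
    off = ~np.eye(n, dtype=bool)
    neg = off & (classes == 0)
    pos = off & (classes == 1)
    neu = off & (classes == 2)
    a[neg] = rng.uniform(-cfg.interaction_scale, -INTERACTION_THRESHOLD, size=neg.sum())
    a[pos] = rng.uniform(INTERACTION_THRESHOLD, cfg.interaction_scale / 2, size=pos.sum())
    a[neu] = rng.uniform(-INTERACTION_THRESHOLD, INTERACTION_THRESHOLD, size=neu.sum())
    glv = GLVParameters(r, a)

    # sparse production model: positive alpha for each producer, a handful of
    # nonzero production-interaction pairs
    bp = sorted(registry.butyrate_producers)
    alpha0 = {j: float(rng.uniform(1.0, 4.0)) for j in bp}
    alpha1 = {j: float(rng.uniform(15.0, 45.0)) for j in bp}
    pairs = [(j, k) for j in bp for k in registry.species_ids if k != j]
    chosen = rng.choice(len(pairs), size=min(cfg.production_sparsity, len(pairs)), replace=False)
    beta0 = {}
    beta1 = {}
    for ci in chosen:
        j, k = pairs[ci]
        beta0[(j, k)] = float(rng.uniform(-1.0, 1.0))
        beta1[(j, k)] = float(rng.uniform(-40.0, 25.0))
    production = ProductionModel(registry, alpha0, alpha1, beta0, beta1)
    return GroundTruth(glv, production, registry)


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_experiment(
    gt: GroundTruth,
    communities: list,
    cfg: SyntheticConfig,
    t_end: float = DEFAULT_T_END,
    total_inoculum_od: float = DEFAULT_INOCULUM_OD,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Emulate endpoint community measurements.

    Per community x replicate: simulate the gLV dynamics to ``t_end``; the
    measured OD600 is the total endpoint biomass times lognormal noise; read
    counts are multinomial draws at Poisson depth from the true relative
    abundances (with occasional >=1% contamination from a non-member
    species); butyrate applies the production regression to the true
    endpoint, times lognormal noise, floored at 0.

    With ``noiseless=True`` the analytic limit is emitted (exact OD, exact
    relative abundances, no contamination, no metabolite noise) and the
    read-count columns hold expected counts at the mean depth.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    registry = gt.registry
    n = registry.n_species
    memberships = [frozenset(c) for c in communities]
    X0 = np.zeros((len(memberships), n))
    for i, mem in enumerate(memberships):
        X0[i, registry.indices(mem)] = total_inoculum_od / len(mem)
    ends = simulate_endpoints_batch(gt.glv, X0, t_end=t_end)

    rows = []
    sample_counter = 0
    n_rep = 1 if noiseless else cfg.n_replicates
    for i, mem in enumerate(memberships):
        x_true = ends[i]
        od_true = float(x_true.sum())
        but_true = predict_butyrate(gt.production, x_true, mem)
        rel_true = x_true / od_true if od_true > 0 else np.zeros(n)
        for rep in range(n_rep):
            if noiseless:
                od_meas = od_true
                but_meas = but_true
                counts = rel_true * cfg.read_depth_mean
            else:
                od_meas = od_true * float(_lognormal_factor(rng, cfg.od_noise_cv, ()))
                but_meas = max(
                    but_true * float(_lognormal_factor(rng, cfg.metabolite_noise_cv, ())),
                    0.0,
                )
                depth = max(int(rng.poisson(cfg.read_depth_mean)), 1)
                rel = rel_true.copy()
                if rng.uniform() < cfg.contamination_rate:
                    non_members = [s for s in registry.species_ids if s not in mem]
                    if non_members:
                        contam = registry.index(
                            non_members[rng.integers(len(non_members))]
                        )
                        frac = rng.uniform(0.011, 0.05)
                        rel = rel * (1 - frac)
                        rel[contam] += frac
                counts = rng.multinomial(depth, rel / rel.sum())
            row = {
                "sample_id": f"s{sample_counter:05d}",
                "community": registry.community_id(mem),
                "replicate": rep,
                "od600": od_meas,
                "butyrate_mM": but_meas,
            }
            for si, s in enumerate(registry.species_ids):
                row[f"reads_{s}"] = counts[si]
            rows.append(row)
            sample_counter += 1
    return pd.DataFrame(rows)


def monoculture_timeseries(
    gt: GroundTruth,
    cfg: SyntheticConfig,
    t_grid: np.ndarray = MONO_TIME_GRID,
    x0: float = DEFAULT_INOCULUM_OD,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Monoculture OD600 time courses on an 8-point grid over 0-48 h, with
    replicate mean and sd columns."""
    rng = np.random.default_rng(cfg.seed + 2)
    registry = gt.registry
    n = registry.n_species
    X0 = np.eye(n) * x0
    traj = simulate_batch_parameter_sets(
        gt.glv.r[None], gt.glv.a[None], X0, t_end=float(t_grid[-1]),
        dt=0.1, t_record=t_grid,
    )[:, 0]  # (T, n_mono, n_species)
    rows = []
    for si, s in enumerate(registry.species_ids):
        truth = traj[:, si, si]
        if noiseless:
            mean, sd = truth, np.zeros_like(truth)
        else:
            reps = truth[None, :] * _lognormal_factor(
                rng, cfg.od_noise_cv, (cfg.n_replicates, truth.size)
            )
            mean, sd = reps.mean(axis=0), reps.std(axis=0, ddof=1)
        for ti, t in enumerate(t_grid):
            rows.append(
                {"species": s, "time_h": float(t), "od_mean": float(mean[ti]),
                 "od_sd": float(sd[ti])}
            )
    return pd.DataFrame(rows)


def training_data_from_tables(
    mono: pd.DataFrame,
    endpoint: pd.DataFrame,
    registry: SpeciesRegistry,
    total_inoculum_od: float = DEFAULT_INOCULUM_OD,
    t_end: float = DEFAULT_T_END,
) -> TrainingData:
    """Assemble TrainingData from the two CSV schemas.

    ``mono``: columns species, time_h, od_mean, od_sd.  ``endpoint``: an
    experiment table (community, replicate, od600, reads_<id> columns);
    replicates are averaged after converting reads to absolute abundance
    (relative abundance x OD600).
    """
    dynamic = []
    for s, sub in mono.groupby("species", sort=False):
        sub = sub.sort_values("time_h")
        dynamic.append(
            DynamicObservation(
                species=str(s),
                t=sub["time_h"].to_numpy(),
                x=sub["od_mean"].to_numpy(),
                sd=sub["od_sd"].to_numpy(),
                x0=total_inoculum_od,
            )
        )

    read_cols = [c for c in endpoint.columns if c.startswith("reads_")]
    species = [c[len("reads_"):] for c in read_cols]
    idx_map = np.array([registry.index(s) for s in species])
    single = []
    for cid, sub in endpoint.groupby("community", sort=False):
        members = frozenset(str(cid).split("+"))
        abs_reps = []
        for _, row in sub.iterrows():
            counts = row[read_cols].to_numpy(dtype=float)
            total = counts.sum()
            rel = counts / total if total > 0 else np.zeros_like(counts)
            x = np.zeros(registry.n_species)
            x[idx_map] = rel * float(row["od600"])
            abs_reps.append(x)
        abs_reps = np.stack(abs_reps)
        mean = abs_reps.mean(axis=0)
        sd = abs_reps.std(axis=0, ddof=1) if abs_reps.shape[0] > 1 else np.zeros_like(mean)
        # species not inoculated carry no signal (contamination reads aside)
        mask = np.zeros(registry.n_species, dtype=bool)
        mask[registry.indices(members)] = True
        mean[~mask] = 0.0
        sd[~mask] = 0.0
        single.append(
            SingleObservation(
                members=members, x=mean, sd=sd, t_end=t_end,
                x0_total=total_inoculum_od,
            )
        )
    return TrainingData(tuple(dynamic), tuple(single))


def standard_fixture(seed: int = 0, noise: bool = True) -> dict:
    """The small standard dataset used throughout the test suite: an
    8-species pool with 2 butyrate producers, monoculture time series, all
    pairs, and a panel of 3-5-member training communities.

    Returns a dict with keys: config, truth, registry, mono (DataFrame),
    endpoint (DataFrame), training (TrainingData), communities (list).
    """
    cfg = SyntheticConfig(
        n_species=8,
        n_bp=2,
        production_sparsity=4,
        od_noise_cv=0.05 if noise else 0.0,
        metabolite_noise_cv=0.05 if noise else 0.0,
        contamination_rate=0.0,
        seed=seed,
    )
    gt = generate_ground_truth(cfg)
    registry = gt.registry
    rng = np.random.default_rng(seed + 10)
    ids = list(registry.species_ids)
    communities = [frozenset([s]) for s in ids]
    from itertools import combinations as _comb

    communities += [frozenset(p) for p in _comb(ids, 2)]
    for _ in range(30):
        k = int(rng.integers(3, 6))
        communities.append(frozenset(rng.choice(ids, size=k, replace=False).tolist()))
    communities = list(dict.fromkeys(communities))
    mono = monoculture_timeseries(gt, cfg, noiseless=not noise)
    endpoint = simulate_experiment(gt, communities, cfg, noiseless=not noise)
    training = training_data_from_tables(mono, endpoint, registry)
    return {
        "config": cfg,
        "truth": gt,
        "registry": registry,
        "mono": mono,
        "endpoint": endpoint,
        "training": training,
        "communities": communities,
    }
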