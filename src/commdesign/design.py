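"""Community design-space enumeration and ensemble prediction.

Given a fitted gLV parameter ensemble and a production regression, this
module enumerates constrained subsets of the species pool, propagates each
community through simulation and the production model to obtain a predicted
butyrate *distribution* (one sample per ensemble member, summarized by the
median and the 20th-80th percentile band — the 60% confidence interval),
selects designed panels spanning the predicted range together with
richness-matched random panels, and summarizes biodiversity-function
relationships (per-richness percentile curves of butyrate and total
biomass).

Full-pool sweeps (2^25 - 1 communities) use the best-fit parameter set only
and stream through the design space in fixed-size chunks; ensemble
propagation is reserved for panels of up to ~1e5 communities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .glv import (
    DEFAULT_INOCULUM_OD,
    DEFAULT_T_END,
    GLVParameters,
    GLVSimulationError,
    SpeciesRegistry,
    simulate_batch_parameter_sets,
    simulate_endpoints_batch,
)
from .inference import ParameterEnsemble
from .production import ProductionModel, build_features, predict_butyrate

__all__ = [
    "DesignConstraint",
    "PredictionDistribution",
    "enumerate_communities",
    "count_communities",
    "predict_distribution",
    "predict_distributions",
    "select_designed_panel",
    "richness_function_summary",
    "richness_landscape",
    "landscape_summaries",
    "predictions_frame",
]

logger = logging.getLogger(__name__)

CI_PERCENTILES = (20.0, 50.0, 80.0)  # the 60% confidence band plus median


@dataclass(frozen=True)
class DesignConstraint:
    """Constraints on community membership.

    richness_min/max bound the number of inoculated species; ``required``
    species must all be present; at least one member of ``at_least_one_of``
    must be present (when non-empty); ``excluded`` species never appear.
    """

    richness_min: int
    richness_max: int
    required: frozenset[str] = frozenset()
    at_least_one_of: frozenset[str] = frozenset()
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "at_least_one_of", frozenset(self.at_least_one_of))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if self.required & self.excluded:
            raise ValueError("required and excluded sets must be disjoint")
        if self.richness_min < 1 or self.richness_min > self.richness_max:
            raise ValueError("need 1 <= richness_min <= richness_max")

    def validate_pool(self, registry: SpeciesRegistry) -> None:
        for s in self.required | self.at_least_one_of | self.excluded:
            registry.index(s)
        if self.richness_max > registry.n_species:
            raise ValueError("richness_max exceeds pool size")


def enumerate_communities(
    registry: SpeciesRegistry, c: DesignConstraint
) -> Iterator[frozenset[str]]:
    """Yield every membership set satisfying the constraint exactly once, in
    deterministic lexicographic order over the phylogenetic species order."""
    c.validate_pool(registry)
    if len(c.required) > c.richness_max:
        warnings.warn("infeasible constraint: more required species than richness_max")
        return
    pool = [s for s in registry.phylo_order if s not in c.excluded and s not in c.required]
    required = sorted(c.required, key=registry.phylo_order.index)
    alo = c.at_least_one_of
    alo_satisfied = (not alo) or bool(c.required & alo)
    for k in range(c.richness_min, c.richness_max + 1):
        extra = k - len(required)
        if extra < 0 or extra > len(pool):
            continue
        for combo in combinations(pool, extra):
            if not alo_satisfied and not (alo & set(combo)):
                continue
            yield frozenset(required) | frozenset(combo)


def count_communities(registry: SpeciesRegistry, c: DesignConstraint) -> int:
    """Closed-form size of the constrained design space (inclusion-exclusion
    over binomial counts); equals ``len(list(enumerate_communities(...)))``."""
    c.validate_pool(registry)
    if len(c.required) > c.richness_max:
        return 0
    free = [s for s in registry.species_ids if s not in c.excluded and s not in c.required]
    n_free = len(free)
    alo_active = bool(c.at_least_one_of) and not (c.required & c.at_least_one_of)
    n_alo = len(set(c.at_least_one_of) & set(free))
    total = 0
    for k in range(c.richness_min, c.richness_max + 1):
        extra = k - len(c.required)
        if extra < 0:
            continue
        total += comb(n_free, extra)
        if alo_active:
            total -= comb(n_free - n_alo, extra)
    return total


@dataclass(frozen=True)
class PredictionDistribution:
    """Ensemble-propagated butyrate prediction for one community."""

    community: frozenset[str]
    samples: np.ndarray            # predicted butyrate per ensemble member (mM)
    endpoints: np.ndarray          # (n_members, n_species) endpoint abundances
    median: float
    q20: float
    q80: float
    total_bp_abundance: float      # ensemble-median total producer biomass (OD600)

    def __post_init__(self) -> None:
        object.__setattr__(self, "community", frozenset(self.community))
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not (self.q20 <= self.median <= self.q80):
            raise ValueError("percentile summaries must be ordered q20 <= median <= q80")

    @property
    def richness(self) -> int:
        return len(self.community)


def predict_distribution(
    community,
    ens: ParameterEnsemble,
    pm: ProductionModel,
    registry: SpeciesRegistry,
    t_end: float = DEFAULT_T_END,
    total_inoculum_od: float = DEFAULT_INOCULUM_OD,
) -> PredictionDistribution:
    """Simulate one community under every ensemble member and map each
    endpoint composition through the production model."""
    community = frozenset(community)
    x0 = np.zeros(registry.n_species)
    x0[registry.indices(community)] = total_inoculum_od / len(community)
    r_b, a_b = ens.stacked()
    try:
        ends = simulate_batch_parameter_sets(r_b, a_b, x0[None, :], t_end=t_end)[:, 0, :]
    except GLVSimulationError:
        # fall back to per-member simulation so healthy members survive
        ends, failed = [], 0
        for m in ens.members:
            try:
                ends.append(
                    simulate_endpoints_batch(m, x0[None, :], t_end=t_end)[0]
                )
            except GLVSimulationError:
                failed += 1
                logger.warning("ensemble member failed for %s", sorted(community))
        if failed > 0.2 * len(ens):
            raise GLVSimulationError(
                f">20% of ensemble members failed for community {sorted(community)}"
            )
        ends = np.stack(ends)
    samples = np.array([predict_butyrate(pm, e, community) for e in ends])
    q20, med, q80 = np.percentile(samples, CI_PERCENTILES)
    bp_idx = registry.bp_indices
    total_bp = float(np.median(ends[:, bp_idx].sum(axis=1)))
    return PredictionDistribution(
        community, samples, ends, float(med), float(q20), float(q80), total_bp
    )


def predict_distributions(
    communities: Iterable,
    ens: ParameterEnsemble,
    pm: ProductionModel,
    registry: SpeciesRegistry,
    t_end: float = DEFAULT_T_END,
) -> list[PredictionDistribution]:
    return [
        predict_distribution(c, ens, pm, registry, t_end=t_end) for c in communities
    ]


def select_designed_panel(
    preds: list[PredictionDistribution],
    n_low: int,
    n_high: int,
    richness_range: tuple[int, int],
    seed: int = 0,
) -> dict:
    """Extreme-median panel plus a matched random panel.

    Returns the ``n_low`` lowest-median and ``n_high`` highest-median
    communities within the richness range, and a random panel of equal size
    whose richness distribution matches the designed panel's, drawn with the
    given seed from the remaining candidates.
    """
    lo, hi = richness_range
    candidates = [p for p in preds if lo <= p.richness <= hi]
    if len(candidates) < n_low + n_high:
        raise ValueError(
            f"insufficient candidates: need {n_low + n_high}, have {len(candidates)}"
        )
    order = sorted(candidates, key=lambda p: (p.median, sorted(p.community)))
    designed = order[:n_low] + order[len(order) - n_high:]
    designed_ids = {p.community for p in designed}

    rng = np.random.default_rng(seed)
    random_panel: list[PredictionDistribution] = []
    remaining = [p for p in candidates if p.community not in designed_ids]
    for k, want in sorted(
        pd.Series([p.richness for p in designed]).value_counts().items()
    ):
        pool_k = [p for p in remaining if p.richness == k]
        if len(pool_k) < want:
            raise ValueError(
                f"insufficient candidates at richness {k}: need {want}, have {len(pool_k)}"
            )
        picks = rng.choice(len(pool_k), size=want, replace=False)
        chosen = [pool_k[i] for i in sorted(picks)]
        random_panel.extend(chosen)
        chosen_ids = {p.community for p in chosen}
        remaining = [p for p in remaining if p.community not in chosen_ids]
    return {"designed": designed, "random": random_panel}


def richness_function_summary(
    preds: list[PredictionDistribution],
    registry: SpeciesRegistry,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> pd.DataFrame:
    """Per-richness percentiles of predicted (median) butyrate and of total
    endpoint biomass across communities."""
    rows = []
    by_k: dict[int, list[PredictionDistribution]] = {}
    for p in preds:
        by_k.setdefault(p.richness, []).append(p)
    for k in sorted(by_k):
        group = by_k[k]
        but = np.array([p.median for p in group])
        biomass = np.array([float(np.median(p.endpoints.sum(axis=1))) for p in group])
        row = {"richness": k, "n_communities": len(group)}
        for q in percentiles:
            row[f"butyrate_p{q:g}"] = float(np.percentile(but, q))
            row[f"biomass_p{q:g}"] = float(np.percentile(biomass, q))
        rows.append(row)
    return pd.DataFrame(rows)


def richness_landscape(
    registry: SpeciesRegistry,
    params: GLVParameters,
    pm: ProductionModel,
    constraint: DesignConstraint,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    t_end: float = DEFAULT_T_END,
    total_inoculum_od: float = DEFAULT_INOCULUM_OD,
    chunk_size: int = 4096,
) -> pd.DataFrame:
    """Best-fit-parameter sweep of a (possibly huge) design space.

    Streams the enumerated communities in chunks through the batched
    integrator and the production model, accumulating butyrate and total
    biomass per richness level, then reports the requested percentiles.
    Intended for full-pool sweeps where ensemble propagation is infeasible.
    """
    per_k_but: dict[int, list[np.ndarray]] = {}
    per_k_bio: dict[int, list[np.ndarray]] = {}
    coef = pm.coefficient_vector()

    def flush(buffer: list[frozenset]):
        X0 = np.zeros((len(buffer), registry.n_species))
        for i, mem in enumerate(buffer):
            X0[i, registry.indices(mem)] = total_inoculum_od / len(mem)
        ends = simulate_endpoints_batch(params, X0, t_end=t_end)
        for i, mem in enumerate(buffer):
            feats = build_features(ends[i], mem, registry)
            but = max(float(feats @ coef), 0.0)
            k = len(mem)
            per_k_but.setdefault(k, []).append(np.float32(but))
            per_k_bio.setdefault(k, []).append(np.float32(ends[i].sum()))

    buffer: list[frozenset] = []
    for mem in enumerate_communities(registry, constraint):
        buffer.append(mem)
        if len(buffer) >= chunk_size:
            flush(buffer)
            buffer = []
    if buffer:
        flush(buffer)

    rows = []
    for k in sorted(per_k_but):
        but = np.asarray(per_k_but[k], dtype=float)
        bio = np.asarray(per_k_bio[k], dtype=float)
        row = {"richness": k, "n_communities": but.size}
        for q in percentiles:
            row[f"butyrate_p{q:g}"] = float(np.percentile(but, q))
            row[f"biomass_p{q:g}"] = float(np.percentile(bio, q))
        rows.append(row)
    return pd.DataFrame(rows)


def landscape_summaries(
    preds: list[PredictionDistribution],
    registry: SpeciesRegistry,
    group_species: str | None = None,
) -> dict:
    """Composition-function scatter table and rank correlations.

    Per community: total butyrate-producer endpoint abundance, median
    predicted butyrate, and (optionally) a presence/absence group label for
    ``group_species``.  Spearman rank correlation between producer abundance
    and butyrate is reported overall and per group; degenerate (constant)
    groups yield NaN with a warning.
    """
    rows = [
        {
            "community": registry.community_id(p.community),
            "richness": p.richness,
            "total_bp_abundance": p.total_bp_abundance,
            "median_butyrate": p.median,
            "group": (
                f"{group_species}+" if group_species and group_species in p.community
                else f"{group_species}-" if group_species else "all"
            ),
        }
        for p in preds
    ]
    table = pd.DataFrame(rows)

    def rank_corr(sub: pd.DataFrame) -> float:
        x = sub["total_bp_abundance"].to_numpy()
        y = sub["median_butyrate"].to_numpy()
        if len(sub) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("degenerate group: rank correlation undefined")
            return float("nan")
        return float(spearmanr(x, y).statistic)

    correlations = {"all": rank_corr(table)}
    if group_species:
        for g, sub in table.groupby("group"):
            correlations[str(g)] = rank_corr(sub)
    return {"table": table, "rank_correlations": correlations}


def predictions_frame(
    preds: list[PredictionDistribution], registry: SpeciesRegistry
) -> pd.DataFrame:
    """Tidy summary of predictions (one row per community)."""
    rows = []
    for p in preds:
        row = {
            "community": registry.community_id(p.community),
            "richness": p.richness,
            "median_butyrate": p.median,
            "q20": p.q20,
            "q80": p.q80,
            "total_bp_abundance": p.total_bp_abundance,
        }
        mean_end = p.endpoints.mean(axis=0)
        for i, s in enumerate(registry.species_ids):
            row[f"x_{s}"] = float(mean_end[i])
        rows.append(row)
    return pd.DataFrame(rows)
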