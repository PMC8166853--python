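"""End-to-end pipeline: measurement tables -> fitted community-function model.

Chains the stages a design-test-learn iteration needs: assemble training
data from the monoculture and endpoint tables, select the regularization
strength on held-out communities, fit the bootstrap parameter ensemble,
KNN-impute interactions for species pairs never observed together, and fit
the butyrate interaction regression on the measured samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .glv import SpeciesRegistry
from .imputation import impute_ensemble
from .inference import (
    InferenceConfig,
    ParameterEnsemble,
    TrainingData,
    observed_pair_mask,
    sample_posterior_ensemble,
    select_lambda,
    standard_prior,
)
from .production import ProductionModel, build_features, fit_production
from .synthetic import training_data_from_tables

__all__ = ["PipelineResult", "fit_pipeline", "production_training_matrix"]


@dataclass(frozen=True)
class PipelineResult:
    ensemble: ParameterEnsemble
    production: ProductionModel
    lambda_l2: float
    observed: np.ndarray  # (N, N) pair-observation mask used for imputation


def production_training_matrix(
    endpoint: pd.DataFrame, registry: SpeciesRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and butyrate response from an experiment table (one
    row per replicate sample; reads converted to absolute abundance)."""
    read_cols = [c for c in endpoint.columns if c.startswith("reads_")]
    idx_map = np.array([registry.index(c[len("reads_"):]) for c in read_cols])
    feats, y = [], []
    for _, row in endpoint.iterrows():
        members = frozenset(str(row["community"]).split("+"))
        counts = row[read_cols].to_numpy(dtype=float)
        total = counts.sum()
        rel = counts / total if total > 0 else np.zeros_like(counts)
        x = np.zeros(registry.n_species)
        x[idx_map] = rel * float(row["od600"])
        feats.append(build_features(x, members, registry))
        y.append(float(row["butyrate_mM"]))
    return np.stack(feats), np.array(y)


def fit_pipeline(
    mono: pd.DataFrame,
    endpoint: pd.DataFrame,
    registry: SpeciesRegistry,
    cfg: InferenceConfig,
    select_lam: bool = True,
    knn_k: int = 2,
    production_folds: int = 10,
) -> PipelineResult:
    """Run fit -> impute -> production-fit on a pair of measurement tables."""
    data: TrainingData = training_data_from_tables(mono, endpoint, registry)
    prior = standard_prior(registry.n_species)
    lam = (
        select_lambda(data, prior, cfg, registry) if select_lam else cfg.lambda_l2
    )
    ens = sample_posterior_ensemble(data, prior, replace(cfg, lambda_l2=lam), registry)
    observed = observed_pair_mask(data, registry)
    if not observed.all():
        ens = impute_ensemble(ens, observed, registry, k=knn_k)
    X, y = production_training_matrix(endpoint, registry)
    pm = fit_production(X, y, registry, folds=production_folds, seed=cfg.seed)
    return PipelineResult(ens, pm, float(lam), observed)
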