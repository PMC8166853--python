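"""Interaction regression mapping endpoint community composition to butyrate.

Butyrate concentration at the 48-h endpoint is modelled as

    P(T) = sum_{i in BP} (alpha_i0 + alpha_i * X_i(T))
         + sum_{j in BP} sum_{k != j} (beta_jk0 + beta_jk * X_j(T) * X_k(T))

where BP is the butyrate-producer guild, the intercept terms alpha_i0 and
beta_jk0 are active whenever the corresponding species (pair) was inoculated
— attributing production to a producer's presence even if its endpoint
abundance is low — and the beta_jk slopes capture production interactions:
inter-species effects on productivity that are separate from effects on
growth.  Third-order terms are assumed negligible.

Coefficients are fitted with L1 (lasso) regularization; the penalty strength
is chosen on a log-spaced grid by 10-fold cross-validation, taking the value
with the lowest median test mean-squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .glv import SpeciesRegistry

__all__ = [
    "ProductionModel",
    "build_features",
    "feature_names",
    "n_features",
    "fit_production",
    "fit_at_alpha",
    "refit_on_support",
    "predict_butyrate",
]


def _pair_index(registry: SpeciesRegistry) -> list[tuple[str, str]]:
    bp = [s for s in registry.species_ids if s in registry.butyrate_producers]
    return [(j, k) for j in bp for k in registry.species_ids if k != j]


def n_features(registry: SpeciesRegistry) -> int:
    """Closed-form feature count 2|BP| + 2|BP|(N-1)."""
    nbp = len(registry.butyrate_producers)
    return 2 * nbp + 2 * nbp * (registry.n_species - 1)


def feature_names(registry: SpeciesRegistry) -> list[str]:
    bp = [s for s in registry.species_ids if s in registry.butyrate_producers]
    names = []
    for j in bp:
        names += [f"presence[{j}]", f"abundance[{j}]"]
    for j, k in _pair_index(registry):
        names += [f"pair_presence[{j},{k}]", f"pair_product[{j},{k}]"]
    return names


def _indicator_columns(registry: SpeciesRegistry) -> np.ndarray:
    """Boolean mask over feature columns: True for 0/1 presence indicators."""
    nbp = len(registry.butyrate_producers)
    npair = nbp * (registry.n_species - 1)
    mask = np.zeros(2 * nbp + 2 * npair, dtype=bool)
    mask[: 2 * nbp : 2] = True
    mask[2 * nbp :: 2] = True
    return mask


def build_features(
    endpoint: np.ndarray, membership, registry: SpeciesRegistry
) -> np.ndarray:
    """Feature vector for one community.

    Presence and pair-presence indicators are 1 iff the species (both
    species) were inoculated, regardless of endpoint abundance; abundance and
    product features use the endpoint abundances.
    """
    endpoint = np.asarray(endpoint, dtype=float)
    if endpoint.size != registry.n_species:
        raise ValueError("endpoint length must match registry")
    if np.any(endpoint < 0):
        raise ValueError("endpoint abundances must be non-negative")
    membership = frozenset(membership)
    for m in membership:
        registry.index(m)

    bp = [s for s in registry.species_ids if s in registry.butyrate_producers]
    feats = []
    for j in bp:
        inoc = j in membership
        feats += [1.0 if inoc else 0.0, endpoint[registry.index(j)] if inoc else 0.0]
    for j, k in _pair_index(registry):
        both = j in membership and k in membership
        feats += [
            1.0 if both else 0.0,
            endpoint[registry.index(j)] * endpoint[registry.index(k)] if both else 0.0,
        ]
    return np.array(feats)


@dataclass(frozen=True)
class ProductionModel:
    """Fitted coefficients of the interaction regression, keyed by species.

    alpha0/alpha1: per-producer presence intercept (mM) and abundance slope
    (mM OD600^-1); beta0/beta1: per (producer, partner) pair-presence
    intercept (mM) and product slope (mM OD600^-2).
    """

    registry: SpeciesRegistry
    alpha0: dict[str, float]
    alpha1: dict[str, float]
    beta0: dict[tuple[str, str], float]
    beta1: dict[tuple[str, str], float]
    l1_coeff: float = 0.0
    cv_report: dict = field(default_factory=dict)

    def coefficient_vector(self) -> np.ndarray:
        bp = [s for s in self.registry.species_ids if s in self.registry.butyrate_producers]
        coefs = []
        for j in bp:
            coefs += [self.alpha0.get(j, 0.0), self.alpha1.get(j, 0.0)]
        for j, k in _pair_index(self.registry):
            coefs += [self.beta0.get((j, k), 0.0), self.beta1.get((j, k), 0.0)]
        return np.array(coefs)

    @classmethod
    def from_coefficient_vector(
        cls, registry: SpeciesRegistry, coefs: np.ndarray, l1_coeff: float = 0.0,
        cv_report: dict | None = None,
    ) -> "ProductionModel":
        coefs = np.asarray(coefs, dtype=float)
        if coefs.size != n_features(registry):
            raise ValueError("coefficient vector has wrong length")
        bp = [s for s in registry.species_ids if s in registry.butyrate_producers]
        alpha0, alpha1 = {}, {}
        pos = 0
        for j in bp:
            alpha0[j], alpha1[j] = float(coefs[pos]), float(coefs[pos + 1])
            pos += 2
        beta0, beta1 = {}, {}
        for j, k in _pair_index(registry):
            beta0[(j, k)], beta1[(j, k)] = float(coefs[pos]), float(coefs[pos + 1])
            pos += 2
        return cls(registry, alpha0, alpha1, beta0, beta1, l1_coeff, cv_report or {})

    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficient_vector()))


def predict_butyrate(
    model: ProductionModel, endpoint: np.ndarray, membership, clip: bool = True
) -> float:
    """Predicted butyrate (mM) for one community; negative raw predictions
    are reported as 0 mM unless ``clip=False``."""
    feats = build_features(endpoint, membership, model.registry)
    raw = float(feats @ model.coefficient_vector())
    return max(raw, 0.0) if clip else raw


DEFAULT_ALPHA_GRID = np.logspace(-4, 1, 30)


def _scales(X: np.ndarray, registry: SpeciesRegistry) -> np.ndarray:
    """Per-column divisors: std for continuous columns, 1 for indicators."""
    scales = np.ones(X.shape[1])
    cont = ~_indicator_columns(registry)
    sd = X.std(axis=0)
    scales[cont] = np.where(sd[cont] > 0, sd[cont], 1.0)
    return scales


def fit_at_alpha(
    X: np.ndarray, y: np.ndarray, alpha: float, registry: SpeciesRegistry
) -> np.ndarray:
    """Lasso fit at a fixed penalty; continuous features are scaled to unit
    variance for the fit and the coefficients back-transformed.  No global
    intercept: the presence indicators play that role."""
    scales = _scales(X, registry)
    lasso = Lasso(alpha=alpha, fit_intercept=False, max_iter=50000, tol=1e-8)
    with warnings.catch_warnings():
        # the smallest grid penalties on collinear pair features legitimately
        # hit the iteration cap; cross-validation discards them
        warnings.simplefilter("ignore", ConvergenceWarning)
        lasso.fit(X / scales, y)
    return lasso.coef_ / scales


def fit_production(
    X: np.ndarray,
    butyrate: np.ndarray,
    registry: SpeciesRegistry,
    folds: int = 10,
    seed: int = 0,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> ProductionModel:
    """Fit the interaction regression with L1 regularization.

    The penalty is selected on ``alpha_grid`` by ``folds``-fold
    cross-validation (shuffled with ``seed``), choosing the value with the
    lowest median test MSE (ties broken toward the sparser, larger penalty),
    then refitting on all samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(butyrate, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and response must have equal sample counts")
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if np.any(y < 0):
        raise ValueError("butyrate concentrations must be non-negative")

    if np.ptp(y) == 0:
        warnings.warn(
            "constant butyrate response: returning an all-zero coefficient model"
        )
        return ProductionModel.from_coefficient_vector(
            registry, np.zeros(n_features(registry)), float(alpha_grid[-1]),
            {"constant_response": True},
        )

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    grid = np.asarray(alpha_grid, dtype=float)
    fold_mse = np.zeros((grid.size, folds))
    for ai, alpha in enumerate(grid):
        for fi, (tr, te) in enumerate(splits):
            coef = fit_at_alpha(X[tr], y[tr], alpha, registry)
            resid = y[te] - X[te] @ coef
            fold_mse[ai, fi] = np.mean(resid**2)
    med = np.median(fold_mse, axis=1)
    # lowest median MSE; among ties prefer the strongest penalty
    best = np.flatnonzero(med <= med.min() + 1e-12)[-1]
    alpha_star = float(grid[best])
    coefs = fit_at_alpha(X, y, alpha_star, registry)
    report = {
        "alpha_grid": grid.tolist(),
        "median_mse": med.tolist(),
        "fold_mse": fold_mse.tolist(),
        "seed": seed,
        "folds": folds,
    }
    return ProductionModel.from_coefficient_vector(registry, coefs, alpha_star, report)


def refit_on_support(
    model: ProductionModel, X: np.ndarray, y: np.ndarray
) -> ProductionModel:
    """Ordinary least squares restricted to the lasso-selected support
    (debiasing step used when coefficient values, not just support, matter)."""
    coefs = model.coefficient_vector()
    support = np.flatnonzero(coefs)
    new = np.zeros_like(coefs)
    if support.size:
        sol, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        new[support] = sol
    return ProductionModel.from_coefficient_vector(
        model.registry, new, model.l1_coeff, model.cv_report
    )
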