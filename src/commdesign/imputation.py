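"""K-nearest-neighbors imputation of unobserved interaction coefficients.

Training data rarely covers every species pair, so the fitted interaction
matrix has entries that are only as informed as the prior.  Those entries
are filled by KNN imputation over the matrix sorted into phylogenetic order:
each species-row's missing coefficients are replaced by the unweighted mean
of the corresponding column values of its k nearest rows, with row distance
the nan-aware Euclidean metric over commonly observed columns (scaled by
sqrt(total columns / shared columns)).  Imputation is applied independently
to every member of a parameter ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .glv import GLVParameters, SpeciesRegistry
from .inference import ParameterEnsemble

__all__ = [
    "MaskedInteractionMatrix",
    "impute_interactions",
    "impute_ensemble",
    "ImputationError",
    "DEFAULT_K",
]

DEFAULT_K = 2


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaskedInteractionMatrix:
    """Square interaction matrix with NaN marking unobserved entries, and the
    species order (phylogenetic) its rows/columns follow."""

    a: np.ndarray
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "order", tuple(self.order))
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("interaction matrix must be square")
        if len(self.order) != a.shape[0]:
            raise ValueError("order length must match matrix size")
        if np.any(np.isnan(np.diag(a))):
            raise ImputationError("diagonal entries must never be masked")

    @classmethod
    def from_params(
        cls,
        params: GLVParameters,
        observed: np.ndarray,
        registry: SpeciesRegistry,
    ) -> "MaskedInteractionMatrix":
        """Mask ``params.a`` where ``observed`` is False and sort rows and
        columns into the registry's phylogenetic order."""
        perm = registry.phylo_permutation()
        a = params.a.copy()
        a[~np.asarray(observed, dtype=bool)] = np.nan
        return cls(a[np.ix_(perm, perm)], registry.phylo_order)


def impute_interactions(m: MaskedInteractionMatrix, k: int = DEFAULT_K) -> np.ndarray:
    """Fill NaN entries of the matrix by row-neighborhood KNN; observed
    entries are returned unchanged."""
    a = m.a
    if not np.isnan(a).any():
        return a.copy()
    obs = ~np.isnan(a)
    rows_missing = np.flatnonzero((~obs).any(axis=1))
    for i in rows_missing:
        overlap = (obs[i][None, :] & obs).sum(axis=1)
        overlap[i] = 0
        if not np.any(overlap > 0):
            raise ImputationError(
                f"species {m.order[i]!r} shares no observed entries with any other row; "
                "imputation infeasible"
            )
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    filled = imputer.fit_transform(a)
    out = np.where(obs, a, filled)
    return out


def impute_ensemble(
    ens: ParameterEnsemble,
    observed: np.ndarray,
    registry: SpeciesRegistry,
    k: int = DEFAULT_K,
) -> ParameterEnsemble:
    """Impute unobserved interactions independently for each ensemble member,
    returning a new ensemble in registry species order."""
    perm = registry.phylo_permutation()
    inv = np.argsort(perm)
    members = []
    for p in ens.members:
        masked = MaskedInteractionMatrix.from_params(p, observed, registry)
        a_phylo = impute_interactions(masked, k=k)
        members.append(GLVParameters(p.r, a_phylo[np.ix_(inv, inv)]))
    return ParameterEnsemble(tuple(members), {**ens.provenance, "imputed_k": k})
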