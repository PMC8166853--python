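"""Reference synthetic-study recipes.

Self-contained experiments that exercise the full pipeline on generated
data with known ground truth: parameter recovery for the gLV inference,
support recovery for the production regression, and an end-to-end
design-test-learn round (fit -> impute -> production fit -> predict held-out
communities, plus a designed-versus-random panel contrast).  The test suite
and the reproduction script both run these, so the measured numbers always
come from the same study conditions.

Problem sizes are desk-scale: an 8-species pool with 2 producers, which is
large enough for non-trivial interaction structure while keeping each
experiment in the minutes range on one core.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .design import (
    DesignConstraint,
    enumerate_communities,
    predict_distributions,
    select_designed_panel,
)
from .glv import DEFAULT_INOCULUM_OD, simulate_endpoints_batch
from .inference import (
    InferenceConfig,
    fit_map,
    observed_pair_mask,
    select_lambda,
    standard_prior,
)
from .pipeline import fit_pipeline
from .production import (
    build_features,
    feature_names,
    fit_production,
    n_features,
    predict_butyrate,
    refit_on_support,
)
from .synthetic import (
    SyntheticConfig,
    generate_ground_truth,
    monoculture_timeseries,
    simulate_experiment,
    training_data_from_tables,
)

__all__ = [
    "recovery_experiment",
    "support_recovery_experiment",
    "end_to_end_experiment",
]


def _recovery_dataset(seed: int, noise: bool):
    """Training design for parameter recovery: monocultures, all pairs, and
    50 random 4-8-member endpoint communities, with 5% multiplicative
    measurement noise (or none)."""
    cfg = SyntheticConfig(
        n_species=8,
        n_bp=2,
        production_sparsity=4,
        contamination_rate=0.0,
        od_noise_cv=0.05 if noise else 0.0,
        metabolite_noise_cv=0.05 if noise else 0.0,
        seed=seed,
    )
    gt = generate_ground_truth(cfg)
    registry = gt.registry
    rng = np.random.default_rng(seed + 10)
    ids = list(registry.species_ids)
    comms = [frozenset([s]) for s in ids] + [frozenset(p) for p in combinations(ids, 2)]
    for _ in range(50):
        k = int(rng.integers(4, 9))
        comms.append(frozenset(rng.choice(ids, size=k, replace=False).tolist()))
    comms = list(dict.fromkeys(comms))
    mono = monoculture_timeseries(gt, cfg, noiseless=not noise)
    endpoint = simulate_experiment(gt, comms, cfg, noiseless=not noise)
    return gt, registry, training_data_from_tables(mono, endpoint, registry)


def recovery_experiment(seed: int, noise: bool) -> dict:
    """MAP parameter recovery: Pearson correlation between true and inferred
    off-diagonal interaction coefficients for co-observed pairs.

    The regularization strength is selected on held-out endpoint communities
    (the package's standard procedure), then the MAP is refitted on the full
    training set at that value.
    """
    gt, registry, data = _recovery_dataset(seed, noise)
    prior = standard_prior(registry.n_species)
    cfg = InferenceConfig(n_starts=1, seed=seed)
    lam = select_lambda(data, prior, cfg, registry)
    fit = fit_map(data, prior, replace(cfg, lambda_l2=lam), registry)
    off = ~np.eye(registry.n_species, dtype=bool)
    observed = observed_pair_mask(data, registry) & off
    r, _ = pearsonr(gt.glv.a[observed], fit.a[observed])
    return {
        "pearson": float(r),
        "n_pairs": int(observed.sum()),
        "lambda": float(lam),
    }


def support_recovery_experiment(seed: int, n_samples: int = 200) -> dict:
    """Lasso support recovery on noiseless data from a sparse truth.

    The generating model has exactly four nonzero coefficients (producer
    presence, two producer abundances, one negative production interaction).
    Success: the selected support contains the true support and, after an
    ordinary-least-squares refit on the support, every true coefficient has
    the correct sign.
    """
    from .synthetic import make_registry

    rng = np.random.default_rng(seed + 20)
    registry = make_registry(8, 2)
    names = feature_names(registry)
    idx = {n: i for i, n in enumerate(names)}
    bp = sorted(registry.butyrate_producers)
    other = [s for s in registry.species_ids if s not in registry.butyrate_producers][0]
    coef = np.zeros(n_features(registry))
    coef[idx[f"presence[{bp[0]}]"]] = 3.0
    coef[idx[f"abundance[{bp[0]}]"]] = 30.0
    coef[idx[f"abundance[{bp[1]}]"]] = 18.0
    coef[idx[f"pair_product[{bp[0]},{other}]"]] = -25.0

    ids = list(registry.species_ids)
    X, y = [], []
    while len(y) < n_samples:
        k = int(rng.integers(1, len(ids) + 1))
        mem = frozenset(rng.choice(ids, size=k, replace=False).tolist())
        end = np.zeros(len(ids))
        for m in mem:
            end[registry.index(m)] = rng.uniform(0.05, 1.0)
        f = build_features(end, mem, registry)
        val = float(f @ coef)
        if val < 0:
            continue  # butyrate concentrations are physical
        X.append(f)
        y.append(val)
    X, y = np.stack(X), np.array(y)
    model = fit_production(X, y, registry, seed=seed)
    debiased = refit_on_support(model, X, y).coefficient_vector()
    true_support = set(np.flatnonzero(coef))
    support_ok = true_support <= set(np.flatnonzero(model.coefficient_vector()))
    signs_ok = all(np.sign(debiased[i]) == np.sign(coef[i]) for i in true_support)
    return {
        "support_recovered": bool(support_ok),
        "signs_correct": bool(signs_ok),
        "n_selected": model.n_nonzero(),
        "n_samples": int(len(y)),
    }


def end_to_end_experiment(seed: int, n_ensemble: int = 30) -> dict:
    """Full design-test-learn round on the standard synthetic conditions.

    Training data mirror the study design: monocultures, every pairwise
    community containing at least one butyrate producer, and 30 random
    3-5-member producer-containing communities, all at the default 5% noise.
    One producer-free species pair is blinded from training (no training
    community contains both species), so its interaction coefficients must
    come from KNN imputation while held-out communities may contain the
    pair.
    The fitted pipeline predicts 30 held-out 3-6-member producer-containing
    communities; reported are the Spearman rank correlation between
    predicted median and ground-truth butyrate, and the variance contrast
    between a designed panel (extreme predicted medians) and a
    richness-matched random panel.
    """
    cfg = SyntheticConfig(
        n_species=8, n_bp=2, production_sparsity=4, contamination_rate=0.0, seed=seed
    )
    gt = generate_ground_truth(cfg)
    registry = gt.registry
    ids = list(registry.species_ids)
    rng = np.random.default_rng(seed + 100)

    non_bp = [s for s in ids if s not in registry.butyrate_producers]
    blind_pair = frozenset(non_bp[:2])
    bp_pairs = [
        frozenset(p)
        for p in combinations(ids, 2)
        if set(p) & registry.butyrate_producers
    ]
    train = [frozenset([s]) for s in ids] + bp_pairs
    while len(train) < len(ids) + len(bp_pairs) + 30:
        k = int(rng.integers(3, 6))
        c = frozenset(rng.choice(ids, size=k, replace=False).tolist())
        if (
            c & registry.butyrate_producers
            and not blind_pair <= c
            and c not in train
        ):
            train.append(c)

    mono = monoculture_timeseries(gt, cfg)
    endpoint = simulate_experiment(gt, train, cfg)
    icfg = InferenceConfig(n_ensemble=n_ensemble, n_starts=1, seed=seed)
    result = fit_pipeline(mono, endpoint, registry, icfg)

    train_set = set(train)
    held: list[frozenset] = []
    while len(held) < 30:
        k = int(rng.integers(3, 7))
        c = frozenset(rng.choice(ids, size=k, replace=False).tolist())
        if c not in train_set and c not in held and (c & registry.butyrate_producers):
            held.append(c)
    preds = predict_distributions(held, result.ensemble, result.production, registry)
    X0 = np.zeros((len(held), registry.n_species))
    for i, mem in enumerate(held):
        X0[i, registry.indices(mem)] = DEFAULT_INOCULUM_OD / len(mem)
    ends_true = simulate_endpoints_batch(gt.glv, X0)
    true_but = np.array(
        [predict_butyrate(gt.production, ends_true[i], held[i]) for i in range(len(held))]
    )
    pred_med = np.array([p.median for p in preds])
    rho = float(spearmanr(true_but, pred_med).statistic)

    constraint = DesignConstraint(3, 5, at_least_one_of=registry.butyrate_producers)
    cand_preds = predict_distributions(
        list(enumerate_communities(registry, constraint)),
        result.ensemble,
        result.production,
        registry,
    )
    panel = select_designed_panel(
        cand_preds, n_low=10, n_high=20, richness_range=(3, 5), seed=seed
    )
    var_designed = float(np.var([p.median for p in panel["designed"]]))
    var_random = float(np.var([p.median for p in panel["random"]]))
    return {
        "spearman_heldout": rho,
        "n_heldout": len(held),
        "var_designed": var_designed,
        "var_random": var_random,
        "n_unobserved_pairs": int((~result.observed).sum()),
        "lambda": result.lambda_l2,
    }
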