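"""MAP fitting, bootstrap ensembles, prior chaining."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import pearsonr

from commdesign.glv import GLVParameters
from commdesign.inference import (
    DynamicObservation,
    InferenceConfig,
    InferenceError,
    ParameterEnsemble,
    PriorSpec,
    SingleObservation,
    TrainingData,
    cost_at,
    fit_map,
    observed_pair_mask,
    pack,
    posterior_to_prior,
    sample_posterior_ensemble,
    standard_prior,
)
from commdesign.synthetic import (
    SyntheticConfig,
    generate_ground_truth,
    monoculture_timeseries,
    simulate_experiment,
    training_data_from_tables,
)

TGRID = np.array([0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0])


def logistic(t, x0, r, a):
    K = -r / a
    return K * x0 * np.exp(r * t) / (K + x0 * (np.exp(r * t) - 1.0))


def mono_data(registry, r, a_diag, x0=0.0066, sd=0.0):
    obs = []
    for i, s in enumerate(registry.species_ids):
        x = logistic(TGRID, x0, r[i], a_diag[i])
        obs.append(DynamicObservation(s, TGRID, x, np.full_like(x, sd), x0=x0))
    return obs


@pytest.fixture(scope="module")
def noiseless_3sp():
    """Noiseless 3-species dataset: monocultures plus all pairs plus the trio."""
    cfg = SyntheticConfig(
        n_species=3, n_bp=1, production_sparsity=1, contamination_rate=0.0,
        od_noise_cv=0.0, metabolite_noise_cv=0.0, seed=11,
    )
    gt = generate_ground_truth(cfg)
    reg = gt.registry
    ids = list(reg.species_ids)
    comms = [frozenset(p) for p in combinations(ids, 2)] + [frozenset(ids)]
    mono = monoculture_timeseries(gt, cfg, noiseless=True)
    end = simulate_experiment(gt, comms, cfg, noiseless=True)
    return gt, reg, training_data_from_tables(mono, end, reg)


class TestFitMap:
    def test_prior_dominated_limit_returns_prior_mean(self, registry5):
        r = np.full(5, 0.4)
        a_diag = np.full(5, -0.8)
        data = TrainingData(mono_data(registry5, r, a_diag), ())
        prior = standard_prior(5)
        cfg = InferenceConfig(lambda_l2=1e9, n_starts=1)
        fit = fit_map(data, prior, cfg, registry5)
        theta = pack(fit)
        diag = 5 + np.arange(5) * 6
        off = np.setdiff1d(np.arange(30), diag)
        assert np.abs(theta[off]).max() < 1e-3
        assert np.abs(fit.r).max() < 1e-3
        # diagonals pinned at the feasibility bound just below zero
        assert np.all(np.diag(fit.a) < 0)
        assert np.abs(np.diag(fit.a)).max() < 1e-3

    def test_single_species_logistic_recovery(self):
        from commdesign.glv import SpeciesRegistry

        reg = SpeciesRegistry(("A",), frozenset())
        x = logistic(TGRID, 0.0066, 0.4, -0.8)
        data = TrainingData(
            (DynamicObservation("A", TGRID, x, np.zeros_like(x)),), ()
        )
        fit = fit_map(data, standard_prior(1), InferenceConfig(lambda_l2=0.0), reg)
        assert abs(fit.r[0] - 0.4) < 1e-2
        assert abs(fit.a[0, 0] + 0.8) < 1e-2

    def test_three_species_interaction_recovery(self, noiseless_3sp):
        gt, reg, data = noiseless_3sp
        fit = fit_map(
            data, standard_prior(3), InferenceConfig(lambda_l2=1e-4, n_starts=1), reg
        )
        off = ~np.eye(3, dtype=bool)
        r, _ = pearsonr(gt.glv.a[off], fit.a[off])
        assert r > 0.95

    def test_fitted_cost_not_above_projected_prior_mean_cost(self, noiseless_3sp):
        gt, reg, data = noiseless_3sp
        prior = standard_prior(3)
        cfg = InferenceConfig(lambda_l2=0.01, n_starts=1)
        fit = fit_map(data, prior, cfg, reg)
        start = GLVParameters(np.zeros(3), np.diag(np.full(3, -0.05)) )
        assert cost_at(fit, data, prior, reg, cfg) <= cost_at(start, data, prior, reg, cfg) + 1e-9

    def test_regularization_monotonicity(self, noiseless_3sp):
        gt, reg, data = noiseless_3sp
        prior = standard_prior(3)
        norms = []
        for lam in (1e-3, 1e-1, 10.0):
            fit = fit_map(data, prior, InferenceConfig(lambda_l2=lam, n_starts=1), reg)
            z = (pack(fit) - prior.mean) / prior.sd
            norms.append((z**2).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_empty_data_raises(self, registry5):
        with pytest.raises(InferenceError, match="empty"):
            fit_map(TrainingData((), ()), standard_prior(5), InferenceConfig(), registry5)

    def test_all_zero_data_raises(self, registry5):
        obs = [
            DynamicObservation(s, TGRID, np.zeros_like(TGRID), np.zeros_like(TGRID))
            for s in registry5.species_ids
        ]
        with pytest.raises(InferenceError, match="degenerate"):
            fit_map(TrainingData(tuple(obs), ()), standard_prior(5), InferenceConfig(), registry5)


@pytest.fixture(scope="module")
def small_noisy():
    cfg = SyntheticConfig(
        n_species=3, n_bp=1, production_sparsity=1, contamination_rate=0.0, seed=5
    )
    gt = generate_ground_truth(cfg)
    reg = gt.registry
    ids = list(reg.species_ids)
    comms = [frozenset(p) for p in combinations(ids, 2)] + [frozenset(ids)]
    mono = monoculture_timeseries(gt, cfg)
    end = simulate_experiment(gt, comms, cfg)
    return gt, reg, training_data_from_tables(mono, end, reg)


class TestEnsemble:
    def test_zero_replicate_sd_gives_identical_members(self, small_noisy):
        gt, reg, data = small_noisy
        data0 = TrainingData(
            tuple(replace(d, sd=np.zeros_like(d.sd)) for d in data.dynamic),
            tuple(replace(s, sd=np.zeros_like(s.sd)) for s in data.single),
        )
        ens = sample_posterior_ensemble(
            data0, standard_prior(3), InferenceConfig(n_ensemble=4, n_starts=1), reg
        )
        r, a = ens.stacked()
        assert np.ptp(r, axis=0).max() == 0.0
        assert np.ptp(a, axis=0).max() == 0.0

    def test_fixed_seed_reproducible(self, small_noisy):
        gt, reg, data = small_noisy
        cfg = InferenceConfig(n_ensemble=4, n_starts=1, seed=42)
        e1 = sample_posterior_ensemble(data, standard_prior(3), cfg, reg)
        e2 = sample_posterior_ensemble(data, standard_prior(3), cfg, reg)
        for m1, m2 in zip(e1.members, e2.members):
            assert np.array_equal(m1.r, m2.r) and np.array_equal(m1.a, m2.a)

    def test_member_zero_is_unperturbed_map(self, small_noisy):
        gt, reg, data = small_noisy
        cfg = InferenceConfig(n_ensemble=3, n_starts=1, seed=0)
        ens = sample_posterior_ensemble(data, standard_prior(3), cfg, reg)
        direct = fit_map(data, standard_prior(3), cfg, reg)
        assert np.allclose(ens.members[0].a, direct.a)

    def test_ensemble_spread_covers_truth(self, small_noisy):
        gt, reg, data = small_noisy
        cfg = InferenceConfig(n_ensemble=20, n_starts=1, seed=1, lambda_l2=0.01)
        ens = sample_posterior_ensemble(data, standard_prior(3), cfg, reg)
        r, a = ens.stacked()
        mean, sd = a.mean(axis=0), np.maximum(a.std(axis=0), 1e-6)
        obs = observed_pair_mask(data, reg)
        covered = np.abs(gt.glv.a - mean)[obs] <= 3 * sd[obs]
        assert covered.mean() >= 0.8


class TestPosteriorToPrior:
    def _params(self, vals):
        return GLVParameters(np.array([vals[0]]), np.array([[vals[1]]]))

    def test_identical_members_floor_sd(self):
        m = self._params([0.4, -0.8])
        with pytest.warns(UserWarning, match="single-member"):
            prior = posterior_to_prior(ParameterEnsemble((m,)))
        assert np.allclose(prior.mean, [0.4, -0.8])
        assert np.all(prior.sd == 1e-3)

    def test_two_point_statistics(self):
        a = self._params([0.4, -0.8])
        b = self._params([0.6, -0.8])
        prior = posterior_to_prior(ParameterEnsemble((a, b)))
        assert prior.mean[0] == pytest.approx(0.5)
        assert prior.sd[0] == pytest.approx(0.1)  # population sd of {0.4, 0.6}
        assert prior.sd[1] == pytest.approx(1e-3)  # floored

    def test_matches_brute_force_summary(self):
        rng = np.random.default_rng(0)
        members = tuple(
            GLVParameters(rng.uniform(0.1, 0.6, 3), np.diag(-rng.uniform(0.5, 1.5, 3)))
            for _ in range(50)
        )
        prior = posterior_to_prior(ParameterEnsemble(members))
        thetas = np.stack([pack(m) for m in members])
        assert np.allclose(prior.mean, thetas.mean(axis=0))
        assert np.allclose(prior.sd, np.maximum(thetas.std(axis=0), 1e-3))


class TestChaining:
    def test_posterior_as_prior_approximates_joint_fit(self):
        """Two-stage fitting (monocultures, then pairs with the chained
        prior) lands near the one-shot fit on all data."""
        cfg = SyntheticConfig(
            n_species=3, n_bp=1, production_sparsity=1, contamination_rate=0.0,
            od_noise_cv=0.0, metabolite_noise_cv=0.0, seed=21,
        )
        gt = generate_ground_truth(cfg)
        reg = gt.registry
        ids = list(reg.species_ids)
        comms = [frozenset(p) for p in combinations(ids, 2)] + [frozenset(ids)]
        mono = monoculture_timeseries(gt, cfg, noiseless=True)
        end = simulate_experiment(gt, comms, cfg, noiseless=True)
        data = training_data_from_tables(mono, end, reg)

        icfg = InferenceConfig(lambda_l2=1e-3, n_starts=1, n_ensemble=8, seed=0)
        joint = fit_map(data, standard_prior(3), icfg, reg)

        stage1 = TrainingData(data.dynamic, ())
        ens1 = sample_posterior_ensemble(stage1, standard_prior(3), icfg, reg)
        chained_prior = posterior_to_prior(ens1)
        stage2 = TrainingData((), data.single)
        final = fit_map(stage2, chained_prior, icfg, reg)

        r, _ = pearsonr(pack(joint), pack(final))
        assert r > 0.8


def test_observed_pair_mask(registry5):
    ids = registry5.species_ids
    data = TrainingData(
        (DynamicObservation(ids[0], TGRID, np.ones_like(TGRID), np.zeros_like(TGRID)),),
        (
            SingleObservation(
                frozenset({ids[1], ids[2]}), np.zeros(5), np.zeros(5)
            ),
        ),
    )
    mask = observed_pair_mask(data, registry5)
    assert mask[0, 0] and mask[1, 2] and mask[2, 1] and mask[1, 1]
    assert not mask[0, 1] and not mask[3, 3]


def test_prior_spec_validation():
    with pytest.raises(ValueError, match="positive"):
        PriorSpec(np.zeros(2), np.array([1.0, 0.0]))
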