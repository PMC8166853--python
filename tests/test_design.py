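"""Design-space enumeration/counting, ensemble prediction, panels, and
biodiversity-function summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from commdesign.design import (
    DesignConstraint,
    count_communities,
    enumerate_communities,
    landscape_summaries,
    predict_distribution,
    predict_distributions,
    predictions_frame,
    richness_function_summary,
    richness_landscape,
    select_designed_panel,
)
from commdesign.glv import GLVParameters, SpeciesRegistry, default_registry
from commdesign.inference import ParameterEnsemble
from commdesign.production import ProductionModel
from commdesign.synthetic import make_registry
from conftest import random_glv


class TestEnumerationAndCounting:
    def test_three_species_power_set(self):
        reg = SpeciesRegistry(("A", "B", "C"), frozenset())
        c = DesignConstraint(1, 3)
        subsets = list(enumerate_communities(reg, c))
        assert len(subsets) == 7
        assert len(set(subsets)) == 7
        assert count_communities(reg, c) == 7

    def test_deterministic_lexicographic_order(self):
        reg = SpeciesRegistry(("A", "B", "C"), frozenset())
        subsets = list(enumerate_communities(reg, DesignConstraint(1, 2)))
        assert subsets == [
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"}),
            frozenset({"A", "B"}), frozenset({"A", "C"}), frozenset({"B", "C"}),
        ]

    @pytest.mark.parametrize(
        "constraint",
        [
            DesignConstraint(1, 10),
            DesignConstraint(3, 5, at_least_one_of=frozenset({"S00", "S01"})),
            DesignConstraint(2, 6, required=frozenset({"S03"})),
            DesignConstraint(2, 6, excluded=frozenset({"S04", "S05"})),
            DesignConstraint(
                3, 7,
                required=frozenset({"S02"}),
                at_least_one_of=frozenset({"S00", "S06"}),
                excluded=frozenset({"S09"}),
            ),
        ],
    )
    def test_count_equals_enumeration(self, constraint):
        reg = SpeciesRegistry(tuple(f"S{i:02d}" for i in range(10)), frozenset())
        enumerated = list(enumerate_communities(reg, constraint))
        assert len(enumerated) == len(set(enumerated))
        assert count_communities(reg, constraint) == len(enumerated)

    def test_study_design_space_sizes(self):
        reg = default_registry()
        bp = reg.butyrate_producers
        assert count_communities(
            reg, DesignConstraint(3, 5, at_least_one_of=bp)
        ) == 46_591
        assert count_communities(
            reg, DesignConstraint(5, 25, required=bp)
        ) == 1_048_576
        ac_excluded = DesignConstraint(
            4, 25, required=bp - {"AC"}, excluded=frozenset({"AC"})
        )
        assert count_communities(reg, ac_excluded) == 1_048_576
        assert count_communities(reg, DesignConstraint(1, 25)) == 33_554_431

    def test_infeasible_constraint_warns_and_is_empty(self):
        reg = SpeciesRegistry(("A", "B", "C"), frozenset())
        c = DesignConstraint(1, 1, required=frozenset({"A", "B"}))
        with pytest.warns(UserWarning, match="infeasible"):
            assert list(enumerate_communities(reg, c)) == []
        assert count_communities(reg, c) == 0


@pytest.fixture(scope="module")
def tiny_setup():
    """5-species registry, a 3-member hand-controllable ensemble, and a
    simple production model."""
    reg = make_registry(5, 1)
    bp = sorted(reg.butyrate_producers)[0]
    members = tuple(random_glv(5, seed=s) for s in (1, 2, 3))
    ens = ParameterEnsemble(members)
    pm = ProductionModel(reg, alpha0={bp: 2.0}, alpha1={bp: 30.0}, beta0={}, beta1={})
    return reg, ens, pm, bp


class TestPredictDistribution:
    def test_identical_members_zero_width_interval(self, tiny_setup):
        reg, _, pm, bp = tiny_setup
        m = random_glv(5, seed=4)
        ens = ParameterEnsemble((m, m, m))
        pred = predict_distribution({bp, reg.species_ids[1]}, ens, pm, reg)
        assert pred.q20 == pred.median == pred.q80

    def test_bp_free_community_is_all_zero(self, tiny_setup):
        reg, ens, pm, bp = tiny_setup
        others = [s for s in reg.species_ids if s != bp][:3]
        pred = predict_distribution(set(others), ens, pm, reg)
        assert np.all(pred.samples == 0.0)
        assert pred.median == 0.0

    def test_percentiles_match_sort_based_oracle(self, tiny_setup):
        reg, _, pm, bp = tiny_setup
        members = tuple(random_glv(5, seed=s) for s in range(5))
        ens = ParameterEnsemble(members)
        pred = predict_distribution(set(reg.species_ids), ens, pm, reg)
        assert pred.q20 == pytest.approx(np.percentile(np.sort(pred.samples), 20))
        assert pred.median == pytest.approx(np.percentile(np.sort(pred.samples), 50))
        assert pred.q80 == pytest.approx(np.percentile(np.sort(pred.samples), 80))
        assert pred.q20 <= pred.median <= pred.q80

    def test_percentile_ordering_holds(self, tiny_setup):
        reg, ens, pm, _ = tiny_setup
        for k in (2, 3, 5):
            pred = predict_distribution(set(reg.species_ids[:k]), ens, pm, reg)
            assert pred.q20 <= pred.median <= pred.q80


def _fake_preds(medians, richness, reg, seed=0):
    rng = np.random.default_rng(seed)
    preds = []
    ids = list(reg.species_ids)
    used = set()
    from commdesign.design import PredictionDistribution

    for med, k in zip(medians, richness):
        while True:
            mem = frozenset(rng.choice(ids, size=k, replace=False).tolist())
            if mem not in used:
                used.add(mem)
                break
        ends = np.tile(np.linspace(0.1, 0.2, reg.n_species), (3, 1))
        preds.append(
            PredictionDistribution(
                mem, np.full(3, med), ends, float(med), float(med), float(med),
                total_bp_abundance=float(med) / 2.0,
            )
        )
    return preds


class TestPanels:
    def test_selects_extremes(self, registry8):
        preds = _fake_preds(range(1, 11), [3] * 10, registry8)
        panel = select_designed_panel(preds, n_low=2, n_high=2, richness_range=(3, 5), seed=0)
        meds = sorted(p.median for p in panel["designed"])
        assert meds == [1.0, 2.0, 9.0, 10.0]
        assert len(panel["random"]) == 4
        assert {p.richness for p in panel["random"]} == {3}

    def test_all_candidates_when_panel_covers_them(self, registry8):
        preds = _fake_preds(range(1, 5), [3] * 4, registry8)
        with pytest.raises(ValueError, match="insufficient"):
            # nothing left for the matched random panel
            select_designed_panel(preds, n_low=2, n_high=2, richness_range=(3, 5), seed=0)
        panel = select_designed_panel(
            _fake_preds(range(1, 9), [3] * 8, registry8),
            n_low=2, n_high=2, richness_range=(3, 5), seed=0,
        )
        assert len(panel["designed"]) == 4

    def test_fixed_seed_reproducible_random_panel(self, registry8):
        preds = _fake_preds(range(1, 21), [3, 4] * 10, registry8)
        p1 = select_designed_panel(preds, 3, 3, (3, 5), seed=9)
        p2 = select_designed_panel(preds, 3, 3, (3, 5), seed=9)
        assert [p.community for p in p1["random"]] == [p.community for p in p2["random"]]

    def test_designed_variance_exceeds_random(self, registry8):
        rng = np.random.default_rng(2)
        meds = rng.uniform(0, 40, 60)
        preds = _fake_preds(meds, rng.integers(3, 6, 60).tolist(), registry8, seed=2)
        panel = select_designed_panel(preds, 10, 10, (3, 5), seed=0)
        v_d = np.var([p.median for p in panel["designed"]])
        v_r = np.var([p.median for p in panel["random"]])
        assert v_d >= v_r


class TestRichnessSummaries:
    def test_single_community_level(self, registry8):
        preds = _fake_preds([7.0], [4], registry8)
        table = richness_function_summary(preds, registry8)
        row = table.iloc[0]
        assert row["richness"] == 4
        assert row["butyrate_p5"] == row["butyrate_p50"] == row["butyrate_p95"] == 7.0

    def test_landscape_matches_exhaustive_recomputation(self):
        """Streaming best-fit sweep over all 1,023 subsets of a 10-species
        pool equals a direct brute-force recomputation."""
        reg = make_registry(10, 2)
        params = random_glv(10, seed=6)
        bp = sorted(reg.butyrate_producers)
        pm = ProductionModel(
            reg,
            alpha0={b: 1.0 for b in bp},
            alpha1={b: 20.0 for b in bp},
            beta0={},
            beta1={},
        )
        c = DesignConstraint(1, 10)
        table = richness_landscape(reg, params, pm, c, chunk_size=100)
        assert table["n_communities"].sum() == 1023

        # independent recomputation
        from commdesign.glv import simulate_endpoints_batch
        from commdesign.production import predict_butyrate

        by_k = {}
        ids = list(reg.species_ids)
        for k in range(1, 11):
            for mem in combinations(ids, k):
                x0 = np.zeros(10)
                for m in mem:
                    x0[reg.index(m)] = 0.0066 / k
                end = simulate_endpoints_batch(params, x0[None])[0]
                but = predict_butyrate(pm, end, frozenset(mem))
                by_k.setdefault(k, []).append((but, end.sum()))
        for _, row in table.iterrows():
            but, bio = zip(*by_k[int(row["richness"])])
            assert row["butyrate_p50"] == pytest.approx(
                np.percentile(np.asarray(but, dtype=np.float32), 50), rel=1e-5
            )
            assert row["biomass_p95"] == pytest.approx(
                np.percentile(np.asarray(bio, dtype=np.float32), 95), rel=1e-5
            )


class TestLandscapeSummaries:
    def test_monotone_map_gives_perfect_rank_correlation(self, registry8):
        meds = np.linspace(1, 30, 15)
        preds = _fake_preds(meds, [3] * 15, registry8)
        # total_bp_abundance = median / 2 by construction: monotone
        out = landscape_summaries(preds, registry8)
        assert out["rank_correlations"]["all"] == pytest.approx(1.0)

    def test_constant_landscape_is_nan_with_warning(self, registry8):
        preds = _fake_preds([5.0] * 6, [3] * 6, registry8)
        with pytest.warns(UserWarning, match="degenerate"):
            out = landscape_summaries(preds, registry8)
        assert np.isnan(out["rank_correlations"]["all"])

    def test_matches_independent_rank_correlation(self, registry8):
        rng = np.random.default_rng(8)
        meds = rng.uniform(0, 50, 50)
        preds = _fake_preds(meds, [4] * 50, registry8, seed=5)
        # perturb bp abundance so the relation is monotone-ish but not exact
        out = landscape_summaries(preds, registry8)
        from scipy.stats import spearmanr

        x = [p.total_bp_abundance for p in preds]
        y = [p.median for p in preds]
        assert out["rank_correlations"]["all"] == pytest.approx(
            spearmanr(x, y).statistic
        )

    def test_group_labels_by_species_presence(self, registry8):
        rng = np.random.default_rng(3)
        meds = rng.uniform(0, 50, 30)
        preds = _fake_preds(meds, [4] * 30, registry8, seed=3)
        sp = registry8.species_ids[0]
        out = landscape_summaries(preds, registry8, group_species=sp)
        table = out["table"]
        assert set(table["group"]) <= {f"{sp}+", f"{sp}-"}


def test_predictions_frame_round_trips_summaries(tiny_setup):
    reg, ens, pm, bp = tiny_setup
    preds = predict_distributions(
        [frozenset({bp, reg.species_ids[1]}), frozenset(reg.species_ids[:3])],
        ens, pm, reg,
    )
    frame = predictions_frame(preds, reg)
    assert list(frame["median_butyrate"]) == [p.median for p in preds]
    assert frame.shape[0] == 2
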