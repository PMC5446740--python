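"""Enrichment statistics, FDR, seed-pruning cross-validation and the
random connected-module null."""

import itertools
import math

import numpy as np
import pytest

from phenomod import (
    ProteinNetwork,
    bh_fdr,
    empirical_p_value,
    enrich_predictions,
    hypergeometric_tail,
    pathway_enrichment,
    predicted_coherence,
    prune_seed_for_cv,
    random_connected_expansion,
    recovery_rate,
)
from phenomod.network import is_connected_in


def enumeration_tail(k, K, n, N):
    """Independent oracle: enumerate every size-n draw from the population."""
    population = list(range(N))
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricTail:
    def test_zero_hits_certain(self):
        assert hypergeometric_tail(0, 4, 3, 10) == 1.0

    def test_impossible_hits(self):
        assert hypergeometric_tail(4, 4, 3, 10) == 0.0
        assert hypergeometric_tail(5, 10, 4, 10) == 0.0

    def test_enumerated_example(self):
        # N=10, K=4, n=3, k=2: (C(4,2)C(6,1)+C(4,3))/C(10,3) = 40/120
        assert hypergeometric_tail(2, 4, 3, 10) == pytest.approx(1 / 3)

    def test_matches_exhaustive_enumeration_small_populations(self):
        """All parameter combinations with N <= 12 agree with draw-by-draw
        enumeration."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeometric_tail(k, K, n, N) == pytest.approx(
                            enumeration_tail(k, K, n, N), abs=1e-12
                        )

    def test_non_increasing_in_k(self):
        for N, K, n in [(20, 7, 9), (15, 15, 4), (30, 3, 10)]:
            ps = [hypergeometric_tail(k, K, n, N) for k in range(min(K, n) + 2)]
            assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 11, 3, 10)


class TestBhFdr:
    def test_single_value_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_equal_values_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_example(self):
        # p*m/rank with tail minima: (0.04, 0.04, 0.05333..., 0.5)
        assert bh_fdr([0.01, 0.02, 0.04, 0.5]) == pytest.approx(
            [0.04, 0.04, 0.04 * 4 / 3, 0.5]
        )

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        assert all(qi >= pi - 1e-12 for pi, qi in zip(p, q))

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(1)
        p = rng.random(40) ** 3
        alpha = 0.05
        q = bh_fdr(p)
        bonferroni = {i for i, pi in enumerate(p) if pi * len(p) < alpha}
        bh = {i for i, qi in enumerate(q) if qi < alpha}
        assert bonferroni <= bh

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestPruneSeedForCv:
    def test_two_protein_seed_removes_one(self):
        net = ProteinNetwork([("a", "b")])
        rng = np.random.default_rng(0)
        pruned, removed = prune_seed_for_cv({"a", "b"}, net, rng)
        assert len(removed) == 1 and len(pruned) == 1
        assert pruned | removed == {"a", "b"}

    def test_size_one_seed_dismissed(self):
        net = ProteinNetwork([("a", "b")])
        assert prune_seed_for_cv({"a"}, net, np.random.default_rng(0)) is None

    def test_star_seed_stays_connected_under_any_rng(self):
        """Even when the hub is removable, the anchor convention keeps the
        pruned seed connected and non-empty."""
        edges = [("hub", f"l{i}") for i in range(9)]
        net = ProteinNetwork(edges)
        seed = {"hub"} | {f"l{i}" for i in range(9)}
        for rng_seed in range(30):
            result = prune_seed_for_cv(seed, net, np.random.default_rng(rng_seed))
            assert result is not None
            pruned, removed = result
            assert pruned and is_connected_in(pruned, net)
            assert pruned | removed == seed and not pruned & removed
            assert len(removed) >= math.ceil(0.1 * len(seed))

    def test_partition_invariant_on_random_chains(self):
        chain = [(f"p{i}", f"p{i+1}") for i in range(19)]
        net = ProteinNetwork(chain)
        seed = {f"p{i}" for i in range(20)}
        for rng_seed in range(10):
            pruned, removed = prune_seed_for_cv(seed, net, np.random.default_rng(rng_seed))
            assert pruned | removed == seed
            assert not pruned & removed
            assert is_connected_in(pruned, net)
            assert len(removed) >= 2  # ceil(0.1 * 20)


class TestRecoveryRate:
    def test_full_recovery(self):
        held = {"d1": {"a", "b"}}
        assert recovery_rate({"d1": {"a", "b", "c"}}, held) == 1.0

    def test_no_recovery(self):
        assert recovery_rate({"d1": {"x"}}, {"d1": {"a"}}) == 0.0

    def test_partial(self):
        held = {"d1": {"a", "b", "c", "d"}, "d2": {"e", "f", "g", "h"}}
        pred = {"d1": {"a"}, "d2": {"e", "z"}}
        assert recovery_rate(pred, held) == pytest.approx(0.25)

    def test_empty_held_out_rejected(self):
        with pytest.raises(ValueError):
            recovery_rate({"d1": {"a"}}, {})


class TestEnrichPredictions:
    def test_perfect_predictions_minimal_p(self):
        universe = {f"p{i}" for i in range(40)}
        gold = {"d1": {"p0", "p1", "p2"}, "d2": {"p5", "p6"}}
        pooled, per = enrich_predictions(gold, gold, universe)
        assert all(r.k == r.n for r in per)
        assert pooled.p_value < 1e-4

    def test_disjoint_predictions_p_one(self):
        universe = {f"p{i}" for i in range(40)}
        gold = {"d1": {"p0", "p1"}}
        pred = {"d1": {"p10", "p11"}}
        pooled, per = enrich_predictions(pred, gold, universe)
        assert per[0].k == 0 and per[0].p_value == 1.0
        assert pooled.p_value == 1.0

    def test_per_disease_matches_direct_tail(self):
        universe = {f"p{i}" for i in range(20)}
        gold = {"d1": {"p0", "p1", "p2", "p3"}, "d2": {"p4", "p5"}}
        pred = {"d1": {"p0", "p1", "p9"}, "d2": {"p4", "p10", "p11"}}
        _, per = enrich_predictions(pred, gold, universe)
        by_label = {r.label: r for r in per}
        assert by_label["d1"].p_value == pytest.approx(hypergeometric_tail(2, 4, 3, 20))
        assert by_label["d2"].p_value == pytest.approx(hypergeometric_tail(1, 2, 3, 20))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_predictions({}, {}, set())


class TestPathwayEnrichment:
    def test_module_equal_to_pathway_is_top_hit(self):
        universe = {f"p{i}" for i in range(100)}
        pathways = {"pw_hit": {"p0", "p1", "p2", "p3"}, "pw_other": {"p50", "p51"}}
        modules = {"d1": {"p0", "p1", "p2", "p3"}}
        results, counts = pathway_enrichment(modules, pathways, universe)
        by_name = {r.label: r for r in results["d1"]}
        assert by_name["pw_hit"].q_value < 0.05
        assert counts["d1"] >= 1

    def test_random_module_hit_count_near_expectation(self):
        rng = np.random.default_rng(0)
        universe = {f"p{i}" for i in range(200)}
        pathway = {f"p{i}" for i in range(20)}  # K=20, N=200
        n = 30
        hits = [
            len(set(rng.choice(sorted(universe), size=n, replace=False)) & pathway)
            for _ in range(300)
        ]
        assert np.mean(hits) == pytest.approx(n * 20 / 200, rel=0.15)

    def test_zero_enriched_pathways_counts_zero(self):
        universe = {f"p{i}" for i in range(100)}
        pathways = {"pw": {"p90", "p91", "p92"}}
        results, counts = pathway_enrichment({"d1": {"p0", "p1"}}, pathways, universe)
        assert counts["d1"] == 0

    def test_empty_pathways_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"d1": {"p0"}}, {}, {"p0"})


class TestPredictedCoherence:
    def test_predictions_inside_reference_union(self):
        universe = {f"p{i}" for i in range(20)}
        ref = {"pw": {"p0", "p1", "p2", "p3"}}
        res = predicted_coherence({"p0", "p1"}, ref, universe)
        assert res.k == res.n == 2
        assert res.p_value < 0.1

    def test_disjoint_predictions_p_one(self):
        universe = {f"p{i}" for i in range(20)}
        ref = {"pw": {"p0", "p1"}}
        res = predicted_coherence({"p10", "p11"}, ref, universe)
        assert res.k == 0 and res.p_value == 1.0

    def test_enumerated_fixture(self):
        # N=20, union K=8, n=5, k=4
        universe = {f"p{i}" for i in range(20)}
        ref = {"pw": {f"p{i}" for i in range(8)}}
        predicted = {"p0", "p1", "p2", "p3", "p15"}
        res = predicted_coherence(predicted, ref, universe)
        assert res.p_value == pytest.approx(enumeration_tail(4, 8, 5, 20), abs=1e-12)

    def test_empty_reference_union_signals_undefined(self):
        assert predicted_coherence({"p0"}, {}, {"p0", "p1"}) is None


class TestRandomConnectedExpansion:
    @pytest.fixture
    def net(self):
        rng = np.random.default_rng(12)
        from conftest import random_network
        return random_network(rng, n=30, p=0.15)

    def test_target_equal_seed_returns_seed(self, net):
        nodes = sorted(net.nodes)
        seed = {nodes[0]}
        rng = np.random.default_rng(0)
        assert random_connected_expansion(seed, 1, net, rng) == seed

    def test_target_beyond_component_rejected(self):
        net = ProteinNetwork([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError):
            random_connected_expansion({"a"}, 3, net, np.random.default_rng(0))

    def test_hundred_draws_valid(self, net):
        nodes = sorted(net.nodes)
        seed = {nodes[0]}
        for i in range(100):
            rng = np.random.default_rng(i)
            module = random_connected_expansion(seed, 8, net, rng)
            assert len(module) == 8
            assert seed <= module
            assert is_connected_in(module, net)


class TestEmpiricalPValue:
    def test_add_one_bounds(self):
        rng = np.random.default_rng(0)
        nulls = list(rng.random(100))
        for obs in [-1.0, 0.5, 2.0]:
            p = empirical_p_value(obs, nulls)
            assert 1 / 101 <= p <= 1.0

    def test_extremes(self):
        nulls = [0.1] * 100
        assert empirical_p_value(5.0, nulls) == pytest.approx(1 / 101)
        assert empirical_p_value(0.0, nulls) == pytest.approx(1.0)
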