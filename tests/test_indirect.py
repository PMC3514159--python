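"""Second-degree expansion and the seed-randomization permutation null."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from y2hnet._bitset import SecondDegreeEngine
from y2hnet.indirect import (
    PermutationConfig,
    bonferroni,
    empirical_fdr,
    exhaustive_null_counts,
    observed_pathway_counts,
    run_indirect_enrichment,
    sample_null_seed_sets,
    second_degree,
)
from y2hnet.io import GeneSet, GeneSetCollection, PPINetwork


class TestSecondDegree:
    def test_star(self):
        net = PPINetwork("cabde", [("c", x) for x in "abde"])
        assert second_degree(net, {"c"}) == {"a", "b", "d", "e"}

    def test_path_interior(self):
        net = PPINetwork("abc", [("a", "b"), ("b", "c")])
        assert second_degree(net, {"a", "c"}) == {"b"}

    def test_self_loop_contributes_nothing(self):
        net = PPINetwork("ab", [("a", "a"), ("a", "b")])
        assert second_degree(net, {"b"}) == {"a"}
        # seed whose only edge is a self-loop expands to the empty set
        loop_only = PPINetwork("ab", [("a", "a")])
        assert second_degree(loop_only, {"a"}) == frozenset()

    def test_bait_excluded(self):
        net = PPINetwork("abc", [("a", "b"), ("a", "c")])
        assert second_degree(net, {"a"}, bait="c") == {"b"}

    def test_no_seed_in_network_raises(self, toy_network):
        with pytest.raises(ValueError, match="seed"):
            second_degree(toy_network, {"zz"})

    def test_partially_absent_seeds_warn(self, toy_network, caplog):
        with caplog.at_level("WARNING"):
            out = second_degree(toy_network, {"a", "zz"})
        assert "absent" in caplog.text
        assert out == toy_network.neighbors("a") - {"a"}


class TestObservedCounts:
    def test_intersection(self, toy_collection):
        counts = observed_pathway_counts({"b", "d", "x"}, toy_collection)
        assert counts == {"P1": 2, "P2": 0}

    def test_subset_pathway(self, toy_collection):
        counts = observed_pathway_counts({"e", "f", "a"}, toy_collection)
        assert counts["P2"] == 2


class TestNullSampling:
    def test_deterministic_and_sized(self, toy_network):
        cfg = PermutationConfig(n_trials=3, rng_seed=17)
        first = sample_null_seed_sets(toy_network, 2, cfg)
        second = sample_null_seed_sets(toy_network, 2, cfg)
        assert first == second
        assert all(len(s) == 2 for s in first)

    def test_k_equals_n_draws_everything(self, toy_network):
        cfg = PermutationConfig(n_trials=2, rng_seed=1)
        draws = sample_null_seed_sets(toy_network, 6, cfg)
        assert all(s == toy_network.nodes for s in draws)

    def test_k_too_large_rejected(self, toy_network):
        with pytest.raises(ValueError):
            sample_null_seed_sets(toy_network, 7, PermutationConfig(n_trials=1))

    def test_uniform_inclusion_frequency(self):
        # 10 nodes, k=2: each node included with probability 0.2; the
        # observed frequency over 10,000 trials must sit within 3 binomial
        # standard deviations
        nodes = [f"n{i}" for i in range(10)]
        net = PPINetwork(nodes, [(nodes[i], nodes[i + 1]) for i in range(9)])
        cfg = PermutationConfig(n_trials=10_000, rng_seed=5)
        draws = sample_null_seed_sets(net, 2, cfg)
        sd = (0.2 * 0.8 / 10_000) ** 0.5
        for node in nodes:
            freq = sum(node in s for s in draws) / 10_000
            assert abs(freq - 0.2) <= 3 * sd

    def test_degree_matched_preserves_bin_counts(self):
        # hub + chain: the hub occupies the top degree bin alone, so a
        # degree-matched null for a hub-containing seed set must always
        # include the hub
        nodes = [f"n{i}" for i in range(12)]
        edges = [("hub", n) for n in nodes] + [
            (nodes[i], nodes[i + 1]) for i in range(11)
        ]
        net = PPINetwork(nodes + ["hub"], edges)
        cfg = PermutationConfig(
            n_trials=20, rng_seed=3, sampling="degree_matched"
        )
        draws = sample_null_seed_sets(
            net, 2, cfg, reference_seeds={"hub", "n5"}
        )
        assert all("hub" in s for s in draws)


class TestEmpiricalFdr:
    def test_zero_obs_is_one(self):
        assert empirical_fdr(0, [0, 1, 2]) == 1.0

    def test_direct_proportion(self):
        assert empirical_fdr(2, [0, 0, 1, 2]) == 0.25

    def test_obs_beyond_null(self):
        assert empirical_fdr(5, [0, 1]) == 0.0
        assert empirical_fdr(5, [0, 1], smoothing="add_one") == pytest.approx(
            1 / 3
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=40),
        st.integers(0, 11),
    )
    def test_monotone_in_obs_and_bounded(self, null, obs):
        lo = empirical_fdr(obs + 1, null)
        hi = empirical_fdr(obs, null)
        assert 0.0 <= lo <= hi <= 1.0


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(5.00e-5, 628, 3.14e-2), (1.00e-4, 150, 1.50e-2), (0.2, 10, 1.0)],
    )
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestEngineMatchesSetRoute:
    """The bit-packed permutation engine must agree with the set algebra."""

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_counts_agree_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        nodes = [f"n{i}" for i in range(n)]
        m = int(rng.integers(n, 3 * n))
        pairs = rng.integers(0, n, size=(m, 2))
        net = PPINetwork(nodes, [(nodes[i], nodes[j]) for i, j in pairs])
        coll = {
            f"P{p}": frozenset(
                nodes[i] for i in rng.choice(n, size=max(1, n // 4),
                                             replace=False)
            )
            for p in range(3)
        }
        bait = nodes[0]
        engine = SecondDegreeEngine(net, coll, bait=bait)
        k = int(rng.integers(1, min(6, n)))
        seeds = frozenset(
            nodes[i] for i in rng.choice(n, size=k, replace=False)
        )
        expanded = second_degree(net, seeds, bait)
        expected = {
            pid: len(expanded & members) for pid, members in coll.items()
        }
        got = engine.counts_for_seed_indices(engine.indices_of(seeds))
        assert {
            pid: int(got[i]) for i, pid in enumerate(engine.pathway_ids)
        } == expected
        assert engine.indirect_size(engine.indices_of(seeds)) == len(expanded)


class TestRunIndirect:
    def test_monte_carlo_matches_exhaustive_on_toy(
        self, toy_network, toy_collection
    ):
        pids, counts = exhaustive_null_counts(toy_network, 2, toy_collection)
        assert counts.shape == (15, 2)  # C(6,2) seed pairs
        cfg = PermutationConfig(n_trials=50_000, rng_seed=3)
        res = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [toy_collection], cfg
        )
        for r in res:
            exact = float(
                (counts[:, pids.index(r.pathway_id)] >= r.obs).mean()
            )
            se = (exact * (1 - exact) / 50_000) ** 0.5
            assert abs(r.empirical_fdr - exact) <= 3 * se + 1e-12

    def test_exhaustive_fdr_is_exact_exceedance(
        self, toy_network, toy_collection
    ):
        # a 15-trial null that enumerates every seed pair reproduces the
        # exhaustive exceedance proportion exactly
        pids, counts = exhaustive_null_counts(toy_network, 2, toy_collection)
        obs = observed_pathway_counts(
            second_degree(toy_network, {"a", "c"}), toy_collection
        )
        for pid in pids:
            exact = float((counts[:, pids.index(pid)] >= obs[pid]).mean())
            fdr = empirical_fdr(obs[pid], counts[:, pids.index(pid)])
            assert fdr == exact

    def test_deterministic_given_seed(self, toy_network, toy_collection):
        cfg = PermutationConfig(n_trials=500, rng_seed=9)
        a = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [toy_collection], cfg
        )
        b = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [toy_collection], cfg
        )
        assert a == b

    def test_min_obs_gates_significance(self):
        # pathway with a single observed protein is never significant, even
        # at empirical FDR 0
        nodes = [f"n{i}" for i in range(8)]
        net = PPINetwork(nodes, [("n0", "n7")])
        coll = GeneSetCollection(
            "toy", {"P": GeneSet("p", frozenset({"n7"}))}
        )
        cfg = PermutationConfig(n_trials=200, rng_seed=2)
        res = run_indirect_enrichment(net, {"n0"}, None, [coll], cfg)
        (r,) = res
        assert r.obs == 1 and not r.significant

    def test_per_source_bonferroni_multiplier(self, toy_network):
        coll_a = GeneSetCollection(
            "A",
            {f"A{i}": GeneSet("x", frozenset({"b"})) for i in range(4)},
        )
        coll_b = GeneSetCollection(
            "B", {"B1": GeneSet("y", frozenset({"d"}))}
        )
        cfg = PermutationConfig(n_trials=300, rng_seed=1)
        res = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [coll_a, coll_b], cfg
        )
        by_id = {r.pathway_id: r for r in res}
        for i in range(4):
            r = by_id[f"A{i}"]
            assert r.corrected_fdr == pytest.approx(
                min(1.0, r.empirical_fdr * 4)
            )
        assert by_id["B1"].corrected_fdr == pytest.approx(
            min(1.0, by_id["B1"].empirical_fdr * 1)
        )

    def test_results_sorted_by_fdr_then_id(self, toy_network, toy_collection):
        cfg = PermutationConfig(n_trials=300, rng_seed=4)
        res = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [toy_collection], cfg
        )
        keys = [(r.empirical_fdr, r.pathway_id) for r in res]
        assert keys == sorted(keys)

    def test_member_hits_are_distinct_genes(self, toy_network, toy_collection):
        cfg = PermutationConfig(n_trials=100, rng_seed=4)
        res = run_indirect_enrichment(
            toy_network, {"a", "c"}, None, [toy_collection], cfg
        )
        for r in res:
            assert len(r.member_hits) == len(set(r.member_hits)) == r.obs
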