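"""Synthetic networks, gene-set collections and planted enrichment.

Everything downstream of the screen — catalog counting, Fisher enrichment,
the permutation null — can be exercised on generated data with known
structure.  The generator plants two kinds of signal:

* *direct* enrichment: a fraction ``direct_q`` of the seed set is drawn
  from one designated term, so the Fisher test must rank that term first;
* *indirect* enrichment: each seed gains ``indirect_k_links`` extra edges
  into one designated pathway, so the second-degree permutation test must
  flag that pathway.

Defaults emulate the scale of a proteome-wide two-hybrid screen: a
10,214-gene universe (one gene per ORFeome-tested gene), 59 seeds, a sparse
network with mean degree ~6, and 50 gene sets of heterogeneous size.

Every generator call derives its own RNG stream from ``(rng_seed, call
label)``, so adding one call never shifts another call's draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .io import GeneSet, GeneSetCollection, PPINetwork, Universe

__all__ = [
    "SyntheticConfig",
    "gen_gene_sets",
    "gen_network",
    "gen_universe",
    "plant_direct",
    "plant_indirect",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic benchmark.

    ``network_model`` is ``"erdos_renyi"`` (edge probability ``er_p``) or
    ``"configuration"`` (power-law degree sequence with exponent ``gamma``
    truncated to [``min_degree``, ``max_degree``]).  ``direct_q`` is the
    fraction of seeds drawn from the planted term; ``indirect_k_links`` the
    number of extra seed-to-pathway edges per seed.
    """

    n_genes: int = 10_214
    network_model: str = "erdos_renyi"
    er_p: float = 6 / 10_214  # mean degree ~6, typical of curated PPI maps
    gamma: float = 2.5
    min_degree: int = 1
    max_degree: int = 100
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 200)
    n_seeds: int = 59
    direct_q: float = 0.0
    indirect_k_links: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.direct_q <= 1:
            raise ValueError("direct_q must lie in [0, 1]")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("set_size_range must lie within [1, n_genes]")
        if self.n_seeds > self.n_genes:
            raise ValueError("n_seeds exceeds n_genes")
        if self.network_model not in ("erdos_renyi", "configuration"):
            raise ValueError(f"unknown network model {self.network_model!r}")
        if self.indirect_k_links < 0:
            raise ValueError("indirect_k_links must be >= 0")


def _rng(cfg: SyntheticConfig, label: str) -> np.random.Generator:
    """Independent stream per (seed, call label)."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [cfg.rng_seed & 0x7FFFFFFF, zlib.crc32(label.encode())]
        )
    )


def gen_universe(cfg: SyntheticConfig) -> Universe:
    """Deterministic gene identifiers G000001..G<n_genes>."""
    width = len(str(cfg.n_genes))
    return Universe(
        frozenset(f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1))
    )


def _universe_order(universe: Universe) -> list[str]:
    return sorted(universe.genes)


def gen_network(cfg: SyntheticConfig, universe: Universe | None = None) -> PPINetwork:
    """Random simple undirected graph over the universe genes."""
    universe = universe or gen_universe(cfg)
    genes = _universe_order(universe)
    rng = _rng(cfg, "gen_network")
    if cfg.network_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(len(genes), cfg.er_p, seed=rng)
    else:
        # power-law degrees truncated to [min_degree, max_degree]
        u = rng.random(len(genes))
        lo, hi, a = cfg.min_degree, cfg.max_degree, cfg.gamma
        # inverse-CDF sampling of a discretized truncated power law
        supports = np.arange(lo, hi + 1, dtype=float)
        weights = supports ** (-a)
        cdf = np.cumsum(weights) / weights.sum()
        degrees = supports[np.searchsorted(cdf, u)].astype(int)
        if degrees.sum() % 2:
            degrees[int(rng.integers(len(degrees)))] += 1
        if degrees.max() >= len(genes):
            raise ValueError("infeasible degree sequence (degree >= n)")
        g = nx.configuration_model(degrees.tolist(), seed=rng)
        g = nx.Graph(g)  # collapse parallel edges
        g.remove_edges_from(nx.selfloop_edges(g))
    mapping = dict(enumerate(genes))
    g = nx.relabel_nodes(g, mapping)
    g.add_nodes_from(genes)
    return PPINetwork.from_networkx(g)


def gen_gene_sets(
    cfg: SyntheticConfig, universe: Universe | None = None
) -> GeneSetCollection:
    """``n_sets`` sets with sizes uniform on ``set_size_range``.

    Members are uniform without replacement from the universe; sets may
    overlap.  Term ids are S001..; the first term (S001) is the designated
    planting target for the direct and indirect benchmarks.
    """
    universe = universe or gen_universe(cfg)
    genes = np.array(_universe_order(universe), dtype=object)
    rng = _rng(cfg, "gen_gene_sets")
    lo, hi = cfg.set_size_range
    width = len(str(cfg.n_sets))
    sets = {}
    for i in range(1, cfg.n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"S{i:0{width}d}"] = GeneSet(
            name=f"synthetic set {i}",
            members=frozenset(genes[members.astype(np.intp)]),
        )
    return GeneSetCollection(source="synthetic", sets=sets)


def plant_direct(
    cfg: SyntheticConfig,
    universe: Universe,
    term_members: Iterable[str],
) -> frozenset[str]:
    """Seed set with ``ceil(direct_q * n_seeds)`` members inside the term.

    The quota is drawn uniformly from the term, the remainder uniformly
    from universe minus term; no duplicates.
    """
    term = sorted(frozenset(term_members) & universe.genes)
    quota = int(np.ceil(cfg.direct_q * cfg.n_seeds))
    if quota > len(term):
        raise ValueError(
            f"planting quota {quota} exceeds term size {len(term)}"
        )
    rng = _rng(cfg, "plant_direct")
    inside = rng.choice(term, size=quota, replace=False) if quota else []
    outside_pool = sorted(universe.genes - frozenset(term))
    n_out = cfg.n_seeds - quota
    if n_out > len(outside_pool):
        raise ValueError("not enough non-term genes for the seed remainder")
    outside = rng.choice(outside_pool, size=n_out, replace=False)
    return frozenset(inside) | frozenset(outside)


def plant_indirect(
    cfg: SyntheticConfig,
    network: PPINetwork,
    pathway_members: Iterable[str],
    seeds: Iterable[str],
) -> PPINetwork:
    """Copy of the network with extra seed-to-pathway edges.

    Each seed gains ``indirect_k_links`` new edges to distinct uniformly
    drawn pathway members; pairs already wired are resampled.  Nothing else
    changes (no deletions, node set invariant).
    """
    pathway = sorted(frozenset(pathway_members) & network.nodes)
    if cfg.indirect_k_links > len(pathway):
        raise ValueError(
            f"indirect_k_links={cfg.indirect_k_links} exceeds pathway size "
            f"{len(pathway)}"
        )
    if cfg.indirect_k_links == 0:
        return network
    rng = _rng(cfg, "plant_indirect")
    existing = set(network.edges)
    new_edges: list[tuple[str, str]] = []
    for s in sorted(frozenset(seeds)):
        chosen: set[str] = set()
        candidates = [p for p in pathway if p != s]
        if cfg.indirect_k_links > len(candidates):
            raise ValueError(
                f"seed {s}: pathway too small for {cfg.indirect_k_links} links"
            )
        # draw until k distinct, not-yet-wired partners are found; fall back
        # to already-wired partners only when no unwired one remains
        order = rng.permutation(len(candidates))
        unwired = [
            candidates[i]
            for i in order
            if (min(s, candidates[i]), max(s, candidates[i])) not in existing
        ]
        wired = [
            candidates[i]
            for i in order
            if (min(s, candidates[i]), max(s, candidates[i])) in existing
        ]
        picks = (unwired + wired)[: cfg.indirect_k_links]
        for p in picks:
            e = (min(s, p), max(s, p))
            if e not in existing:
                existing.add(e)
                new_edges.append(e)
            chosen.add(p)
    return network.with_edges(new_edges)
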