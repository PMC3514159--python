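"""Bit-packed adjacency engine for the seed-randomization null.

The permutation null requires, per trial, the union of the neighborhoods of
k random seeds minus the seeds and bait, intersected with every pathway.
Nodes are mapped to bit positions; adjacency rows and pathway membership are
packed into uint64 words so one trial is a handful of vectorized bitwise
ops plus ``np.bitwise_count``.  Results are bit-for-bit equal to the
set-based ``second_degree`` / ``observed_pathway_counts`` route, which the
test suite asserts.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import PPINetwork

__all__ = ["SecondDegreeEngine"]


class SecondDegreeEngine:
    """Precomputed bitset views of a network and a pathway family."""

    def __init__(
        self,
        network: PPINetwork,
        pathways: Mapping[str, Iterable[str]],
        bait: str | None = None,
    ) -> None:
        self.node_order: list[str] = sorted(network.nodes)
        self.index: dict[str, int] = {
            n: i for i, n in enumerate(self.node_order)
        }
        n = len(self.node_order)
        self.n_nodes = n
        self.words = (n + 63) // 64 or 1
        # adjacency: self-loops deliberately omitted (they add no neighbors)
        self.adj = np.zeros((n, self.words), dtype=np.uint64)
        for u, v in network.edges:
            iu, iv = self.index[u], self.index[v]
            self.adj[iu, iv >> 6] |= np.uint64(1) << np.uint64(iv & 63)
            self.adj[iv, iu >> 6] |= np.uint64(1) << np.uint64(iu & 63)
        self.pathway_ids: list[str] = list(pathways)
        self.pathway_masks = np.zeros(
            (len(self.pathway_ids), self.words), dtype=np.uint64
        )
        for row, pid in enumerate(self.pathway_ids):
            for g in pathways[pid]:
                i = self.index.get(g)
                if i is not None:
                    self.pathway_masks[row, i >> 6] |= (
                        np.uint64(1) << np.uint64(i & 63)
                    )
        self.pathway_network_sizes = (
            np.bitwise_count(self.pathway_masks).sum(axis=1).astype(int)
        )
        self.bait_mask = np.zeros(self.words, dtype=np.uint64)
        if bait is not None and bait in self.index:
            i = self.index[bait]
            self.bait_mask[i >> 6] |= np.uint64(1) << np.uint64(i & 63)
        self.degrees = np.bitwise_count(self.adj).sum(axis=1).astype(int)

    def _mask_of(self, idx: np.ndarray) -> np.ndarray:
        mask = np.zeros(self.words, dtype=np.uint64)
        np.bitwise_or.at(
            mask, idx >> 6, np.uint64(1) << (idx & np.uint64(63))
        )
        return mask

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(
            sorted(self.index[g] for g in genes if g in self.index),
            dtype=np.uint64,
        )

    def expand(self, seed_idx: np.ndarray) -> np.ndarray:
        """Packed second-degree set for the given seed indices."""
        union = np.bitwise_or.reduce(self.adj[seed_idx.astype(np.intp)], axis=0)
        union &= ~self._mask_of(seed_idx)
        union &= ~self.bait_mask
        return union

    def pathway_counts(self, packed: np.ndarray) -> np.ndarray:
        """Distinct-gene overlap of a packed set with every pathway."""
        return (
            np.bitwise_count(self.pathway_masks & packed[None, :])
            .sum(axis=1)
            .astype(np.int64)
        )

    def counts_for_seed_indices(self, seed_idx: np.ndarray) -> np.ndarray:
        if seed_idx.size == 0:
            return np.zeros(len(self.pathway_ids), dtype=np.int64)
        return self.pathway_counts(self.expand(seed_idx))

    def indirect_size(self, seed_idx: np.ndarray) -> int:
        if seed_idx.size == 0:
            return 0
        return int(np.bitwise_count(self.expand(seed_idx)).sum())

    def null_counts(
        self, seed_sets: Sequence[np.ndarray]
    ) -> np.ndarray:
        """Stack of pathway-count vectors, one row per null seed set."""
        out = np.empty((len(seed_sets), len(self.pathway_ids)), dtype=np.int64)
        for t, idx in enumerate(seed_sets):
            out[t] = self.counts_for_seed_indices(idx)
        return out
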