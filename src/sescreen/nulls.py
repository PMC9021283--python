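"""Degree-preserving randomization: sampling gene sets that match a query
set's size and degree distribution.

Exact-degree matching is infeasible for hub proteins (a degree-300 hub may
have no degree-300 peer), so nodes are grouped into logarithmic (base-2)
degree bins that are merged upward until each holds at least ``min_bin_size``
candidates. A null sample replaces each query gene with a uniformly chosen
node from its bin, without replacement within one sample; a gene may map to
itself.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io import Interactome


class DegreeBins:
    """Merged logarithmic degree bins over the nodes of an interactome."""

    def __init__(self, interactome: Interactome, min_bin_size: int = 20):
        self.min_bin_size = min_bin_size
        # raw bin key: degree.bit_length() -> {0}, {1}, {2,3}, {4..7}, ...
        raw: dict[int, list[str]] = {}
        for node in interactome.graph.nodes:
            raw.setdefault(interactome.degree(node).bit_length(), []).append(node)
        keys = sorted(raw)
        merged: list[tuple[list[int], list[str]]] = []
        pending_keys: list[int] = []
        pending_nodes: list[str] = []
        for k in keys:
            pending_keys.append(k)
            pending_nodes.extend(raw[k])
            if len(pending_nodes) >= min_bin_size:
                merged.append((pending_keys, pending_nodes))
                pending_keys, pending_nodes = [], []
        if pending_nodes:
            if merged:  # fold a small top bin into the one below it
                merged[-1][0].extend(pending_keys)
                merged[-1][1].extend(pending_nodes)
            else:
                merged.append((pending_keys, pending_nodes))
        self._key_to_bin: dict[int, int] = {}
        self.members: list[np.ndarray] = []
        for i, (bin_keys, nodes) in enumerate(merged):
            for k in bin_keys:
                self._key_to_bin[k] = i
            self.members.append(np.array(sorted(nodes), dtype=object))
        self._degree = {n: interactome.degree(n) for n in interactome.graph.nodes}

    def bin_of(self, node: str) -> int:
        return self._key_to_bin[self._degree[node].bit_length()]

    def sample_matched(self, genes: Iterable[str], rng: np.random.Generator) -> set[str]:
        """Draw a degree-matched stand-in set of the same cardinality."""
        demand: dict[int, int] = {}
        for g in genes:
            if g not in self._degree:
                raise ValueError(f"gene {g!r} not in the interactome")
            b = self.bin_of(g)
            demand[b] = demand.get(b, 0) + 1
        sample: set[str] = set()
        for b in sorted(demand):
            pool = self.members[b]
            k = demand[b]
            if k > len(pool):  # cannot happen when genes are graph nodes
                raise ValueError(f"degree bin {b} holds {len(pool)} nodes, {k} demanded")
            sample.update(rng.choice(pool, size=k, replace=False).tolist())
        return sample


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate substream: changing the replicate count
    never reshuffles earlier replicates."""
    return np.random.default_rng([seed, replicate])
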