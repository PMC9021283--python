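"""Disease-module detection: does a gene set occupy a denser network
neighborhood than degree-matched chance?

Three metrics are computed on the subgraph the gene set induces in the
interactome — the size of its largest connected component (LCC), the number
of interactions inside the LCC, and the total number of induced
interactions — and each is z-scored against the distribution obtained from
randomly drawn gene sets of the same size and degree distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .io import Interactome
from .nulls import DegreeBins, replicate_rng

METRICS = ("lcc_size", "lcc_edges", "total_edges")


@dataclass
class MetricSignificance:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float


@dataclass
class ModuleStats:
    """Observed module metrics and their degree-matched null comparison."""

    set_id: str
    lcc_size: int
    lcc_edges: int
    total_edges: int
    metrics: dict[str, MetricSignificance]
    n_reps: int
    seed: int


def lcc_metrics(genes: Iterable[str], interactome: Interactome) -> tuple[int, int, int]:
    """(lcc_size, lcc_edges, total_edges) of the subgraph induced by *genes*.

    Hand-rolled BFS on the cached adjacency: this is called hundreds of
    thousands of times inside null loops, where building a networkx subgraph
    per call would dominate the run time.
    """
    adj = interactome.adjacency
    gene_set = set(genes)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = gene_set - adj.keys()
    if missing:
        raise ValueError(f"genes not in interactome: {sorted(missing)[:5]}")

    total_edges = 0
    for g in gene_set:
        total_edges += len(adj[g] & gene_set)
    total_edges //= 2

    best_size, best_edges = 0, 0
    unseen = set(gene_set)
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node] & gene_set:
                    if nb not in comp:
                        comp.add(nb)
                        nxt.append(nb)
            frontier = nxt
        unseen -= comp
        comp_edges = sum(len(adj[n] & comp) for n in comp) // 2
        if (len(comp), comp_edges) > (best_size, best_edges):
            best_size, best_edges = len(comp), comp_edges
    return best_size, best_edges, total_edges


def _normal_upper_p(z: float, n_reps: int) -> float:
    if math.isinf(z):
        return 1.0 / n_reps if z > 0 else 1.0
    return float(stats.norm.sf(z))


def summarize_metric(observed: float, null: np.ndarray, n_reps: int) -> MetricSignificance:
    """z-score one observed metric against its null replicate values.

    A degenerate null (sd = 0) yields z = 0 when the observation equals the
    null mean, otherwise a +/-inf sentinel with p reported as 1/n_reps.
    """
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        z = 0.0 if observed == mean else math.copysign(math.inf, observed - mean)
    else:
        z = (observed - mean) / sd
    p_emp = (1.0 + int((null >= observed).sum())) / (n_reps + 1.0)
    return MetricSignificance(float(observed), mean, sd, z, _normal_upper_p(z, n_reps), p_emp)


def module_significance(genes: Iterable[str], interactome: Interactome,
                        n_reps: int = 1000, seed: int = 0,
                        min_bin_size: int = 20, set_id: str = "",
                        bins: DegreeBins | None = None) -> ModuleStats:
    """Test whether *genes* form a significant module in the interactome.

    The null draws ``n_reps`` degree-matched gene sets and recomputes the
    three metrics on each; z-scores and one-sided upper-tail normal p-values
    follow, with the empirical rank p emitted alongside. Deterministic under
    (seed, n_reps): replicate r uses its own RNG substream.
    """
    gene_set = set(genes)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if interactome.n_edges == 0:
        raise ValueError("interactome has no edges")
    observed = lcc_metrics(gene_set, interactome)
    if bins is None:
        bins = DegreeBins(interactome, min_bin_size=min_bin_size)
    null = np.empty((n_reps, 3))
    for r in range(n_reps):
        sample = bins.sample_matched(gene_set, replicate_rng(seed, r))
        null[r] = lcc_metrics(sample, interactome)
    metrics = {name: summarize_metric(observed[i], null[:, i], n_reps)
               for i, name in enumerate(METRICS)}
    return ModuleStats(set_id, observed[0], observed[1], observed[2],
                       metrics, n_reps, seed)
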