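"""Adjusted similarity and the weighted bipartite drug-disease network.

Proximity p is rescaled to (m - p)/m with m the maximum proximity over the
run, boosted by a quality-cluster bonus QC for pairs co-located in one
network cluster, and squashed through a sigmoid:

    AS(p) = 1 / (1 + exp(-c * [(1 + QC) * (m - p)/m - midpoint]))

AS lies strictly in (0, 1); with the default midpoint 0.5 an AS >= 0.5
marks a pair as "proximal". Only pairs with proximity z <= z_cutoff enter
the network; clusters come from greedy modularity optimization on the
weighted bipartite graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .proximity import ProximityResult, is_significant

_WEIGHT_FLOOR = 1e-12  # modularity needs positive total weight


@dataclass
class SimilarityParams:
    """Sigmoid and threshold parameters; c and midpoint must be set
    explicitly in run configs and are echoed in all output metadata."""

    c: float = 10.0
    midpoint: float = 0.5
    m: float | None = None          # max proximity; set by assemble_network
    z_cutoff: float = -1.65
    as_cutoff: float = 0.5
    m_policy: str = "post_filter"   # or "pre_filter"

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("steepness c must be > 0")
        if not 0.0 <= self.midpoint <= 1.0:
            raise ValueError("midpoint must lie in [0, 1]")
        if self.m is not None and self.m <= 0:
            raise ValueError("m must be > 0")
        if self.m_policy not in ("post_filter", "pre_filter"):
            raise ValueError(f"unknown m_policy {self.m_policy!r}")


@dataclass
class DrugDiseaseEdge:
    drug_id: str
    set_id: str
    p: float
    z: float
    qc: float
    as_value: float
    cluster: int | None = None


@dataclass
class DrugDiseaseNetwork:
    """Significant drug-disease/side-effect links, their clusters and AS
    weights. ``status`` is "ok" or an explanation of an empty result."""

    edges: list[DrugDiseaseEdge] = field(default_factory=list)
    params: SimilarityParams | None = None
    clusters: dict = field(default_factory=dict)   # ("drug"|"set", id) -> int
    status: str = "ok"

    @property
    def drugs(self) -> set[str]:
        return {e.drug_id for e in self.edges}

    @property
    def sets(self) -> set[str]:
        return {e.set_id for e in self.edges}

    def edge(self, drug_id: str, set_id: str) -> DrugDiseaseEdge | None:
        for e in self.edges:
            if e.drug_id == drug_id and e.set_id == set_id:
                return e
        return None

    def cluster_of_drug(self, drug_id: str) -> int | None:
        return self.clusters.get(("drug", drug_id))


def raw_similarity(p: float, m: float) -> float:
    """(m - p)/m: proximity rescaled to [0, 1], 1 at p = 0, 0 at p = m."""
    if m <= 0:
        raise ValueError("m must be > 0")
    if not 0 <= p <= m:
        raise ValueError(f"p={p} outside [0, m={m}]")
    return (m - p) / m


def adjusted_similarity(p: float, qc: float, params: SimilarityParams) -> float:
    """Evaluate the adjusted-similarity sigmoid.

    Strictly decreasing in p and increasing in qc (at p < m). Accepts
    p > m (pairs outside the retained set scored for map coordinates): the
    inner bracket simply goes negative and AS stays in (0, 1).
    """
    if params.m is None:
        raise ValueError("params.m is unset; assemble a network first or set m")
    if not 0.0 <= qc <= 1.0:
        raise ValueError(f"qc={qc} outside [0, 1]")
    inner = (1.0 + qc) * (params.m - p) / params.m - params.midpoint
    return 1.0 / (1.0 + math.exp(-params.c * inner))


def detect_clusters(graph: nx.Graph) -> dict:
    """Partition a weighted graph by greedy (CNM) modularity maximization.

    Nodes and edges are inserted in sorted order and communities labelled
    by their lexicographically smallest member, so the partition is
    reproducible across runs.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    for u, v in sorted(tuple(sorted((u, v))) for u, v in graph.edges):
        g.add_edge(u, v, weight=max(graph[u][v].get("weight", 1.0), _WEIGHT_FLOOR))
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(g.nodes))}
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {node: i for i, comm in enumerate(communities) for node in comm}


def quality_cluster_score(graph: nx.Graph, partition: dict) -> dict[int, float]:
    """Per-cluster QC: intra-cluster edge weight over the total weight
    incident to the cluster's nodes (1 when no edge leaves the cluster,
    0 for an edgeless cluster). A pair's QC is its cluster's score when the
    endpoints are co-clustered and 0 otherwise."""
    intra: dict[int, float] = {}
    incident: dict[int, float] = {}
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        cu, cv = partition[u], partition[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
            incident[cu] = incident.get(cu, 0.0) + w
        else:
            incident[cu] = incident.get(cu, 0.0) + w
            incident[cv] = incident.get(cv, 0.0) + w
    scores = {}
    for c in set(partition.values()):
        total = incident.get(c, 0.0)
        scores[c] = (intra.get(c, 0.0) / total) if total > 0 else 0.0
    return scores


def pair_qc(drug_id: str, set_id: str, partition: dict,
            cluster_scores: dict[int, float]) -> float:
    cd = partition.get(("drug", drug_id))
    cs = partition.get(("set", set_id))
    if cd is None or cs is None or cd != cs:
        return 0.0
    return cluster_scores[cd]


def assemble_network(results: list[ProximityResult],
                     params: SimilarityParams | None = None) -> DrugDiseaseNetwork:
    """Build the drug-disease network from scored proximity results.

    Pipeline: keep pairs with z <= z_cutoff; fix m = max(p) over the
    retained pairs (or over all scored pairs under ``m_policy="pre_filter"``);
    weight each link provisionally by (m - p)/m; detect clusters; attach the
    quality-cluster bonus; score the final AS. All intermediates stay on the
    edges. The procedure is deterministic.
    """
    params = params if params is not None else SimilarityParams()
    scored = [r for r in results if r.scored]
    kept = [r for r in scored if is_significant(r.z, params.z_cutoff)]
    if not kept:
        return DrugDiseaseNetwork(params=params, status="no significant drug-disease pair")
    pool = kept if params.m_policy == "post_filter" else scored
    m = max(r.p for r in pool)
    if m <= 0:  # every retained proximity is 0; widen to all scored pairs
        m = max((r.p for r in scored), default=0.0)
    if m <= 0:
        m = 1.0
    params.m = m

    g = nx.Graph()
    for r in kept:
        g.add_edge(("drug", r.drug_id), ("set", r.set_id),
                   weight=max(0.0, (m - r.p) / m))
    partition = detect_clusters(g)
    scores = quality_cluster_score(g, partition)

    edges = []
    for r in kept:
        qc = pair_qc(r.drug_id, r.set_id, partition, scores)
        edges.append(DrugDiseaseEdge(
            drug_id=r.drug_id, set_id=r.set_id, p=r.p, z=r.z, qc=qc,
            as_value=adjusted_similarity(r.p, qc, params),
            cluster=partition[("drug", r.drug_id)]))
    return DrugDiseaseNetwork(edges=edges, params=params, clusters=partition)
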