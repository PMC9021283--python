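"""Side-effect-aware candidate filtering and mode-of-action classification.

Two criteria prune the repurposing candidates for a disease A against a
side effect B:

1. remove drugs whose proximity z-score to the disease exceeds -1.65
   (not significantly close to the disease module);
2. among the survivors, remove drugs significantly proximal to the side
   effect (z_se <= -1.65) with adjusted similarity AS_se >= 0.5.

Every drug is also placed in one of four modes of action, named
side-effect axis first: proximal/distal (close to the side effect, far from
the disease) through distal/distal. A drug with no significant side-effect
association is distal on that axis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import DrugProfile, GeneSet, Interactome
from .proximity import ProximityResult, is_significant
from .similarity import DrugDiseaseNetwork, SimilarityParams, adjusted_similarity

MODES = ("proximal_distal", "proximal_proximal", "distal_proximal", "distal_distal")

MODE_COLORS = {
    "proximal_distal": "dark red",
    "proximal_proximal": "red",
    "distal_proximal": "dark green",
    "distal_distal": "green",
}


@dataclass
class DrugActionRecord:
    """One (drug, disease, side-effect) triple with both similarity axes,
    the mode-of-action class, and the filtering verdict."""

    drug_id: str
    disease_id: str
    side_effect_id: str
    z_disease: float
    z_se: float
    as_disease: float            # network AS when significant, else raw AS
    as_se: float | None          # None when z_se is not significant
    as_se_raw: float | None      # raw AS regardless of significance (map use)
    mode: str
    verdict: str                 # removed_criterion1 | removed_criterion2 | retained
    as_disease_source: str = "network"   # "network" | "raw"


@dataclass
class FilterReport:
    disease_id: str
    side_effect_id: str
    n_predicted: int     # drugs passing criterion 1 (disease-significant)
    n_removed: int       # of those, removed by the side-effect criterion
    n_retained: int
    mode_counts: dict[str, int] = field(default_factory=dict)


def classify_mode(as_se: float | None, as_disease: float | None,
                  as_cutoff: float = 0.5) -> str:
    """Four-way quadrant class; the side-effect axis is named first.
    A missing similarity (no significant association on that axis) counts
    as distal."""
    se_proximal = as_se is not None and as_se >= as_cutoff
    dis_proximal = as_disease is not None and as_disease >= as_cutoff
    if se_proximal:
        return "proximal_proximal" if dis_proximal else "proximal_distal"
    return "distal_proximal" if dis_proximal else "distal_distal"


def apply_disease_criterion(results: list[ProximityResult], disease_id: str,
                            z_cutoff: float = -1.65) -> set[str]:
    """Drugs significantly proximal to the disease (z <= cutoff, inclusive)."""
    scored = [r for r in results if r.set_id == disease_id]
    if not scored:
        raise ValueError(f"no proximity results for disease {disease_id!r}")
    return {r.drug_id for r in scored if r.scored and is_significant(r.z, z_cutoff)}


def apply_side_effect_criterion(kept: set[str], se_results: list[ProximityResult],
                                as_se: dict[str, float], z_cutoff: float = -1.65,
                                as_cutoff: float = 0.5) -> tuple[set[str], set[str]]:
    """Split criterion-1 survivors into (removed, retained).

    Removed means significantly proximal to the side effect AND similar
    enough (AS >= cutoff, inclusive); a drug not significantly proximal to
    the side effect is retained regardless of any AS value.
    """
    z_by_drug = {r.drug_id: r.z for r in se_results if r.scored}
    removed = set()
    for drug in kept:
        z = z_by_drug.get(drug, math.nan)
        if is_significant(z, z_cutoff) and as_se.get(drug, -1.0) >= as_cutoff:
            removed.add(drug)
    return removed, kept - removed


def screen_drugs(results: list[ProximityResult], network: DrugDiseaseNetwork,
                 disease_id: str, side_effect_ids: list[str],
                 params: SimilarityParams | None = None,
                 ) -> tuple[list[DrugActionRecord], list[FilterReport]]:
    """Run both criteria and classify modes for every scored drug.

    ``results`` must contain proximity results for the disease and each side
    effect; ``network`` supplies the cluster-aware AS for significant pairs,
    while non-significant pairs get a raw (no cluster bonus) AS so they can
    still be placed on the drug-action map. With several side effects the
    removals are the union over side effects (order-independent).
    """
    params = params if params is not None else (network.params or SimilarityParams())
    by_set: dict[str, dict[str, ProximityResult]] = {}
    for r in results:
        by_set.setdefault(r.set_id, {})[r.drug_id] = r
    if disease_id not in by_set:
        raise ValueError(f"no proximity results for disease {disease_id!r}")

    def as_for(r: ProximityResult) -> tuple[float | None, float | None, str]:
        """(network AS or None, raw AS or None, source)."""
        edge = network.edge(r.drug_id, r.set_id)
        raw = (adjusted_similarity(r.p, 0.0, params)
               if (r.scored and params.m is not None) else None)
        if edge is not None:
            return edge.as_value, raw, "network"
        return None, raw, "raw"

    records: list[DrugActionRecord] = []
    reports: list[FilterReport] = []
    for se_id in side_effect_ids:
        if se_id not in by_set:
            raise ValueError(f"no proximity results for side effect {se_id!r}")
        n_pred = n_rem = 0
        mode_counts: Counter = Counter()
        for drug_id, r_dis in sorted(by_set[disease_id].items()):
            as_dis_net, as_dis_raw, _ = as_for(r_dis)
            as_disease = as_dis_net if as_dis_net is not None else as_dis_raw
            source = "network" if as_dis_net is not None else "raw"
            r_se = by_set[se_id].get(drug_id)
            z_se = r_se.z if (r_se is not None and r_se.scored) else math.nan
            as_se_net = as_se_raw = None
            if r_se is not None:
                as_se_net, as_se_raw, _ = as_for(r_se)
            se_significant = is_significant(z_se, params.z_cutoff)
            as_se = as_se_net if (se_significant and as_se_net is not None) else None

            dis_significant = r_dis.scored and is_significant(r_dis.z,
                                                              params.z_cutoff)
            if not dis_significant:
                verdict = "removed_criterion1"
            elif as_se is not None and as_se >= params.as_cutoff:
                verdict = "removed_criterion2"
            else:
                verdict = "retained"

            if as_disease is None:
                continue  # unscored against the disease: nothing to place
            # the disease axis mirrors the SE axis: only a significant
            # association can make a drug "proximal" to the disease
            mode = classify_mode(as_se, as_disease if dis_significant else None,
                                 params.as_cutoff)
            if verdict != "removed_criterion1":
                n_pred += 1
                mode_counts[mode] += 1
                if verdict == "removed_criterion2":
                    n_rem += 1
            records.append(DrugActionRecord(
                drug_id=drug_id, disease_id=disease_id, side_effect_id=se_id,
                z_disease=r_dis.z, z_se=z_se, as_disease=as_disease,
                as_se=as_se, as_se_raw=as_se_raw, mode=mode, verdict=verdict,
                as_disease_source=source))
        reports.append(FilterReport(disease_id, se_id, n_pred, n_rem,
                                    n_pred - n_rem, dict(mode_counts)))
    return records, reports


def drug_action_map(records: list[DrugActionRecord]) -> pd.DataFrame:
    """Plot-ready drug-action map: x = AS(disease), y = 1 - AS(side effect).

    Drugs without a significant side-effect association fall back to their
    raw AS for y when available, and are marked in a separate
    "not_significant" stratum rather than being given an invented score.
    """
    rows = []
    for rec in records:
        if rec.as_se is not None:
            y, stratum = 1.0 - rec.as_se, "significant"
        elif rec.as_se_raw is not None:
            y, stratum = 1.0 - rec.as_se_raw, "not_significant"
        else:
            y, stratum = math.nan, "unscored"
        rows.append({"drug": rec.drug_id, "disease": rec.disease_id,
                     "side_effect": rec.side_effect_id, "x_as_disease": rec.as_disease,
                     "y_one_minus_as_se": y, "mode": rec.mode,
                     "color": MODE_COLORS[rec.mode], "stratum": stratum,
                     "verdict": rec.verdict})
    return pd.DataFrame(rows)


def mode_counts_by_cluster(network: DrugDiseaseNetwork,
                           records: list[DrugActionRecord]) -> pd.DataFrame:
    """Per-cluster histogram of drug modes (drugs outside the network are
    reported under cluster -1)."""
    rows = []
    tally: dict[tuple[int, str], int] = Counter()
    for rec in records:
        cluster = network.cluster_of_drug(rec.drug_id)
        tally[(cluster if cluster is not None else -1, rec.mode)] += 1
    clusters = sorted({c for c, _ in tally})
    for c in clusters:
        row = {"cluster": c}
        for mode in MODES:
            row[mode] = tally.get((c, mode), 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["cluster", *MODES])


def extract_moa_subnetwork(drug: DrugProfile, disease: GeneSet, se: GeneSet,
                           interactome: Interactome) -> tuple[nx.Graph, dict[str, set[str]]]:
    """Mechanism-of-action subnetwork around a drug's targets.

    Nodes: the mapped targets; disease genes adjacent to a target;
    side-effect genes adjacent to a target; and bridge nodes — first
    neighbors of targets belonging to neither gene set that are themselves
    adjacent to at least one disease-module gene. Edges are those induced.
    Each node carries combinable role flags (target / disease /
    side_effect / bridge).
    """
    adj = interactome.adjacency
    targets = {t for t in drug.targets if t in adj}
    dis = {g for g in disease.genes if g in adj}
    se_genes = {g for g in se.genes if g in adj}

    neighbor_pool = set().union(*(adj[t] for t in targets)) if targets else set()
    dis_adj = dis & neighbor_pool
    se_adj = se_genes & neighbor_pool
    bridges = {v for v in neighbor_pool - dis - se_genes - targets
               if adj[v] & dis}

    nodes = targets | dis_adj | se_adj | bridges
    roles: dict[str, set[str]] = {n: set() for n in nodes}
    for n in nodes:
        if n in targets:
            roles[n].add("target")
        if n in dis:
            roles[n].add("disease")
        if n in se_genes:
            roles[n].add("side_effect")
        if n in bridges:
            roles[n].add("bridge")

    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    for n in nodes:
        for nb in adj[n] & nodes:
            sub.add_edge(n, nb)
    return sub, roles
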