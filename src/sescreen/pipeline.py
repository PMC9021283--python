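"""End-to-end orchestration: proximity scoring of every drug against every
module, network assembly, and the side-effect screen, from in-memory
objects. The CLI is a thin shell over these functions."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import DrugProfile, GeneSet, Interactome, restrict_to_interactome
from .nulls import DegreeBins
from .proximity import ProximityResult, proximity_zscore
from .screen import DrugActionRecord, FilterReport, screen_drugs
from .similarity import DrugDiseaseNetwork, SimilarityParams, assemble_network


def score_all(drugs: list[DrugProfile], gene_sets: list[GeneSet],
              interactome: Interactome, n_reps: int = 1000, seed: int = 0,
              min_bin_size: int = 20, randomize: str = "both",
              ) -> list[ProximityResult]:
    """Proximity z-scores for every (drug, gene set) pair.

    Entities are restricted to the interactome first; pairs where either
    side maps to nothing are skipped. Each pair gets its own deterministic
    seed derived from the run seed and the pair's rank, so results do not
    depend on evaluation order.
    """
    bins = DegreeBins(interactome, min_bin_size=min_bin_size)
    usable_sets = []
    for gs in gene_sets:
        r = restrict_to_interactome(gs, interactome)
        if r.usable:
            usable_sets.append(r.entity)
    usable_drugs = []
    for d in drugs:
        r = restrict_to_interactome(d, interactome)
        if r.usable:
            usable_drugs.append(r.entity)
    results = []
    pair_index = 0
    for drug in sorted(usable_drugs, key=lambda d: d.id):
        for gs in sorted(usable_sets, key=lambda s: s.id):
            results.append(proximity_zscore(
                drug.targets, gs.genes, interactome, n_reps=n_reps,
                seed=(seed * 100003 + pair_index) % (2**31),
                randomize=randomize, drug_id=drug.id, set_id=gs.id, bins=bins))
            pair_index += 1
    return results


@dataclass
class ScreenOutput:
    results: list[ProximityResult]
    network: DrugDiseaseNetwork
    records: list[DrugActionRecord]
    reports: list[FilterReport]


def run_screen(drugs: list[DrugProfile], gene_sets: list[GeneSet],
               interactome: Interactome, disease_id: str,
               side_effect_ids: list[str], params: SimilarityParams | None = None,
               n_reps: int = 1000, seed: int = 0, min_bin_size: int = 20,
               randomize: str = "both") -> ScreenOutput:
    """Score, assemble the network, and apply both filtering criteria."""
    params = params if params is not None else SimilarityParams()
    results = score_all(drugs, gene_sets, interactome, n_reps=n_reps,
                        seed=seed, min_bin_size=min_bin_size, randomize=randomize)
    network = assemble_network(results, params)
    records, reports = screen_drugs(results, network, disease_id,
                                    side_effect_ids, params)
    return ScreenOutput(results, network, records, reports)


def results_table(results: list[ProximityResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def records_table(records: list[DrugActionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def as_matrix(network: DrugDiseaseNetwork) -> pd.DataFrame:
    """Gene-set x drug matrix of adjusted similarities (NaN where the pair
    is absent from the network)."""
    rows = sorted(network.sets)
    cols = sorted(network.drugs)
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for e in network.edges:
        mat.loc[e.set_id, e.drug_id] = e.as_value
    return mat
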