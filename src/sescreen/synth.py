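"""Synthetic interactomes with planted disease/side-effect modules, drugs at
controlled network distances, and distance-biased adverse labels.

Everything downstream of the loaders can be exercised on these scenarios
with full knowledge of the ground truth: which gene sets are real modules,
how far each drug's targets sit from each module, and which drugs carry a
planted "known adverse" label. The background graph is a configuration
model over a truncated power-law degree sequence (interactome degree
distributions are heavy-tailed); an Erdos-Renyi background is available for
the simplest tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (DrugProfile, GeneSet, Interactome, SideEffectCatalog)
from .proximity import _min_distances


@dataclass
class ModuleSpec:
    id: str
    size: int = 20
    density: float = 0.35     # induced edge density; a spanning tree guarantees connectivity
    role: str = "disease"


@dataclass
class DrugSpec:
    """A batch of drugs with a common placement.

    placement: ("inside", module_id) — targets sampled from the module;
               ("ring", module_id, k) — targets at hop distance exactly k;
               ("random",) — targets anywhere outside all modules.
    """
    count: int
    targets_per_drug: int = 3
    placement: tuple = ("random",)
    prefix: str = "drug"


def _default_modules() -> list[ModuleSpec]:
    return [ModuleSpec("disease_A", 20, 0.35, "disease"),
            ModuleSpec("se_B", 20, 0.35, "side_effect")]


def _default_drugs() -> list[DrugSpec]:
    return [DrugSpec(8, 3, ("inside", "disease_A"), "near_dis"),
            DrugSpec(8, 3, ("inside", "se_B"), "near_se"),
            DrugSpec(16, 3, ("random",), "far")]


@dataclass
class ScenarioConfig:
    n_nodes: int = 400
    edge_model: str = "powerlaw"      # "powerlaw" | "er"
    er_p: float = 0.016
    powerlaw_exponent: float = 2.5
    min_degree: int = 2
    max_degree: int = 20
    modules: list[ModuleSpec] = field(default_factory=_default_modules)
    drugs: list[DrugSpec] = field(default_factory=_default_drugs)
    adverse_se: str = "se_B"
    # P(adverse label) by planted distance to the adverse SE module
    label_probs: dict = field(default_factory=lambda: {0: 0.85, 1: 0.35})
    label_prob_far: float = 0.05
    n_other_se_terms: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        for m in self.modules:
            if m.size <= 0 or m.size > self.n_nodes:
                raise ValueError(f"module {m.id!r} size {m.size} infeasible for "
                                 f"{self.n_nodes} nodes")
            if not 0.0 <= m.density <= 1.0:
                raise ValueError(f"module {m.id!r} density outside [0, 1]")
        for d in self.drugs:
            if d.count <= 0 or d.targets_per_drug <= 0:
                raise ValueError("drug counts must be positive")


@dataclass
class Scenario:
    interactome: Interactome
    gene_sets: list[GeneSet]
    drug_profiles: list[DrugProfile]
    catalog: SideEffectCatalog
    ground_truth: pd.DataFrame   # drug, module, distance, placement
    adverse_drugs: set[str]
    config: ScenarioConfig


def _background_graph(config: ScenarioConfig, rng: np.random.Generator) -> nx.Graph:
    if config.edge_model == "er":
        g = nx.gnp_random_graph(config.n_nodes, config.er_p,
                                seed=int(rng.integers(2**31)))
    elif config.edge_model == "powerlaw":
        u = rng.random(config.n_nodes)
        a = config.powerlaw_exponent
        lo, hi = config.min_degree, config.max_degree
        # inverse-CDF sample of a truncated continuous power law, floored
        deg = np.floor((lo**(1 - a) + u * (hi**(1 - a) - lo**(1 - a)))
                       ** (1.0 / (1 - a))).astype(int)
        if deg.sum() % 2:
            deg[0] += 1
        g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise ValueError(f"unknown edge model {config.edge_model!r}")
    return nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})


def _plant_module(g: nx.Graph, members: list[str], density: float,
                  rng: np.random.Generator) -> None:
    """Wire *members* into a connected induced subgraph of roughly the
    requested density (random recursive tree + uniform extra edges)."""
    order = list(members)
    rng.shuffle(order)
    for i in range(1, len(order)):
        g.add_edge(order[i], order[rng.integers(i)])
    want = int(round(density * len(members) * (len(members) - 1) / 2))
    candidates = [e for e in itertools.combinations(sorted(members), 2)
                  if not g.has_edge(*e)]
    have = sum(1 for e in itertools.combinations(members, 2) if g.has_edge(*e))
    extra = min(max(want - have, 0), len(candidates))
    if extra:
        for idx in rng.choice(len(candidates), size=extra, replace=False):
            g.add_edge(*candidates[idx])


def make_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate a full scenario; byte-identical outputs at a fixed seed."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    g = _background_graph(config, rng)

    lcc = max(nx.connected_components(g), key=len)
    placeable = sorted(lcc)
    total_module_nodes = sum(m.size for m in config.modules)
    if total_module_nodes > len(placeable):
        raise ValueError("modules larger than the graph's usable component")

    chosen = rng.choice(placeable, size=total_module_nodes, replace=False).tolist()
    gene_sets, module_nodes = [], {}
    offset = 0
    for spec in config.modules:
        members = chosen[offset:offset + spec.size]
        offset += spec.size
        _plant_module(g, members, spec.density, rng)
        module_nodes[spec.id] = set(members)
        gene_sets.append(GeneSet(spec.id, frozenset(members), role=spec.role))

    interactome = Interactome(g)
    all_module_nodes = set().union(*module_nodes.values())
    dist_to = {mid: _min_distances(interactome.adjacency, nodes)
               for mid, nodes in module_nodes.items()}

    drugs: list[DrugProfile] = []
    placements: dict[str, str] = {}
    for spec in config.drugs:
        if spec.placement[0] == "inside":
            pool = sorted(module_nodes[spec.placement[1]])
        elif spec.placement[0] == "ring":
            _, mid, k = spec.placement
            pool = sorted(n for n, d in dist_to[mid].items()
                          if d == k and n not in all_module_nodes)
        elif spec.placement[0] == "random":
            pool = sorted(set(placeable) - all_module_nodes)
        else:
            raise ValueError(f"unknown placement {spec.placement!r}")
        if len(pool) < spec.targets_per_drug:
            raise ValueError(f"placement {spec.placement!r} offers only "
                             f"{len(pool)} candidate targets")
        for i in range(spec.count):
            drug_id = f"{spec.prefix}_{i:02d}"
            targets = rng.choice(pool, size=spec.targets_per_drug,
                                 replace=False).tolist()
            drugs.append(DrugProfile(drug_id, frozenset(targets)))
            placements[drug_id] = ":".join(map(str, spec.placement))

    gt_rows = []
    dist_of: dict[tuple[str, str], float] = {}
    for drug in drugs:
        for mid in module_nodes:
            finite = [dist_to[mid][t] for t in drug.targets if t in dist_to[mid]]
            d = float(np.mean(finite)) if finite else np.nan
            dist_of[(drug.id, mid)] = d
            gt_rows.append({"drug": drug.id, "module": mid, "distance": d,
                            "placement": placements[drug.id]})
    ground_truth = pd.DataFrame(gt_rows)

    adverse: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    vocab = [f"SE_term_{i:02d}" for i in range(config.n_other_se_terms)]
    shared_vocab = vocab[:max(1, len(vocab) // 2)]
    for drug in drugs:
        d = dist_of.get((drug.id, config.adverse_se), np.nan)
        prob = config.label_probs.get(int(d) if d == int(d) else -1,
                                      config.label_prob_far) \
            if not np.isnan(d) else config.label_prob_far
        if rng.random() < prob:
            adverse.add(drug.id)
            pairs.add((drug.id, config.adverse_se))
        source = shared_vocab if drug.id in adverse else vocab
        n_terms = int(rng.integers(2, 6))
        for term in rng.choice(source, size=min(n_terms, len(source)),
                               replace=False):
            pairs.add((drug.id, str(term)))
    catalog = SideEffectCatalog(frozenset(pairs))
    return Scenario(interactome, gene_sets, drugs, catalog, ground_truth,
                    adverse, config)


def write_scenario(scenario: Scenario, directory: str | Path) -> dict[str, Path]:
    """Write a scenario as the TSV dialects the loaders read (with headers);
    returns the file paths. The directory is created if missing."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"edges": directory / "edges.tsv",
             "gene_sets": directory / "gene_sets.tsv",
             "drug_targets": directory / "drug_targets.tsv",
             "se_labels": directory / "se_labels.tsv",
             "ground_truth": directory / "ground_truth.tsv"}
    scenario.interactome.write_edge_table(paths["edges"])
    with paths["gene_sets"].open("w") as fh:
        fh.write("set_id\tgene\n")
        for gs in scenario.gene_sets:
            for gene in sorted(gs.genes):
                fh.write(f"{gs.id}\t{gene}\n")
    with paths["drug_targets"].open("w") as fh:
        fh.write("drug_id\ttarget\n")
        for drug in scenario.drug_profiles:
            for t in sorted(drug.targets):
                fh.write(f"{drug.id}\t{t}\n")
    with paths["se_labels"].open("w") as fh:
        fh.write("drug_id\tside_effect\n")
        for d, t in sorted(scenario.catalog.pairs):
            fh.write(f"{d}\t{t}\n")
    scenario.ground_truth.sort_values(["drug", "module"]).to_csv(
        paths["ground_truth"], sep="\t", index=False)
    return paths
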