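"""Readers and containers for interactome, gene-set, drug-target and label tables.

All tables are plain delimited text (tab by default). Gene and drug
identifiers are opaque, case-sensitive strings: no identifier mapping is
attempted, inputs are assumed pre-mapped to a single namespace. Whether the
first row is a header is decided by an explicit flag, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

import networkx as nx

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row in an input table, with its line number."""


@dataclass
class LoadReport:
    """Bookkeeping emitted by :func:`load_interactome`."""

    rows_read: int = 0
    self_loops_dropped: int = 0
    duplicates_collapsed: int = 0
    extra_columns_seen: bool = False


class Interactome:
    """An undirected, unweighted protein-protein interaction network.

    Thin wrapper over a :class:`networkx.Graph` guaranteeing no self-loops
    and no duplicate edges, plus a cached dict-of-sets adjacency used by the
    BFS primitives in :mod:`sescreen.modules` and :mod:`sescreen.proximity`.
    """

    def __init__(self, graph: nx.Graph, report: LoadReport | None = None):
        if any(u == v for u, v in graph.edges()):
            raise ValueError("interactome must not contain self-loops")
        self.graph = graph
        self.report = report or LoadReport()
        self._adjacency: dict[str, set[str]] | None = None

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "Interactome":
        report = LoadReport()
        g = nx.Graph()
        for u, v in pairs:
            report.rows_read += 1
            if u == v:
                report.self_loops_dropped += 1
                continue
            if g.has_edge(u, v):
                report.duplicates_collapsed += 1
                continue
            g.add_edge(u, v)
        return cls(g, report)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    @property
    def adjacency(self) -> dict[str, set[str]]:
        """Dict-of-sets adjacency, built once and cached."""
        if self._adjacency is None:
            self._adjacency = {n: set(self.graph.neighbors(n)) for n in self.graph.nodes}
        return self._adjacency

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}

    def write_edge_table(self, path: Union[str, Path], delimiter: str = "\t",
                         header: bool = True) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header:
                fh.write(delimiter.join(("gene_a", "gene_b")) + "\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                fh.write(f"{u}{delimiter}{v}\n")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()


@dataclass(frozen=True)
class GeneSet:
    """A disease or side-effect module: an identifier plus its gene set."""

    id: str
    genes: frozenset[str]
    role: str = "disease"  # "disease" | "side_effect"

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")
        if self.role not in ("disease", "side_effect"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class DrugProfile:
    """A drug and its protein targets."""

    id: str
    targets: frozenset[str]

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.id!r} has no targets")


@dataclass(frozen=True)
class SideEffectCatalog:
    """Known drug -> side-effect-term associations (SIDER-like)."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def terms_for(self, drug: str) -> set[str]:
        return {t for d, t in self.pairs if d == drug}

    def drugs_with(self, term: str) -> set[str]:
        return {d for d, t in self.pairs if t == term}


class Restriction(NamedTuple):
    """Result of mapping an entity onto the interactome."""

    entity: Union[GeneSet, DrugProfile, None]
    dropped: list[str]
    usable: bool


def _iter_rows(path: Union[str, Path], delimiter: str, header: bool):
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line.split(delimiter)


def load_interactome(path: Union[str, Path], delimiter: str = "\t",
                     header: bool = False) -> Interactome:
    """Load an edge table into an :class:`Interactome`.

    Self-loops are dropped and duplicate rows (in either orientation)
    collapsed; both are counted in the load report. Rows with more than two
    columns use the first two (extra columns are ignored with a warning);
    rows with fewer than two non-empty fields raise :class:`ParseError`.
    """
    report = LoadReport()
    g = nx.Graph()
    extra_warned = False
    for lineno, fields in _iter_rows(path, delimiter, header):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: expected two identifier fields, got {fields!r}")
        if len(fields) > 2 and not extra_warned:
            logger.warning("%s:%d: extra columns ignored", path, lineno)
            report.extra_columns_seen = True
            extra_warned = True
        u, v = fields[0].strip(), fields[1].strip()
        report.rows_read += 1
        if u == v:
            report.self_loops_dropped += 1
            continue
        if g.has_edge(u, v):
            report.duplicates_collapsed += 1
            continue
        g.add_edge(u, v)
    if report.rows_read == 0:
        raise ParseError(f"{path}: empty edge table")
    return Interactome(g, report)


def _load_two_column(path, delimiter, header, what):
    """(id, value) rows grouped by id, order of first appearance preserved."""
    groups: dict[str, set[str]] = {}
    order: list[str] = []
    for lineno, fields in _iter_rows(path, delimiter, header):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: expected ({what}) row, got {fields!r}")
        key, value = fields[0].strip(), fields[1].strip()
        if key not in groups:
            groups[key] = set()
            order.append(key)
        groups[key].add(value)
    return [(k, groups[k]) for k in order]


def load_gene_sets(path: Union[str, Path], role: str = "disease",
                   delimiter: str = "\t", header: bool = False) -> list[GeneSet]:
    """Load a (set_id, gene) table into one :class:`GeneSet` per distinct id."""
    return [GeneSet(k, frozenset(genes), role=role)
            for k, genes in _load_two_column(path, delimiter, header, "set_id, gene")]


def load_drug_targets(path: Union[str, Path], delimiter: str = "\t",
                      header: bool = False) -> list[DrugProfile]:
    """Load a (drug_id, target_gene) table into :class:`DrugProfile` objects."""
    return [DrugProfile(k, frozenset(targets))
            for k, targets in _load_two_column(path, delimiter, header, "drug_id, target")]


def load_side_effect_labels(path: Union[str, Path], delimiter: str = "\t",
                            header: bool = False) -> SideEffectCatalog:
    """Load a (drug_id, side_effect_term) table into a :class:`SideEffectCatalog`."""
    pairs = set()
    for lineno, fields in _iter_rows(path, delimiter, header):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: expected (drug_id, term) row, got {fields!r}")
        pairs.add((fields[0].strip(), fields[1].strip()))
    return SideEffectCatalog(frozenset(pairs))


def restrict_to_interactome(entity: Union[GeneSet, DrugProfile],
                            interactome: Interactome) -> Restriction:
    """Keep only genes present in the interactome; report the dropped ones.

    An entity whose gene list becomes empty is returned as ``usable=False``
    with ``entity=None`` rather than raising: downstream code must check the
    flag instead of silently scoring an empty module.
    """
    attr = "genes" if isinstance(entity, GeneSet) else "targets"
    genes = getattr(entity, attr)
    kept = frozenset(g for g in genes if g in interactome.adjacency)
    dropped = sorted(genes - kept)
    if not kept:
        return Restriction(None, dropped, False)
    return Restriction(replace(entity, **{attr: kept}), dropped, True)
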