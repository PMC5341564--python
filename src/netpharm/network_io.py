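"""Weighted PPI edge tables, gene lists, and background-network construction.

The background network is built from a confidence-scored edge table (STRING
dialect: ``protein1 protein2 combined_score`` with raw scores on 0-1000) by
keeping every edge at or above a confidence cutoff.  Seed genes (disease genes,
drug targets) that the cutoff would exclude are re-admitted through a per-gene
threshold-lowering rule so that every seed present in the raw data ends up in
the network.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "ParseError",
    "EdgeRecord",
    "GeneList",
    "WeightedNetwork",
    "read_weighted_edges",
    "write_weighted_edges",
    "read_gene_list",
    "write_gene_list",
    "build_background_network",
    "write_network",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected weighted interaction, endpoints in canonical sorted order."""

    node_a: str
    node_b: str
    weight: float

    def __post_init__(self) -> None:
        a, b = self.node_a.strip(), self.node_b.strip()
        if a == b:
            raise ValueError(f"self-edge not allowed: {a!r}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "node_a", a)
        object.__setattr__(self, "node_b", b)
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free, non-empty list of gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene list {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene list {self.name!r} contains duplicates")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneList":
        """Build a list, trimming whitespace and dropping duplicates (order kept)."""
        seen: dict[str, None] = {}
        for g in genes:
            g = g.strip()
            if g:
                seen.setdefault(g)
        return cls(name=name, genes=tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class WeightedNetwork:
    """Undirected weighted graph with no isolated nodes.

    ``nodes`` is the sorted node order used for all matrix/vector indexing,
    so results are reproducible regardless of edge-file ordering.
    """

    graph: nx.Graph
    unmapped_required: tuple[str, ...] = ()
    _nodes: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError("network is empty")
        isolated = [n for n, d in self.graph.degree() if d == 0]
        if isolated:
            raise ValueError(f"network has isolated nodes: {isolated[:5]}")
        self._nodes = tuple(sorted(self.graph.nodes))

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_weights(self) -> dict[str, float]:
        return {n: w for n, w in self.graph.degree(weight="weight")}

    def edge_records(self) -> list[EdgeRecord]:
        recs = [
            EdgeRecord(a, b, float(d["weight"]))
            for a, b, d in self.graph.edges(data=True)
        ]
        recs.sort(key=lambda e: e.key)
        return recs

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def read_weighted_edges(path: str | Path, score_max: float = 1000.0) -> list[EdgeRecord]:
    """Parse a STRING-dialect edge table into canonical deduplicated records.

    Raw scores are rescaled by ``score_max`` and clamped to [0, 1].  Duplicate
    pairs (including reversed orientation) keep the maximum weight; self-edges
    are dropped.  A header line is auto-detected from a non-numeric third
    column on the first data line.  An empty file yields an empty list.
    """
    if score_max <= 0:
        raise ValueError("score_max must be positive")
    best: dict[tuple[str, str], EdgeRecord] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            try:
                raw = float(cols[2])
            except ValueError:
                if first_data_line:  # header row
                    first_data_line = False
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric score {cols[2]!r}") from None
            first_data_line = False
            a, b = cols[0], cols[1]
            if a.strip() == b.strip():
                continue
            w = min(1.0, max(0.0, raw / score_max))
            rec = EdgeRecord(a, b, w)
            prev = best.get(rec.key)
            if prev is None or rec.weight > prev.weight:
                best[rec.key] = rec
    return [best[k] for k in sorted(best)]


def write_weighted_edges(records: Sequence[EdgeRecord], path: str | Path,
                         score_max: float = 1000.0) -> None:
    """Write records back in STRING dialect (raw score = weight * score_max)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for rec in sorted(records, key=lambda e: e.key):
            fh.write(f"{rec.node_a}\t{rec.node_b}\t{rec.weight * score_max:g}\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read one identifier per line (first TSV column); '#' lines are comments."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0].split()[0])
    label = name if name is not None else Path(path).stem
    if not any(g.strip() for g in genes):
        raise ValueError(f"gene list file {path} is empty")
    return GeneList.from_iterable(label, genes)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {genes.name}\n")
        for g in genes:
            fh.write(g + "\n")


def build_background_network(
    edges: Sequence[EdgeRecord],
    required_genes: GeneList | Sequence[str] | None = None,
    threshold: float = 0.9,
) -> WeightedNetwork:
    """Filter edges at ``threshold``, then lower it per-gene for required genes.

    Every edge with weight >= threshold is kept.  For each required gene that
    the filter excluded but that has raw edges, its edges are admitted in
    descending weight order (ties broken by neighbour id) until one attaches
    the gene to the already-filtered network; if none of its neighbours is in
    the network, all its raw edges are kept so the gene is not isolated.
    Required genes with no raw edges at all are reported in
    ``unmapped_required`` (a warning, not an error).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    raw_incident: dict[str, list[EdgeRecord]] = {}
    for rec in edges:
        raw_incident.setdefault(rec.node_a, []).append(rec)
        raw_incident.setdefault(rec.node_b, []).append(rec)
        if rec.weight >= threshold:
            g.add_edge(rec.node_a, rec.node_b, weight=rec.weight)

    unmapped: list[str] = []
    req = list(required_genes) if required_genes is not None else []
    for gene in req:
        if gene in g:
            continue
        incident = raw_incident.get(gene)
        if not incident:
            unmapped.append(gene)
            continue
        present = set(g.nodes)
        ordered = sorted(
            incident,
            key=lambda e: (-e.weight, e.node_b if e.node_a == gene else e.node_a),
        )
        for rec in ordered:
            other = rec.node_b if rec.node_a == gene else rec.node_a
            g.add_edge(rec.node_a, rec.node_b, weight=rec.weight)
            if other in present:
                break

    if g.number_of_nodes() == 0:
        raise ValueError("background network is empty at this threshold")
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} required gene(s) absent from the raw edge table: "
            f"{unmapped[:10]}",
            stacklevel=2,
        )
    return WeightedNetwork(graph=g, unmapped_required=tuple(unmapped))


def write_network(network: WeightedNetwork, tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    """Export edges as ``node_a node_b weight`` TSV plus a JSON summary."""
    with open(tsv_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for rec in network.edge_records():
            fh.write(f"{rec.node_a}\t{rec.node_b}\t{rec.weight!r}\n")
    if json_path is not None:
        summary = {
            "n_nodes": network.n_nodes,
            "n_edges": network.n_edges,
            "unmapped_required_genes": list(network.unmapped_required),
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
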