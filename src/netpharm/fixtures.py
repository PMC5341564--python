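"""Synthetic study fixtures: scale-free weighted networks with a planted
disease module, pathway collections enriched for the module, and fold-change
expression tables.

These generators emulate the statistical structure the propagation method
assumes — a heavy-tailed PPI-like degree distribution, a densified
disease-affected sub-network, pathway sets that preferentially contain module
genes, and a handful of strongly differentially expressed genes — so the full
pipeline (network build, RWR, permutation Z, pathway projection) can be
exercised and calibrated end to end without any external database.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network_io import (
    EdgeRecord,
    GeneList,
    WeightedNetwork,
    write_gene_list,
    write_weighted_edges,
)
from .pathways import Pathway, PathwayCollection, write_gmt
from .seeds import ExpressionTable, write_expression_table

__all__ = [
    "FixtureSpec",
    "generate_network",
    "fixture_network",
    "plant_disease_module",
    "generate_pathway_collection",
    "generate_expression_table",
    "make_demo_workspace",
]

logger = logging.getLogger(__name__)

#: Prefix used for pathways that preferentially sample planted-module genes;
#: recovery tests read ground truth straight off the name.
ENRICHED_PREFIX = "PW_ENR_"
BACKGROUND_PREFIX = "PW_BG_"


@dataclass(frozen=True)
class FixtureSpec:
    """Default study conditions for the synthetic benchmark.

    500 nodes with attachment 3 gives a connected scale-free graph of ~1500
    edges; weights are uniform on [0.4, 1] (mimicking a confidence-filtered
    interaction table); the planted module of 30 nodes is densified to
    within-module edge probability 0.35, strong enough that propagation from
    the module is clearly localized yet far from a clique.
    """

    n_nodes: int = 500
    attachment: int = 3
    weight_low: float = 0.4
    module_size: int = 30
    module_density: float = 0.35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.module_size <= self.n_nodes):
            raise ValueError("need 0 < module_size <= n_nodes")
        if not (0.0 < self.module_density <= 1.0):
            raise ValueError("module_density must be in (0, 1]")
        if not (0.0 <= self.weight_low < 1.0):
            raise ValueError("weight_low must be in [0, 1)")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(spec: FixtureSpec) -> tuple[list[EdgeRecord], list[str]]:
    """Connected scale-free weighted graph; reproducible under ``spec.rng_seed``.

    Preferential-attachment growth with m = ``attachment`` edges per new node
    yields m * (n - m) edges and a heavy-tailed degree distribution.  If a
    parameter combination ever produces a disconnected graph, components are
    bridged with minimum-weight edges (logged).
    """
    rng = np.random.default_rng(spec.rng_seed)
    g = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment, seed=int(rng.integers(2**31))
    )
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        logger.warning("generated graph disconnected (%d components); bridging", len(comps))
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    names = [_node_name(i) for i in range(spec.n_nodes)]
    records = []
    for i, j in sorted(g.edges()):
        w = float(rng.uniform(spec.weight_low, 1.0))
        records.append(EdgeRecord(names[i], names[j], w))
    return records, names


def plant_disease_module(
    network: WeightedNetwork,
    module_size: int,
    module_density: float,
    rng_seed: int,
    weight_low: float = 0.4,
) -> tuple[WeightedNetwork, GeneList]:
    """Densify a random node subset into a disease-affected sub-network.

    Draws ``module_size`` nodes and adds within-module edges until the module's
    edge probability reaches ``module_density`` (existing edges count toward
    the target; density 1 yields a clique).  Returns the augmented network and
    the module members as the disease gene list.
    """
    if not (0 < module_size <= network.n_nodes):
        raise ValueError("need 0 < module_size <= n_nodes")
    rng = np.random.default_rng(rng_seed)
    members = sorted(rng.choice(np.asarray(network.nodes), size=module_size, replace=False))
    g = network.graph.copy()
    possible = [
        (a, b)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if not g.has_edge(a, b)
    ]
    n_pairs = module_size * (module_size - 1) // 2
    target_edges = int(round(module_density * n_pairs))
    have = n_pairs - len(possible)
    n_add = max(0, target_edges - have)
    if n_add and possible:
        chosen = rng.choice(len(possible), size=min(n_add, len(possible)), replace=False)
        for idx in sorted(chosen):
            a, b = possible[idx]
            g.add_edge(a, b, weight=float(rng.uniform(weight_low, 1.0)))
    disease = GeneList.from_iterable("planted_module", members)
    return WeightedNetwork(graph=g, unmapped_required=network.unmapped_required), disease


def fixture_network(spec: FixtureSpec = FixtureSpec()) -> tuple[WeightedNetwork, GeneList]:
    """Generate a network and plant its disease module in one call."""
    records, _ = generate_network(spec)
    g = nx.Graph()
    for rec in records:
        g.add_edge(rec.node_a, rec.node_b, weight=rec.weight)
    return plant_disease_module(
        WeightedNetwork(graph=g),
        spec.module_size,
        spec.module_density,
        rng_seed=spec.rng_seed + 1,
        weight_low=spec.weight_low,
    )


def generate_pathway_collection(
    nodes: list[str],
    n_pathways: int = 200,
    size_range: tuple[int, int] = (10, 40),
    module_genes: GeneList | None = None,
    enriched_fraction: float = 0.2,
    rng_seed: int = 0,
) -> PathwayCollection:
    """Synthetic gene-set collection with a known enriched subset.

    A fraction of pathways ("enriched", named ``PW_ENR_*``) draw roughly 60% of
    their genes from the planted module and the rest uniformly; the remainder
    (``PW_BG_*``) sample uniformly from all nodes.  Names carry the ground
    truth so recovery tests need no side channel.
    """
    lo, hi = size_range
    if not (0 < lo <= hi <= len(nodes)):
        raise ValueError("infeasible size_range")
    if not (0.0 <= enriched_fraction <= 1.0):
        raise ValueError("enriched_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_enriched = int(round(enriched_fraction * n_pathways))
    if n_enriched and module_genes is None:
        raise ValueError("module_genes required when enriched_fraction > 0")
    all_nodes = np.asarray(nodes)
    module = np.asarray(list(module_genes)) if module_genes is not None else np.asarray([])
    pathways = []
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        enriched = k < n_enriched
        if enriched:
            n_mod = min(len(module), max(1, int(round(0.6 * size))))
            mod_part = rng.choice(module, size=n_mod, replace=False)
            rest = rng.choice(all_nodes, size=size - n_mod, replace=False)
            genes = list(dict.fromkeys([*mod_part, *rest]))
            name = f"{ENRICHED_PREFIX}{k:04d}"
        else:
            genes = list(rng.choice(all_nodes, size=size, replace=False))
            name = f"{BACKGROUND_PREFIX}{k:04d}"
        pathways.append(Pathway(name=name, description="synthetic", genes=tuple(genes)))
    return PathwayCollection(tuple(pathways))


def generate_expression_table(
    nodes: list[str],
    n_de: int = 60,
    fold_range: tuple[float, float] = (4.5, 12.0),
    rng_seed: int = 0,
    upper: float = 4.0,
    lower: float = 0.25,
) -> ExpressionTable:
    """Fold-ratio table with ``n_de`` planted differentially expressed genes.

    Planted genes get ratios strictly outside (lower, upper): half up-regulated
    with folds drawn from ``fold_range``, half down-regulated with the
    reciprocal folds.  All other genes get ratios near 1 (within the null
    band), so the fold-change filter recovers exactly the planted set.
    """
    if n_de > len(nodes):
        raise ValueError("n_de exceeds number of genes")
    if not (fold_range[0] > upper and fold_range[1] >= fold_range[0]):
        raise ValueError(f"fold_range must lie strictly above the threshold {upper}")
    rng = np.random.default_rng(rng_seed)
    de_idx = set(rng.choice(len(nodes), size=n_de, replace=False).tolist())
    rows = []
    for i, gene in enumerate(nodes):
        if i in de_idx:
            fold = float(rng.uniform(*fold_range))
            ratio = fold if rng.random() < 0.5 else 1.0 / fold
        else:
            ratio = float(np.clip(np.exp(rng.normal(0.0, 0.3)), lower * 1.05, upper * 0.95))
        rows.append((gene, ratio))
    return ExpressionTable.from_records(rows)


def make_demo_workspace(outdir: str | Path, spec: FixtureSpec = FixtureSpec()) -> dict[str, Path]:
    """Emit a complete demo workspace in the formats the pipeline reads.

    Writes the edge table, disease gene list, drug-target list (a sample of
    module genes), a GMT collection, and an expression table; returns the path
    of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, disease = fixture_network(spec)
    rng = np.random.default_rng(spec.rng_seed + 2)
    n_targets = max(2, spec.module_size // 2)
    targets = GeneList.from_iterable(
        "demo_targets", sorted(rng.choice(np.asarray(disease.genes), size=n_targets, replace=False))
    )
    collection = generate_pathway_collection(
        list(network.nodes), module_genes=disease, rng_seed=spec.rng_seed + 3
    )
    expr = generate_expression_table(list(network.nodes), rng_seed=spec.rng_seed + 4)

    paths = {
        "edges": outdir / "edges.tsv",
        "disease_genes": outdir / "disease_genes.txt",
        "drug_targets": outdir / "drug_targets.txt",
        "pathways": outdir / "pathways.gmt",
        "expression": outdir / "expression.tsv",
    }
    write_weighted_edges(network.edge_records(), paths["edges"])
    write_gene_list(disease, paths["disease_genes"])
    write_gene_list(targets, paths["drug_targets"])
    write_gmt(collection, paths["pathways"])
    write_expression_table(expr, paths["expression"])
    return paths
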