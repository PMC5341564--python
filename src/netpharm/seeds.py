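"""Seed (initial preference) vectors for disease genes, drug targets, and
differentially expressed genes, plus random counterpart sampling.

Three seeding conventions are supported:

* disease genes — each of the m network-mapped disease genes gets 1/m, so the
  seed vector is a probability distribution over the disease module;
* drug targets — each mapped target gets a fixed 0.01, reflecting the weaker
  per-target effect assumed for natural-product formulas; the vector sums to
  0.01 x (mapped target count) and is deliberately not a distribution;
* expression-weighted — each mapped differentially expressed gene is weighted
  by |log2(fold ratio)|, normalized to sum 1 (an 8-fold induction and an
  8-fold repression carry equal weight).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .network_io import GeneList, WeightedNetwork
from .rwr import InitialVector

__all__ = [
    "SeedAssignment",
    "ExpressionTable",
    "split_mapped",
    "disease_seed_vector",
    "drug_seed_vector",
    "expression_seed_vector",
    "filter_de_genes",
    "read_expression_table",
    "write_expression_table",
    "sample_random_seed_sets",
    "sample_degree_matched_sets",
    "DRUG_TARGET_WEIGHT",
]

DRUG_TARGET_WEIGHT = 0.01

SeedMode = Literal["disease_uniform", "drug_fixed", "expression_weighted"]


@dataclass(frozen=True)
class SeedAssignment:
    """Partition of a seed gene list into network-mapped and unmapped genes."""

    seed_genes: GeneList
    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]
    mode: SeedMode

    def __post_init__(self) -> None:
        if not self.mapped:
            raise ValueError(
                f"none of the {len(self.seed_genes)} seed genes of "
                f"{self.seed_genes.name!r} map to the network"
            )
        if set(self.mapped) | set(self.unmapped) != set(self.seed_genes.genes):
            raise ValueError("mapped and unmapped must partition the seed list")


@dataclass
class ExpressionTable:
    """Rows of (gene, mean expression ratio treatment/control); ratios > 0."""

    frame: pd.DataFrame  # columns: gene, ratio

    def __post_init__(self) -> None:
        if list(self.frame.columns) != ["gene", "ratio"]:
            raise ValueError("expression table needs columns ['gene', 'ratio']")
        if self.frame["gene"].duplicated().any():
            dup = self.frame.loc[self.frame["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene in expression table: {dup!r}")
        if (self.frame["ratio"] <= 0).any():
            raise ValueError("expression ratios must be positive")

    @classmethod
    def from_records(cls, rows: Sequence[tuple[str, float]]) -> "ExpressionTable":
        return cls(pd.DataFrame(rows, columns=["gene", "ratio"]))

    def __len__(self) -> int:
        return len(self.frame)


def split_mapped(genes: GeneList, network: WeightedNetwork, mode: SeedMode) -> SeedAssignment:
    mapped = tuple(g for g in genes if g in network)
    unmapped = tuple(g for g in genes if g not in network)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)}/{len(genes)} genes of {genes.name!r} not in the network",
            stacklevel=2,
        )
    return SeedAssignment(seed_genes=genes, mapped=mapped, unmapped=unmapped, mode=mode)


def disease_seed_vector(genes: GeneList, network: WeightedNetwork) -> InitialVector:
    """Uniform 1/m over the m network-mapped disease genes (sums to 1)."""
    assignment = split_mapped(genes, network, "disease_uniform")
    m = len(assignment.mapped)
    return InitialVector.from_dict({g: 1.0 / m for g in assignment.mapped}, network.nodes)


def drug_seed_vector(targets: GeneList, network: WeightedNetwork,
                     weight: float = DRUG_TARGET_WEIGHT) -> InitialVector:
    """Fixed ``weight`` (default 0.01) on every mapped drug target."""
    assignment = split_mapped(targets, network, "drug_fixed")
    return InitialVector.from_dict({g: weight for g in assignment.mapped}, network.nodes)


def expression_seed_vector(
    table: ExpressionTable,
    network: WeightedNetwork,
    mode: Literal["abs_log2", "raw_ratio"] = "abs_log2",
) -> InitialVector:
    """Seed vector weighted by differential expression, normalized to sum 1.

    ``abs_log2`` (default): weight_i = |log2 ratio_i| / sum_j |log2 ratio_j|,
    treating k-fold induction and repression symmetrically.  ``raw_ratio``:
    weight_i = ratio_i / sum_j ratio_j (up-regulation dominates; provided for
    sensitivity analysis).
    """
    genes = GeneList.from_iterable("expression_seeds", table.frame["gene"])
    assignment = split_mapped(genes, network, "expression_weighted")
    sub = table.frame[table.frame["gene"].isin(assignment.mapped)]
    if mode == "abs_log2":
        raw = np.abs(np.log2(sub["ratio"].to_numpy()))
    elif mode == "raw_ratio":
        raw = sub["ratio"].to_numpy().astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all mapped genes have ratio 1 (zero log-fold weight)")
    values = dict(zip(sub["gene"], raw / total))
    return InitialVector.from_dict(values, network.nodes)


def filter_de_genes(table: ExpressionTable, upper: float = 4.0,
                    lower: float = 0.25) -> ExpressionTable:
    """Keep genes with ratio strictly > upper or strictly < lower."""
    if not (upper > 1.0 > lower > 0.0):
        raise ValueError("need upper > 1 > lower > 0")
    mask = (table.frame["ratio"] > upper) | (table.frame["ratio"] < lower)
    kept = table.frame[mask].reset_index(drop=True)
    if kept.empty:
        warnings.warn("no genes pass the differential-expression filter", stacklevel=2)
    return ExpressionTable(kept)


def read_expression_table(path: str | Path) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = ["gene", "ratio"] + list(frame.columns[2:])
    return ExpressionTable(frame[["gene", "ratio"]].astype({"gene": str, "ratio": float}))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def sample_random_seed_sets(network: WeightedNetwork, size: int, n_sets: int,
                            rng_seed: int) -> list[GeneList]:
    """Draw ``n_sets`` sets of ``size`` distinct nodes uniformly at random.

    Sampling is without replacement within each set, uniform over all network
    nodes, and fully reproducible under ``rng_seed``.
    """
    if size > network.n_nodes:
        raise ValueError(f"size {size} exceeds network size {network.n_nodes}")
    if size < 1 or n_sets < 1:
        raise ValueError("size and n_sets must be positive")
    rng = np.random.default_rng(rng_seed)
    nodes = np.asarray(network.nodes)
    return [
        GeneList.from_iterable(f"random_{k}", rng.choice(nodes, size=size, replace=False))
        for k in range(n_sets)
    ]


def sample_degree_matched_sets(network: WeightedNetwork, reference: GeneList,
                               n_sets: int, rng_seed: int,
                               n_bins: int = 10) -> list[GeneList]:
    """Random counterparts matched to the reference set's weighted-degree profile.

    Nodes are binned into ``n_bins`` weighted-degree quantiles; each counterpart
    draws, per bin, as many nodes as the reference set has there.  Optional
    sensitivity-analysis mode; the default null is plain uniform sampling.
    """
    ref = [g for g in reference if g in network]
    if not ref:
        raise ValueError("no reference gene maps to the network")
    deg = network.degree_weights()
    nodes = list(network.nodes)
    order = np.argsort([deg[n] for n in nodes], kind="stable")
    bin_of = {}
    for rank, idx in enumerate(order):
        bin_of[nodes[idx]] = min(n_bins - 1, rank * n_bins // len(nodes))
    by_bin: dict[int, list[str]] = {}
    for n in nodes:
        by_bin.setdefault(bin_of[n], []).append(n)
    need: dict[int, int] = {}
    for g in ref:
        need[bin_of[g]] = need.get(bin_of[g], 0) + 1
    rng = np.random.default_rng(rng_seed)
    out = []
    for k in range(n_sets):
        picked: list[str] = []
        for b, count in sorted(need.items()):
            pool = by_bin[b]
            picked.extend(rng.choice(pool, size=min(count, len(pool)), replace=False))
        out.append(GeneList.from_iterable(f"degree_matched_{k}", picked))
    return out
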