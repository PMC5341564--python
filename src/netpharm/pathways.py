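"""Pathway projection of node scores, top-fraction selection, and set overlaps.

Node-level RWR scores are mapped onto a gene-set collection (GMT format): a
pathway gene absent from the network contributes a score of zero, and the
pathway score is the mean over ALL of its genes (the full pathway size is the
denominator).  The pathways in the highest 5% of scores are called
"significantly regulated"; agreement between disease-, drug-, and
expression-derived selections is summarized by Venn-style intersection counts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import floor
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .rwr import ScoreVector

__all__ = [
    "Pathway",
    "PathwayCollection",
    "OverlapSummary",
    "read_gmt",
    "write_gmt",
    "score_pathways",
    "select_top_fraction",
    "overlap_counts",
    "percent_shared",
]


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    """Ordered collection of uniquely named pathways."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise ValueError(f"duplicate pathway name: {dup!r}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> Pathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pathways)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse MSigDB GMT: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are removed (order preserved); a duplicate
    pathway name or a line with fewer than 3 fields is an error.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, description = fields[0], fields[1]
            genes: dict[str, None] = {}
            for g in fields[2:]:
                g = g.strip()
                if g:
                    genes.setdefault(g)
            pathways.append(Pathway(name=name, description=description, genes=tuple(genes)))
    return PathwayCollection(tuple(pathways))


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


def score_pathways(
    x: ScoreVector,
    collection: PathwayCollection,
    denominator: Literal["all", "mapped"] = "all",
) -> pd.DataFrame:
    """Per-pathway mean of node scores, zero-filling genes absent from the network.

    With ``denominator="all"`` (default) the mean divides by the full pathway
    size, so unmapped genes dilute the score; ``"mapped"`` divides by the
    number of network-mapped genes only (alternative behaviour for sensitivity
    analysis; a pathway with no mapped genes scores 0 either way).
    """
    score_of = x.as_dict()
    rows = []
    for p in collection:
        mapped = [g for g in p.genes if g in score_of]
        total = sum(score_of[g] for g in mapped)
        if denominator == "all":
            mean = total / len(p.genes)
        elif denominator == "mapped":
            mean = total / len(mapped) if mapped else 0.0
        else:
            raise ValueError(f"unknown denominator mode {denominator!r}")
        rows.append((p.name, len(p.genes), len(mapped), mean))
    return pd.DataFrame(rows, columns=["pathway", "n_genes", "n_mapped", "mean_score"])


def select_top_fraction(table: pd.DataFrame, fraction: float = 0.05) -> set[str]:
    """Names of the floor(fraction * n) highest-scoring pathways.

    Ranking is by mean_score descending with ties broken by lexicographic
    pathway name, so the selection is deterministic across runs and platforms.
    """
    if table.empty:
        raise ValueError("pathway score table is empty")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    k = floor(fraction * len(table))
    if k == 0:
        raise ValueError(
            f"floor({fraction} * {len(table)}) = 0 pathways; use a larger fraction"
        )
    ranked = table.sort_values(
        ["mean_score", "pathway"], ascending=[False, True], kind="stable"
    )
    return set(ranked["pathway"].head(k))


@dataclass
class OverlapSummary:
    """Venn decomposition of 2-4 named sets.

    ``labels`` maps the single-letter aliases A, B, C, D (in input order) to
    the caller's set names.  ``regions`` holds exclusive region counts keyed by
    the letters of exactly the sets containing those elements ("A", "AB", ...);
    ``intersections`` holds inclusive intersection cardinalities |A∩B| etc.
    """

    labels: dict[str, str]
    regions: dict[str, int]
    intersections: dict[str, int]
    union_size: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "labels": self.labels,
            "regions": self.regions,
            "intersections": self.intersections,
            "union_size": self.union_size,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def overlap_counts(named_sets: Mapping[str, Iterable[str]]) -> OverlapSummary:
    """Counts for every intersection region of 2-4 named sets."""
    names = list(named_sets)
    if not (2 <= len(names) <= 4):
        raise ValueError("overlap report supports 2-4 sets")
    letters = "ABCD"[: len(names)]
    sets = {letter: set(named_sets[name]) for letter, name in zip(letters, names)}
    universe = set().union(*sets.values())

    regions: dict[str, int] = {}
    for element in universe:
        key = "".join(letter for letter in letters if element in sets[letter])
        regions[key] = regions.get(key, 0) + 1

    intersections: dict[str, int] = {}
    for size in range(2, len(letters) + 1):
        for combo in combinations(letters, size):
            inter = set.intersection(*(sets[l] for l in combo))
            intersections["".join(combo)] = len(inter)

    return OverlapSummary(
        labels={letter: name for letter, name in zip(letters, names)},
        regions=regions,
        intersections=intersections,
        union_size=len(universe),
    )


def percent_shared(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be nonnegative")
    quant = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quant, rounding=ROUND_HALF_UP
    )
    return float(value)
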