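"""Drug-disease effect score and its permutation Z-score.

The anti-disease effect score of a drug is the inner product
S = <x_disease, x_drug> of the two converged RWR score vectors: it measures
how strongly the sub-network influenced by the drug's targets overlaps the
sub-network impacted by the disease genes.  Significance is calibrated by
rerunning the drug-side RWR on size-matched random counterpart node sets and
reporting Z = (S - mean_null) / sd_null.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .network_io import GeneList, WeightedNetwork
from .rwr import InitialVector, RWRConfig, ScoreVector, TransitionMatrix, column_normalize, rwr
from .seeds import (
    DRUG_TARGET_WEIGHT,
    disease_seed_vector,
    drug_seed_vector,
    sample_random_seed_sets,
    split_mapped,
)

__all__ = ["PermutationResult", "effect_score", "permutation_z", "assess_drug_disease"]

#: Z above this is conventionally called a significant deviation from the null.
DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class PermutationResult:
    """Observed effect score with its permutation null and Z-score."""

    observed: float
    null_scores: tuple[float, ...]
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    rng_seed: int | None
    z_threshold: float = DEFAULT_Z_THRESHOLD

    @property
    def significant(self) -> bool:
        return self.z > self.z_threshold

    def to_json(self, path: str | Path | None = None, *, include_null: bool = False) -> str:
        payload = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "n_perm": self.n_perm,
            "rng_seed": self.rng_seed,
            "z_threshold": self.z_threshold,
            "significant": self.significant,
        }
        if include_null:
            payload["null_scores"] = list(self.null_scores)
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def effect_score(x_disease: ScoreVector, x_drug: ScoreVector) -> float:
    """Inner product S = sum_i x_disease(i) * x_drug(i)."""
    if x_disease.nodes != x_drug.nodes:
        raise ValueError("score vectors are indexed over different node sets")
    return float(np.dot(x_disease.x, x_drug.x))


def permutation_z(observed: float, null_scores: Sequence[float],
                  rng_seed: int | None = None,
                  z_threshold: float = DEFAULT_Z_THRESHOLD) -> PermutationResult:
    """Z = (S - mean) / sd over the null scores, with sample (n-1) sd."""
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.size < 2:
        raise ValueError("need >= 2 null scores")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null scores have zero variance; Z undefined")
    return PermutationResult(
        observed=float(observed),
        null_scores=tuple(nulls.tolist()),
        null_mean=mean,
        null_sd=sd,
        z=(float(observed) - mean) / sd,
        n_perm=int(nulls.size),
        rng_seed=rng_seed,
        z_threshold=z_threshold,
    )


def _drug_side_score(P: TransitionMatrix, x_disease: ScoreVector,
                     target_nodes: Sequence[str], config: RWRConfig) -> float:
    x0 = InitialVector.from_dict(
        {g: DRUG_TARGET_WEIGHT for g in target_nodes}, P.nodes
    )
    return effect_score(x_disease, rwr(P, x0, config))


def assess_drug_disease(
    network: WeightedNetwork,
    disease_genes: GeneList,
    drug_targets: GeneList,
    config: RWRConfig = RWRConfig(),
    n_perm: int = 1000,
    rng_seed: int = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> PermutationResult:
    """Full assessment: disease RWR, drug RWR, permutation null, Z-score.

    Each of the ``n_perm`` counterpart sets has the same size as the mapped
    drug-target set and is seeded with the same 0.01 per node, so observed and
    null scores share a scale and Z is invariant to that scale.
    """
    P = column_normalize(network)
    x_disease = rwr(P, disease_seed_vector(disease_genes, network), config)
    x_drug = rwr(P, drug_seed_vector(drug_targets, network), config)
    observed = effect_score(x_disease, x_drug)

    mapped = split_mapped(drug_targets, network, "drug_fixed").mapped
    counterparts = sample_random_seed_sets(network, len(mapped), n_perm, rng_seed)
    nulls = [
        _drug_side_score(P, x_disease, counterpart.genes, config)
        for counterpart in counterparts
    ]
    return permutation_z(observed, nulls, rng_seed=rng_seed, z_threshold=z_threshold)
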