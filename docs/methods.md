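# Methods

## Model

`netpharm` treats a disease and a drug as two perturbation sources on a
weighted protein–protein interaction (PPI) network and asks how strongly the
sub-networks they influence overlap.

**Propagation.** Influence is spread by random walk with restart (RWR).  With
`P` the column-normalized weighted adjacency matrix (`p_ij = w_ij / Σ_k w_kj`)
and `x⁰` a nonnegative seed preference vector, the walk iterates

    x^{t+1} = (1 − r) P x^t + r x⁰

to its fixed point `x = r (I − (1−r)P)⁻¹ x⁰`.  Because `P` is
column-stochastic and `r > 0`, the system matrix is strictly diagonally
dominant in the 1-norm, so the fixed point exists, is unique, and the
iteration converges geometrically at rate `(1 − r)`.  The converged `x`
scores every node's proximity to the seed set; on a connected graph every
score is strictly positive.

**Seeding conventions.** Three seed vectors are supported:

- *disease*: `x⁰(i) = 1/m` for each of the `m` network-mapped disease genes
  (a probability distribution; propagation conserves its unit mass);
- *drug*: `x⁰(i) = 0.01` for each mapped target.  The constant reflects the
  weaker per-target effect assumed for multi-compound natural-product
  formulas; the vector deliberately sums to `0.01·k`, not 1, and is never
  renormalized.  Because RWR is linear in `x⁰`, the scale cancels out of the
  Z-score (verified by a scale-equivariance test);
- *expression-weighted*: each differentially expressed gene is weighted by
  `|log₂(fold ratio)|`, normalized to sum 1, so k-fold induction and k-fold
  repression carry equal weight.  A raw-ratio normalization is available via
  `mode="raw_ratio"` for sensitivity analysis (it up-weights induction).

**Effect score and significance.** The drug–disease effect score is the inner
product `S = ⟨x_disease, x_drug⟩`.  Its null distribution is built by
rerunning the drug-side RWR on `n_perm` node sets sampled uniformly without
replacement from the network, each the size of the mapped target set and
seeded with the same 0.01 per node, and the result is reported as
`Z = (S − mean_null) / sd_null` with the sample (n−1) standard deviation
(immaterial at n = 1000 but stated for reproducibility).  `Z > 3` is flagged
"significant" by convention; the threshold is a parameter, not hard-coded.
Uniform (rather than degree-matched) counterparts are the primary null; a
degree-matched sampler is provided for sensitivity analysis.

**Pathway projection.** Node scores are mapped onto a GMT gene-set
collection; a pathway gene absent from the network contributes zero, and the
pathway score is the mean over **all** of its genes (full pathway size in the
denominator, so poorly covered pathways are diluted; a mapped-only
denominator is available behind a flag).  The top `floor(0.05 · n)` pathways
by score are called significantly regulated — floor, because a 4722-set
collection yields exactly 236 selections.  Ties at the cutoff are broken by
lexicographic pathway name so selections are deterministic across platforms.
Agreement between selections is summarized by Venn-region counts (2–4 sets,
labelled A/B/C/AB/… in input order) and by percentages rounded half-up at the
reported precision.

## Background-network construction

The network is built from a STRING-dialect edge table (`protein1 protein2
combined_score`, raw scores rescaled by 1000 and clamped to [0, 1]).  Edges
at or above the confidence threshold (default 0.9) are kept.  Self-edges are
dropped (they would distort column normalization) and duplicate pairs keep
the maximum weight.  A seed gene excluded by the cutoff is re-admitted by
per-gene threshold lowering: its raw edges are added in descending weight
order (ties by neighbour id) until one lands on a node already in the
filtered network.  This particular rule — attach with the fewest,
most-confident edges — is one defensible reading of "lowering the threshold
for these genes"; the exact full-scale procedure is underdetermined, so node
and edge counts of a full-scale rebuild may differ slightly from published
ones.  Seed genes with no raw edges at all are reported as unmappable, never
invented.  Identifier matching is exact string equality after whitespace
trimming; alias resolution is out of scope.

## Numerical choices

- Convergence: L1 change < 1e−10, cap 1000 iterations (typical runs converge
  in 30–70).  The converged fixed-point residual is below 10× the tolerance.
- Matrix work is sparse (CSC) end to end; the dense closed-form solver is a
  verification oracle only and is guarded to ≤ 2000 nodes.
- Node order for all vectors/matrices is the sorted node id list, making
  outputs independent of edge-file ordering.
- Floats are serialized with `repr` (TSV) / standard JSON, so identical
  inputs and seeds give byte-identical outputs.
- All sampling uses `numpy.random.default_rng` with caller-supplied seeds;
  the CLI makes the seed mandatory for `assess`.

## Synthetic study fixtures

Real inputs (a STRING release, curated disease genes, compound-target lists,
MSigDB C2:CP) require downloads, so the test bench generates stand-ins with
the statistical structure the method assumes:

- **Network**: preferential-attachment growth (500 nodes, 3 edges per new
  node by default) gives a connected, heavy-tailed graph like a PPI network;
  edge weights are uniform on [0.4, 1], mimicking a confidence-filtered
  table.
- **Disease module**: 30 nodes densified to within-module edge probability
  0.35 — strong enough that propagation from the module is clearly localized,
  far from a clique.
- **Pathways**: 200 sets of 10–40 genes; 20% ("enriched", `PW_ENR_*`) draw
  ~60% of their genes from the module, the rest sample uniformly.  Names
  carry ground truth for recovery tests.
- **Expression**: 60 genes with fold ratios drawn outside (0.25, 4) — half up
  (folds 4.5–12), half down (reciprocals) — and the rest near 1, so the
  fold-change filter recovers exactly the planted set.

These fixtures do **not** reproduce STRING's evidence-channel structure,
real pathway topology, overlapping module architecture, or microarray noise.
Passing the calibration and recovery tests shows the statistic is correctly
standardized and has power against localized target sets on PPI-like graphs;
it does not certify performance on any particular real disease or compound
set.

What the benchmark shows at these defaults: random "drug" sets score
Z ≈ N(0, 1) against the permutation null (mean within ±0.15, SD within
[0.8, 1.2] over 200 repetitions); target sets drawn inside the planted module
are flagged (Z > 3) in ≥ 90% of 50 replicates while uniformly random sets are
flagged in ≤ 10%; and module-enriched pathways dominate the top-5% selection.
Problem sizes (500 nodes, 100 permutations for calibration/recovery, 1000
permutations for the single demo assessment) were chosen so the whole
benchmark completes in well under a minute on one CPU while leaving the
statistical checks comfortably powered.

## Full-scale reproduction recipe (not run here)

The published full-scale figures (effect scores 0.4452 / 0.1138, Z-scores
12.1930 / 7.7493, a 9289-node / 57 179-edge background network, 236-pathway
selections with 113 / 97 / 81 overlaps) require STRING v9.05, the curated
disease-gene and target lists, and MSigDB C2:CP (4722 gene sets).  Given
those files, the pipeline is: `build-network` at threshold 0.9 with all seed
lists required; `assess` with r = 0.3 and 1000 permutations per drug; `rwr`
plus `pathways` at top fraction 0.05 per entity; `overlap` on the selections.
The printed-count arithmetic of that analysis (the 236 = floor(0.05·4722)
selection size and all sharing percentages) is recomputed exactly by
`scripts/acceptance.py`.

## Known limitations

- The adaptive threshold-lowering rule is one reading of an underdetermined
  procedure (see above).
- The permutation null is uniform over nodes; hub-heavy target sets score
  high partly through degree.  Use the degree-matched sampler to probe this.
- Scores are proximity measures, not causal estimates; no direction of
  regulation (activation vs inhibition) is modelled.
- One identifier namespace; no ortholog or alias mapping.
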