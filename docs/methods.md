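# Methods

## Problem and pipeline

Single-cell Hi-C (scHi-C) measures pairwise chromatin contacts in individual
cells, but a single cell yields only thousands of read pairs, so per-cell
contact matrices are extremely sparse. `schictype` classifies cells into cell
types from these maps through five deterministic stages:

1. **Binning.** Intra-chromosomal read pairs are accumulated into a symmetric
   n×n count matrix per chromosome per cell at a fixed resolution R (default
   1 Mbp). For a chromosome of length L the bin count is n = ⌈L/R⌉; the
   ceiling keeps the chromosome tail, so every valid 1-based position maps to
   the 0-based bin ⌊(pos−1)/R⌋. Inter-chromosomal pairs are discarded.
2. **Quality control.** A cell is removed if its total unique contact mass
   (upper triangle plus diagonal, summed over chromosomes) is below
   `min_contacts` (default 5,000), or if any chromosome carries no read pair
   at all. Contacts are counted after binning; a read pair counts once.
3. **Imputation.** Per chromosome: a (2·pad+1)² mean-filter convolution with
   zero padding and a constant divisor (default pad = 1, i.e. 3×3), then a
   random walk with restart (RWR) on the row-normalized contact graph,

       Q_{t+1} = p·Q_t·P + (1−p)·I,   Q_0 = I,

   with continuation weight p (default 0.5), iterated until the maximum
   row-wise L1 change falls below `tol` (default 1e-6) or `max_iter`
   (default 30) is reached. All-zero rows of the transition matrix P are
   replaced by identity rows (self-loops) so P stays stochastic; every
   iterate Q_t is then exactly row-stochastic. Because the update need not
   produce a symmetric Q, the result is symmetrized as (Q + Qᵀ)/2.
   Optionally (default on) the top 20 % of entries are kept as a 0/1
   matrix, ties at the cutoff broken by (row, col) order.
4. **Embedding.** Each chromosome's imputed matrices are vectorized (upper
   triangle including the diagonal, n(n+1)/2 features) across cells and
   reduced by PCA to `k_chrom` components (default 10); the per-chromosome
   blocks are concatenated in genome order and a second PCA yields the final
   `k_cell`-dimensional cell embedding (default 20). PCA signs are pinned by
   forcing the largest-magnitude loading of each component positive, making
   the pipeline bit-reproducible. Component counts are capped at
   min(cells, features) when the data are smaller than the defaults.
5. **Classification.** A feed-forward network with two hidden ReLU layers
   (default widths 256 and 64) maps the embedding to one sigmoid score per
   cell type. Training minimizes the mean elementwise binary cross-entropy
   against one-hot targets (a one-vs-rest reading of the multiclass problem
   that matches the sigmoid output; a softmax/categorical-cross-entropy
   switch exists) by mini-batch gradient descent with momentum 0.9, learning
   rate 1e-3, batch size 32, up to 100 epochs. Inverted dropout (default
   rate 0.5) is applied to the hidden activations at train time only. A 10 %
   validation split drives early stopping (patience 10 epochs) and the best
   validation-loss weights are restored. Prediction is the argmax over the
   per-class scores, ties resolved by class order. Weight initialization,
   batch shuffling, dropout masks and the validation split all derive from
   one seed.

## Evaluation stack

All agreement metrics are computed from a single contingency table of joint
label counts. Mutual information uses natural logarithms with the 0·log 0 := 0
convention; NMI = 2·MI/(H(A)+H(B)), defined as 1.0 when both partitions are
trivial (both entropies zero, in which case the groupings coincide). ARI is
the Hubert–Arabie permutation-adjusted Rand index over pair counts, 1.0 when
the adjustment denominator degenerates. Confusion counts are one-vs-rest per
class; TPR = TP/(TP+FN) and FPR = FP/(TN+FP), with empty denominators
reported as 0.0 with a warning. ROC curves enumerate all distinct score
thresholds descending with ties collapsed; AUC is the trapezoid area, which
equals the tie-corrected Mann–Whitney statistic. Multiclass AUC is the
macro-averaged one-vs-rest AUC. K-fold cross-validation (default K = 10)
partitions indices by a seeded permutation into folds whose sizes differ by
at most one; a stratified mode assigns each class round-robin.

## Synthetic data generator

The generator produces labelled datasets with exactly the structure the
pipeline assumes, so every stage can be tested without downloads:

* **Distance decay** — base contact probability B_ij ∝ (1+|i−j|)^(−α),
  α = 1 by default, the canonical coarse-resolution falloff.
* **Type signal** — each of T types multiplies a few (default 3) seeded
  random contiguous diagonal blocks of the map by `block_strength`,
  emulating compartment-scale differences between cell types at Mb
  resolution; `block_strength=1` produces identical maps (a null dataset).
* **Sparsity** — per-cell depths are negative-binomial with mean 10,000 and
  dispersion 0.3 (var = μ + 0.3 μ²), deliberately straddling the 5,000
  QC threshold so the filter has nontrivial behaviour; each cell's contacts
  are one multinomial draw from its type's map over all intra-chromosomal
  bin pairs (chromosomes weighted by their upper-triangle element counts),
  so the generated depth is conserved exactly.
* **Imbalance** — `cells_per_type` accepts skewed counts.

The default genome is two toy chromosomes of 50 bins at 1 Mbp and the default
population is 4 types × 50 cells, sized so that the full pipeline (including
10-fold CV) runs in seconds on one CPU. Serialized output (pairs TSV with
uniformly placed within-bin positions, chrom.sizes, labels TSV) round-trips
losslessly through the binning stage and is byte-identical for a fixed seed.

What the generator does **not** model: TADs and loops, cell-cycle structure,
inter-chromosomal contacts, genomic coverage biases, or barcode collisions.
Passing tests on this data therefore demonstrate that the pipeline recovers
planted compartment-scale type differences under realistic sparsity and
class imbalance — not that it attains any particular accuracy on real
libraries.

## Design choices where the design was open

* **Imputation parameters** (pad 1, continuation 0.5, tol 1e-6, max 30
  iterations, top-20 % binarization) follow the convention established for
  RWR-based scHi-C smoothing; all are exposed in `ImputationParams`,
  including the `binarize` flag, since embedding raw diffusion magnitudes is
  equally defensible.
* **Inductive vs transductive embedding.** By default the PCA stages are
  fitted on training cells only and held-out cells are projected through the
  stored transforms, avoiding information leakage into the evaluation. A
  `transductive` flag embeds all cells jointly before the split; K-fold CV
  uses the joint embedding.
* **Loss.** Per-class sigmoid + binary cross-entropy honours the sigmoid
  output layer; for both this and the softmax alternative the output-layer
  gradient is (scores − targets)/constant, verified against central finite
  differences to < 1e-4 relative error.
* **Degenerate inputs.** Zero-variance features give zero PCA scores;
  all-zero RWR rows become self-loops; single-class training data and
  non-finite losses abort with diagnostics rather than returning silently.

## Problem sizes

Tests and the acceptance script use the default synthetic population
(200 cells, two 50-bin chromosomes, ~10k contacts per cell), 4×4 and
O(10²) matrices for numerical oracles, 500 random partition pairs (n = 100)
for metric cross-checks, and 200 random score sets for the AUC/Mann–Whitney
identity. These sizes give sub-minute runs while leaving every check
statistically meaningful.

## Known limitations

* Real scHi-C atlases are orders of magnitude larger (thousands of cells,
  23+ chromosomes, 1–3k bins each); the per-chromosome RWR is O(n³) per cell
  and would dominate at high resolution.
* The classifier is a plain MLP trained with fixed hyperparameters; no
  search or adaptive optimizers are included.
* No balancing/ICE normalization and no inter-chromosomal features.
* The QC contact count is computed on binned intra-chromosomal mass;
  pipelines counting raw pairs before binning may keep or drop borderline
  cells differently.
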