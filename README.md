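# schictype

Cell-type classification from single-cell Hi-C (scHi-C) contact maps.

A single cell's Hi-C experiment yields only thousands of read pairs, so its
per-chromosome contact matrices are far too sparse to compare directly.
`schictype` implements a complete pipeline that turns per-cell read-pair
tables into cell-type predictions:

1. **bin** — intra-chromosomal read pairs → symmetric n×n count matrices at a
   fixed resolution R (default 1 Mbp), n = ⌈L/R⌉ bins per chromosome;
2. **qc** — drop cells with < 5,000 total contacts or any chromosome without
   a single read pair;
3. **impute** — 3×3 mean-filter convolution, then a random walk with restart
   Q ← p·Q·P + (1−p)·I on the row-normalized contact graph, optionally
   keeping the top 20 % of entries as a binary matrix;
4. **embed** — per-chromosome PCA of the vectorized upper triangles,
   concatenation, then a second PCA giving one low-dimensional vector per
   cell;
5. **classify** — a feed-forward network (two hidden ReLU layers, per-class
   sigmoid output, inverted dropout, early stopping) trained by
   backpropagation.

The evaluation stack computes ACC, the adjusted Rand index
ARI = (Index − E[Index])/(Max − E[Index]), normalized mutual information
NMI = 2·MI(A,B)/(H(A)+H(B)), one-vs-rest TPR/FPR and macro-averaged ROC/AUC,
and K-fold cross-validation (K = 10). A synthetic generator produces
labelled scHi-C datasets (distance decay, type-specific contact blocks,
negative-binomial depths, class imbalance) so everything runs without
downloads. See `docs/methods.md` for the model details.

## Worked example

```python
from schictype import PipelineConfig, SimParams, generate_dataset, run_pipeline

paths = generate_dataset(SimParams(block_strength=3.0, seed=0), "example")
result = run_pipeline(paths["pairs"], paths["chrom_sizes"], paths["labels"],
                      PipelineConfig(seed=0), with_cv=True)
r = result.report
print(f"cells in: {r['n_input_cells']}, removed by QC: {r['n_qc_removed']}")
print(f"held-out ACC={r['acc']:.3f} ARI={r['ari']:.3f} "
      f"NMI={r['nmi']:.3f} AUC={r['macro_auc']:.3f}")
print(f"10-fold CV mean accuracy: {r['cv_mean_accuracy']:.3f}")
```

prints

```
cells in: 200, removed by QC: 33
held-out ACC=1.000 ARI=1.000 NMI=1.000 AUC=1.000
10-fold CV mean accuracy: 1.000
```

The generator drew 200 cells (4 types × 50) with ~10k contacts each; 33 fell
below the 5,000-contact QC threshold or lost a chromosome. With strong
planted type structure (`block_strength=3`) the pipeline separates the four
types perfectly on the 30 % held-out split; with `block_strength=1` (no type
signal) held-out accuracy drops to chance level.

The same pipeline is available stage by stage from the shell:

```bash
schictype simulate --out-dir sim --seed 0
schictype bin --pairs sim/pairs.tsv --chrom-sizes sim/chrom.sizes --out run.h5
schictype qc --container run.h5
schictype impute --container run.h5
schictype embed --container run.h5 --out embedding.tsv
schictype train --embedding embedding.tsv --labels sim/labels.tsv --model-out model.npz
schictype predict --embedding embedding.tsv --model model.npz --out pred.tsv
schictype evaluate --predictions pred.tsv --labels sim/labels.tsv
```

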