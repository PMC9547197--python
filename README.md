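# glycopred

Predict a binarized cell-surface glycan phenotype from single-cell
transcriptomes, and explain the prediction gene by gene.

Single-cell assays such as SUGAR-seq measure a transcriptome together with
a per-cell lectin binding signal — for example PHA-L, which binds
β1,6-branched N-glycans. `glycopred` implements the downstream analysis
for such paired data: it binarizes the lectin signal into high/low
quartile classes, trains a feed-forward classifier to predict the class
from expression, and interprets the model with Shapley-value attribution,
permutation feature importance, and Wilcoxon differential expression. It
is aimed at computational glycobiologists and single-cell analysts who
want to rank genes by their association with a glycan phenotype — and at
method developers, since a built-in synthetic-data generator plants known
driver genes so every step can be validated against ground truth.

## The model

Cells are labeled from the centered log-ratio of lectin counts,
clr(x_c) = ln(x_c + 1) − mean ln(x + 1): top quartile → class 1
(lectin-high), bottom quartile → class 0, middle half discarded. Labeled
cells are split 72/18/10 into train/validation/test.

The classifier is a multilayer perceptron with hidden layers of 128, 64,
16 and 8 units — leaky ReLU (slope 0.01), dropout (0.4, 0.4, 0.2) and
batch normalization after the first three — ending in a sigmoid output
P(lectin-high). It is trained with binary cross-entropy, Adam, batch size
128 and a cosine-annealed learning rate from 1e-4, keeping the best
validation-loss checkpoint. Random-forest (500 trees, depth 2) and
AdaBoost (300 rounds, lr 0.1) baselines train on the same split.

For interpretation, per-cell per-gene attributions φ are computed by
multiple-reference DeepLIFT-style backpropagation on the inference-mode
network (linear rule through affine layers, rescale rule through
nonlinearities), averaged over three replicate models trained with
different split seeds. For every cell, Σ_g φ_g = f(x) − base value (local
accuracy). Genes are ranked by median |φ|; the top 10% are the
high-importance gene set, a per-subtype variant flags genes specific to
one cell subtype (top 2% there and ≥ 1.25 sd above its mean percentile
elsewhere), and the ranking is cross-checked against permutation feature
importance (mean BCE increase over 25 column shuffles) and Wilcoxon
rank-sum differential expression with a 0.25 |log2FC| pre-filter and
Benjamini–Hochberg control at 0.05.

## Worked example

```python
import numpy as np
from glycopred.pipeline import PipelineConfig, run_pipeline

# default synthetic study conditions: 3000 cells, 2000 genes, 9 subtypes,
# 40 positive + 10 negative planted driver genes
run = run_pipeline(PipelineConfig(seed=1))

test = [r["metrics"]["test"] for r in run.report["replicates"]]
print("mean test F1 :", round(np.mean([m["f1_positive"] for m in test]), 4))
print("mean test AUC:", round(np.mean([m["roc_auc"] for m in test]), 4))
print("top genes    :", run.shap_genes[:5])
print("strong-driver recall:",
      run.recovery["strong_driver_recall_top_fraction"])
print("DEA significant genes:", run.report["dea_summary"]["n_significant"])
```

On the default conditions this prints (seed 1; a ~4-minute run on one CPU):

```
mean test F1 : 0.8508
mean test AUC: 0.9263
top genes    : ['gene0983', 'gene1194', 'gene0421', 'gene0960', 'gene1112']
strong-driver recall: 1.0
DEA significant genes: 202
```

The three replicate classifiers reach a mean test AUC of 0.926; every
planted strong driver is recovered in the top-10% attribution set, and all
positive-coefficient drivers show positive expression–φ correlation. Each
run writes gene rankings (TSV), per-subtype rankings, the differential
expression table, permutation importances, overlap reports and a
deterministic JSON report when `output_dir` is set.

The same analysis is available from the shell:

```bash
glycopred simulate --seed 1 --out data/      # write MTX triplet + lectin CSV
glycopred run --seed 1 --out results/run1    # full pipeline, report.json
```

Real data enter through the same path: a Matrix Market triplet
(matrix.mtx, features.tsv, barcodes.tsv), a lectin CSV (cell_id,
raw_count) and an optional subtype TSV, configured via `--config`.

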