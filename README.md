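# scimpute

Dropout imputation for single-cell RNA-seq count matrices.

Single-cell RNA-seq suffers from *dropouts*: genes that are expressed in
a cell but read out as zero because too little mRNA was captured. This
package implements scImpute-style imputation: it decides, per gene and
per cell, whether a value is likely a dropout, and rewrites **only**
those entries — every value the model trusts is passed through
bit-identical, and outlier cells are neither imputed nor used to impute
others. It is aimed at anyone running clustering, differential
expression or trajectory analyses downstream of a raw count matrix.

## Method in brief

Counts are CPM-normalized and transformed as `X = log10(CPM + 1.01)`.
Cells are grouped into K candidate subpopulations (PCA retaining ≥ 40%
variance → nearest-neighbor-distance outlier rule → spectral
clustering). Within each subpopulation, every gene's expression is
modeled as a two-component mixture

```
f(x) = λ · Gamma(x; α, β) + (1 − λ) · Normal(x; μ, σ),
```

fitted by EM: the Gamma component captures dropout mass near zero, the
Normal the actual expression level. The posterior probability that entry
X_ij came from the Gamma component is its dropout probability d_ij.
Entries with `d_ij ≥ t` (default t = 0.5) form the imputable set A_j;
the trusted rest, B_j, anchor a non-negative least-squares regression

```
β̂(j) = argmin_{β ≥ 0} ‖X[B_j, j] − X[B_j, N_j] β‖²
```

that selects and weights similar cells among the cell's cluster
neighbors N_j, and the A_j entries are rewritten as `X[A_j, N_j] β̂(j)`.
The imputed matrix is returned on both the log and the count scale.

Also included: the three-cell-type simulation generator with known DE
genes and double-exponential dropout, and the evaluation measures
(adjusted Rand index, Jaccard, NMI, purity, within-cluster sum of
squares on the first two PCs, DE precision-recall curves) used to
benchmark the method. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import numpy as np
from scimpute import (
    simulate_complete, apply_dropout, impute_log_matrix, log_zero_fraction,
    first_two_pcs, within_cluster_ss, de_ranking_scores, de_pr_curve,
)

# the reference simulation: 20,000 genes, 3 x 50 cells, 810 DE genes
truth = apply_dropout(simulate_complete(seed=1), seed=1)
print("zero fraction of raw data:", round(log_zero_fraction(truth.raw_log), 3))

result = impute_log_matrix(truth.raw_log, n_clusters=3, random_state=1)
print("entries imputed:", result.imputed_mask.sum())
print("outlier cells:", len(result.assignment.outliers))

for name, mat in [("complete", truth.complete_log),
                  ("raw", truth.raw_log),
                  ("imputed", result.imputed_log.values)]:
    wcss = within_cluster_ss(first_two_pcs(mat), truth.type_of)
    print(f"wcss {name}: {wcss:.1f}")

scores = de_ranking_scores(result.imputed_log.values, truth.type_of)
print("AUPRC imputed:", round(de_pr_curve(scores, truth.de_mask).auc, 3))
```

prints

```
zero fraction of raw data: 0.72
entries imputed: 2147985
outlier cells: 0
wcss complete: 105.3
wcss raw: 10008.3
wcss imputed: 1265.7
AUPRC imputed: 0.932
```

Reading: dropout corrupted 72% of entries and inflated the
within-cluster sum of squares on the first two PCs by two orders of
magnitude (105 → 10008); imputation recovers most of the lost structure
(→ 1266, the three cell types are tightly separated again), and ranking
genes by one-vs-rest mean log-expression difference on the imputed
matrix retrieves the 810 true DE genes with 0.93 area under the
precision-recall curve.

For real data the same thing is available as a scikit-learn transformer
(`ScImpute(n_clusters=..., dropout_threshold=0.5).fit_transform(X)` on a
cells × genes count matrix) or from the shell:

```
scimpute run --input counts.csv --K 3 --t 0.5 --seed 1 --out imputed.csv
scimpute simulate --genes 20000 --cells-per-type 50 --de-per-type 270 \
    --seed 1 --out-prefix sim
scimpute evaluate clustering --truth labels.txt --pred clusters.txt
scimpute reproduce-sim --seed 1 --out report.txt
```

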