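# gliomanet

Two-stage analysis of transcriptomic heterogeneity across related disease
classes (e.g. glioma subtypes), combining **joint sparse Gaussian graphical
model estimation** with **robust sparse K-means clustering**.

The package is aimed at computational biologists who have expression
matrices (samples × genes, already library-size normalized, e.g. TPM) for
two or three related cohorts and want to (1) infer class-specific gene
networks that share structure where the biology is shared, (2) use the
genes participating in those networks as a data-driven feature selection,
and (3) ask whether those genes separate patients into meaningful groups.

## The model

**Stage 1 — fused graphical lasso (FGL).** For classes d = 1..D with
empirical covariances S⁽ᵈ⁾ and sample sizes n_d, FGL estimates sparse
precision matrices Θ⁽ᵈ⁾ by solving

```
min_{Θ⁽ᵈ⁾ ≻ 0}  Σ_d n_d ( tr(S⁽ᵈ⁾Θ⁽ᵈ⁾) − log det Θ⁽ᵈ⁾ )
              + λ₁ Σ_d Σ_{i≠j} |θ⁽ᵈ⁾ᵢⱼ|
              + λ₂ Σ_{d<d'} Σ_{i,j} |θ⁽ᵈ⁾ᵢⱼ − θ⁽ᵈ'⁾ᵢⱼ|
```

A zero off-diagonal entry of Θ⁽ᵈ⁾ means the two genes are conditionally
independent given all others — no edge in class d's network. λ₁ controls
sparsity, λ₂ pulls the class networks toward each other (entries fuse
exactly for large λ₂), so edges come out *shared* or *class-exclusive*.
The solver is ADMM with an exact elementwise fused proximal operator
(D ≤ 4). Because the Gaussian model is assumed, features are first filtered
by the Jarque–Bera normality test and passed through the nonparanormal
(rank-Gaussian) transformation.

**Stage 2 — robust sparse K-means (RSKC).** Samples are clustered on the
z-scored network-selected genes by trimmed K-means with non-negative
feature weights w maximizing the weighted between-cluster sum of squares
w′b subject to ‖w‖₂ ≤ 1 and the lasso bound ‖w‖₁ ≤ L1 (smaller L1 → fewer
active genes). A fraction α of samples is trimmed — in weighted and in
unweighted space — as outliers, but every sample receives a final
assignment. Clusterings are scored with the simplified silhouette, the
Calinski–Harabasz index, and the adjusted Rand index against diagnostic
labels, and compared against a null built from random feature subsets of
the same size.

## Worked example

Network stage on a synthetic two-class cohort with 4 shared and 2
per-class-exclusive planted edges (p = 30, n_d = 250):

```python
import pandas as pd
from gliomanet import *

spec = SynthGGMSpec(p=30, D=2, n_shared=4, n_exclusive=2, seed=5)
precisions, truth = make_joint_ggm(spec)
frames, labels = sample_ggm_classes(precisions, [250, 250], seed=5,
                                    class_names=["lgg", "gbm"])
ds = ClassDataset([npn_transform(f) for f in frames], ["lgg", "gbm"])
fits, summary = lambda_grid_fit(ds, [40.0, 60.0], [2.0])
print(summary)
net = extract_edges(fits[(60.0, 2.0)], tol=0.1)
print("edge categories:", classify_edges(net))
print("selected features:", selected_features(net))
```

```
 lambda1  lambda2  n_nodes_union  converged  edges_lgg  edges_gbm
    40.0      2.0             20       True          8         10
    60.0      2.0             13       True          7          7
edge categories: {(0, 1): 4, (1,): 2, (0,): 2}
selected features: ['g0000', 'g0002', 'g0003', 'g0006', 'g0007', 'g0009',
 'g0013', 'g0018', 'g0021', 'g0024', 'g0025', 'g0026', 'g0027']
```

At λ₁ = 60 the pattern counts recover the planted design exactly: 4 edges
present in both classes and 2 exclusive to each. The selected features are
the 13 genes incident to at least one edge — the input to the clustering
stage.

Clustering stage on planted 2-cluster data (6 informative of 40 genes, 10%
gross outliers):

```python
cspec = SynthClusterSpec(n_per_cluster=(60, 60), p=40, q=6, shift=5.0,
                         outlier_fraction=0.1, outlier_scale=6.0, seed=3)
X, ctruth = make_cluster_dataset(cspec)
res = rskc_fit(zscore(X), RSKCConfig(K=2, L1=2.0, alpha=0.1, seed=3))
```

```
silhouette: 0.356          CH: 13.6          ARI vs truth: 0.808
outliers flagged: 13  planted: 12  overlap: 12
weight on informative features: 1.0
```

All 12 planted outliers are trimmed, the entire weight budget lands on the
6 informative genes, and the assignment agrees with the planted labels at
ARI 0.81 (scores are computed over *all* samples, outliers included, which
is why the silhouette is moderate).

The same workflow is available from the shell:

```sh
gliomanet simulate --mode ggm --p 30 --seed 5 --out-dir sim/
gliomanet run-case --expression sim/expression.tsv --labels sim/labels.tsv \
    --lambda1 60 --lambda2 2 --k-grid 2,3 --l1-grid 2 --out-dir case/
```

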