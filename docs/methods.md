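# Methods

## Preprocessing

Three transformations connect raw (already library-size-normalized)
expression matrices to the two analysis stages.

**Jarque–Bera filter.** The Gaussian graphical model assumes approximately
normal marginals, so features are screened with the Jarque–Bera test,
JB = (n/6)(g₁² + (g₂ − 3)²/4), with g₁ and g₂ the moment
(population-denominator) skewness and kurtosis and the p-value from the
asymptotic χ²(2) law. The asymptotic approximation is adequate at the
sample sizes this package targets (hundreds); at n = 600 its measured
type-I error at α = 0.05 is ≈ 0.05. The significance level defaults to
0.05 and is configurable. The filter pools all samples rather than testing
per class: the selection must be a single shared feature list, and a
per-class variant would require a rule for reconciling disagreements.
Surviving nothing is an explicit error carrying the full report.

**Nonparanormal transformation.** Per feature, average ranks r are mapped
to r/(n+1), clamped to [δ, 1−δ] with δ = 1/(4·n^{1/4}·√(π·log n)) (the
truncation that controls tail variance), passed through the standard
normal quantile, and rescaled to unit sample SD. The transform depends on
the data only through within-column ranks, hence is idempotent and
invariant to any strictly increasing per-feature distortion. It is applied
**per class** before covariance estimation, because the Gaussian
assumption is asserted within class; applying it to the pooled matrix
would let class-specific location shifts leak into the copula estimate.
Ties take average ranks (deterministic).

**Z-scoring** (clustering stage): per-feature mean 0, sample SD 1 (n−1
denominator), computed on the pooled selected submatrix since all patients
are clustered jointly. Subsetting to the selected genes happens before
scaling.

## Fused graphical lasso

The joint estimator minimizes

n_d-weighted negative log-likelihood + λ₁·(off-diagonal L1) +
λ₂·(all-entries cross-class L1 differences),

the formulation in which λ₁ does not penalize the diagonal but λ₂ does
penalize diagonal differences. Solved by ADMM with consensus variable Z:

* **Θ-update** (per class): eigendecompose S⁽ᵈ⁾ − (ρ/n_d)(Z⁽ᵈ⁾ − U⁽ᵈ⁾) =
  VΛVᵀ and set the new eigenvalues to (n_d/2ρ)(−λⱼ + √(λⱼ² + 4ρ/n_d)),
  which is the exact minimizer and positive for every λⱼ, so every iterate
  is positive definite. The sign convention was verified against the
  numeric oracle below.
* **Z-update**: elementwise fused proximal operator. For sorted inputs the
  clique fusion penalty Σ_{d<d'}|z_d − z_{d'}| is linear with coefficients
  (2d − D + 1), so the prox reduces to an isotonic problem solved exactly
  by enumerating the 2^{D−1} ordered fusion patterns (contiguous blocks)
  and keeping the feasible candidate with the lowest objective; the prox
  is exchange-symmetric and order-preserving, which justifies sorting.
  The λ₁ part is applied by soft-thresholding the fused solution
  (off-diagonal entries only), the exact composition for this penalty
  pair. A chain fused-lasso solver would be *incorrect* here because the
  fusion penalty couples all class pairs, not consecutive ones. D ≤ 4 is
  enforced; the analyses this package targets use D ∈ {2, 3}.
* **Convergence**: relative entrywise-L1 change of every Θ⁽ᵈ⁾ below tol
  (default 1e−5, max 500 iterations; non-convergence returns a flagged
  result with a warning).

**Step parameter ρ.** The default scales ρ to the mean class sample size.
Because the likelihood term carries n_d, a fixed ρ = 1 produces extremely
slow consensus (thousands of iterations at n_d ≈ 300) while ρ ≈ n̄
converges in tens of iterations to the same optimum (checked against the
oracle). ρ remains configurable.

**Reported networks.** The off-diagonal support of Z (exact zeros from
soft-thresholding) defines the edges; Θ is the smooth PD iterate. An edge
(i, j) is present in class d iff |z⁽ᵈ⁾ᵢⱼ| > tol with tol = 0 by default.
A small reporting tolerance (e.g. 0.1 on the nonparanormal scale) is
useful to suppress the well-known lasso-bias residue that appears on
two-hop neighbour pairs near the selection boundary.

**Independent oracle.** Tests compare the solver against direct convex
minimization: every |·| smoothed as √(x² + ε), analytic-gradient L-BFGS
with continuation ε = 1e−4 → 1e−16 (restarts reset the quasi-Newton
memory near kinks). The smoothed objective value sandwiches the true
optimum within λ·ε·(number of penalized terms), and true-zero entries of
the minimizer land below √ε, so the oracle support is read off at 1e−6.
Agreement on random instances (p ≤ 4, D ≤ 3): objective gap < 1e−6,
support identical.

## Network artifacts

Edges live in canonical (i < j) order; per-edge presence patterns over the
D classes partition the edge union (shared / exclusive categories for
D = 2, the seven non-empty patterns for D = 3). Hubs are the top-k
(default 5) features per class by within-class degree; all features tied
with the k-th degree are included and flagged, with deterministic
secondary ordering by name — real degree distributions tie often. The
"selected variables" handed to clustering are the union-graph nodes
(features incident to ≥ 1 edge in ≥ 1 class), in input order. Connected
components use networkx on either the union or a per-class graph.

## Robust sparse K-means

Outer loop until weight convergence (relative L1 change < 1e−4, max 15
iterations):

1. trimmed K-means in the weighted metric d_w(x,c) = Σⱼ wⱼ(xⱼ−cⱼ)²:
   Lloyd iterations that assign all points, trim the ⌈αn⌉ farthest from
   their assigned centers, and recompute centers from untrimmed points
   (O_W); 10 random restarts on the first pass, warm-started afterwards;
   an emptied cluster is re-seeded at the farthest untrimmed point;
2. centers recomputed in unweighted space from non-O_W points; the ⌈αn⌉
   largest unweighted distances form O_E;
3. per-feature between-cluster SS b computed on points outside
   O = O_W ∪ O_E;
4. w ← argmax w′b s.t. ‖w‖₂ ≤ 1, ‖w‖₁ ≤ L1, w ≥ 0, via soft-thresholding
   with the threshold found by bisection (1e−8); if no feature has
   positive b the update falls back to feasible uniform weights with a
   warning.

The double trimming makes the weights robust to samples that are extreme
in dimensions the current weights ignore. ⌈·⌉ is used for the trim count
since αn is rarely integral, so |O| ≤ 2⌈αn⌉. Initial weights are uniform
1/√p. Finally **every** sample, outliers included, is assigned to its
nearest weighted center; validity scores are computed over all samples
(an exclude-outliers variant raises the silhouette, as expected, and is
available to the caller by subsetting). With α = 0 and L1 = √p both
constraints are vacuous and the procedure reproduces standard K-means
partitions on separated data. L1 is validated to [1, √p]; values outside
only make a constraint vacuous and draw a warning.

## Validity indices and the random baseline

* Simplified silhouette: centroid-based, s = (b−a)/max(a,b) with a the
  distance to the own-cluster centroid and b the nearest other centroid;
  s = 0 when a = b = 0. Centroids are recomputed from the final
  assignment, not the weighted RSKC centers, because the index is defined
  on the partition.
* Calinski–Harabasz: [B/(K−1)]/[W/(n−K)]; W = 0 returns an infinite-score
  sentinel with a warning.
* Adjusted Rand index: permutation-model (Hubert–Arabie) form computed by
  integer combinatorics from the contingency table, so printed tables can
  be scored exactly; a zero denominator (two trivial partitions) scores 1
  if they coincide up to relabelling, else 0, with a warning.
* Random baseline: each replicate draws an equal-size feature subset
  uniformly without replacement, z-scores it, runs RSKC (L1 capped at
  √subset_size), and scores the assignment; best/average/median are
  reported. Replicate seeds derive deterministically from (master seed,
  replicate index), so the summary is reproducible and independent of
  evaluation order.

## Synthetic data generator

The generator emulates the structure the two stages assume, with known
ground truth:

* **Joint GGM**: D precision matrices over p features with n_shared edges
  planted in all classes and n_exclusive per class; weights uniform on
  ±[0.2, 0.6] with random sign (detectable but not dominating partial
  correlations); positive definiteness by diagonal dominance (diagonal =
  absolute off-diagonal row sum + 0.1), which preserves the planted
  support exactly, at the cost of heterogeneous marginal variances
  (handled downstream by the nonparanormal rescaling). Samples are
  zero-mean Gaussians from each Θ⁽ᵈ⁾.
* **Clustered samples**: informative features get cluster means spaced by
  `shift` noise-SDs; ⌊outlier_fraction·n⌋ samples are replaced by draws
  with SD inflated by `outlier_scale` (default 6) — large distance to
  every center, which is the trimming model, rather than a mean-shifted
  third cluster.
* **Contamination**: a chosen fraction of columns replaced by
  exponential/lognormal/uniform draws, to exercise the normality filter.

GGM, cluster, and contamination draws use independent sub-streams derived
from the master seed by fixed offsets, so changing one spec field never
reshuffles the other component. All generators are pure functions of
(spec, seed).

What the generator does **not** emulate: RNA-seq count noise,
library-size or batch effects, gene–gene correlation among "noise"
features, heavy-tailed expression, or realistic effect sizes — no
effect-size information is available for the real cohorts, so defaults
are calibrated to make recovery measurable, not to mimic TCGA. Passing
recovery tests therefore demonstrates correctness of the algorithms under
their own assumptions, not expected performance on real tumors.

## Default problem sizes

Tests and the acceptance script run at desk scale: network recovery at
p = 40, D = 3, n_d = 300 over a λ₁ grid {55, 75, 100} (on the
n_d-weighted scale) with the grid point chosen by selection-size
proximity; clustering recovery at n = 100–200, p = 50–200; the random
baseline at 100 replicates. These sizes make every property measurable in
seconds while leaving the algorithms unchanged.

## Known limitations

* No block-diagonal screening rules: full eigendecompositions per
  iteration make p in the tens of thousands impractical; the package
  targets method development and moderate p.
* The fused prox enumeration is exact only for D ≤ 4 (clique fusion
  penalty); more classes would need a general graph-fused solver.
* λ and (K, L1) selection is by inspection of grid summaries, as in the
  intended workflow; no cross-validation or information criteria.
* The Jarque–Bera χ²(2) p-value is asymptotic; for n below ~100 a
  small-sample calibration would be preferable.
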