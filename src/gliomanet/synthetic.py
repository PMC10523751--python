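"""Synthetic multi-class Gaussian graphical model and clustered-sample generators.

Provides ground-truth-annotated stand-ins for multi-cohort expression data:
class-specific sparse precision matrices with planted shared and
class-exclusive edges, Gaussian samples drawn from them, clustered sample
matrices with mean-shifted informative features and gross outliers, and
non-Gaussian feature contamination for exercising normality filtering.

All generators are pure functions of (spec, seed): rerunning with the same
spec yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynthGGMSpec",
    "SynthClusterSpec",
    "GroundTruth",
    "make_joint_ggm",
    "sample_ggm_classes",
    "make_cluster_dataset",
    "contaminate_features",
]

# fixed offsets so GGM and cluster generation draw from independent streams
# even when built from the same master seed
_GGM_SEED_OFFSET = 101
_CLUSTER_SEED_OFFSET = 211
_CONTAMINATE_SEED_OFFSET = 307


@dataclass(frozen=True)
class SynthGGMSpec:
    """Parameters of a planted joint Gaussian graphical model.

    Edge weights (partial covariances) are drawn uniformly from
    ``±[weight_range]`` with random sign; positive definiteness is enforced
    by diagonal dominance, which preserves the planted support exactly.
    """

    p: int
    D: int = 2
    n_shared: int = 3
    n_exclusive: int = 2
    weight_range: tuple[float, float] = (0.2, 0.6)
    diag_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.D < 2:
            raise ValueError("D must be >= 2")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ValueError("weight_range must be a strictly positive interval")
        if self.diag_margin <= 0:
            raise ValueError("diag_margin must be positive")
        capacity = self.p * (self.p - 1) // 2
        if self.n_shared + self.D * self.n_exclusive > capacity:
            raise ValueError(
                f"edge budget {self.n_shared} + {self.D}*{self.n_exclusive} "
                f"exceeds capacity p(p-1)/2 = {capacity}"
            )


@dataclass(frozen=True)
class SynthClusterSpec:
    """Parameters of a clustered sample matrix with planted outliers.

    ``shift`` is the between-cluster mean separation in noise-SD units on the
    ``q`` informative features; outliers are generated by inflating the noise
    SD by ``outlier_scale`` (large distance to every center, matching the
    trimming model of robust clustering).
    """

    n_per_cluster: tuple[int, ...]
    p: int
    q: int
    shift: float = 6.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_cluster):
            raise ValueError("every cluster size must be positive")
        if not 0 < self.q <= self.p:
            raise ValueError("require 0 < q <= p")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside generated data."""

    precisions: list[np.ndarray] = field(default_factory=list)
    supports: list[set[tuple[int, int]]] = field(default_factory=list)
    shared_edges: set[tuple[int, int]] = field(default_factory=set)
    exclusive_edges: list[set[tuple[int, int]]] = field(default_factory=list)
    cluster_labels: np.ndarray | None = None
    outlier_indices: np.ndarray | None = None
    informative_features: np.ndarray | None = None


def _draw_edges(rng: np.random.Generator, p: int, k: int,
                taken: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Draw k distinct unordered pairs not in `taken`."""
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
             if (i, j) not in taken]
    idx = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[i] for i in sorted(idx)]


def make_joint_ggm(spec: SynthGGMSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Build D sparse precision matrices with planted shared/exclusive edges.

    Returns the precision matrices and a :class:`GroundTruth` with the exact
    per-class supports. Each matrix is symmetric positive definite: every
    diagonal entry is set to the absolute row sum of off-diagonal entries
    plus ``diag_margin`` (strict diagonal dominance, hence PD by Gershgorin).
    """
    rng = np.random.default_rng(spec.seed + _GGM_SEED_OFFSET)
    taken: set[tuple[int, int]] = set()
    shared = _draw_edges(rng, spec.p, spec.n_shared, taken)
    taken.update(shared)
    exclusive: list[list[tuple[int, int]]] = []
    for _ in range(spec.D):
        e = _draw_edges(rng, spec.p, spec.n_exclusive, taken)
        taken.update(e)
        exclusive.append(e)

    lo, hi = spec.weight_range

    def _weight() -> float:
        return rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])

    shared_w = {e: _weight() for e in shared}
    precisions: list[np.ndarray] = []
    supports: list[set[tuple[int, int]]] = []
    for d in range(spec.D):
        theta = np.zeros((spec.p, spec.p))
        for (i, j), w in shared_w.items():
            theta[i, j] = theta[j, i] = w
        for i, j in exclusive[d]:
            w = _weight()
            theta[i, j] = theta[j, i] = w
        np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + spec.diag_margin)
        precisions.append(theta)
        supports.append(set(shared) | set(exclusive[d]))

    truth = GroundTruth(
        precisions=[t.copy() for t in precisions],
        supports=supports,
        shared_edges=set(shared),
        exclusive_edges=[set(e) for e in exclusive],
    )
    return precisions, truth


def sample_ggm_classes(
    precisions: list[np.ndarray],
    n_per_class: list[int] | tuple[int, ...],
    seed: int = 0,
    feature_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> tuple[list[pd.DataFrame], pd.Series]:
    """Draw zero-mean Gaussian samples from each class's precision matrix.

    Returns one samples x features DataFrame per class (shared feature
    names) and a Series mapping sample id -> class name.
    """
    if len(n_per_class) != len(precisions):
        raise ValueError("need one sample size per class")
    if any(n < 2 for n in n_per_class):
        raise ValueError("each class needs n_d >= 2")
    p = precisions[0].shape[0]
    if feature_names is None:
        feature_names = [f"g{j:04d}" for j in range(p)]
    if class_names is None:
        class_names = [f"class{d + 1}" for d in range(len(precisions))]
    rng = np.random.default_rng(seed)
    frames = []
    labels: dict[str, str] = {}
    for d, (theta, n_d) in enumerate(zip(precisions, n_per_class)):
        w = np.linalg.eigvalsh(theta)
        if w.min() <= 0:
            raise np.linalg.LinAlgError(
                f"class {d}: precision matrix is not positive definite"
            )
        cov = np.linalg.inv(theta)
        cov = (cov + cov.T) / 2
        x = rng.multivariate_normal(np.zeros(p), cov, size=n_d,
                                    method="cholesky")
        ids = [f"{class_names[d]}_s{i:04d}" for i in range(n_d)]
        frames.append(pd.DataFrame(x, index=ids, columns=feature_names))
        labels.update({s: class_names[d] for s in ids})
    return frames, pd.Series(labels, name="class")


def make_cluster_dataset(spec: SynthClusterSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a clustered sample matrix with known labels and outliers.

    Informative features get cluster-specific means spaced ``shift`` noise-SD
    apart (clusters placed at 0, shift, 2*shift, ...); the rest are standard
    Gaussian noise. ``floor(outlier_fraction * n)`` samples are then replaced
    by zero-mean draws with SD multiplied by ``outlier_scale``.
    """
    rng = np.random.default_rng(spec.seed + _CLUSTER_SEED_OFFSET)
    n = int(sum(spec.n_per_cluster))
    K = len(spec.n_per_cluster)
    labels = np.repeat(np.arange(K), spec.n_per_cluster)
    informative = rng.choice(spec.p, size=spec.q, replace=False)
    informative.sort()
    x = rng.standard_normal((n, spec.p))
    for k in range(K):
        x[np.ix_(labels == k, informative)] += k * spec.shift
    n_out = int(np.floor(spec.outlier_fraction * n))
    out_idx = np.sort(rng.choice(n, size=n_out, replace=False))
    if n_out:
        x[out_idx] = spec.outlier_scale * rng.standard_normal((n_out, spec.p))
    ids = [f"s{i:04d}" for i in range(n)]
    cols = [f"g{j:04d}" for j in range(spec.p)]
    truth = GroundTruth(
        cluster_labels=labels,
        outlier_indices=out_idx,
        informative_features=informative,
    )
    return pd.DataFrame(x, index=ids, columns=cols), truth


_FAMILIES = {
    "exponential": lambda rng, n: rng.exponential(1.0, size=n),
    "lognormal": lambda rng, n: rng.lognormal(0.0, 1.0, size=n),
    "uniform": lambda rng, n: rng.uniform(0.0, 1.0, size=n),
}


def contaminate_features(
    matrix: pd.DataFrame, fraction: float, family: str = "exponential",
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replace a fraction of feature columns with i.i.d. non-Gaussian draws.

    Used to exercise the Jarque-Bera normality filter. Returns the modified
    copy and the (sorted) positional indices of contaminated columns.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; "
                         f"choose from {sorted(_FAMILIES)}")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed + _CONTAMINATE_SEED_OFFSET)
    n, p = matrix.shape
    k = int(round(fraction * p))
    idx = np.sort(rng.choice(p, size=k, replace=False))
    out = matrix.copy()
    for j in idx:
        out.iloc[:, j] = _FAMILIES[family](rng, n)
    return out, idx
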