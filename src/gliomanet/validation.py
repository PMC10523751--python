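"""Cluster-validity scoring and the random-feature-subset baseline.

Indices: simplified (centroid-based) silhouette, the Calinski-Harabasz
ratio, and the adjusted Rand index (permutation-model, Hubert-Arabie) for
agreement with reference labels. The random baseline repeats the clustering
on many uniformly drawn feature subsets of the same size as the candidate
selection, summarizing score distributions (best / average / median) to
show whether the selected features beat chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .preprocess import zscore
from .rskc import RSKCConfig, rskc_fit

__all__ = [
    "ValidationScores",
    "RandomBaselineSummary",
    "simplified_silhouette",
    "calinski_harabasz",
    "adjusted_rand_index",
    "ari_from_contingency",
    "cross_tabulate",
    "random_baseline",
]


@dataclass
class ValidationScores:
    silhouette: float
    calinski_harabasz: float
    ari: float | None
    K: int
    n_samples: int
    include_outliers: bool = True

    def to_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "ari": self.ari,
            "K": self.K,
            "n_samples": self.n_samples,
            "include_outliers": self.include_outliers,
        }


@dataclass
class RandomBaselineSummary:
    """Best/average/median of each score over random-subset replicates."""

    scores: pd.DataFrame            # one row per replicate
    n_replicates: int
    subset_size: int
    K: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in ("silhouette", "calinski_harabasz"):
            s = self.scores[col]
            rows.append({"score": col, "best": s.max(),
                         "average": s.mean(), "median": s.median()})
        return pd.DataFrame(rows)


def _centroids(X: np.ndarray, assignment: np.ndarray):
    clusters = np.unique(assignment)
    cents = np.vstack([X[assignment == k].mean(axis=0) for k in clusters])
    return clusters, cents


def simplified_silhouette(X, assignment) -> float:
    """Mean centroid-based silhouette over all samples.

    For sample i with own-centroid distance a_i and nearest-other-centroid
    distance b_i, s_i = (b_i - a_i) / max(a_i, b_i), with s_i = 0 when
    a_i = b_i = 0. Requires >= 2 distinct clusters.
    """
    X = np.asarray(X, dtype=float)
    assignment = np.asarray(assignment)
    clusters, cents = _centroids(X, assignment)
    if len(clusters) < 2:
        raise ValueError("need at least 2 distinct clusters")
    d = np.linalg.norm(X[:, None, :] - cents[None, :, :], axis=2)
    own_col = np.searchsorted(clusters, assignment)
    n = X.shape[0]
    a = d[np.arange(n), own_col]
    d_others = d.copy()
    d_others[np.arange(n), own_col] = np.inf
    b = d_others.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def calinski_harabasz(X, assignment) -> float:
    """Calinski-Harabasz index: [B/(K-1)] / [W/(n-K)].

    B is the between-cluster and W the within-cluster sum of squared
    Euclidean distances to centroids. W = 0 (each cluster a single point or
    coincident points) returns inf with a warning.
    """
    X = np.asarray(X, dtype=float)
    assignment = np.asarray(assignment)
    clusters, cents = _centroids(X, assignment)
    K = len(clusters)
    n = X.shape[0]
    if K < 2:
        raise ValueError("need at least 2 distinct clusters")
    if K >= n:
        raise ValueError("need K < n")
    gm = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for k, c in zip(clusters, cents):
        pts = X[assignment == k]
        B += len(pts) * float(((c - gm) ** 2).sum())
        W += float(((pts - c) ** 2).sum())
    if W == 0:
        warnings.warn("zero within-cluster dispersion; CH is infinite",
                      RuntimeWarning)
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


def ari_from_contingency(table) -> float:
    """Adjusted Rand index from a contingency table of two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (max_index - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(N,2) and
    max_index = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2. A zero denominator
    (both partitions trivial) yields 1 when the partitions coincide up to
    relabelling, else 0, with a warning.
    """
    ct = np.asarray(table, dtype=np.int64)
    N = ct.sum()
    if N < 2:
        raise ValueError("need at least 2 samples")
    sum_ij = comb(ct, 2).sum()
    a = comb(ct.sum(axis=1), 2).sum()
    b = comb(ct.sum(axis=0), 2).sum()
    expected = a * b / comb(N, 2)
    denom = 0.5 * (a + b) - expected
    if denom == 0:
        warnings.warn("degenerate partitions: ARI denominator is zero",
                      RuntimeWarning)
        identical = (np.count_nonzero(ct, axis=0) <= 1).all() and \
                    (np.count_nonzero(ct, axis=1) <= 1).all()
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / denom)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI of two labelings of the same samples (any hashable labels)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 samples")
    ct = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
    return ari_from_contingency(ct.to_numpy())


def cross_tabulate(assignment, labels, margins: bool = True) -> pd.DataFrame:
    """Contingency table of reference labels (rows) vs clusters (columns)."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if assignment.shape != labels.shape:
        raise ValueError("lengths differ")
    return pd.crosstab(pd.Series(labels, name="label"),
                       pd.Series(assignment, name="cluster"),
                       margins=margins)


def random_baseline(
    full_matrix: pd.DataFrame,
    subset_size: int,
    n_rep: int,
    K: int,
    cfg: RSKCConfig | None = None,
    seed: int = 0,
) -> RandomBaselineSummary:
    """Score RSKC clusterings of random feature subsets of the full pool.

    Each replicate draws ``subset_size`` features uniformly without
    replacement, z-scores the submatrix, runs RSKC, and records the
    simplified silhouette and Calinski-Harabasz of the resulting assignment
    (all samples included). Replicate seeds are derived deterministically
    from (seed, replicate index), so results do not depend on evaluation
    order.
    """
    p = full_matrix.shape[1]
    if subset_size > p:
        raise ValueError("subset_size exceeds the feature pool")
    if n_rep < 1:
        raise ValueError("need n_rep >= 1")
    if cfg is None:
        cfg = RSKCConfig(K=K, L1=2.0, alpha=0.1)
    rows = []
    for r in range(n_rep):
        rng = np.random.default_rng([seed, r])
        rep_seed = int(rng.integers(0, 2**31 - 1))
        idx = rng.choice(p, size=subset_size, replace=False)
        sub = zscore(full_matrix.iloc[:, np.sort(idx)])
        rep_cfg = RSKCConfig(K=K, L1=min(cfg.L1, np.sqrt(subset_size)),
                             alpha=cfg.alpha, n_init=cfg.n_init,
                             max_weight_iter=cfg.max_weight_iter,
                             tol=cfg.tol, seed=rep_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = rskc_fit(sub, rep_cfg)
        Xs = sub.to_numpy()
        rows.append({
            "replicate": r,
            "silhouette": simplified_silhouette(Xs, res.assignment),
            "calinski_harabasz": calinski_harabasz(Xs, res.assignment),
        })
    return RandomBaselineSummary(scores=pd.DataFrame(rows),
                                 n_replicates=n_rep,
                                 subset_size=subset_size, K=K, seed=seed)
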