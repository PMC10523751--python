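"""Robust sparse K-means (RSKC).

Trimmed K-means with lasso-bounded non-negative feature weights. The
algorithm alternates (i) trimmed Lloyd iterations in the feature-weighted
metric, flagging the alpha fraction of samples farthest from their centers
in weighted space (O_W) and, after recomputing centers, in unweighted space
(O_E); and (ii) a feature-weight update maximizing the weighted
between-cluster sum of squares w'b subject to ||w||_2 <= 1, ||w||_1 <= L1,
w >= 0 — the lasso bound L1 drives feature selection (smaller L1, fewer
features). Outliers O = O_W | O_E are excluded from the weight update but
every sample receives a final cluster assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RSKCConfig", "ClusterResult", "update_weights",
           "trimmed_kmeans", "rskc_fit"]


@dataclass(frozen=True)
class RSKCConfig:
    """Tuning parameters of robust sparse K-means.

    K: number of clusters; L1: lasso bound on the weight vector, valid in
    [1, sqrt(p)]; alpha: trimming proportion; n_init: random restarts of the
    first trimmed-K-means pass.
    """

    K: int
    L1: float
    alpha: float = 0.1
    n_init: int = 10
    max_weight_iter: int = 15
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.L1 < 1:
            raise ValueError("L1 must be >= 1")
        if not 0 <= self.alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class ClusterResult:
    """RSKC output: assignment (1..K, all samples), weights, outliers, centers."""

    assignment: np.ndarray
    weights: np.ndarray
    outliers: np.ndarray          # sorted union O_W | O_E
    outliers_weighted: np.ndarray
    outliers_unweighted: np.ndarray
    centers: np.ndarray
    objective_trace: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    sample_ids: list[str] | None = None


def update_weights(b: np.ndarray, L1: float) -> np.ndarray:
    """Maximize w'b subject to ||w||_2 <= 1, ||w||_1 <= L1, w >= 0.

    Solution: w = s(b+, delta) / ||s(b+, delta)||_2 with s soft-thresholding
    and delta = 0 when the L1 constraint is slack, otherwise chosen by
    bisection so that ||w||_1 = L1 (to 1e-8). If no b is positive there is
    no informative feature; returns feasible uniform weights with a warning.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("b must be finite")
    if L1 < 1:
        raise ValueError("L1 must be >= 1")
    bp = np.maximum(b, 0.0)
    if bp.max() == 0.0:
        warnings.warn("no feature has positive between-cluster SS; "
                      "falling back to uniform weights", RuntimeWarning)
        p = b.size
        return np.full(p, min(1.0 / np.sqrt(p), L1 / p))

    def w_of(delta: float) -> np.ndarray:
        s = np.maximum(bp - delta, 0.0)
        nrm = np.linalg.norm(s)
        return s / nrm if nrm > 0 else s

    w = w_of(0.0)
    if w.sum() <= L1 + 1e-12:
        return w
    lo, hi = 0.0, bp.max()
    for _ in range(200):
        mid = (lo + hi) / 2
        if w_of(mid).sum() > L1:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, bp.max()):
            break
    w = w_of((lo + hi) / 2)
    # final exactness check
    if abs(w.sum() - L1) > 1e-6:
        w = w_of(hi)
    return w


def _weighted_sq_dist(X: np.ndarray, centers: np.ndarray,
                      w: np.ndarray) -> np.ndarray:
    """d[i, k] = sum_j w_j (x_ij - c_kj)^2."""
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("ikj,j->ik", diff ** 2, w)


def _lloyd_trimmed(X: np.ndarray, K: int, alpha: float, w: np.ndarray,
                   centers: np.ndarray, max_iter: int = 100,
                   rng: np.random.Generator | None = None):
    """One trimmed Lloyd run from given centers; returns final state."""
    n = X.shape[0]
    m_trim = int(np.ceil(alpha * n))
    labels = np.full(n, -1)
    trimmed = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        d = _weighted_sq_dist(X, centers, w)
        new_labels = d.argmin(axis=1)
        own = d[np.arange(n), new_labels]
        new_trim = np.zeros(n, dtype=bool)
        if m_trim > 0:
            new_trim[np.argsort(own, kind="stable")[-m_trim:]] = True
        if np.array_equal(new_labels, labels) and np.array_equal(new_trim, trimmed):
            break
        labels, trimmed = new_labels, new_trim
        for k in range(K):
            mask = (labels == k) & ~trimmed
            if mask.any():
                centers[k] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the untrimmed point farthest
                # from its current center
                keep = ~trimmed
                far = np.argmax(own * keep)
                centers[k] = X[far]
    d = _weighted_sq_dist(X, centers, w)
    labels = d.argmin(axis=1)
    own = d[np.arange(n), labels]
    trimmed = np.zeros(n, dtype=bool)
    if m_trim > 0:
        trimmed[np.argsort(own, kind="stable")[-m_trim:]] = True
    obj = own[~trimmed].sum()
    return labels, centers, trimmed, obj


def trimmed_kmeans(X, K: int, alpha: float = 0.0,
                   weights: np.ndarray | None = None, n_init: int = 10,
                   seed: int = 0, max_iter: int = 100,
                   init_centers: np.ndarray | None = None):
    """Trimmed K-means in a feature-weighted metric.

    Assigns every point to its nearest center under
    d_w(x, c) = sum_j w_j (x_j - c_j)^2, trims the ceil(alpha n) points with
    the largest distance to their assigned center, and recomputes centers
    from untrimmed points, iterating to convergence. Returns
    (labels, centers, trimmed_mask) of the best of ``n_init`` seeded
    restarts by untrimmed within-cluster weighted SS (or of the single run
    from ``init_centers`` when given).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if K > n:
        raise ValueError("K cannot exceed the number of samples")
    if n <= K + int(np.ceil(alpha * n)):
        raise ValueError("too few samples for this K and alpha")
    w = np.full(p, 1.0) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    best = None
    if init_centers is not None:
        starts = [np.array(init_centers, dtype=float, copy=True)]
    else:
        starts = []
        for _ in range(n_init):
            idx = rng.choice(n, size=K, replace=False)
            starts.append(X[idx].copy())
    for centers0 in starts:
        labels, centers, trimmed, obj = _lloyd_trimmed(
            X, K, alpha, w, centers0, max_iter=max_iter, rng=rng)
        if best is None or obj < best[3]:
            best = (labels, centers, trimmed, obj)
    labels, centers, trimmed, _ = best
    return labels, centers, trimmed


def rskc_fit(X, cfg: RSKCConfig) -> ClusterResult:
    """Run robust sparse K-means to weight convergence.

    ``X`` is expected z-scored (a warning is issued when columns look far
    from standardized). Outer loop: (a) trimmed K-means in the weighted
    metric giving partition and O_W; (b) centers recomputed in unweighted
    space from non-O_W points, trimming the ceil(alpha n) largest unweighted
    distances into O_E; (c) per-feature between-cluster SS b computed on
    points outside O = O_W | O_E; (d) weight update. Finally every sample
    (outliers included) is assigned to its nearest weighted center.
    """
    ids = None
    if isinstance(X, pd.DataFrame):
        ids = list(X.index)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    col_mean = np.abs(X.mean(axis=0)).max()
    col_sd = X.std(axis=0, ddof=1)
    if col_mean > 0.5 or col_sd.min() < 0.4 or col_sd.max() > 2.5:
        warnings.warn("input does not look z-scored; RSKC assumes "
                      "standardized features", RuntimeWarning)
    if not 1 <= cfg.L1 <= np.sqrt(p) + 1e-9:
        warnings.warn(f"L1={cfg.L1} outside [1, sqrt(p)={np.sqrt(p):.3f}]; "
                      "constraint may be vacuous", RuntimeWarning)
    m_trim = int(np.ceil(cfg.alpha * n))
    w = np.full(p, 1.0 / np.sqrt(p))
    centers = None
    trace: list[float] = []
    converged = False
    it = 0
    labels = np.zeros(n, dtype=int)
    o_w = np.zeros(n, dtype=bool)
    o_e = np.zeros(n, dtype=bool)
    for it in range(1, cfg.max_weight_iter + 1):
        if centers is None:
            labels, centers, o_w = trimmed_kmeans(
                X, cfg.K, cfg.alpha, weights=w, n_init=cfg.n_init,
                seed=cfg.seed)
        else:
            labels, centers, o_w = trimmed_kmeans(
                X, cfg.K, cfg.alpha, weights=w, seed=cfg.seed,
                init_centers=centers)
        # (b) unweighted re-trim: centers from non-O_W points, then flag the
        # largest unweighted distances
        centers_u = np.empty_like(centers)
        for k in range(cfg.K):
            mask = (labels == k) & ~o_w
            centers_u[k] = X[mask].mean(axis=0) if mask.any() else centers[k]
        du = ((X - centers_u[labels]) ** 2).sum(axis=1)
        o_e = np.zeros(n, dtype=bool)
        if m_trim > 0:
            o_e[np.argsort(du, kind="stable")[-m_trim:]] = True
        out = o_w | o_e
        # (d) between-cluster SS per feature on the untrimmed points
        keep = ~out
        Xk = X[keep]
        lk = labels[keep]
        gm = Xk.mean(axis=0)
        total = ((Xk - gm) ** 2).sum(axis=0)
        within = np.zeros(p)
        for k in range(cfg.K):
            pts = Xk[lk == k]
            if len(pts):
                within += ((pts - pts.mean(axis=0)) ** 2).sum(axis=0)
        b = total - within
        w_new = update_weights(b, cfg.L1)
        # (old, new) value of w'b on the same b: the weight update is a
        # constrained argmax, so new >= old whenever old w was feasible
        trace.append((float(w @ b), float(w_new @ b)))
        delta = np.abs(w_new - w).sum() / max(np.abs(w).sum(), 1e-12)
        w = w_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn("RSKC weight iteration did not converge", RuntimeWarning)
    # final assignment of every sample in the weighted metric
    d = _weighted_sq_dist(X, centers, w)
    assignment = d.argmin(axis=1) + 1
    outliers = np.flatnonzero(o_w | o_e)
    return ClusterResult(
        assignment=assignment,
        weights=w,
        outliers=outliers,
        outliers_weighted=np.flatnonzero(o_w),
        outliers_unweighted=np.flatnonzero(o_e),
        centers=centers,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
        sample_ids=ids,
    )
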