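"""Independent numeric oracles used by the tests.

The FGL oracle minimizes the penalized negative log-likelihood directly by
smoothing every absolute value as sqrt(x^2 + eps) and running analytic-
gradient L-BFGS with a continuation schedule eps -> 0. It shares no code
with the ADMM solver under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def fgl_numeric_oracle(S, n, lam1, lam2,
                       eps_schedule=(1e-4, 1e-6, 1e-8, 1e-10, 1e-12,
                                     1e-14, 1e-16)):
    """Direct convex minimization of the FGL objective; returns Theta list."""
    D = len(S)
    p = S[0].shape[0]
    off = ~np.eye(p, dtype=bool)

    def f_grad(v, eps):
        T = v.reshape(D, p, p)
        T = (T + np.transpose(T, (0, 2, 1))) / 2
        val = 0.0
        G = np.zeros_like(T)
        for d in range(D):
            sign, ld = np.linalg.slogdet(T[d])
            if sign <= 0:
                return np.inf, np.zeros_like(v)
            val += n[d] * (np.trace(S[d] @ T[d]) - ld)
            G[d] += n[d] * (S[d] - np.linalg.inv(T[d]))
        s = np.sqrt(T ** 2 + eps)
        val += lam1 * (s * off).sum()
        G += lam1 * (T / s) * off
        for d in range(D):
            for e in range(d + 1, D):
                diff = T[d] - T[e]
                sd = np.sqrt(diff ** 2 + eps)
                val += lam2 * sd.sum()
                G[d] += lam2 * diff / sd
                G[e] -= lam2 * diff / sd
        return val, G.ravel()

    x = np.stack([np.eye(p)] * D).ravel()
    for eps in eps_schedule:
        for _ in range(3):  # restarts reset L-BFGS memory near the kinks
            r = minimize(f_grad, x, args=(eps,), jac=True, method="L-BFGS-B",
                         options={"maxiter": 50000, "ftol": 1e-18,
                                  "gtol": 1e-14, "maxcor": 30})
            x = r.x
    T = x.reshape(D, p, p)
    T = (T + np.transpose(T, (0, 2, 1))) / 2
    return [T[d] for d in range(D)]


def fused_prox_brute(a, lam1, lam2, n_grid=41, n_refine=8):
    """Grid-refinement minimizer of the fused prox objective (D <= 3)."""
    a = np.asarray(a, dtype=float)
    D = a.size

    def f(Z):
        # Z: (m, D)
        pen = lam1 * np.abs(Z).sum(axis=1)
        for i in range(D):
            for j in range(i + 1, D):
                pen = pen + lam2 * np.abs(Z[:, i] - Z[:, j])
        return 0.5 * ((Z - a) ** 2).sum(axis=1) + pen

    center = a.copy()
    width = np.abs(a).max() + 1.0
    best = center
    for _ in range(n_refine):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        Z = np.stack([g.ravel() for g in grids], axis=1)
        vals = f(Z)
        best = Z[vals.argmin()]
        center = best
        width *= 4.0 / n_grid
    return best, float(f(best[None, :])[0])
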