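"""Batched non-negative least squares via QR reduction.

Solving ``min ||A x - b||, x >= 0`` for many right-hand sides against the same
tall matrix A is the inner loop of every unmixing step.  With the thin QR
``A = Q R``, the minimiser of ``||R x - Q^T b||`` is identical, so each pixel
reduces to a k x k problem (k = number of components) — orders of magnitude
faster than running Lawson-Hanson on the full channel dimension per pixel.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls


def nnls_single(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Lawson-Hanson NNLS for one right-hand side (no reduction)."""
    x, _ = _scipy_nnls(A, b)
    return x


#: largest component count handled by the vectorised active-set enumeration
_SMALL_K = 4


def _nnls_enumerate(design: np.ndarray, Bt: np.ndarray) -> np.ndarray:
    """Vectorised exact NNLS for k <= _SMALL_K via active-set enumeration.

    For every subset F of components, solve the unconstrained LS restricted to
    F for all right-hand sides at once, then keep solutions that are feasible
    (x >= 0) and KKT-optimal (negative gradient <= 0 on the complement).
    Among valid subsets the smallest residual wins.  Exact for full-column-rank
    designs; samples with no valid subset (degenerate geometry) fall back to
    Lawson-Hanson.
    """
    k = design.shape[1]
    G = design.T @ design
    ATB = Bt @ design  # (n_samples, k)
    n_samples = Bt.shape[0]
    scale = max(float(np.abs(ATB).max()), 1.0)
    best_x = np.zeros((n_samples, k))
    best_r = np.einsum("ij,ij->i", Bt, Bt)  # residual^2 of x = 0
    solved = ATB.max(axis=1) <= 1e-12 * scale  # x = 0 already optimal
    for mask in range(1, 2**k):
        free = [j for j in range(k) if mask >> j & 1]
        Gff = G[np.ix_(free, free)]
        try:
            Ginv = np.linalg.inv(Gff)
        except np.linalg.LinAlgError:
            continue
        Xf = ATB[:, free] @ Ginv.T  # (n_samples, |F|)
        feasible = np.all(Xf >= -1e-12, axis=1)
        # KKT on the complement: w = A^T b - G x must be <= 0 there
        X = np.zeros((n_samples, k))
        X[:, free] = np.clip(Xf, 0.0, None)
        W = ATB - X @ G
        comp = [j for j in range(k) if not (mask >> j & 1)]
        optimal = feasible
        if comp:
            optimal = feasible & np.all(W[:, comp] <= 1e-9 * scale, axis=1)
        if not optimal.any():
            continue
        r = best_r.copy()
        r[optimal] = (
            np.einsum("ij,ij->i", Bt[optimal], Bt[optimal])
            - np.einsum("ij,ij->i", X[optimal], ATB[optimal])
        )
        better = optimal & (r < best_r * (1 - 1e-12))
        improved = better | (optimal & ~solved)
        best_x[improved] = X[improved]
        best_r[improved] = r[improved]
        solved |= optimal
    for i in np.flatnonzero(~solved):  # pragma: no cover - degenerate designs
        best_x[i], _ = _scipy_nnls(design, Bt[i])
    return best_x


def nnls_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``min ||A x_i - b_i||, x_i >= 0`` for every row ``b_i`` of B.

    Parameters
    ----------
    A : (n_features, k) design matrix shared by all problems.
    B : (n_samples, n_features) stacked right-hand sides.

    Returns
    -------
    (n_samples, k) non-negative coefficients.
    """
    A = np.asarray(A, dtype=float)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n, k = A.shape
    if B.shape[1] != n:
        raise ValueError(f"B has {B.shape[1]} features, A has {n}")
    if n > k:
        Q, R = np.linalg.qr(A)  # thin QR: R is (k, k)
        Bt = B @ Q
        design = R
    else:
        design = A
        Bt = B
    if k <= _SMALL_K and np.linalg.matrix_rank(design) == k:
        return _nnls_enumerate(design, Bt)
    out = np.empty((B.shape[0], k))
    for i in range(B.shape[0]):
        out[i], _ = _scipy_nnls(design, Bt[i])
    return out
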