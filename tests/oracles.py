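"""Independent reference implementations used only as test oracles.

Deliberately naive and separate from the package code paths they check:
closed-form Bateman chains vs the ODE integrator, exhaustive active-set
enumeration vs Lawson-Hanson NNLS, and a hand-written pool-adjacent-violators
unimodal regression vs the isotonic-regression-based projection.
"""

import itertools

import numpy as np


def bateman_chain(rates, t):
    """Closed-form consecutive first-order chain A1 -> A2 -> ... -> An.

    ``rates`` are the n-1 positive, pairwise-distinct rate constants; the
    terminal species is absorbing (rate 0).  Initial state is pure A1.
    Returns an array (len(t), n).
    """
    k = np.asarray(list(rates) + [0.0], dtype=float)
    n = k.size
    t = np.asarray(t, dtype=float)
    out = np.zeros((t.size, n))
    for i in range(n):
        # c_i(t) = (prod_{j<i} k_j) * sum_{j<=i} exp(-k_j t)/prod_{l<=i, l!=j}(k_l - k_j)
        prefactor = np.prod(k[:i]) if i > 0 else 1.0
        acc = np.zeros_like(t)
        for j in range(i + 1):
            denom = 1.0
            for l in range(i + 1):
                if l != j:
                    denom *= k[l] - k[j]
            acc += np.exp(-k[j] * t) / denom
        out[:, i] = prefactor * acc
    return out


def nnls_bruteforce(A, b):
    """Exact NNLS by enumerating all active sets (KKT check per candidate)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    best_x, best_r = np.zeros(n), float(np.dot(b, b))
    for mask in itertools.product([0, 1], repeat=n):
        free = np.flatnonzero(mask)
        x = np.zeros(n)
        if free.size:
            sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
            if np.any(sol < -1e-12):
                continue
            x[free] = np.clip(sol, 0.0, None)
        r = b - A @ x
        rnorm = float(r @ r)
        grad = A.T @ r  # KKT: gradient of fit w.r.t. inactive vars must be <= 0
        inactive = np.flatnonzero(x == 0)
        if np.all(grad[inactive] <= 1e-9 * max(1.0, np.abs(grad).max())):
            if rnorm < best_r - 1e-15:
                best_x, best_r = x, rnorm
    return best_x


def _pava_inc(y):
    """Pool adjacent violators, non-decreasing fit, uniform weights."""
    values = []
    weights = []
    for v in y:
        values.append(float(v))
        weights.append(1.0)
        while len(values) > 1 and values[-2] > values[-1]:
            w = weights[-2] + weights[-1]
            merged = (values[-2] * weights[-2] + values[-1] * weights[-1]) / w
            values[-2:] = [merged]
            weights[-2:] = [w]
    out = []
    for v, w in zip(values, weights):
        out.extend([v] * int(w))
    return np.array(out)


def unimodal_bruteforce(y):
    """Exhaustive unimodal regression: try every mode split, PAVA each side."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    best, best_sse = None, np.inf
    for m in range(n):
        head = _pava_inc(y[: m + 1])
        tail = _pava_inc(y[m + 1 :][::-1])[::-1] if m + 1 < n else np.empty(0)
        cand = np.concatenate([head, tail])
        sse = float(((cand - y) ** 2).sum())
        if sse < best_sse - 1e-15:
            best, best_sse = cand, sse
    return best
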