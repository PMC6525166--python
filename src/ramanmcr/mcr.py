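"""Library-constrained multivariate curve resolution by alternating least squares.

The bilinear model is ``D = C S + E``.  Spectra of the stable forms are known
and held fixed (equality constraint); the remaining library rows — the
metastable intermediates — are resolved from the data.  Constraints follow
standard soft-modelling practice: non-negativity on both C and S, closure
(fractions sum to 1 per observation) and unimodality of the concentration
time profiles.

Because the known spectra are fixed at unit maximum while C is closed to 1, a
single global gain ``g`` is fitted each cycle so the model ``g * C @ S`` can
match detector-count-scaled data; ``g`` absorbs the arbitrary intensity unit
of the instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._lsq import nnls_batch
from .types import MCRResult, SpectralLibrary

__all__ = [
    "lack_of_fit",
    "estimate_rank",
    "RankSelection",
    "initialize_unknowns",
    "unimodality_project",
    "MCRConstraints",
    "mcr_als",
]


def lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray, gain: float = 1.0) -> float:
    """Percent lack of fit: ``100 * sqrt(sum((D - g*C@S)^2) / sum(D^2))``."""
    D = np.asarray(D, dtype=float)
    denom = float((D**2).sum())
    if denom == 0.0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    resid = D - gain * np.asarray(C) @ np.asarray(S)
    return 100.0 * float(np.sqrt((resid**2).sum() / denom))


@dataclass
class RankSelection:
    """Chosen component count with the LoF-versus-k audit table."""

    k: int
    table: pd.DataFrame = field(repr=False)


def estimate_rank(
    D: np.ndarray,
    k_max: int,
    rel_improvement_threshold: float = 0.25,
    perfect_lof: float = 1e-8,
) -> RankSelection:
    """Select the number of components from unconstrained truncated-SVD fits.

    ``LoF(k)`` of the best rank-k approximation is computed for k = 1..k_max;
    the selected k is the smallest one whose successor adds less than
    ``rel_improvement_threshold`` relative improvement (the elbow), with ties
    at the threshold resolved toward the smaller k.  A k whose LoF is already
    below ``perfect_lof`` percent is accepted immediately.
    """
    D = np.asarray(D, dtype=float)
    if not np.any(D):
        raise ValueError("cannot estimate rank of an all-zero matrix")
    if not 1 <= k_max <= min(D.shape):
        raise ValueError(f"k_max must be in [1, {min(D.shape)}], got {k_max}")
    sv = np.linalg.svd(D, compute_uv=False)
    total = float((sv**2).sum())
    tail = np.concatenate([np.cumsum((sv**2)[::-1])[::-1][1:], [0.0]])
    lof = 100.0 * np.sqrt(np.maximum(tail[:k_max], 0.0) / total)

    improvement = np.full(k_max, np.nan)
    for k in range(1, k_max):
        improvement[k] = 0.0 if lof[k - 1] == 0 else (lof[k - 1] - lof[k]) / lof[k - 1]

    selected = k_max
    for k in range(k_max):
        if lof[k] <= perfect_lof:
            selected = k + 1
            break
        if k >= 1 and improvement[k] <= rel_improvement_threshold:
            selected = k  # elbow: keep the previous (smaller) k
            break
    table = pd.DataFrame(
        {
            "k": np.arange(1, k_max + 1),
            "lof_percent": lof,
            "rel_improvement": improvement,
        }
    )
    return RankSelection(k=selected, table=table)


def _purity_select(R: np.ndarray, n_pick: int, offset_frac: float = 0.05) -> list[int]:
    """Pick ``n_pick`` mutually dissimilar high-purity rows of R.

    Purity of a row is std / (mean + alpha) with alpha = 5% of the largest row
    mean, weighted by the row norm so that near-empty residuals (pure noise)
    cannot outscore structured ones; subsequent picks are weighted by the Gram
    determinant of the normalised candidates against the already-selected set,
    so near-duplicates of a selected spectrum are suppressed.  The outcome
    depends on the rows only as a set, not on their order.
    """
    mu = R.mean(axis=1)
    sigma = R.std(axis=1)
    alpha = offset_frac * max(float(mu.max()), np.finfo(float).tiny)
    norms = np.linalg.norm(R, axis=1)
    purity = norms * sigma / (mu + alpha)
    N = np.divide(R, norms[:, None], out=np.zeros_like(R), where=norms[:, None] > 0)

    selected: list[int] = []
    for _ in range(n_pick):
        score = purity.copy()
        if selected:
            base = N[selected]
            for j in range(R.shape[0]):
                if j in selected:
                    continue
                Y = np.vstack([base, N[j]])
                score[j] *= max(float(np.linalg.det(Y @ Y.T)), 0.0)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def initialize_unknowns(D: np.ndarray, library: SpectralLibrary) -> np.ndarray:
    """Deterministic initial full S for ALS.

    Known rows are copied verbatim.  Unknown rows are seeded from the
    stable-form residual spectra of the observations: after a non-negative fit
    of the known spectra is subtracted from every row of D, the most mutually
    dissimilar high-purity residuals (SIMPLISMA-style, 5% offset) are taken,
    clipped to non-negative and normalised to unit maximum.
    """
    D = np.asarray(D, dtype=float)
    unknown_idx = np.flatnonzero(~library.known_mask)
    S0 = library.spectra.copy()
    if unknown_idx.size == 0:
        return S0
    if D.shape[0] < unknown_idx.size:
        raise ValueError(
            f"{unknown_idx.size} unknowns but only {D.shape[0]} observations"
        )
    known = library.spectra[library.known_mask]
    if known.shape[0]:
        coeff = nnls_batch(known.T, D)
        R = D - coeff @ known
    else:
        R = D.copy()
    picks = _purity_select(R, unknown_idx.size)
    for row, pick in zip(unknown_idx, picks):
        s = np.clip(R[pick], 0.0, None)
        peak = s.max()
        if peak <= 0:
            raise ValueError(
                "initialization failed: a selected residual spectrum is non-positive"
            )
        S0[row] = s / peak
    return S0


def _pava(y: np.ndarray, increasing: bool) -> np.ndarray:
    """Pool-adjacent-violators isotonic fit (uniform weights), O(n)."""
    if not increasing:
        return _pava(y[::-1], True)[::-1]
    # blocks of (sum, count) with non-decreasing means
    sums: list[float] = []
    counts: list[int] = []
    for v in y:
        s, c = float(v), 1
        while sums and sums[-1] / counts[-1] > s / c:
            s += sums.pop()
            c += counts.pop()
        sums.append(s)
        counts.append(c)
    out = np.empty(y.size)
    i = 0
    for s, c in zip(sums, counts):
        out[i : i + c] = s / c
        i += c
    return out


def _prefix_isotonic_sse(y: np.ndarray) -> np.ndarray:
    """sse[m] = squared error of the non-decreasing fit to y[: m + 1].

    Single left-to-right PAVA sweep; the running SSE is the sum over blocks of
    (sumsq - sum^2 / count), updated as blocks merge (amortised O(n)).
    """
    n = y.size
    sse = np.empty(n)
    sums: list[float] = []
    sqs: list[float] = []
    counts: list[int] = []
    total = 0.0
    for m, v in enumerate(y):
        s, q, c = float(v), float(v) * float(v), 1
        block_err = 0.0
        while sums and sums[-1] / counts[-1] > s / c:
            total -= sqs[-1] - sums[-1] ** 2 / counts[-1]
            s += sums.pop()
            q += sqs.pop()
            c += counts.pop()
        sums.append(s)
        sqs.append(q)
        counts.append(c)
        total += q - s**2 / c
        sse[m] = max(total, 0.0)
    return sse


def _is_unimodal(y: np.ndarray) -> bool:
    d = np.diff(y)
    seen_fall = False
    for step in d:
        if step < 0:
            seen_fall = True
        elif step > 0 and seen_fall:
            return False
    return True


def unimodality_project(profile: np.ndarray) -> np.ndarray:
    """Least-squares projection onto the unimodal cone (rise, single peak, fall).

    Every mode position is tried; for each, the prefix is fitted by
    non-decreasing and the suffix by non-increasing isotonic regression, and
    the split with the smallest squared error wins.  An already-unimodal input
    (plateaus allowed, including fully monotone vectors) is returned unchanged;
    non-negativity is preserved because isotonic fits average input values.
    """
    y = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("profile must be finite")
    n = y.size
    if n <= 2 or _is_unimodal(y):
        return y.copy()
    # sse of rising fit to y[:m+1] plus falling fit to y[m+1:], for every m;
    # the falling-side sse comes from the same sweep on the reversed vector
    sse_inc = _prefix_isotonic_sse(y)
    sse_dec = _prefix_isotonic_sse(y[::-1])[::-1]  # sse_dec[i]: fit of y[i:]
    total = sse_inc + np.concatenate([sse_dec[1:], [0.0]])
    m = int(np.argmin(total))
    head = _pava(y[: m + 1], increasing=True)
    tail = _pava(y[m + 1 :], increasing=False) if m + 1 < n else np.empty(0)
    return np.concatenate([head, tail])


@dataclass(frozen=True)
class MCRConstraints:
    """Constraint toggles for :func:`mcr_als`.

    ``unimodality`` applies to the time profiles of ``"unknown"`` (metastable)
    components by default, or ``"all"`` / ``"none"``.
    """

    nonneg_C: bool = True
    nonneg_S: bool = True
    closure: bool = True
    unimodality: str = "unknown"

    def __post_init__(self) -> None:
        if self.unimodality not in ("unknown", "all", "none"):
            raise ValueError("unimodality must be 'unknown', 'all' or 'none'")


def _lstsq_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sol, *_ = np.linalg.lstsq(A, B.T, rcond=None)
    return sol.T


def _c_step(
    D: np.ndarray,
    S: np.ndarray,
    cons: MCRConstraints,
    unimodal_idx: np.ndarray,
) -> tuple[np.ndarray, float]:
    solver = nnls_batch if cons.nonneg_C else _lstsq_batch
    C = solver(S.T, D)
    gain = 1.0
    if cons.closure:
        rowsum = C.sum(axis=1)
        safe = np.where(rowsum > 0, rowsum, 1.0)
        C = C / safe[:, None]
        C[rowsum == 0] = 1.0 / S.shape[0]
    for j in unimodal_idx:
        C[:, j] = unimodality_project(C[:, j])
    if cons.closure:
        rowsum = C.sum(axis=1)
        safe = np.where(rowsum > 0, rowsum, 1.0)
        C = C / safe[:, None]
        C[rowsum == 0] = 1.0 / S.shape[0]
        CS = C @ S
        denom = float((CS**2).sum())
        gain = float((D * CS).sum() / denom) if denom > 0 else 1.0
    return C, gain


def _s_step(
    D: np.ndarray,
    C: np.ndarray,
    S: np.ndarray,
    gain: float,
    known_mask: np.ndarray,
    cons: MCRConstraints,
) -> tuple[np.ndarray, np.ndarray]:
    """Update unknown rows of S (knowns held fixed); returns (S, C) with the
    unknown C columns rescaled so the product C @ S is unchanged by the
    unit-max normalisation of the unknown spectra."""
    unknown = ~known_mask
    if not unknown.any():
        return S, C
    target = D / gain - C[:, known_mask] @ S[known_mask]
    solver = nnls_batch if cons.nonneg_S else _lstsq_batch
    Su = solver(C[:, unknown], target.T)  # (channels, u)
    Su = Su.T
    C = C.copy()
    u_rows = np.flatnonzero(unknown)
    for i, row in enumerate(u_rows):
        peak = Su[i].max()
        if peak > 0:
            S[row] = Su[i] / peak
            C[:, row] = C[:, row] * peak
        else:
            S[row] = Su[i]
    return S, C


def _subspace_polish(
    D: np.ndarray,
    S: np.ndarray,
    known_mask: np.ndarray,
    cons: MCRConstraints,
    unimodal_idx: np.ndarray,
    maxfev: int = 20000,
) -> tuple[np.ndarray, bool]:
    """Joint refinement of the unknown spectra inside the signal subspace.

    Plain alternation creeps along the near-degenerate valley where a small
    admixture of one component into an unknown spectrum is compensated in C.
    Here each unknown row is re-parameterised by its k coordinates in the
    rank-k right-singular basis of D (the denoised signal subspace), and the
    lack of fit — with C always the exact constrained solve for the candidate
    spectra — is minimised jointly over those few coordinates with Powell's
    method.  Deterministic; non-negativity and unit-max normalisation are
    enforced inside the parameterisation.
    """
    unk = np.flatnonzero(~known_mask)
    k = S.shape[0]
    if unk.size == 0 or min(D.shape) < k:
        return S, True
    _, _, Vt = np.linalg.svd(D, full_matrices=False)
    V = Vt[:k]

    def build(theta: np.ndarray) -> np.ndarray:
        S_new = S.copy()
        for i, j in enumerate(unk):
            row = np.clip(theta[i * k : (i + 1) * k] @ V, 0.0, None)
            peak = row.max()
            S_new[j] = row / peak if peak > 0 else row
        return S_new

    def objective(theta: np.ndarray) -> float:
        S_new = build(theta)
        C, gain = _c_step(D, S_new, cons, unimodal_idx)
        return lack_of_fit(D, C, S_new, gain)

    theta0 = np.concatenate([V @ S[j] for j in unk])
    f0 = objective(theta0)
    res = minimize(
        objective,
        theta0,
        method="Powell",
        options={"xtol": 1e-10, "ftol": 1e-12, "maxfev": maxfev},
    )
    # Accept whenever the subspace-restricted objective improved.  The raw
    # lack of fit of the unrestricted ALS spectra can be lower only because
    # their out-of-subspace part fits detector noise; within the signal
    # subspace a lower objective means a genuinely better solution.
    if res.fun <= f0:
        return build(res.x), bool(res.success)
    return S, True  # pragma: no cover - Powell is monotone from theta0


def mcr_als(
    D: np.ndarray,
    library: SpectralLibrary,
    constraints: MCRConstraints | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    init_S: np.ndarray | None = None,
    refine: bool = True,
) -> MCRResult:
    """Constrained alternating least squares on ``D`` (observations x channels).

    Each cycle solves a per-observation NNLS for C (then closure and
    unimodality), and a per-channel NNLS for the unknown rows of S with the
    known rows held fixed and unknown rows renormalised to unit maximum.
    Iteration stops when the relative change of the lack of fit falls below
    ``tol`` or after ``max_iter`` cycles; non-convergence is reported with a
    warning, never silently.  With ``refine`` on (the default) the unknown
    spectra are then polished jointly in the rank-k signal subspace
    (:func:`_subspace_polish`), which escapes the slow compensation valley
    plain alternation is prone to when component spectra overlap strongly.

    Returns
    -------
    MCRResult with closed C, resolved S (known rows bit-identical to the
    input), the fitted global gain, the LoF trace and the averaged relative
    residual ``100 * mean|D - g*C@S| / mean|D|``.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("D must be finite")
    cons = constraints or MCRConstraints()
    known_mask = library.known_mask.copy()
    S = init_S.copy() if init_S is not None else initialize_unknowns(D, library)
    S[known_mask] = library.spectra[known_mask]

    if cons.unimodality == "all":
        unimodal_idx = np.arange(library.n_components)
    elif cons.unimodality == "unknown":
        unimodal_idx = np.flatnonzero(~known_mask)
    else:
        unimodal_idx = np.empty(0, dtype=int)

    C, gain = _c_step(D, S, cons, unimodal_idx)
    trace = [lack_of_fit(D, C, S, gain)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        S, C = _s_step(D, C, S, gain, known_mask, cons)
        C, gain = _c_step(D, S, cons, unimodal_idx)
        lof = lack_of_fit(D, C, S, gain)
        prev = trace[-1]
        trace.append(lof)
        if lof <= 1e-10 or abs(prev - lof) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break
    if refine and (~known_mask).any():
        S, polish_ok = _subspace_polish(D, S, known_mask, cons, unimodal_idx)
        C, gain = _c_step(D, S, cons, unimodal_idx)
        trace.append(lack_of_fit(D, C, S, gain))
        converged = converged or polish_ok
    if not converged:
        warnings.warn(
            f"MCR-ALS did not converge within {max_iter} iterations "
            f"(last LoF {trace[-1]:.4g}%)",
            RuntimeWarning,
            stacklevel=2,
        )
    model = gain * C @ S
    avg_rel = 100.0 * float(np.abs(D - model).mean() / np.abs(D).mean())
    return MCRResult(
        C=C,
        S=S,
        gain=gain,
        labels=list(library.labels),
        known_mask=known_mask,
        lof_trace=np.asarray(trace),
        avg_rel_residual=avg_rel,
        n_iterations=n_iter,
        converged=converged,
    )
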