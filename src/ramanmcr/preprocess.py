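"""Trace selection and stable-form subtraction.

Profile resolution uses a single lateral point on the laser line — the one
with the highest signal-to-noise ratio — while the residual map isolates the
dynamics of metastable intermediates by removing everything the stable-form
spectra can explain (a per-spectrum non-negative fit, so stable contributions
cannot go negative).
"""

from __future__ import annotations

import numpy as np

from ._lsq import nnls_batch
from .types import HyperLineScan, ResidualMap, SpectralLibrary

__all__ = ["snr_per_position", "select_best_position", "residual_map"]

#: default window placement as fractions of the axis span: the top tenth of
#: the axis serves as the signal-free noise region
_SIGNAL_FRACTION = (0.0, 0.85)
_NOISE_FRACTION = (0.90, 1.0)


def snr_per_position(
    scan: HyperLineScan,
    t: int,
    signal_window: tuple[float, float] | None = None,
    noise_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-position SNR at time index ``t``.

    SNR = (peak intensity inside ``signal_window``) / (robust noise scale
    estimated from the signal-free ``noise_window`` via the median absolute
    deviation).  By default the lower 85% of the axis is the signal window and
    the top 10% the noise window.  The two windows must not overlap.
    Positions with zero signal report SNR 0; a vanishing noise estimate is
    floored at machine precision so the result is always finite.
    """
    if not 0 <= t < scan.n_times:
        raise IndexError(f"time index {t} out of range [0, {scan.n_times})")
    span = scan.axis.stop - scan.axis.start
    if signal_window is None:
        signal_window = (
            scan.axis.start + _SIGNAL_FRACTION[0] * span,
            scan.axis.start + _SIGNAL_FRACTION[1] * span,
        )
    if noise_window is None:
        noise_window = (
            scan.axis.start + _NOISE_FRACTION[0] * span,
            scan.axis.start + _NOISE_FRACTION[1] * span,
        )
    lo_s, hi_s = signal_window
    lo_n, hi_n = noise_window
    if max(lo_s, lo_n) < min(hi_s, hi_n):
        raise ValueError(
            f"signal window {signal_window} overlaps noise window {noise_window}"
        )
    sig_mask = scan.axis.window_mask(lo_s, hi_s)
    noise_mask = scan.axis.window_mask(lo_n, hi_n)
    if not sig_mask.any() or not noise_mask.any():
        raise ValueError("a window contains no channels on this axis")

    spectra = scan.intensities[t]  # (n_positions, channels)
    signal = spectra[:, sig_mask].max(axis=1)
    signal = np.maximum(signal, 0.0)
    w = spectra[:, noise_mask]
    med = np.median(w, axis=1, keepdims=True)
    noise = 1.4826 * np.median(np.abs(w - med), axis=1)

    floor = np.finfo(float).eps * max(float(signal.max()), 1.0)
    snr = signal / np.maximum(noise, floor)
    snr[signal == 0.0] = 0.0
    return snr


def select_best_position(snr: np.ndarray) -> int:
    """Index of the maximum SNR; ties resolved to the lowest index."""
    snr = np.asarray(snr, dtype=float)
    if snr.size == 0:
        raise ValueError("SNR vector is empty")
    if np.all(np.isnan(snr)):
        raise ValueError("SNR vector is all-NaN")
    return int(np.nanargmax(snr))


def residual_map(scan: HyperLineScan, stable: SpectralLibrary) -> ResidualMap:
    """Residual intensity after non-negative subtraction of stable forms.

    For every spectrum d the stable-form coefficients solve
    ``min ||d - A^T x||  s.t.  x >= 0`` with A the stable spectra; the
    residual spectrum is ``d - A^T x_hat`` and the residual intensity its
    Euclidean norm.  The result is invariant to non-negative rescaling of
    individual stable spectra (the coefficients compensate).
    """
    if stable.n_components == 0:
        raise ValueError("stable library is empty")
    if not stable.axis.matches(scan.axis):
        raise ValueError("stable library axis does not match the scan axis")
    nt, nx, nc = scan.intensities.shape
    flat = scan.intensities.reshape(-1, nc)
    A = stable.spectra  # (k, channels)
    coeff = nnls_batch(A.T, flat)
    resid = flat - coeff @ A
    intensity = np.linalg.norm(resid, axis=1)
    return ResidualMap(
        intensity=intensity.reshape(nt, nx),
        spectra=resid.reshape(nt, nx, nc),
        times=scan.times,
        positions=scan.positions,
    )
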