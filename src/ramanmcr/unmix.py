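"""Per-pixel NNLS unmixing: concentration profiles, chemical maps, area plots.

Once the spectral library is complete (stable forms plus resolved metastable
intermediates), every spectrum of a line scan or area raster is unmixed
independently by non-negative least squares.  Unmixing is pixel-separable, so
maps inherit no spatial smoothing from the algorithm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._lsq import nnls_batch, nnls_single
from .types import ChemicalMap, ConcentrationField, HyperLineScan, SpectralLibrary

__all__ = [
    "nnls_solve",
    "unmix_scan",
    "metastable_area_plot",
    "unmix_area_map",
    "grid_shape",
    "field_from_map",
]

#: pixels whose summed coefficients fall below this fraction of the reference
#: total are treated as empty substrate
EMPTY_FLOOR_FACTOR = 1e-3


def nnls_solve(
    A: np.ndarray, b: np.ndarray, labels: list[str] | None = None
) -> np.ndarray:
    """Solve ``min ||A x - b||  s.t.  x >= 0`` (Lawson-Hanson active set).

    ``A`` is (channels x k); a component whose column is all zero is rejected
    by name, since it could never receive a meaningful coefficient.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.shape != (A.shape[0],):
        raise ValueError(f"incompatible shapes A {A.shape}, b {b.shape}")
    zero_cols = np.flatnonzero(~A.any(axis=0))
    if zero_cols.size:
        j = int(zero_cols[0])
        name = labels[j] if labels else f"column {j}"
        raise ValueError(f"library component {name!r} is all-zero")
    return nnls_single(A, b)


def _empty_floor(totals: np.ndarray, factor: float) -> float:
    ref = float(np.median(totals))
    if ref <= 0:  # mostly-background scene: reference the occupied pixels
        pos = totals[totals > 0]
        ref = float(np.median(pos)) if pos.size else 0.0
    return factor * ref


def unmix_scan(
    scan: HyperLineScan,
    library: SpectralLibrary,
    closure: bool = True,
    profile: str | int = "mean",
    channel_mask: np.ndarray | None = None,
    empty_floor_factor: float = EMPTY_FLOOR_FACTOR,
) -> tuple[ChemicalMap, pd.DataFrame]:
    """Unmix every (time, position) spectrum against a resolved library.

    With ``closure`` on, each pixel's coefficients are normalised to sum to 1;
    pixels whose total coefficient falls below the empty floor are reported as
    empty (NaN in the map, flagged in ``empty_mask``).  ``profile`` selects the
    per-time concentration series: ``"mean"`` averages over the line, an
    integer takes a single lateral position.  ``channel_mask`` restricts the
    fit to a subset of channels (e.g. to probe robustness to masked regions).
    """
    if not scan.axis.matches(library.axis):
        raise ValueError("scan and library axes do not match")
    A = library.spectra.T  # (channels, k)
    nt, nx, nc = scan.intensities.shape
    flat = scan.intensities.reshape(-1, nc)
    if channel_mask is not None:
        channel_mask = np.asarray(channel_mask, dtype=bool)
        if channel_mask.shape != (nc,):
            raise ValueError("channel_mask length must equal the channel count")
        A = A[channel_mask]
        flat = flat[:, channel_mask]
    zero_cols = np.flatnonzero(~A.any(axis=0))
    if zero_cols.size:
        raise ValueError(
            f"library component {library.labels[int(zero_cols[0])]!r} is all-zero "
            "on the fitted channels"
        )
    coeff = nnls_batch(A, flat)  # (nt*nx, k)
    totals = coeff.sum(axis=1)
    empty = totals < _empty_floor(totals, empty_floor_factor)
    if closure:
        safe = np.where(totals > 0, totals, 1.0)
        frac = coeff / safe[:, None]
        frac[empty] = np.nan
        values = frac
    else:
        values = coeff
    k = library.n_components
    maps = values.reshape(nt, nx, k).transpose(2, 0, 1)
    cmap = ChemicalMap(
        labels=list(library.labels),
        values=maps,
        coords={"time": scan.times, "position": scan.positions},
        kind="line",
        empty_mask=empty.reshape(nt, nx),
    )
    if profile == "mean":
        with np.errstate(invalid="ignore"):
            series = np.nanmean(maps, axis=2)  # (k, nt)
    else:
        series = maps[:, :, int(profile)]
    profiles = pd.DataFrame(series.T, index=scan.times, columns=library.labels)
    profiles.index.name = "time_min"
    return cmap, profiles


def field_from_map(cmap: ChemicalMap) -> ConcentrationField:
    """Convert a fully occupied, closed line map into a ConcentrationField."""
    if cmap.kind != "line":
        raise ValueError("only line-scan maps convert to a ConcentrationField")
    frac = cmap.values.transpose(1, 2, 0)
    if np.isnan(frac).any():
        raise ValueError("map contains empty pixels; cannot form a closed field")
    return ConcentrationField(
        fractions=frac,
        labels=list(cmap.labels),
        times=cmap.coords["time"],
        positions=cmap.coords["position"],
    )


def metastable_area_plot(
    field: ConcentrationField, metastable_labels: list[str]
) -> pd.DataFrame:
    """Per-time stacked series for the metastable intermediates only.

    The field must come from unmixing with the *full* library — stable forms
    included, so the fractions are on the closed scale — after which only the
    metastable columns are emitted (mean over the line per time point).
    """
    missing = [l for l in metastable_labels if l not in field.labels]
    if missing:
        raise ValueError(f"unknown component label(s): {missing}")
    series = field.fractions.mean(axis=1)  # (n_times, k)
    df = pd.DataFrame(series, index=field.times, columns=field.labels)
    df.index.name = "time_min"
    return df[list(metastable_labels)]


def grid_shape(extent_um: tuple[float, float], step_um: float) -> tuple[int, int]:
    """Raster dimensions of an area map: ``floor(extent / step) + 1`` per axis."""
    if step_um <= 0:
        raise ValueError("step must be positive")
    return (
        int(extent_um[0] // step_um) + 1,
        int(extent_um[1] // step_um) + 1,
    )


def unmix_area_map(
    cube: np.ndarray,
    library: SpectralLibrary,
    step_um: float | None,
    origin_um: tuple[float, float] = (0.0, 0.0),
    closure: bool = False,
    roi_um: tuple[tuple[float, float], tuple[float, float]] | None = None,
    empty_floor_factor: float = EMPTY_FLOOR_FACTOR,
) -> ChemicalMap:
    """Per-pixel NNLS of an (ny, nx, channel) area raster.

    ``step_um`` is the raster step and is required; ``roi_um`` optionally crops
    to ((y_lo, y_hi), (x_lo, x_hi)) in micrometres before unmixing.  Raw NNLS
    coefficients are returned by default (closure off), since area scenes
    contain empty substrate pixels where closed fractions are meaningless.
    """
    if step_um is None or step_um <= 0:
        raise ValueError("area maps require a positive grid step (um)")
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValueError("cube must be (ny, nx, channels)")
    ny, nx, nc = cube.shape
    if nc != library.axis.n_channels:
        raise ValueError("cube channel count does not match the library axis")
    y = origin_um[0] + step_um * np.arange(ny)
    x = origin_um[1] + step_um * np.arange(nx)
    if roi_um is not None:
        (y_lo, y_hi), (x_lo, x_hi) = roi_um
        ysel = (y >= y_lo) & (y <= y_hi)
        xsel = (x >= x_lo) & (x <= x_hi)
        cube = cube[ysel][:, xsel]
        y, x = y[ysel], x[xsel]
        ny, nx = cube.shape[:2]
    flat = cube.reshape(-1, nc)
    coeff = nnls_batch(library.spectra.T, flat)
    totals = coeff.sum(axis=1)
    empty = totals < _empty_floor(totals, empty_floor_factor)
    if closure:
        safe = np.where(totals > 0, totals, 1.0)
        coeff = coeff / safe[:, None]
        coeff[empty] = np.nan
    k = library.n_components
    return ChemicalMap(
        labels=list(library.labels),
        values=coeff.reshape(ny, nx, k).transpose(2, 0, 1),
        coords={"y_um": y, "x_um": x},
        kind="area",
        empty_mask=empty.reshape(ny, nx),
    )
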