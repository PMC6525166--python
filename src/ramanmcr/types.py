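"""Core containers for hyperspectral line-scan Raman analysis.

The bilinear model underlying everything here is ``D = C @ S + E``: measured
spectra ``D`` are non-negative mixtures of component spectra ``S`` weighted by
concentration profiles ``C``.  The containers enforce the physical invariants
each object must satisfy (closure of concentration fields, non-negativity of
known spectra, monotone axes) so that downstream algorithms can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WavenumberAxis",
    "Band",
    "BandTable",
    "SpectralLibrary",
    "HyperLineScan",
    "ConcentrationField",
    "KineticScheme",
    "NoiseSpec",
    "ResidualMap",
    "MCRResult",
    "ChemicalMap",
]

#: default spectral coverage of the line-focus spectrograph, cm^-1
DEFAULT_START = 350.0
DEFAULT_STOP = 2300.0
DEFAULT_STEP = 2.0


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform Raman-shift grid in cm^-1 (strictly increasing).

    Defaults span 350-2300 cm^-1 at 2 cm^-1, i.e. 976 channels.
    """

    start: float = DEFAULT_START
    stop: float = DEFAULT_STOP
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"axis step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(
                f"axis stop ({self.stop}) must exceed start ({self.start})"
            )

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return float(self.start) + float(self.step) * np.arange(n, dtype=float)

    @property
    def n_channels(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with ``lo <= wavenumber <= hi``."""
        v = self.values
        return (v >= lo) & (v <= hi)

    def matches(self, other: "WavenumberAxis") -> bool:
        return (
            np.isclose(self.start, other.start)
            and np.isclose(self.stop, other.stop)
            and np.isclose(self.step, other.step)
        )


@dataclass(frozen=True)
class Band:
    """A single Raman band: pseudo-Voigt profile with FWHM parameterisation.

    ``eta`` mixes Lorentzian (1) and Gaussian (0) character; both pure shapes
    reach half their peak amplitude at ``center +/- fwhm / 2``.
    """

    center: float
    fwhm: float
    amplitude: float = 1.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} cm^-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} cm^-1: amplitude must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"band at {self.center} cm^-1: eta must be in [0, 1]")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, dtype=float) - self.center
        gauss = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        lorentz = 1.0 / (1.0 + (2.0 * x / self.fwhm) ** 2)
        return self.amplitude * (self.eta * lorentz + (1.0 - self.eta) * gauss)


@dataclass(frozen=True)
class BandTable:
    """Band list defining one component's spectrum."""

    bands: tuple[Band, ...] = ()

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[float]]) -> "BandTable":
        """Build from ``(center, fwhm, amplitude[, eta])`` rows."""
        return cls(tuple(Band(*row) for row in rows))

    def validate_on(self, axis: WavenumberAxis) -> None:
        for band in self.bands:
            if not axis.contains(band.center):
                raise ValueError(
                    f"band center {band.center} cm^-1 lies outside the axis "
                    f"span {axis.start}-{axis.stop} cm^-1"
                )

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        v = axis.values
        out = np.zeros_like(v)
        for band in self.bands:
            out += band.profile(v)
        return out


@dataclass
class SpectralLibrary:
    """Component spectra with known/unknown flags.

    ``spectra`` is (k components x channels).  Rows flagged ``known`` are fixed
    reference spectra of stable forms and must be finite and non-negative.
    Rows flagged unknown are placeholders to be resolved (their contents are
    ignored on input and are conventionally NaN).
    """

    labels: list[str]
    spectra: np.ndarray
    known_mask: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.known_mask = np.asarray(self.known_mask, dtype=bool)
        k, c = self.spectra.shape
        if len(self.labels) != k or self.known_mask.shape != (k,):
            raise ValueError("labels, spectra rows and known_mask must agree in length")
        if c != self.axis.n_channels:
            raise ValueError(
                f"spectra have {c} channels but axis has {self.axis.n_channels}"
            )
        known = self.spectra[self.known_mask]
        if known.size and (not np.all(np.isfinite(known)) or known.min() < 0):
            raise ValueError("known library rows must be finite and non-negative")

    @property
    def n_components(self) -> int:
        return self.spectra.shape[0]

    @property
    def known_labels(self) -> list[str]:
        return [l for l, m in zip(self.labels, self.known_mask) if m]

    @property
    def unknown_labels(self) -> list[str]:
        return [l for l, m in zip(self.labels, self.known_mask) if not m]

    def known_subset(self) -> "SpectralLibrary":
        """Library restricted to the known (stable) components."""
        m = self.known_mask
        return SpectralLibrary(
            labels=self.known_labels,
            spectra=self.spectra[m].copy(),
            known_mask=np.ones(int(m.sum()), dtype=bool),
            axis=self.axis,
        )

    def with_unknowns(self, unknown_labels: Sequence[str]) -> "SpectralLibrary":
        """Append NaN rows for components to be resolved."""
        u = len(unknown_labels)
        nan_rows = np.full((u, self.spectra.shape[1]), np.nan)
        return SpectralLibrary(
            labels=list(self.labels) + list(unknown_labels),
            spectra=np.vstack([self.spectra, nan_rows]),
            known_mask=np.concatenate(
                [self.known_mask, np.zeros(u, dtype=bool)]
            ),
            axis=self.axis,
        )

    def resolved(self, full_spectra: np.ndarray) -> "SpectralLibrary":
        """Copy with all rows filled in and flagged known (post-MCR library)."""
        return SpectralLibrary(
            labels=list(self.labels),
            spectra=np.asarray(full_spectra, dtype=float).copy(),
            known_mask=np.ones(self.n_components, dtype=bool),
            axis=self.axis,
        )


@dataclass
class HyperLineScan:
    """Time-resolved line-scan cube: (time point x lateral position x channel).

    ``positions`` are mm along the laser line (1.8 mm, 220 points by default);
    ``times`` are minutes and must be strictly increasing.
    """

    intensities: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    axis: WavenumberAxis
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        nt, nx, nc = self.intensities.shape
        if self.times.shape != (nt,) or self.positions.shape != (nx,):
            raise ValueError("times/positions do not match the intensity cube")
        if nc != self.axis.n_channels:
            raise ValueError("cube channel count does not match the axis")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if nt > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_positions(self) -> int:
        return self.intensities.shape[1]

    def trace(self, position_index: int) -> np.ndarray:
        """The (n_times x channels) matrix at one lateral position."""
        return self.intensities[:, position_index, :]


CLOSURE_TOL = 1e-9


@dataclass
class ConcentrationField:
    """Component fractions over (time, position, component), closed to 1."""

    fractions: np.ndarray
    labels: list[str]
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        nt, nx, k = self.fractions.shape
        if len(self.labels) != k:
            raise ValueError("label count does not match component axis")
        if self.times.shape != (nt,) or self.positions.shape != (nx,):
            raise ValueError("times/positions do not match the fraction array")
        if self.fractions.min() < -CLOSURE_TOL or self.fractions.max() > 1 + CLOSURE_TOL:
            raise ValueError("fractions must lie in [0, 1]")
        closure_err = np.abs(self.fractions.sum(axis=2) - 1.0).max()
        if closure_err > CLOSURE_TOL:
            raise ValueError(
                f"closure violated: max |sum - 1| = {closure_err:.3e} > {CLOSURE_TOL}"
            )

    @property
    def n_components(self) -> int:
        return self.fractions.shape[2]

    def component(self, label: str) -> np.ndarray:
        return self.fractions[:, :, self.labels.index(label)]


@dataclass(frozen=True)
class KineticScheme:
    """Sequential solid-state transformation chain, e.g. MH -> MS1 -> MS2 -> AH.

    ``rates`` are first-order rate constants (1/min) for each arrow; optional
    Avrami-type induction exponents ``avrami`` (n >= 1, default 1 = plain
    first order) sharpen the onset of each step.  ``defects`` are
    (start_mm, stop_mm, factor) intervals where all rates are multiplied by
    ``factor``, emulating defect-rich regions that convert faster.
    """

    labels: tuple[str, ...]
    rates: tuple[float, ...]
    avrami: tuple[float, ...] | None = None
    defects: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.labels) - 1:
            raise ValueError("need exactly one rate per transformation arrow")
        if any(k < 0 for k in self.rates):
            raise ValueError("rate constants must be >= 0")
        if self.avrami is not None:
            if len(self.avrami) != len(self.rates):
                raise ValueError("need one Avrami exponent per step")
            if any(n < 1 for n in self.avrami):
                raise ValueError("Avrami exponents must be >= 1")
        for lo, hi, f in self.defects:
            if f <= 0:
                raise ValueError("defect rate multipliers must be > 0")
            if hi <= lo:
                raise ValueError("defect interval must have stop > start")

    @property
    def n_components(self) -> int:
        return len(self.labels)

    def exponents(self) -> np.ndarray:
        if self.avrami is None:
            return np.ones(len(self.rates))
        return np.asarray(self.avrami, dtype=float)

    def multiplier_profile(self, positions: np.ndarray) -> np.ndarray:
        """Piecewise-constant rate multiplier along the laser line."""
        mult = np.ones_like(np.asarray(positions, dtype=float))
        for lo, hi, f in self.defects:
            mult[(positions >= lo) & (positions <= hi)] = f
        return mult


@dataclass(frozen=True)
class NoiseSpec:
    """Detector-noise model: scaled-Poisson shot noise plus Gaussian read noise.

    ``gain`` converts unit-scale clean intensities to detector counts; with the
    default gain of 1e4 the shot-noise SNR at a unit-max band is
    sqrt(1e4) = 100, i.e. about 40 dB.  ``baseline_amplitude`` (fraction of
    gain) adds a broad, slowly varying background hump; off by default.
    """

    gain: float = 1.0e4
    shot: bool = True
    read_sigma: float = 10.0
    baseline_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_sigma < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def noiseless(cls, gain: float = 1.0e4) -> "NoiseSpec":
        return cls(gain=gain, shot=False, read_sigma=0.0, baseline_amplitude=0.0)

    @property
    def is_noiseless(self) -> bool:
        return not self.shot and self.read_sigma == 0.0


@dataclass
class ResidualMap:
    """What remains after non-negative subtraction of the stable forms.

    ``intensity[t, x]`` is the Euclidean norm of the residual spectrum at
    (time, position); it is zero iff the measured spectrum lies in the
    non-negative cone spanned by the stable-form spectra.
    """

    intensity: np.ndarray
    spectra: np.ndarray
    times: np.ndarray
    positions: np.ndarray


@dataclass
class MCRResult:
    """Output of constrained alternating least squares.

    ``C`` rows are closed (sum to 1); ``S`` rows are component spectra with
    known rows bit-identical to the input library; ``gain`` is the fitted
    global intensity scale so that ``D ~ gain * C @ S``.
    """

    C: np.ndarray
    S: np.ndarray
    gain: float
    labels: list[str]
    known_mask: np.ndarray
    lof_trace: np.ndarray
    avg_rel_residual: float
    n_iterations: int
    converged: bool


@dataclass
class ChemicalMap:
    """Per-component concentration maps over a line scan or area raster.

    ``values`` is (k, n_time, n_position) for line scans or (k, ny, nx) for
    area maps; ``coords`` holds the axis vectors (minutes / mm / um).  Pixels
    flagged in ``empty_mask`` had negligible total signal (bare substrate).
    """

    labels: list[str]
    values: np.ndarray
    coords: dict[str, np.ndarray]
    kind: str = "line"
    empty_mask: np.ndarray | None = None

    def component(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]
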