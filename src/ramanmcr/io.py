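"""Dataset archives, spectral-library CSVs and result exports.

Archives are NumPy ``.npz`` files of named arrays; spectra and maps also round
trip through plain CSV so every figure has a machine-readable twin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthesize import SimulatedDataset
from .types import (
    ChemicalMap,
    ConcentrationField,
    HyperLineScan,
    KineticScheme,
    MCRResult,
    NoiseSpec,
    SpectralLibrary,
    WavenumberAxis,
)

__all__ = [
    "save_dataset",
    "load_dataset",
    "write_library_csv",
    "read_library_csv",
    "read_library_roles",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "export_timepoint_csvs",
    "save_mcr_result",
    "load_mcr_result",
    "write_map_csvs",
    "read_map_csv",
]


def save_dataset(path: str | Path, ds: SimulatedDataset) -> Path:
    """Write a simulated dataset plus its ground truth to one ``.npz`` archive."""
    path = Path(path)
    defects = np.asarray(ds.scheme.defects, dtype=float).reshape(-1, 3)
    np.savez(
        path,
        intensities=ds.scan.intensities,
        times=ds.scan.times,
        positions=ds.scan.positions,
        wavenumbers=ds.scan.axis.values,
        axis_params=np.array(
            [ds.scan.axis.start, ds.scan.axis.stop, ds.scan.axis.step]
        ),
        temperature=np.array(
            np.nan if ds.scan.temperature is None else ds.scan.temperature
        ),
        truth_C=ds.truth_field.fractions,
        truth_S=ds.truth_library.spectra,
        labels=np.array(ds.truth_library.labels),
        known_mask=ds.stable_library.known_mask,
        rates=np.asarray(ds.scheme.rates),
        avrami=ds.scheme.exponents(),
        defects=defects,
        noise_params=np.array(
            [ds.noise.gain, float(ds.noise.shot), ds.noise.read_sigma,
             ds.noise.baseline_amplitude]
        ),
        seed=np.array(ds.seed),
    )
    return path


def load_dataset(path: str | Path) -> SimulatedDataset:
    with np.load(path, allow_pickle=False) as z:
        start, stop, step = z["axis_params"]
        axis = WavenumberAxis(float(start), float(stop), float(step))
        temp = float(z["temperature"])
        labels = [str(l) for l in z["labels"]]
        scan = HyperLineScan(
            intensities=z["intensities"],
            times=z["times"],
            positions=z["positions"],
            axis=axis,
            temperature=None if np.isnan(temp) else temp,
        )
        field = ConcentrationField(
            fractions=z["truth_C"],
            labels=labels,
            times=z["times"],
            positions=z["positions"],
        )
        known_mask = z["known_mask"].astype(bool)
        truth_library = SpectralLibrary(
            labels=labels,
            spectra=z["truth_S"],
            known_mask=np.ones(len(labels), dtype=bool),
            axis=axis,
        )
        stable_spectra = z["truth_S"].copy()
        stable_spectra[~known_mask] = np.nan
        stable_library = SpectralLibrary(
            labels=labels, spectra=stable_spectra, known_mask=known_mask, axis=axis
        )
        gain, shot, read_sigma, baseline = z["noise_params"]
        scheme = KineticScheme(
            labels=tuple(labels),
            rates=tuple(float(r) for r in z["rates"]),
            avrami=tuple(float(a) for a in z["avrami"]),
            defects=tuple(tuple(row) for row in z["defects"]),
        )
        return SimulatedDataset(
            scan=scan,
            truth_field=field,
            truth_library=truth_library,
            stable_library=stable_library,
            scheme=scheme,
            noise=NoiseSpec(
                gain=float(gain),
                shot=bool(shot),
                read_sigma=float(read_sigma),
                baseline_amplitude=float(baseline),
            ),
            seed=int(z["seed"]),
        )


def write_library_csv(
    path: str | Path,
    library: SpectralLibrary,
    roles: list[str] | None = None,
) -> Path:
    """Library CSV: label header, known/unknown mask row, then channel rows.

    ``roles`` optionally refines the mask row (e.g. ``"resolved"`` for a
    metastable spectrum filled in by MCR); any role other than ``"unknown"``
    is read back as a known row.  NaN cells are only valid in unknown columns.
    """
    path = Path(path)
    if roles is None:
        roles = ["known" if m else "unknown" for m in library.known_mask]
    df = pd.DataFrame(
        library.spectra.T,
        columns=library.labels,
        index=library.axis.values,
    )
    df.index.name = "wavenumber"
    with open(path, "w") as fh:
        fh.write("wavenumber," + ",".join(library.labels) + "\n")
        fh.write("mask," + ",".join(roles) + "\n")
        df.to_csv(fh, header=False)
    return path


def _read_library_frame(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    head = pd.read_csv(path, nrows=1)
    labels = list(head.columns[1:])
    mask_row = pd.read_csv(path, skiprows=1, nrows=1, header=None)
    roles = [str(v).strip() for v in mask_row.iloc[0, 1:]]
    data = pd.read_csv(path, skiprows=2, header=None)
    data.columns = ["wavenumber"] + labels
    return data, roles


def read_library_csv(path: str | Path) -> SpectralLibrary:
    data, roles = _read_library_frame(path)
    wn = data["wavenumber"].to_numpy()
    step = float(np.median(np.diff(wn)))
    axis = WavenumberAxis(float(wn[0]), float(wn[-1]), step)
    labels = [c for c in data.columns if c != "wavenumber"]
    spectra = data[labels].to_numpy().T
    known_mask = np.array([r != "unknown" for r in roles])
    if np.isnan(spectra[known_mask]).any():
        raise ValueError("NaN cells are only permitted in unknown columns")
    return SpectralLibrary(
        labels=labels, spectra=spectra, known_mask=known_mask, axis=axis
    )


def read_library_roles(path: str | Path) -> dict[str, str]:
    data, roles = _read_library_frame(path)
    labels = [c for c in data.columns if c != "wavenumber"]
    return dict(zip(labels, roles))


def write_spectrum_csv(
    path: str | Path, axis: WavenumberAxis, intensity: np.ndarray
) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavenumber": axis.values, "intensity": np.asarray(intensity)}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df["wavenumber"].to_numpy(), df["intensity"].to_numpy()


def export_timepoint_csvs(directory: str | Path, scan: HyperLineScan) -> list[Path]:
    """One CSV per time point: rows = lateral positions, columns = channels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, t in enumerate(scan.times):
        df = pd.DataFrame(
            scan.intensities[i],
            index=scan.positions,
            columns=scan.axis.values,
        )
        df.index.name = "position_mm"
        p = directory / f"t{i:03d}_{t:07.2f}min.csv"
        df.to_csv(p)
        written.append(p)
    return written


def save_mcr_result(
    path: str | Path, result: MCRResult, provenance: dict | None = None
) -> Path:
    """Result archive (C, S, LoF trace, metadata) with a JSON provenance twin."""
    path = Path(path)
    np.savez(
        path,
        C=result.C,
        S=result.S,
        gain=np.array(result.gain),
        labels=np.array(result.labels),
        known_mask=result.known_mask,
        lof_trace=result.lof_trace,
        avg_rel_residual=np.array(result.avg_rel_residual),
        n_iterations=np.array(result.n_iterations),
        converged=np.array(result.converged),
    )
    if provenance is not None:
        sidecar = path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return path


def load_mcr_result(path: str | Path) -> MCRResult:
    with np.load(path, allow_pickle=False) as z:
        return MCRResult(
            C=z["C"],
            S=z["S"],
            gain=float(z["gain"]),
            labels=[str(l) for l in z["labels"]],
            known_mask=z["known_mask"].astype(bool),
            lof_trace=z["lof_trace"],
            avg_rel_residual=float(z["avg_rel_residual"]),
            n_iterations=int(z["n_iterations"]),
            converged=bool(z["converged"]),
        )


def write_map_csvs(directory: str | Path, cmap: ChemicalMap) -> list[Path]:
    """One CSV per component map (exact float round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    row_key, col_key = list(cmap.coords)
    written = []
    for i, label in enumerate(cmap.labels):
        df = pd.DataFrame(
            cmap.values[i],
            index=cmap.coords[row_key],
            columns=cmap.coords[col_key],
        )
        df.index.name = row_key
        safe = label.replace(" ", "_").replace("/", "-")
        p = directory / f"map_{safe}.csv"
        df.to_csv(p, float_format="%.17g")
        written.append(p)
    return written


def read_map_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (values, row_coords, col_coords) of one component map CSV."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return (
        df.to_numpy(),
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
    )
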