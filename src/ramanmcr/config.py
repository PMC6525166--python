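"""Validated scenario and run configurations (JSON-facing).

A :class:`ScenarioConfig` fully describes a synthetic dehydration experiment —
axis, band tables, kinetic scheme, geometry, noise, seed — and
:func:`realize_scenario` turns it into a ground-truthed dataset.  Every
pipeline run writes a resolved copy of its configuration plus a content hash,
so results are reproducible bit-for-bit from the archived JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .synthesize import (
    SimulatedDataset,
    make_component_spectra,
    simulate_kinetics,
    synthesize_linescan,
)
from .types import (
    Band,
    BandTable,
    KineticScheme,
    NoiseSpec,
    SpectralLibrary,
    WavenumberAxis,
)

__all__ = [
    "AxisConfig",
    "BandConfig",
    "ComponentConfig",
    "DefectConfig",
    "NoiseConfig",
    "ScenarioConfig",
    "RunConfig",
    "realize_scenario",
    "config_hash",
]


class AxisConfig(BaseModel):
    start: float = 350.0
    stop: float = 2300.0
    step: float = 2.0


class BandConfig(BaseModel):
    center: float
    fwhm: float
    amplitude: float = 1.0
    eta: float = 0.0


class ComponentConfig(BaseModel):
    label: str
    stable: bool = False
    bands: list[BandConfig] = Field(default_factory=list)


class DefectConfig(BaseModel):
    start_mm: float
    stop_mm: float
    factor: float = 1.5


class NoiseConfig(BaseModel):
    gain: float = 1.0e4
    shot: bool = True
    read_sigma: float = 10.0
    baseline_amplitude: float = 0.0

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(
            gain=self.gain,
            shot=self.shot,
            read_sigma=self.read_sigma,
            baseline_amplitude=self.baseline_amplitude,
        )


class ScenarioConfig(BaseModel):
    """Complete description of a synthetic line-scan dehydration experiment."""

    name: str = "custom"
    axis: AxisConfig = Field(default_factory=AxisConfig)
    components: list[ComponentConfig]
    rates_per_min: list[float]
    avrami: list[float] | None = None
    defects: list[DefectConfig] = Field(default_factory=list)
    t_max_min: float = 90.0
    t_step_min: float = 1.5
    temperature_c: float | None = None
    n_positions: int = 220
    line_length_mm: float = 1.8
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 42

    @field_validator("components")
    @classmethod
    def _at_least_two(cls, v: list[ComponentConfig]) -> list[ComponentConfig]:
        if len(v) < 2:
            raise ValueError("a scenario needs at least two components")
        return v

    @model_validator(mode="after")
    def _rates_match(self) -> "ScenarioConfig":
        if len(self.rates_per_min) != len(self.components) - 1:
            raise ValueError("need exactly one rate per transformation step")
        return self

    def wavenumber_axis(self) -> WavenumberAxis:
        return WavenumberAxis(self.axis.start, self.axis.stop, self.axis.step)

    def kinetic_scheme(self) -> KineticScheme:
        return KineticScheme(
            labels=tuple(c.label for c in self.components),
            rates=tuple(self.rates_per_min),
            avrami=tuple(self.avrami) if self.avrami is not None else None,
            defects=tuple(
                (d.start_mm, d.stop_mm, d.factor) for d in self.defects
            ),
        )

    def band_tables(self) -> dict[str, BandTable]:
        return {
            c.label: BandTable(
                tuple(Band(b.center, b.fwhm, b.amplitude, b.eta) for b in c.bands)
            )
            for c in self.components
        }


class RunConfig(BaseModel):
    """Analysis-stage settings for resolve/map commands."""

    k_max: int = 6
    tol: float = 1.0e-6
    max_iter: int = 200
    nonneg_C: bool = True
    nonneg_S: bool = True
    closure: bool = True
    unimodality: str = "unknown"
    snr_time_index: int = 0
    map_closure: bool = True


def realize_scenario(
    config: ScenarioConfig,
    seed: int | None = None,
    noiseless: bool = False,
) -> SimulatedDataset:
    """Generate the scenario's dataset together with its ground truth.

    ``seed`` overrides the configured seed; ``noiseless`` disables shot and
    read noise but keeps the detector gain.
    """
    axis = config.wavenumber_axis()
    known_mask = [c.stable for c in config.components]
    truth_library = make_component_spectra(config.band_tables(), axis)
    scheme = config.kinetic_scheme()
    times = np.arange(0.0, config.t_max_min + 0.5 * config.t_step_min, config.t_step_min)
    positions = np.linspace(0.0, config.line_length_mm, config.n_positions)
    field = simulate_kinetics(scheme, times, positions)
    noise = (
        NoiseSpec.noiseless(gain=config.noise.gain)
        if noiseless
        else config.noise.to_spec()
    )
    use_seed = config.seed if seed is None else seed
    scan = synthesize_linescan(
        field, truth_library, noise, seed=use_seed, temperature=config.temperature_c
    )
    stable_spectra = truth_library.spectra.copy()
    stable_spectra[~np.asarray(known_mask)] = np.nan
    stable_library = SpectralLibrary(
        labels=list(truth_library.labels),
        spectra=stable_spectra,
        known_mask=np.asarray(known_mask, dtype=bool),
        axis=axis,
    )
    return SimulatedDataset(
        scan=scan,
        truth_field=field,
        truth_library=truth_library,
        stable_library=stable_library,
        scheme=scheme,
        noise=noise,
        seed=use_seed,
    )


def config_hash(model: BaseModel) -> str:
    """Stable SHA-256 over the canonical JSON form of a config."""
    payload = json.dumps(model.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_scenario(path: str | Path) -> ScenarioConfig:
    return ScenarioConfig.model_validate_json(Path(path).read_text())
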