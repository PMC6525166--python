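"""Shipped dehydration scenarios: theophylline-like (TP4) and nitrofurantoin-like (NF4).

Both presets model a four-form sequential dehydration
``monohydrate -> metastable 1 -> metastable 2 -> anhydrate`` on a 1.8 mm
laser line sampled at 220 lateral positions, 90 min at 1.5 min intervals.
Band tables are synthetic emulations: each form shares a common skeleton of
ring/backbone bands and carries the distinguishing marker bands at their
characteristic positions —

* TP anhydrate form II: carbonyl doublet at 1690 and 1730 cm^-1;
* TP metastable 1 vs 2: opposite intensity pattern near 1150 / 1230 cm^-1
  and a weak 1750 cm^-1 band only in metastable 2;
* NF monohydrates: C=N stretch at 1615 (form II) vs 1605 cm^-1 (form I);
* NF anhydrates alpha vs beta: distinct bands inside 950-1000, 1200-1300,
  1310-1400 and 1550-1650 cm^-1.

The stable endpoints (hydrate, final anhydrate) are flagged as known library
entries; the two intermediates are the unknowns to resolve.
"""

from __future__ import annotations

from .config import (
    BandConfig,
    ComponentConfig,
    DefectConfig,
    NoiseConfig,
    ScenarioConfig,
)

__all__ = ["tp4", "nf4", "get_scenario", "SCENARIOS"]


def _bands(rows: list[tuple[float, float, float]]) -> list[BandConfig]:
    return [BandConfig(center=c, fwhm=w, amplitude=a) for c, w, a in rows]


def tp4() -> ScenarioConfig:
    """Theophylline-like four-form isothermal dehydration at 50 degC.

    Defect-rich intervals (faster conversion) sit at 0.02-0.38, 0.48-0.72 and
    0.75-1.13 mm along the line.
    """
    components = [
        ComponentConfig(
            label="TP MH",
            stable=True,
            bands=_bands(
                [
                    (555, 14, 0.35), (668, 12, 1.00), (930, 14, 0.18),
                    (1188, 13, 0.30), (1243, 13, 0.22), (1318, 15, 0.28),
                    (1424, 16, 0.22), (1608, 13, 0.45), (1663, 15, 0.55),
                ]
            ),
        ),
        ComponentConfig(
            label="TP MS1",
            bands=_bands(
                [
                    (560, 14, 0.30), (673, 12, 0.95), (935, 14, 0.20),
                    (1150, 13, 0.50), (1230, 13, 0.10), (1323, 15, 0.24),
                    (1430, 16, 0.20), (1613, 13, 0.40), (1668, 15, 0.48),
                ]
            ),
        ),
        ComponentConfig(
            label="TP MS2",
            bands=_bands(
                [
                    (565, 14, 0.32), (678, 12, 0.90), (940, 14, 0.16),
                    (1150, 13, 0.10), (1230, 13, 0.50), (1328, 15, 0.28),
                    (1436, 16, 0.24), (1618, 13, 0.44), (1673, 15, 0.45),
                    (1750, 14, 0.20),
                ]
            ),
        ),
        ComponentConfig(
            label="TP AH II",
            stable=True,
            bands=_bands(
                [
                    (570, 14, 0.35), (683, 12, 1.00), (945, 14, 0.18),
                    (1170, 13, 0.28), (1248, 13, 0.22), (1333, 15, 0.26),
                    (1442, 16, 0.22), (1611, 13, 0.40), (1690, 13, 0.70),
                    (1730, 13, 0.55),
                ]
            ),
        ),
    ]
    return ScenarioConfig(
        name="TP4",
        components=components,
        rates_per_min=[0.10, 0.05, 0.03],
        defects=[
            DefectConfig(start_mm=0.02, stop_mm=0.38, factor=1.5),
            DefectConfig(start_mm=0.48, stop_mm=0.72, factor=1.5),
            DefectConfig(start_mm=0.75, stop_mm=1.13, factor=1.5),
        ],
        temperature_c=50.0,
        noise=NoiseConfig(),
        seed=42,
    )


def nf4() -> ScenarioConfig:
    """Nitrofurantoin-like four-form isothermal dehydration at 120 degC.

    The pathway is hydrate-to-hydrate first (MH II -> MH I), then through the
    metastable anhydrate alpha to the stable beta form; conversion is faster
    in the particle centre.
    """
    components = [
        ComponentConfig(
            label="NF MH II",
            stable=True,
            bands=_bands(
                [
                    (600, 14, 0.20), (968, 13, 0.28), (1010, 12, 0.30),
                    (1255, 14, 0.38), (1355, 14, 0.80), (1515, 14, 0.30),
                    (1575, 14, 0.40), (1615, 12, 1.00),
                ]
            ),
        ),
        ComponentConfig(
            label="NF MH I",
            bands=_bands(
                [
                    (602, 14, 0.20), (972, 13, 0.28), (1010, 12, 0.30),
                    (1260, 14, 0.35), (1352, 14, 0.75), (1518, 14, 0.30),
                    (1578, 14, 0.38), (1605, 12, 1.00),
                ]
            ),
        ),
        ComponentConfig(
            label="NF AH α",
            bands=_bands(
                [
                    (604, 14, 0.20), (980, 13, 0.50), (1010, 12, 0.30),
                    (1225, 14, 0.50), (1330, 14, 0.60), (1520, 14, 0.28),
                    (1595, 13, 0.70), (1628, 13, 0.40),
                ]
            ),
        ),
        ComponentConfig(
            label="NF AH β",
            stable=True,
            bands=_bands(
                [
                    (606, 14, 0.20), (955, 13, 0.30), (1010, 12, 0.30),
                    (1280, 14, 0.50), (1372, 14, 0.60), (1520, 14, 0.28),
                    (1560, 13, 0.30), (1620, 12, 0.85),
                ]
            ),
        ),
    ]
    return ScenarioConfig(
        name="NF4",
        components=components,
        rates_per_min=[0.20, 0.08, 0.05],
        defects=[DefectConfig(start_mm=0.70, stop_mm=1.10, factor=1.6)],
        temperature_c=120.0,
        noise=NoiseConfig(),
        seed=42,
    )


SCENARIOS = {"TP4": tp4, "NF4": nf4}


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name.upper()]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
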