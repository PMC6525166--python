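"""Hydrate stoichiometry: theoretical water loss on dehydration.

A monohydrate losing its lattice water sheds a mass fraction
``n * M(H2O) / (M(anhydrous) + n * M(H2O))``, which is the plateau step a
thermogravimetric (TGA) curve shows.  Used as an analytic cross-check that a
measured weight loss corresponds to full dehydration.
"""

from __future__ import annotations

import re

__all__ = [
    "molar_mass",
    "water_mass_fraction",
    "THEOPHYLLINE",
    "NITROFURANTOIN",
]

# IUPAC 2021 standard atomic weights (abridged), g/mol
_ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
    "P": 30.974,
}

THEOPHYLLINE = "C7H8N4O2"
NITROFURANTOIN = "C8H6N4O5"

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a simple molecular formula like ``C7H8N4O2``."""
    consumed = 0
    total = 0.0
    for m in _TOKEN.finditer(formula):
        if m.start() != consumed:
            break
        consumed = m.end()
        symbol, count = m.group(1), m.group(2)
        if symbol not in _ATOMIC_MASS:
            raise ValueError(f"unsupported element {symbol!r} in {formula!r}")
        total += _ATOMIC_MASS[symbol] * (int(count) if count else 1)
    if consumed != len(formula) or total == 0.0:
        raise ValueError(f"cannot parse molecular formula {formula!r}")
    return total


def water_mass_fraction(anhydrous_formula: str, n_water: int = 1) -> float:
    """Percent mass lost when an n-hydrate dehydrates completely.

    >>> round(water_mass_fraction(THEOPHYLLINE))
    9
    >>> round(water_mass_fraction(NITROFURANTOIN))
    7
    """
    if n_water < 1:
        raise ValueError("n_water must be >= 1")
    m_water = n_water * molar_mass("H2O")
    return 100.0 * m_water / (molar_mass(anhydrous_formula) + m_water)
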