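"""Per-element constants used across the package.

Covalent radii follow Cordero et al. (2008), van der Waals radii follow
Bondi (1964) with the common extensions for metals, and masses are standard
atomic weights.  Only the elements that actually occur in protected-cluster
models are tabulated; unknown elements raise ``KeyError`` at the call site
so that typos in input files surface early.
"""

from __future__ import annotations

# Covalent radii, Angstrom.
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Na": 1.66,
    "Au": 1.36,
}

# van der Waals radii, Angstrom (Bondi; Au from the consensus metallic value).
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Na": 2.27,
    "Au": 1.66,
}

# Standard atomic weights, unified atomic mass units.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Na": 22.990,
    "Au": 196.967,
}

#: Elements this package knows how to handle.
KNOWN_ELEMENTS = frozenset(ATOMIC_MASS)


def normalize_element(symbol: str) -> str:
    """Canonicalize an element symbol (``"AU"`` -> ``"Au"``).

    Raises ``ValueError`` for symbols not in the tables above.
    """
    sym = symbol.strip().capitalize()
    if sym not in KNOWN_ELEMENTS:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return sym


def covalent_cutoff(elem_a: str, elem_b: str, scale: float = 1.2) -> float:
    """Bond-detection cutoff for an element pair, Angstrom.

    Sum of covalent radii times ``scale``; Au-S contacts use a fixed 2.6 A
    cutoff appropriate for thiolate-gold bonds.
    """
    pair = {elem_a, elem_b}
    if pair == {"Au", "S"}:
        return 2.6
    return (COVALENT_RADIUS[elem_a] + COVALENT_RADIUS[elem_b]) * scale
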