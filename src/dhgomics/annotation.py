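"""Elemental formulas, monoisotopic masses, adduct m/z, and ppm matching.

A minimal ESI-MS identification layer: parse Hill-notation formulas, sum
monoisotopic atomic masses, derive [M+H]+ / [M-H]- ion m/z (the charge
carrier is a proton, 1.00727646 Da), and match measured feature m/z values
against a compound table within a ppm tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

PROTON_MASS = 1.00727646  # Da

# CODATA/IUPAC monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.968852682,
    "F": 18.9984031627,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AdductSpec:
    name: str
    mass_delta: float
    charge: int


ADDUCT_SPECS = {
    "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula (e.g. ``C5H4N4O3``) into element counts."""
    if not formula or not formula.strip():
        raise AnnotationError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise AnnotationError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise AnnotationError(f"unknown element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise AnnotationError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass in Da of a formula string or element-count mapping."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if not counts:
        raise AnnotationError("empty formula")
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())


def adduct_mz(mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass."""
    if mass <= 0:
        raise AnnotationError("mass must be positive")
    if isinstance(adduct, str):
        if adduct not in ADDUCT_SPECS:
            raise AnnotationError(f"unsupported adduct {adduct!r}")
        adduct = ADDUCT_SPECS[adduct]
    return (mass + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in ppm, relative to the theoretical m/z."""
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MzMatch:
    feature_id: str
    compound_id: str
    compound_name: str
    theoretical_mz: float
    delta_ppm: float


def match_features(
    measured: list[tuple[str, float, str]],
    compounds,
    tol_ppm: float = 10.0,
) -> list[MzMatch]:
    """Match (feature id, m/z, adduct) triples against compound records.

    Every compound whose theoretical adduct m/z lies within ``tol_ppm`` of
    the measured value (and whose adduct agrees) is reported; matches for a
    feature are sorted by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise AnnotationError("tol_ppm must be positive")
    theo = [
        (c, adduct_mz(monoisotopic_mass(c.formula), c.adduct)) for c in compounds
    ]
    out: list[MzMatch] = []
    for fid, mz, adduct in measured:
        hits = []
        for c, tmz in theo:
            if c.adduct != adduct:
                continue
            dppm = ppm_error(mz, tmz)
            if abs(dppm) <= tol_ppm:
                hits.append(MzMatch(fid, c.id, c.name, tmz, dppm))
        hits.sort(key=lambda h: (abs(h.delta_ppm), h.compound_id))
        out.extend(hits)
    return out
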