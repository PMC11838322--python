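"""Elemental mass and isotope-abundance helpers.

Monoisotopic masses and natural isotope abundances come from the NIST
tables shipped with :mod:`pyteomics.mass`; nothing in this module is a
measured or fitted quantity.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

from .errors import DomainError

#: Mass of a proton (Da), used for [M-H]-/[M+H]+ adduct arithmetic.
PROTON = 1.00727646688

#: m/z shift applied to the neutral monoisotopic mass for each adduct.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M-H]-": -PROTON,
    "[M+H]+": +PROTON,
}


def monoisotopic_mass(composition: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition map."""
    if not composition:
        raise DomainError("empty composition")
    total = 0.0
    for element, count in composition.items():
        if element not in _pmass.nist_mass:
            raise DomainError(f"unknown element {element!r}")
        if count < 0:
            raise DomainError(f"negative count for element {element!r}")
        total += _pmass.nist_mass[element][0][0] * count
    return total


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string ('C8H5F13O3S') to an element map."""
    if not formula or not formula.strip():
        return {}
    try:
        comp = _pmass.Composition(formula=formula.strip())
    except Exception as exc:  # pyteomics raises PyteomicsError subclasses
        raise DomainError(f"unparsable formula {formula!r}: {exc}") from exc
    return dict(comp)


def hill_formula(composition: dict[str, int]) -> str:
    """Format an element map in Hill order (C, H, then alphabetical)."""
    parts = []
    rest = {el: n for el, n in composition.items() if n > 0}
    for el in ("C", "H"):
        if el in rest:
            n = rest.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(rest):
        n = rest[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def ion_mz(neutral_mass: float, adduct: str = "[M-H]-") -> float:
    """m/z of a singly charged adduct ion for a neutral monoisotopic mass."""
    if adduct not in ADDUCT_SHIFTS:
        raise DomainError(f"unsupported adduct {adduct!r}")
    return neutral_mass + ADDUCT_SHIFTS[adduct]


def neutral_mass_from_ion(mz: float, adduct: str = "[M-H]-") -> float:
    """Neutral monoisotopic mass implied by a measured adduct m/z."""
    if mz <= 0:
        raise DomainError("m/z must be positive")
    if adduct not in ADDUCT_SHIFTS:
        raise DomainError(f"unsupported adduct {adduct!r}")
    return mz - ADDUCT_SHIFTS[adduct]


def isotope_poly(element: str) -> tuple[float, float, float]:
    """Per-atom isotope abundance polynomial truncated at a +2 Da shift.

    Returns ``(p0, p1, p2)``: the natural abundance of the monoisotopic
    form and of the isotopologues one and two nominal mass units heavier.
    Heavier isotopes (e.g. 36S) are dropped by the truncation.
    """
    if element not in _pmass.nist_mass:
        raise DomainError(f"unknown element {element!r}")
    entries = {
        num: (m, ab)
        for num, (m, ab) in _pmass.nist_mass[element].items()
        if num != 0 and ab > 0.0
    }
    if not entries:
        # element with no tabulated natural abundances (rare in practice)
        return (1.0, 0.0, 0.0)
    base = min(entries)
    poly = [0.0, 0.0, 0.0]
    for num, (_m, ab) in entries.items():
        shift = num - base
        if 0 <= shift <= 2:
            poly[shift] += ab
    return (poly[0], poly[1], poly[2])
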