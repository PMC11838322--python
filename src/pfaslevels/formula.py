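"""Mass-defect screens, isotope envelopes and molecular-formula enumeration.

Supports the "unequivocal molecular formula" test: a feature earns that
status only when exactly one bounded-composition formula survives the
exact-mass window and every available filter — never merely because one
formula ranks first.

The default element set is the PFAS-relevant {C, H, N, O, S, F}. Chemical
filters applied to every candidate formula:

* rings-plus-double-bonds equivalent DBE = C + 1 + (N - H - F)/2 must be
  a non-negative integer for an even-electron neutral (halogens counted
  as monovalent like hydrogen, the nitrogen rule in DBE form);
* valence cap H + F <= 2C + 2 + N.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import chem
from .errors import ConfigurationError, DomainError


class ElementBounds(BaseModel):
    """Inclusive per-element count ranges defining the search lattice."""

    model_config = ConfigDict(frozen=True)

    bounds: dict[str, tuple[int, int]]

    @model_validator(mode="after")
    def _check(self):
        if not self.bounds:
            raise ValueError("at least one element range is required")
        for el, (lo, hi) in self.bounds.items():
            if el not in chem._pmass.nist_mass:
                raise ValueError(f"unknown element {el!r}")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {el}: ({lo}, {hi})")
        return self

    @classmethod
    def pfas_default(cls) -> "ElementBounds":
        """Generous bounds for PFAS-sized molecules (< ~1200 Da)."""
        return cls(
            bounds={
                "C": (0, 40),
                "H": (0, 60),
                "N": (0, 3),
                "O": (0, 12),
                "S": (0, 3),
                "F": (0, 60),
            }
        )

    def lattice_size(self) -> int:
        n = 1
        for lo, hi in self.bounds.values():
            n *= hi - lo + 1
        return n


class FormulaCandidate(BaseModel):
    model_config = ConfigDict(frozen=True)

    composition: dict[str, int]
    neutral_mass: float
    ppm_error: float
    dbe: float

    @property
    def formula(self) -> str:
        return chem.hill_formula(self.composition)


def mass_defect(mz: float) -> float:
    """Difference between exact and nearest-integer mass, in (-0.5, 0.5].

    Strongly negative values are characteristic of highly fluorinated
    molecules and serve as Level 5 diagnostic evidence.
    """
    if mz <= 0:
        raise DomainError("m/z must be positive")
    return mz - math.ceil(mz - 0.5)


def dbe_value(composition: dict[str, int]) -> float:
    """Rings-plus-double-bonds equivalent with halogens counted as H."""
    c = composition.get("C", 0)
    h = composition.get("H", 0)
    n = composition.get("N", 0)
    halogens = sum(composition.get(x, 0) for x in ("F", "Cl", "Br", "I"))
    return c + 1 + (n - h - halogens) / 2.0


def _chemical_filters_ok(composition: dict[str, int]) -> bool:
    c = composition.get("C", 0)
    h = composition.get("H", 0)
    n = composition.get("N", 0)
    f = composition.get("F", 0)
    if (n - h - f) % 2 != 0:  # non-integer DBE: odd-electron neutral
        return False
    if dbe_value(composition) < 0:
        return False
    if h + f > 2 * c + 2 + n:
        return False
    return True


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float,
    bounds: Optional[ElementBounds] = None,
) -> list[FormulaCandidate]:
    """All chemically plausible formulas within a ppm window of a mass.

    Performs an exhaustive depth-first search of the bounded composition
    lattice with mass-window pruning; the result is identical to brute
    force enumeration over the full lattice. Candidates are sorted by
    absolute ppm error (ties by Hill formula).
    """
    if neutral_mass <= 0:
        raise DomainError("neutral_mass must be positive")
    if tol_ppm <= 0:
        raise DomainError("tol_ppm must be positive")
    if bounds is None:
        bounds = ElementBounds.pfas_default()
    lo = neutral_mass * (1 - tol_ppm * 1e-6)
    hi = neutral_mass * (1 + tol_ppm * 1e-6)

    elements = sorted(
        bounds.bounds, key=lambda el: chem.monoisotopic_mass({el: 1}), reverse=True
    )
    masses = [chem.monoisotopic_mass({el: 1}) for el in elements]
    ranges = [bounds.bounds[el] for el in elements]
    # suffix_min/max[i]: attainable mass from elements i..end
    k = len(elements)
    suffix_min = [0.0] * (k + 1)
    suffix_max = [0.0] * (k + 1)
    for i in range(k - 1, -1, -1):
        lo_i, hi_i = ranges[i]
        suffix_min[i] = suffix_min[i + 1] + masses[i] * lo_i
        suffix_max[i] = suffix_max[i + 1] + masses[i] * hi_i

    out: list[FormulaCandidate] = []
    counts = [0] * k

    def descend(i: int, acc: float) -> None:
        if i == k:
            if lo <= acc <= hi:
                comp = {el: c for el, c in zip(elements, counts) if c > 0}
                if comp and _chemical_filters_ok(comp):
                    out.append(
                        FormulaCandidate(
                            composition=comp,
                            neutral_mass=acc,
                            ppm_error=(acc - neutral_mass) / neutral_mass * 1e6,
                            dbe=dbe_value(comp),
                        )
                    )
            return
        m = masses[i]
        lo_i, hi_i = ranges[i]
        # count window keeping the total mass inside [lo, hi]
        c_min = max(lo_i, math.ceil((lo - acc - suffix_max[i + 1]) / m - 1e-12))
        c_max = min(hi_i, math.floor((hi - acc - suffix_min[i + 1]) / m + 1e-12))
        for c in range(c_min, c_max + 1):
            counts[i] = c
            descend(i + 1, acc + m * c)
        counts[i] = 0

    descend(0, 0.0)
    out.sort(key=lambda fc: (abs(fc.ppm_error), fc.formula))
    return out


def is_unequivocal(
    candidates: Iterable[FormulaCandidate],
    envelope_filter: Optional[Callable[[FormulaCandidate], bool]] = None,
) -> bool:
    """True iff exactly one formula candidate survives all filters."""
    survivors = [
        c for c in candidates if envelope_filter is None or envelope_filter(c)
    ]
    return len(survivors) == 1


def surviving_formulas(
    candidates: Iterable[FormulaCandidate],
    envelope_filter: Optional[Callable[[FormulaCandidate], bool]] = None,
) -> list[FormulaCandidate]:
    return [c for c in candidates if envelope_filter is None or envelope_filter(c)]


def theoretical_envelope(composition: dict[str, int]) -> tuple[float, float, float]:
    """Base-peak-normalized M, M+1, M+2 relative abundances of a formula.

    Computed by truncated polynomial expansion of per-element natural
    isotope abundances (nominal shifts beyond +2 Da are dropped).
    """
    if not composition:
        raise DomainError("composition must not be empty")
    poly = [1.0, 0.0, 0.0]
    for el, count in composition.items():
        if count < 0:
            raise DomainError(f"negative count for {el!r}")
        if count == 0:
            continue
        ep = chem.isotope_poly(el)
        for _ in range(count):
            nxt = [0.0, 0.0, 0.0]
            for a in range(3):
                for b in range(3 - a):
                    nxt[a + b] += poly[a] * ep[b]
            poly = nxt
    base = max(poly)
    return (poly[0] / base, poly[1] / base, poly[2] / base)


#: Default CCS-vs-m/z boundary line (slope, intercept) below which a
#: feature lies in "fluorinated space": dense fluorination gives PFAS
#: smaller collision cross sections than biomolecules of equal mass.
#: Midline between the synthetic PFAS and biomolecule populations of the
#: fixture generator; override per experiment.
FLUORINATED_BOUNDARY: tuple[float, float] = (0.285, 75.0)


def in_fluorinated_space(
    mz: float, ccs: float, boundary: tuple[float, float] = FLUORINATED_BOUNDARY
) -> bool:
    """True when the feature's CCS falls below the fluorinated-space line."""
    if mz <= 0 or ccs <= 0:
        raise DomainError("m/z and CCS must be positive")
    slope, intercept = boundary
    return ccs < slope * mz + intercept
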