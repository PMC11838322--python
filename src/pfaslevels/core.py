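"""Shared domain model for IMS-HRMS confidence-level assignment.

This module defines the data types exchanged between all other modules:
measured features, candidate structures, tiered reference records, the
tolerance profile (one acceptance tolerance per measured dimension and
evidence tier), and per-dimension match results.

Three evidence tiers are distinguished throughout the package, in
decreasing order of confidence:

``reference_standard``
    values measured in-house from an authenticated standard on the same
    analytical platform as the unknown;
``library``
    values from a reputable external spectral or CCS repository;
``predicted``
    values computed, e.g. from homologous-series trendlines.

Recommended default tolerances correspond to a drift-tube IMS-QTOF
platform (Agilent 6560 class): ±10 ppm m/z, isotope envelope within 0.10
absolute relative abundance (features below 5000 peak area exempt), CCS
±0.2 / 2.0 / 5.0 % by tier, RT ±0.5 min (predicted RT judged only by
monotonicity along a homologous series), and MS/MS cosine ≥ 0.9 / 0.8 /
0.7 for same-platform standards, similar-instrument libraries and other
instrumentation respectively.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import chem
from .errors import ConfigurationError, DomainError


class Tier(str, Enum):
    REFERENCE_STANDARD = "reference_standard"
    LIBRARY = "library"
    PREDICTED = "predicted"


#: Preference order when a candidate offers several tiers for one dimension.
TIER_PRIORITY: tuple[Tier, ...] = (
    Tier.REFERENCE_STANDARD,
    Tier.LIBRARY,
    Tier.PREDICTED,
)


class Dimension(str, Enum):
    MZ = "mz"
    ISOTOPE = "isotope"
    CCS = "ccs"
    RT = "rt"
    MS2 = "ms2"


#: The four dimensions a structure identification must satisfy (MS/MS is
#: conditionally required; see the level engine).
CORE_DIMENSIONS: tuple[Dimension, ...] = (
    Dimension.MZ,
    Dimension.ISOTOPE,
    Dimension.CCS,
    Dimension.RT,
)


class Status(str, Enum):
    MATCH = "match"
    SUPPORT = "support"
    NO_MATCH = "no_match"
    NOT_AVAILABLE = "not_available"


class StructureResolution(str, Enum):
    EXACT_STRUCTURE = "exact_structure"
    ISOMER_CLASS = "isomer_class"


class MobilitySpectrum(BaseModel):
    """A centroided fragmentation spectrum, optionally mobility-aligned."""

    model_config = ConfigDict(frozen=True)

    peaks: tuple[tuple[float, float], ...]
    mobility_aligned: bool = True

    @field_validator("peaks")
    @classmethod
    def _check_peaks(cls, peaks):
        if len(peaks) == 0:
            raise ValueError("spectrum must contain at least one peak")
        last = -math.inf
        for mz, intensity in peaks:
            if mz <= last:
                raise ValueError("fragment m/z must be strictly ascending")
            if intensity < 0:
                raise ValueError("intensities must be >= 0")
            last = mz
        return peaks

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)


class Feature(BaseModel):
    """One detected analyte signal from an LC/GC-IMS-HRMS feature table.

    Exactly one of ``rt_measured`` (LC) or ``ri_measured`` (GC) may be
    set; the two are alternates for the same generic retention dimension
    and are never mixed within an experiment.
    """

    model_config = ConfigDict(frozen=True)

    feature_id: str
    mz_measured: float = Field(gt=0)
    adduct: str = "[M-H]-"
    rt_measured: Optional[float] = None
    ri_measured: Optional[float] = None
    ccs_measured: Optional[float] = None
    isotope_envelope: Optional[tuple[float, ...]] = None
    peak_area: float = Field(default=0.0, ge=0)
    ms2: Optional[MobilitySpectrum] = None

    @field_validator("ccs_measured")
    @classmethod
    def _ccs_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("ccs_measured must be > 0")
        return v

    @field_validator("isotope_envelope")
    @classmethod
    def _envelope_normalized(cls, v):
        if v is None:
            return v
        if len(v) == 0:
            raise ValueError("isotope_envelope must not be empty if given")
        if any(a < 0 or a > 1 + 1e-9 for a in v):
            raise ValueError("isotope abundances must lie in [0, 1]")
        if abs(max(v) - 1.0) > 1e-9:
            raise ValueError("isotope envelope must be base-peak normalized")
        return v

    @model_validator(mode="after")
    def _retention_exclusive(self):
        if self.rt_measured is not None and self.ri_measured is not None:
            raise ValueError("use rt_measured (LC) or ri_measured (GC), not both")
        return self

    @property
    def retention(self) -> Optional[float]:
        """The generic retention value: RT for LC, RI for GC."""
        return self.rt_measured if self.rt_measured is not None else self.ri_measured


class CandidateStructure(BaseModel):
    model_config = ConfigDict(frozen=True)

    candidate_id: str
    name: str = ""
    formula: dict[str, int] = Field(default_factory=dict)
    structure_resolution: StructureResolution = StructureResolution.EXACT_STRUCTURE
    neutral_mass: Optional[float] = None

    @field_validator("formula")
    @classmethod
    def _counts_nonnegative(cls, v):
        if any(n < 0 for n in v.values()):
            raise ValueError("element counts must be >= 0")
        return v

    @model_validator(mode="after")
    def _mass_consistent(self):
        if self.neutral_mass is not None and self.formula:
            calc = chem.monoisotopic_mass(self.formula)
            if abs(calc - self.neutral_mass) > 1e-6:
                raise ValueError(
                    f"neutral_mass {self.neutral_mass} inconsistent with formula "
                    f"({calc:.6f} Da)"
                )
        return self

    def monoisotopic_mass(self) -> Optional[float]:
        if self.neutral_mass is not None:
            return self.neutral_mass
        if self.formula:
            return chem.monoisotopic_mass(self.formula)
        return None


class ReferenceRecord(BaseModel):
    """Comparison values for one candidate at one evidence tier."""

    model_config = ConfigDict(frozen=True)

    candidate: CandidateStructure
    tier: Tier
    exact_mz: float = Field(gt=0)
    adduct: str = "[M-H]-"
    rt_ref: Optional[float] = None
    ccs_ref: Optional[float] = None
    spectrum_ref: Optional[MobilitySpectrum] = None
    provenance: str = ""
    same_platform: bool = False
    similar_instrument: bool = False
    in_house: bool = False
    branched_isomer: bool = False

    @field_validator("ccs_ref")
    @classmethod
    def _ccs_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("ccs_ref must be > 0")
        return v

    @model_validator(mode="after")
    def _standard_needs_platform(self):
        if self.tier is Tier.REFERENCE_STANDARD and not self.same_platform:
            raise ValueError(
                "reference_standard tier requires same_platform provenance"
            )
        return self

    @property
    def candidate_id(self) -> str:
        return self.candidate.candidate_id


MONOTONIC = "monotonic"

_DEFAULT_CCS = {Tier.REFERENCE_STANDARD: 0.2, Tier.LIBRARY: 2.0, Tier.PREDICTED: 5.0}
_DEFAULT_RT = {Tier.REFERENCE_STANDARD: 0.5, Tier.LIBRARY: 0.5, Tier.PREDICTED: MONOTONIC}
_DEFAULT_COSINE = {
    "reference_standard": 0.9,
    "library_similar": 0.8,
    "library_other": 0.7,
}


class ToleranceProfile(BaseModel):
    """Dimension x tier acceptance tolerances plus the support band.

    Defaults are the recommended drift-tube IMS-QTOF values (see module
    docstring). ``support_multiplier`` widens each numeric tolerance into
    the "support" band used at Level 3 and below: an error inside
    ``multiplier x tolerance`` but outside the tolerance itself counts as
    supporting (not matching) evidence.
    """

    model_config = ConfigDict(frozen=True)

    mz_ppm: float = 10.0
    isotope_reldev_max: float = 0.10
    isotope_exempt_area: float = 5000.0
    ccs_pct: dict[Tier, float] = Field(default_factory=lambda: dict(_DEFAULT_CCS))
    rt_min: dict[Tier, Union[float, Literal["monotonic"]]] = Field(
        default_factory=lambda: dict(_DEFAULT_RT)
    )
    cosine_min: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_COSINE))
    ms2_fragment_tol: float = 0.01
    support_multiplier: float = 2.0
    platform_rp: float = 60.0

    @model_validator(mode="after")
    def _invariants(self):
        for name in ("mz_ppm", "isotope_reldev_max", "isotope_exempt_area",
                     "ms2_fragment_tol", "platform_rp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for tier in Tier:
            if tier not in self.ccs_pct:
                raise ValueError(f"ccs_pct missing tier entry {tier.value!r}")
            if self.ccs_pct[tier] <= 0:
                raise ValueError(f"ccs_pct[{tier.value}] must be > 0")
            if tier not in self.rt_min:
                raise ValueError(f"rt_min missing tier entry {tier.value!r}")
            tol = self.rt_min[tier]
            if tol != MONOTONIC and tol <= 0:
                raise ValueError(f"rt_min[{tier.value}] must be > 0 or 'monotonic'")
        for key in _DEFAULT_COSINE:
            if key not in self.cosine_min:
                raise ValueError(f"cosine_min missing entry {key!r}")
            if not (0 < self.cosine_min[key] <= 1):
                raise ValueError(f"cosine_min[{key}] must lie in (0, 1]")
        if self.support_multiplier <= 1:
            raise ValueError("support_multiplier must be > 1")
        return self


def validate_profile(profile) -> ToleranceProfile:
    """Validate a tolerance profile (or mapping), filling defaults.

    Accepts either a :class:`ToleranceProfile` or a plain mapping of its
    fields. Raises :class:`~pfaslevels.errors.ConfigurationError` naming
    the offending field when an invariant is violated.
    """
    try:
        if isinstance(profile, ToleranceProfile):
            return ToleranceProfile.model_validate(profile.model_dump())
        return ToleranceProfile.model_validate(profile)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc


class MatchResult(BaseModel):
    """Outcome of comparing one feature dimension against one tier.

    ``signed_error`` units depend on the dimension: ppm (m/z), absolute
    relative-abundance deviation (isotope), percent (CCS), minutes or RI
    units (retention), cosine similarity (MS/MS). ``None`` marks results
    established without a numeric error (e.g. RT monotonicity, exemption).
    """

    model_config = ConfigDict(frozen=True)

    dimension: Dimension
    tier: Optional[Tier] = None
    signed_error: Optional[float] = None
    status: Status
    note: str = ""


def not_available(dimension: Dimension, note: str = "") -> MatchResult:
    return MatchResult(dimension=dimension, status=Status.NOT_AVAILABLE, note=note)
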