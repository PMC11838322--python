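"""Per-dimension error computation and match-status evaluation.

Error conventions follow the tolerance definitions: the denominator of
ppm and percent errors is always the *reference* (exact, library or
predicted) value, never the measured one, because tolerances are phrased
as "± x of the reference value".
"""

from __future__ import annotations

import math
from typing import Optional

from .core import (
    Dimension,
    Feature,
    MatchResult,
    MobilitySpectrum,
    ReferenceRecord,
    Status,
    Tier,
    ToleranceProfile,
    MONOTONIC,
    not_available,
)
from .errors import DomainError
from .formula import theoretical_envelope


def ppm_error(measured_mz: float, reference_mz: float) -> float:
    """Signed mass error in ppm: (measured - reference)/reference * 1e6."""
    if measured_mz <= 0 or reference_mz <= 0:
        raise DomainError("m/z values must be positive")
    return (measured_mz - reference_mz) / reference_mz * 1e6


def ccs_percent_error(measured_ccs: float, reference_ccs: float) -> float:
    """Signed CCS error in percent of the reference value."""
    if measured_ccs <= 0 or reference_ccs <= 0:
        raise DomainError("CCS values must be positive")
    return (measured_ccs - reference_ccs) / reference_ccs * 100.0


def _banded_status(error: float, tolerance: float, multiplier: float) -> Status:
    a = abs(error)
    if a <= tolerance:
        return Status.MATCH
    if a <= tolerance * multiplier:
        return Status.SUPPORT
    return Status.NO_MATCH


def isotope_match(
    observed: tuple[float, ...],
    theoretical: tuple[float, ...],
    profile: ToleranceProfile,
    peak_area: float,
    tier: Optional[Tier] = None,
) -> MatchResult:
    """Compare base-peak-normalized isotope envelopes.

    The comparison is the maximum absolute deviation between relative
    abundances on the 0-1 scale (missing isotopologues count as 0);
    status is ``match`` iff every deviation is within
    ``isotope_reldev_max``. Features below ``isotope_exempt_area`` with
    no M+1/M+2 entries observed are exempt and match by definition.
    """
    if theoretical is None or len(theoretical) == 0:
        raise DomainError("theoretical envelope must not be empty")
    if observed is None or len(observed) <= 1:
        if peak_area < profile.isotope_exempt_area:
            return MatchResult(
                dimension=Dimension.ISOTOPE,
                tier=tier,
                status=Status.MATCH,
                note="exempt: low-abundance feature without M+1/M+2",
            )
        return MatchResult(
            dimension=Dimension.ISOTOPE,
            tier=tier,
            status=Status.NO_MATCH,
            note="no M+1/M+2 observed for a feature above the exemption area",
        )
    n = max(len(observed), len(theoretical))
    worst = 0.0
    for i in range(n):
        o = observed[i] if i < len(observed) else 0.0
        t = theoretical[i] if i < len(theoretical) else 0.0
        dev = o - t
        if abs(dev) > abs(worst):
            worst = dev
    status = Status.MATCH if abs(worst) <= profile.isotope_reldev_max else Status.NO_MATCH
    return MatchResult(
        dimension=Dimension.ISOTOPE, tier=tier, signed_error=worst, status=status
    )


def spectral_cosine(
    a: MobilitySpectrum, b: MobilitySpectrum, fragment_tol: float = 0.01
) -> float:
    """Cosine similarity between two centroided spectra in [0, 1].

    Peak pairing is greedy on |Δm/z|: all cross-spectrum peak pairs
    within ``fragment_tol`` are sorted by mass distance (ties broken by
    m/z) and accepted while both peaks are unused, which makes the score
    symmetric in its arguments. Unpaired peaks contribute only to the
    norms, i.e. zero to the dot product.
    """
    if fragment_tol <= 0:
        raise DomainError("fragment_tol must be > 0")
    pa, pb = a.peaks, b.peaks
    pairs = []
    for i, (ma, _) in enumerate(pa):
        for j, (mb, _) in enumerate(pb):
            d = abs(ma - mb)
            if d <= fragment_tol:
                pairs.append((d, min(ma, mb), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _d, _m, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += pa[i][1] * pb[j][1]
    norm = math.sqrt(sum(x * x for _, x in pa)) * math.sqrt(sum(x * x for _, x in pb))
    if norm == 0.0:
        return 0.0
    return min(dot / norm, 1.0)


def _cosine_threshold(record: ReferenceRecord, profile: ToleranceProfile) -> float:
    if record.tier is Tier.REFERENCE_STANDARD:
        return profile.cosine_min["reference_standard"]
    if record.tier is Tier.LIBRARY and record.similar_instrument:
        return profile.cosine_min["library_similar"]
    # other-instrument libraries and predicted spectra
    return profile.cosine_min["library_other"]


def evaluate_dimension(
    feature: Feature,
    record: ReferenceRecord,
    dimension: Dimension,
    profile: ToleranceProfile,
) -> MatchResult:
    """Evaluate one dimension of a feature against one reference record.

    Returns ``not_available`` whenever the feature or the record lacks
    the dimension, including predicted-tier retention, whose
    monotonicity-only semantics are handled by the homologue module.
    """
    if dimension is Dimension.MZ:
        if feature.adduct != record.adduct:
            return not_available(dimension, note="adduct mismatch")
        err = ppm_error(feature.mz_measured, record.exact_mz)
        status = _banded_status(err, profile.mz_ppm, profile.support_multiplier)
        return MatchResult(
            dimension=dimension, tier=record.tier, signed_error=err, status=status
        )

    if dimension is Dimension.ISOTOPE:
        if feature.isotope_envelope is None or not record.candidate.formula:
            return not_available(dimension)
        theo = theoretical_envelope(record.candidate.formula)
        return isotope_match(
            feature.isotope_envelope, theo, profile, feature.peak_area, tier=record.tier
        )

    if dimension is Dimension.CCS:
        if feature.ccs_measured is None or record.ccs_ref is None:
            return not_available(dimension)
        err = ccs_percent_error(feature.ccs_measured, record.ccs_ref)
        tol = profile.ccs_pct[record.tier]
        status = _banded_status(err, tol, profile.support_multiplier)
        return MatchResult(
            dimension=dimension, tier=record.tier, signed_error=err, status=status
        )

    if dimension is Dimension.RT:
        tol = profile.rt_min[record.tier]
        if record.tier is Tier.PREDICTED or tol == MONOTONIC:
            return not_available(
                dimension, note="predicted retention assessed via series monotonicity"
            )
        if feature.retention is None or record.rt_ref is None:
            return not_available(dimension)
        err = feature.retention - record.rt_ref
        status = _banded_status(err, tol, profile.support_multiplier)
        return MatchResult(
            dimension=dimension, tier=record.tier, signed_error=err, status=status
        )

    if dimension is Dimension.MS2:
        if feature.ms2 is None or record.spectrum_ref is None:
            return not_available(dimension)
        sim = spectral_cosine(feature.ms2, record.spectrum_ref, profile.ms2_fragment_tol)
        threshold = _cosine_threshold(record, profile)
        status = Status.MATCH if sim >= threshold else Status.NO_MATCH
        return MatchResult(
            dimension=dimension, tier=record.tier, signed_error=sim, status=status
        )

    raise DomainError(f"unknown dimension {dimension!r}")
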