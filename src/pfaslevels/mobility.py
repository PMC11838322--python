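"""IMS resolving-power arithmetic and collapsing of unresolvable isomers.

The single-peak resolving power needed to separate two ions of similar
mobility is Rp = CCS/ΔCCS, with the pair midpoint CCS as numerator. A
pair is separable on a given platform iff the platform's achievable Rp
meets that requirement. Typical single-peak values: drift-tube IMS up to
~60, traveling-wave platforms up to ~300 without post-processing; high
resolution demultiplexing is modeled simply as a user-raised platform Rp.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict

from .core import (
    CORE_DIMENSIONS,
    Dimension,
    Feature,
    ReferenceRecord,
    Status,
    ToleranceProfile,
)
from .errors import DomainError
from . import matching

#: Platform resolving-power defaults by IMS type.
PLATFORM_RP_DEFAULTS = {"DTIMS": 60.0, "TWIMS": 300.0}


class SeparabilityVerdict(BaseModel):
    model_config = ConfigDict(frozen=True)

    ccs_pair: tuple[float, float]
    required_rp: float  # math.inf when the pair has identical CCS
    platform_rp: float
    separable: bool


def required_resolving_power(ccs_a: float, ccs_b: float) -> float:
    """Rp needed to separate two CCS values: midpoint / |ΔCCS|.

    Returns ``math.inf`` for identical CCS values (no finite resolving
    power separates them) rather than raising.
    """
    if ccs_a <= 0 or ccs_b <= 0:
        raise DomainError("CCS values must be positive")
    delta = abs(ccs_a - ccs_b)
    if delta == 0.0:
        return math.inf
    return (ccs_a + ccs_b) / 2.0 / delta


def assess_separability(
    ccs_a: float, ccs_b: float, platform_rp: float
) -> SeparabilityVerdict:
    if platform_rp <= 0:
        raise DomainError("platform_rp must be positive")
    required = required_resolving_power(ccs_a, ccs_b)
    return SeparabilityVerdict(
        ccs_pair=(ccs_a, ccs_b),
        required_rp=required,
        platform_rp=platform_rp,
        separable=platform_rp >= required,
    )


def _other_dim_statuses(
    feature: Feature, record: ReferenceRecord, profile: ToleranceProfile
) -> dict[Dimension, Status]:
    dims = [d for d in CORE_DIMENSIONS if d is not Dimension.CCS] + [Dimension.MS2]
    return {
        d: matching.evaluate_dimension(feature, record, d, profile).status for d in dims
    }


def collapse_candidates(
    feature: Feature,
    records: list[ReferenceRecord],
    profile: ToleranceProfile,
) -> list[list[ReferenceRecord]]:
    """Group candidates the platform cannot tell apart for this feature.

    Two candidates fall in one group when their CCS values require more
    resolving power than the platform offers *and* no other available
    dimension distinguishes them (their match statuses agree in every
    non-CCS dimension). Resolved candidates pass through as singleton
    groups. Annotating the feature as whichever group member has the
    closer CCS would overstate confidence; the whole group must be
    reported together.
    """
    if not records:
        return []
    n = len(records)
    statuses = [_other_dim_statuses(feature, r, profile) for r in records]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        if records[i].ccs_ref is None:
            continue
        for j in range(i + 1, n):
            if records[j].ccs_ref is None:
                continue
            required = required_resolving_power(records[i].ccs_ref, records[j].ccs_ref)
            if required <= profile.platform_rp:
                continue  # the platform separates this pair
            if all(statuses[i][d] == statuses[j][d] for d in statuses[i]):
                union(i, j)

    groups: dict[int, list[ReferenceRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(records[i])
    ordered = [sorted(g, key=lambda r: r.candidate_id) for g in groups.values()]
    ordered.sort(key=lambda g: g[0].candidate_id)
    return ordered
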