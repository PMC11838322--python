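"""Evidence-ledger compilation and Level 1-5 confidence assignment.

The five confidence levels, tested in order (the first satisfied wins):

1. **Confirmed structure** — m/z, isotope envelope, CCS and retention
   all match same-platform reference-standard values for exactly one
   exact structure, and either the MS/MS spectrum matches the standard
   or at least one corroborating piece of diagnostic evidence exists
   (mobility-aligned fragments are not mandatory when such evidence,
   e.g. other series homologues, is present).
2. **Probable structure** — all four dimensions match at library or
   predicted tier and exactly one exact structure survives mobility
   collapse and the evidence; every alternative is ruled out.
3. **Tentative candidates** — at least one candidate satisfies every
   available dimension at match-or-support status; multiple candidates
   are retained together (isomers the platform cannot resolve are
   reported as a group, optionally with a "most likely" nominee that is
   explicitly *not* a Level 2 probable structure).
4. **Unequivocal molecular formula** — no structure is retained but
   exactly one molecular formula survives the exact-mass window and all
   available filters.
5. **Feature of interest** — measured m/z and CCS plus at least one
   corroborating piece of evidence that the feature is a PFAS (negative
   mass defect, fluorinated-space CCS, CF2 homologues, suspect-list
   match, ...).

Features meeting none of these receive no level and are excluded from
reports by default.

Conflicting evidence handling: an item whose polarity is conflicting and
that targets a specific candidate eliminates that candidate everywhere;
a feature-level conflicting item blocks the single-structure Levels 1
and 2 (recorded in ``downgraded_from``) and forces evaluation at Level 3
and below, which by definition tolerate imperfectly aligned evidence.
"""

from __future__ import annotations

import itertools
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import chem, matching, mobility
from .core import (
    CORE_DIMENSIONS,
    CandidateStructure,
    Dimension,
    Feature,
    MatchResult,
    ReferenceRecord,
    Status,
    StructureResolution,
    Tier,
    TIER_PRIORITY,
    ToleranceProfile,
    MONOTONIC,
    not_available,
)
from .errors import DomainError
from .formula import (
    ElementBounds,
    FLUORINATED_BOUNDARY,
    enumerate_formulas,
    in_fluorinated_space,
    is_unequivocal,
    mass_defect,
    surviving_formulas,
    theoretical_envelope,
)
from .homologue import HomologousSeries, rt_monotonic


class EvidenceKind(str, Enum):
    HOMOLOGUE_PRESENT = "homologue_present"
    NEGATIVE_MASS_DEFECT = "negative_mass_defect"
    FLUORINATED_SPACE = "fluorinated_space"
    SUSPECT_LIST_MATCH = "suspect_list_match"
    FRAGMENT_CF2 = "fragment_cf2"
    USER_CONTEXTUAL = "user_contextual"
    OTHER = "other"


class Polarity(str, Enum):
    CORROBORATING = "corroborating"
    CONFLICTING = "conflicting"


class EvidenceItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: EvidenceKind
    description: str = ""
    supports: Optional[str] = None  # candidate_id, or None for feature-level
    polarity: Polarity = Polarity.CORROBORATING

    @model_validator(mode="after")
    def _contextual_needs_description(self):
        if self.kind is EvidenceKind.USER_CONTEXTUAL and not self.description.strip():
            raise ValueError(
                "user_contextual evidence requires a non-empty description"
            )
        return self


class EvidenceLedger(BaseModel):
    """Everything known about one feature, per candidate and dimension."""

    model_config = ConfigDict(frozen=True)

    feature: Feature
    candidates: tuple[CandidateStructure, ...]
    results: dict[str, dict[Dimension, MatchResult]]
    evidence: tuple[EvidenceItem, ...] = ()
    collapse_groups: tuple[tuple[str, ...], ...] = ()
    formula_unequivocal: Optional[bool] = None
    formula_survivors: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _complete(self):
        for cand in self.candidates:
            entry = self.results.get(cand.candidate_id)
            if entry is None:
                raise ValueError(f"no results entry for candidate {cand.candidate_id}")
            for dim in Dimension:
                if dim not in entry:
                    raise ValueError(
                        f"candidate {cand.candidate_id} missing dimension {dim.value}"
                    )
        return self

    def group_of(self, candidate_id: str) -> tuple[str, ...]:
        for group in self.collapse_groups:
            if candidate_id in group:
                return group
        return (candidate_id,)


class LevelAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    feature_id: str
    level: Optional[int] = None  # 1..5, or None for "no level"
    retained: tuple[str, ...] = ()
    most_likely: Optional[str] = None
    rationale: tuple[str, ...] = ()
    downgraded_from: Optional[int] = None


def _best_record(
    records: Sequence[ReferenceRecord], has_dim
) -> Optional[ReferenceRecord]:
    for tier in TIER_PRIORITY:
        for rec in records:
            if rec.tier is tier and has_dim(rec):
                return rec
    return None


def _series_with_feature(
    series_context: Optional[Sequence[HomologousSeries]], feature_id: str
) -> list[HomologousSeries]:
    if not series_context:
        return []
    return [s for s in series_context if feature_id in s.member_ids]


def compile_ledger(
    feature: Feature,
    records: Sequence[ReferenceRecord],
    profile: ToleranceProfile,
    series_context: Optional[Sequence[HomologousSeries]] = None,
    extra_evidence: Sequence[EvidenceItem] = (),
    bounds: Optional[ElementBounds] = None,
    fluorinated_boundary: tuple[float, float] = FLUORINATED_BOUNDARY,
    formula_search: bool = True,
) -> EvidenceLedger:
    """Aggregate per-dimension match results and diagnostic evidence.

    For each candidate the best available tier is chosen per dimension
    (reference standard > library > predicted). Predicted-tier retention
    is resolved through homologous-series monotonicity when the feature
    belongs to a detected series. Feature-level diagnostic evidence
    (homologues, negative mass defect, fluorinated space) is derived
    automatically; caller-supplied items are appended unchanged.
    """
    if feature.mz_measured is None or feature.mz_measured <= 0:
        raise DomainError("feature without a valid m/z")

    by_cand: dict[str, list[ReferenceRecord]] = {}
    cand_objs: dict[str, CandidateStructure] = {}
    for rec in records:
        by_cand.setdefault(rec.candidate_id, []).append(rec)
        cand_objs.setdefault(rec.candidate_id, rec.candidate)

    my_series = _series_with_feature(series_context, feature.feature_id)

    results: dict[str, dict[Dimension, MatchResult]] = {}
    for cid in sorted(by_cand):
        recs = by_cand[cid]
        entry: dict[Dimension, MatchResult] = {}

        rec = _best_record(recs, lambda r: True)
        entry[Dimension.MZ] = matching.evaluate_dimension(
            feature, rec, Dimension.MZ, profile
        )
        rec = _best_record(recs, lambda r: bool(r.candidate.formula))
        entry[Dimension.ISOTOPE] = (
            matching.evaluate_dimension(feature, rec, Dimension.ISOTOPE, profile)
            if rec is not None
            else not_available(Dimension.ISOTOPE)
        )
        rec = _best_record(recs, lambda r: r.ccs_ref is not None)
        entry[Dimension.CCS] = (
            matching.evaluate_dimension(feature, rec, Dimension.CCS, profile)
            if rec is not None
            else not_available(Dimension.CCS)
        )
        rec = _best_record(
            recs, lambda r: r.rt_ref is not None and r.tier is not Tier.PREDICTED
        )
        if rec is not None:
            entry[Dimension.RT] = matching.evaluate_dimension(
                feature, rec, Dimension.RT, profile
            )
        elif feature.retention is not None and any(
            sum(f.retention is not None for f in s.features) >= 2 for s in my_series
        ):
            mono = all(
                rt_monotonic(s)
                for s in my_series
                if sum(f.retention is not None for f in s.features) >= 2
            )
            entry[Dimension.RT] = MatchResult(
                dimension=Dimension.RT,
                tier=Tier.PREDICTED,
                status=Status.MATCH if mono else Status.NO_MATCH,
                note="homologous-series retention monotonicity",
            )
        else:
            entry[Dimension.RT] = not_available(Dimension.RT)
        rec = _best_record(recs, lambda r: r.spectrum_ref is not None)
        entry[Dimension.MS2] = (
            matching.evaluate_dimension(feature, rec, Dimension.MS2, profile)
            if rec is not None
            else not_available(Dimension.MS2)
        )
        results[cid] = entry

    evidence: list[EvidenceItem] = []
    for s in my_series:
        evidence.append(
            EvidenceItem(
                kind=EvidenceKind.HOMOLOGUE_PRESENT,
                description=(
                    f"member of a {s.repeat_unit.label} homologous series "
                    f"with {len(s)} detected members"
                ),
            )
        )
    md = mass_defect(feature.mz_measured)
    if md < 0:
        evidence.append(
            EvidenceItem(
                kind=EvidenceKind.NEGATIVE_MASS_DEFECT,
                description=f"mass defect {md:+.4f} Da",
            )
        )
    if feature.ccs_measured is not None and in_fluorinated_space(
        feature.mz_measured, feature.ccs_measured, fluorinated_boundary
    ):
        evidence.append(
            EvidenceItem(
                kind=EvidenceKind.FLUORINATED_SPACE,
                description="CCS below the fluorinated-space boundary line",
            )
        )
    evidence.extend(extra_evidence)

    flat_records = [
        _best_record(by_cand[cid], lambda r: r.ccs_ref is not None)
        or _best_record(by_cand[cid], lambda r: True)
        for cid in sorted(by_cand)
    ]
    groups = mobility.collapse_candidates(feature, flat_records, profile)
    group_ids = tuple(tuple(r.candidate_id for r in g) for g in groups)

    formula_unequivocal = None
    survivors: tuple[str, ...] = ()
    if formula_search:
        neutral = chem.neutral_mass_from_ion(feature.mz_measured, feature.adduct)
        candidates = enumerate_formulas(neutral, profile.mz_ppm, bounds)
        env_filter = None
        if feature.isotope_envelope is not None:
            env_filter = (
                lambda fc: matching.isotope_match(
                    feature.isotope_envelope,
                    theoretical_envelope(fc.composition),
                    profile,
                    feature.peak_area,
                ).status
                is Status.MATCH
            )
        remaining = surviving_formulas(candidates, env_filter)
        formula_unequivocal = is_unequivocal(candidates, env_filter)
        survivors = tuple(fc.formula for fc in remaining[:25])

    return EvidenceLedger(
        feature=feature,
        candidates=tuple(cand_objs[cid] for cid in sorted(by_cand)),
        results=results,
        evidence=tuple(evidence),
        collapse_groups=group_ids,
        formula_unequivocal=formula_unequivocal,
        formula_survivors=survivors,
    )


def _eliminated_ids(ledger: EvidenceLedger) -> set[str]:
    return {
        e.supports
        for e in ledger.evidence
        if e.polarity is Polarity.CONFLICTING and e.supports is not None
    }


def _feature_conflicts(ledger: EvidenceLedger) -> list[EvidenceItem]:
    return [
        e
        for e in ledger.evidence
        if e.polarity is Polarity.CONFLICTING and e.supports is None
    ]


def _has_corroborating(ledger: EvidenceLedger, candidate_id: Optional[str] = None) -> bool:
    return any(
        e.polarity is Polarity.CORROBORATING
        and (e.supports is None or e.supports == candidate_id)
        for e in ledger.evidence
    )


def _no_contradicting_dimension(entry: dict[Dimension, MatchResult]) -> bool:
    return all(r.status is not Status.NO_MATCH for r in entry.values())


def _rival_exists(ledger: EvidenceLedger, eliminated: set[str], cid: str) -> bool:
    """A rival is any other live candidate no dimension contradicts.

    "All other structural possibilities ruled out" means every other
    candidate must be excluded by a ``no_match`` in some dimension (or
    by conflicting evidence); a candidate that aligns with everything
    available — including one known only by m/z — is *not* ruled out
    and blocks the single-structure levels.
    """
    for cand in ledger.candidates:
        other = cand.candidate_id
        if other == cid or other in eliminated:
            continue
        if _no_contradicting_dimension(ledger.results[other]):
            return True
    return False


def _level1_candidates(ledger: EvidenceLedger, eliminated: set[str]) -> list[str]:
    out = []
    for cand in ledger.candidates:
        cid = cand.candidate_id
        if cid in eliminated:
            continue
        if cand.structure_resolution is not StructureResolution.EXACT_STRUCTURE:
            continue
        entry = ledger.results[cid]
        if not all(
            entry[d].status is Status.MATCH
            and entry[d].tier is Tier.REFERENCE_STANDARD
            for d in CORE_DIMENSIONS
        ):
            continue
        if not _no_contradicting_dimension(entry):
            continue
        if _rival_exists(ledger, eliminated, cid):
            continue
        ms2 = entry[Dimension.MS2]
        ms2_confirms = (
            ms2.status is Status.MATCH and ms2.tier is Tier.REFERENCE_STANDARD
        )
        if ms2_confirms or _has_corroborating(ledger, cid):
            out.append(cid)
    return out


def _level2_candidates(ledger: EvidenceLedger, eliminated: set[str]) -> list[str]:
    out = []
    for cand in ledger.candidates:
        cid = cand.candidate_id
        if cid in eliminated:
            continue
        if cand.structure_resolution is not StructureResolution.EXACT_STRUCTURE:
            continue
        entry = ledger.results[cid]
        if not all(entry[d].status is Status.MATCH for d in CORE_DIMENSIONS):
            continue
        if not _no_contradicting_dimension(entry):
            continue
        if _rival_exists(ledger, eliminated, cid):
            continue  # unresolved alternatives (incl. collapse-group mates)
        out.append(cid)
    return out


def _level3_candidates(ledger: EvidenceLedger, eliminated: set[str]) -> list[str]:
    out = []
    for cand in ledger.candidates:
        cid = cand.candidate_id
        if cid in eliminated:
            continue
        entry = ledger.results[cid]
        if entry[Dimension.MZ].status not in (Status.MATCH, Status.SUPPORT):
            continue
        if all(
            r.status in (Status.MATCH, Status.SUPPORT, Status.NOT_AVAILABLE)
            for r in entry.values()
        ):
            out.append(cid)
    return out


def assign_level(ledger: EvidenceLedger, profile: ToleranceProfile) -> LevelAssignment:
    """Assign the confidence level for one feature from its ledger.

    Levels are tested in order 1 through 5; the first whose requirements
    hold is returned, with a machine-readable rationale. Total over all
    valid ledgers: features qualifying for nothing get ``level=None``.
    """
    eliminated = _eliminated_ids(ledger)
    conflicts = _feature_conflicts(ledger)
    rationale: list[str] = []
    downgraded_from: Optional[int] = None
    for e in sorted(
        (e for e in ledger.evidence if e.polarity is Polarity.CONFLICTING),
        key=lambda e: (e.kind.value, e.supports or "", e.description),
    ):
        target = f"candidate {e.supports}" if e.supports else "feature"
        rationale.append(
            f"conflicting evidence against {target}: {e.kind.value}"
            + (f" ({e.description})" if e.description else "")
        )

    l1 = _level1_candidates(ledger, eliminated)
    if len(l1) == 1:
        if not conflicts:
            cid = l1[0]
            entry = ledger.results[cid]
            ms2 = entry[Dimension.MS2]
            basis = (
                "MS/MS matches the reference standard"
                if ms2.status is Status.MATCH and ms2.tier is Tier.REFERENCE_STANDARD
                else "corroborating diagnostic evidence present"
            )
            rationale.append(
                f"level 1: m/z, isotope, CCS and retention all match "
                f"reference-standard values for {cid}; {basis}"
            )
            return LevelAssignment(
                feature_id=ledger.feature.feature_id,
                level=1,
                retained=(cid,),
                most_likely=cid,
                rationale=tuple(rationale),
            )
        downgraded_from = 1
        rationale.append(
            "level 1 requirements met but blocked by conflicting evidence"
        )

    l2 = _level2_candidates(ledger, eliminated)
    if len(l2) == 1:
        if not conflicts:
            cid = l2[0]
            rationale.append(
                f"level 2: all dimensions match and {cid} is the only exact "
                "structure surviving mobility collapse and evidence"
            )
            return LevelAssignment(
                feature_id=ledger.feature.feature_id,
                level=2,
                retained=(cid,),
                most_likely=cid,
                rationale=tuple(rationale),
                downgraded_from=downgraded_from,
            )
        if downgraded_from is None:
            downgraded_from = 2
        rationale.append(
            "level 2 requirements met but blocked by conflicting evidence"
        )

    l3 = _level3_candidates(ledger, eliminated)
    if l3:
        rationale.append(
            f"level 3: {len(l3)} tentative candidate(s) satisfy every "
            "available dimension at match or support status"
        )
        return LevelAssignment(
            feature_id=ledger.feature.feature_id,
            level=3,
            retained=tuple(sorted(l3)),
            rationale=tuple(rationale),
            downgraded_from=downgraded_from,
        )

    if ledger.formula_unequivocal:
        formula = ledger.formula_survivors[0] if ledger.formula_survivors else "?"
        rationale.append(
            f"level 4: exactly one molecular formula ({formula}) survives the "
            "exact-mass window and all available filters"
        )
        return LevelAssignment(
            feature_id=ledger.feature.feature_id,
            level=4,
            rationale=tuple(rationale),
            downgraded_from=downgraded_from,
        )

    if ledger.feature.ccs_measured is not None and _has_corroborating(ledger):
        kinds = sorted(
            {
                e.kind.value
                for e in ledger.evidence
                if e.polarity is Polarity.CORROBORATING
            }
        )
        rationale.append(
            "level 5: measured m/z and CCS with corroborating evidence "
            f"({', '.join(kinds)})"
        )
        return LevelAssignment(
            feature_id=ledger.feature.feature_id,
            level=5,
            rationale=tuple(rationale),
            downgraded_from=downgraded_from,
        )

    rationale.append("no level: requirements for levels 1-5 all unmet")
    return LevelAssignment(
        feature_id=ledger.feature.feature_id,
        level=None,
        rationale=tuple(rationale),
        downgraded_from=downgraded_from,
    )


def _tolerance_for(
    result: MatchResult, profile: ToleranceProfile
) -> Optional[float]:
    if result.tier is None or result.signed_error is None:
        return None
    if result.dimension is Dimension.MZ:
        return profile.mz_ppm
    if result.dimension is Dimension.ISOTOPE:
        return profile.isotope_reldev_max
    if result.dimension is Dimension.CCS:
        return profile.ccs_pct[result.tier]
    if result.dimension is Dimension.RT:
        tol = profile.rt_min[result.tier]
        return None if tol == MONOTONIC else tol
    return None  # MS/MS similarity is not an error magnitude


def nominate_most_likely(
    assignment: LevelAssignment,
    ledger: EvidenceLedger,
    profile: ToleranceProfile,
) -> LevelAssignment:
    """Nominate a "most likely" tentative candidate at Level 3.

    The nominee minimizes the tolerance-normalized L1 error sum across
    the available numeric dimensions. Exact ties yield no nominee. The
    level itself is never changed: a most-likely candidate is not a
    Level 2 probable structure.
    """
    if assignment.level != 3 or not assignment.retained:
        return assignment
    if len(assignment.retained) == 1:
        cid = assignment.retained[0]
        return assignment.model_copy(
            update={
                "most_likely": cid,
                "rationale": assignment.rationale
                + (f"most likely: {cid} (sole tentative candidate)",),
            }
        )
    scores: dict[str, float] = {}
    for cid in assignment.retained:
        total = 0.0
        for result in ledger.results[cid].values():
            tol = _tolerance_for(result, profile)
            if tol is not None:
                total += abs(result.signed_error) / tol
        scores[cid] = total
    best = min(scores.values())
    winners = sorted(cid for cid, s in scores.items() if s == best)
    if len(winners) != 1:
        return assignment.model_copy(
            update={
                "rationale": assignment.rationale
                + ("no most-likely nominee: tolerance-normalized errors tie",),
            }
        )
    cid = winners[0]
    return assignment.model_copy(
        update={
            "most_likely": cid,
            "rationale": assignment.rationale
            + (
                f"most likely: {cid} (smallest tolerance-normalized error sum "
                f"{best:.4f}); not equivalent to a level 2 probable structure",
            ),
        }
    )


def apply_contextual_evidence(
    assignment: LevelAssignment,
    ledger: EvidenceLedger,
    item: EvidenceItem,
    profile: ToleranceProfile,
) -> LevelAssignment:
    """Apply user-supplied contextual knowledge, possibly promoting 3 -> 2.

    Contextual evidence (e.g. knowledge of which candidate a local
    manufacturer produces) may eliminate candidates. Promotion from
    Level 3 to Level 2 happens only when exactly one candidate remains
    afterwards *and* that candidate already matches (not merely
    supports) every Level 2 dimension requirement. No other promotion is
    permitted, and refusals are recorded with their reason.
    """
    if item.kind is not EvidenceKind.USER_CONTEXTUAL:
        raise DomainError("contextual application requires a user_contextual item")
    if assignment.level != 3:
        return assignment
    eliminated = (
        {item.supports}
        if item.polarity is Polarity.CONFLICTING and item.supports
        else set()
    )
    remaining = [cid for cid in assignment.retained if cid not in eliminated]
    note = f"contextual evidence: {item.description}"
    if len(remaining) != 1:
        return assignment.model_copy(
            update={
                "rationale": assignment.rationale
                + (
                    f"{note}; promotion refused: {len(remaining)} candidates remain",
                ),
            }
        )
    cid = remaining[0]
    entry = ledger.results[cid]
    cand = next(c for c in ledger.candidates if c.candidate_id == cid)
    # mass, CCS and RT requirements must still be *met* (matched, not
    # merely supported); an unmeasured isotope envelope does not block
    dims_ok = (
        entry[Dimension.MZ].status is Status.MATCH
        and all(
            entry[d].status in (Status.MATCH, Status.NOT_AVAILABLE)
            for d in CORE_DIMENSIONS
        )
        and _no_contradicting_dimension(entry)
        and cand.structure_resolution is StructureResolution.EXACT_STRUCTURE
    )
    if not dims_ok:
        return assignment.model_copy(
            update={
                "rationale": assignment.rationale
                + (
                    f"{note}; promotion refused: {cid} does not match all "
                    "level 2 dimension requirements",
                ),
            }
        )
    return assignment.model_copy(
        update={
            "level": 2,
            "retained": (cid,),
            "most_likely": cid,
            "downgraded_from": None,
            "rationale": assignment.rationale
            + (f"{note}; promoted level 3 -> 2 retaining {cid}",),
        }
    )


def screen_overlaps(
    library: Sequence[ReferenceRecord],
    profile: ToleranceProfile,
) -> list[tuple[str, str]]:
    """Find library pairs indistinguishable across m/z, RT and CCS.

    Two entries overlap when their ±tolerance error bars intersect in
    both m/z (ppm difference <= 2x the ppm tolerance) and RT, and their
    CCS difference demands more resolving power than the platform
    offers. Entries flagged as branched isomers are excluded.
    """
    rt_tol = profile.rt_min[Tier.REFERENCE_STANDARD]
    if rt_tol == MONOTONIC:
        raise DomainError("overlap screening needs a numeric RT tolerance")
    usable = [
        r
        for r in library
        if not r.branched_isomer
        and r.rt_ref is not None
        and r.ccs_ref is not None
    ]
    pairs: list[tuple[str, str]] = []
    for a, b in itertools.combinations(
        sorted(usable, key=lambda r: r.candidate_id), 2
    ):
        ppm = abs(matching.ppm_error(a.exact_mz, b.exact_mz))
        if ppm > 2 * profile.mz_ppm:
            continue
        if abs(a.rt_ref - b.rt_ref) > 2 * rt_tol:
            continue
        required = mobility.required_resolving_power(a.ccs_ref, b.ccs_ref)
        if required <= profile.platform_rp:
            continue
        pairs.append((a.candidate_id, b.candidate_id))
    return pairs


def run_assignment(
    features: Sequence[Feature],
    records: Sequence[ReferenceRecord],
    profile: ToleranceProfile,
    series_context: Optional[Sequence[HomologousSeries]] = None,
    extra_evidence: Sequence[EvidenceItem] = (),
    bounds: Optional[ElementBounds] = None,
    formula_search: bool = True,
) -> list[tuple[LevelAssignment, EvidenceLedger]]:
    """Assign levels to a batch of features against a record library.

    Candidate records are preselected per feature by adduct and an m/z
    window equal to the support band; series context defaults to CF2 /
    CF2O / CH2CF2 detection over the input features. Level 3 results get
    a most-likely nomination.
    """
    from .homologue import detect_series  # local: keeps import graph acyclic

    if series_context is None:
        series_context = detect_series(features, profile=profile)
    out = []
    for feature in features:
        window = profile.mz_ppm * profile.support_multiplier
        cands = [
            r
            for r in records
            if r.adduct == feature.adduct
            and abs(matching.ppm_error(feature.mz_measured, r.exact_mz)) <= window
        ]
        ledger = compile_ledger(
            feature,
            cands,
            profile,
            series_context=series_context,
            extra_evidence=extra_evidence,
            bounds=bounds,
            formula_search=formula_search,
        )
        assignment = assign_level(ledger, profile)
        assignment = nominate_most_likely(assignment, ledger, profile)
        out.append((assignment, ledger))
    return out
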