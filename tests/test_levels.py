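import numpy as np
import pytest

from helpers import level_rank, random_ledger
from pfaslevels.core import (
    CandidateStructure,
    Dimension,
    Feature,
    MobilitySpectrum,
    ReferenceRecord,
    Status,
    Tier,
    ToleranceProfile,
)
from pfaslevels.formula import theoretical_envelope
from pfaslevels.homologue import detect_series
from pfaslevels.levels import (
    EvidenceItem,
    EvidenceKind,
    Polarity,
    apply_contextual_evidence,
    assign_level,
    compile_ledger,
    nominate_most_likely,
    run_assignment,
    screen_overlaps,
)
from pfaslevels.simulate import worked_example_library


def _standard_record(cid="std", mz=426.9679, rt=5.8, ccs=168.1, formula=None,
                     spectrum=None):
    return ReferenceRecord(
        candidate=CandidateStructure(
            candidate_id=cid, formula=formula or {"C": 8, "H": 5, "F": 13, "O": 3, "S": 1}
        ),
        tier=Tier.REFERENCE_STANDARD,
        exact_mz=mz,
        rt_ref=rt,
        ccs_ref=ccs,
        spectrum_ref=spectrum,
        same_platform=True,
        in_house=True,
    )


def _matching_feature(record, **kw):
    defaults = dict(
        feature_id="f",
        mz_measured=record.exact_mz,
        rt_measured=record.rt_ref,
        ccs_measured=record.ccs_ref,
        isotope_envelope=theoretical_envelope(record.candidate.formula),
        peak_area=1e5,
        ms2=record.spectrum_ref,
    )
    defaults.update(kw)
    return Feature(**defaults)


class TestCompileLedger:
    def test_standard_tier_chosen_for_all_dimensions(self, profile):
        rec = _standard_record()
        feature = _matching_feature(rec)
        ledger = compile_ledger(feature, [rec], profile, formula_search=False)
        entry = ledger.results["std"]
        for dim in (Dimension.MZ, Dimension.ISOTOPE, Dimension.CCS, Dimension.RT):
            assert entry[dim].tier is Tier.REFERENCE_STANDARD
            assert entry[dim].status is Status.MATCH

    def test_library_ccs_only(self, profile):
        rec = ReferenceRecord(
            candidate=CandidateStructure(candidate_id="lib"),
            tier=Tier.LIBRARY,
            exact_mz=500.0,
            ccs_ref=200.0,
        )
        feature = Feature(feature_id="f", mz_measured=500.0, ccs_measured=200.1)
        ledger = compile_ledger(feature, [rec], profile, formula_search=False)
        entry = ledger.results["lib"]
        assert entry[Dimension.CCS].tier is Tier.LIBRARY
        assert entry[Dimension.RT].status is Status.NOT_AVAILABLE

    def test_homologue_evidence_from_series_context(self, profile):
        # the 6:2 member makes the 8:2 feature a CF2 homologue
        light = Feature(feature_id="light", mz_measured=426.9679)
        heavy = Feature(feature_id="heavy", mz_measured=526.9615, ccs_measured=210.0)
        series = detect_series([light, heavy], profile=profile)
        ledger = compile_ledger(
            heavy, [], profile, series_context=series, formula_search=False
        )
        kinds = {e.kind for e in ledger.evidence}
        assert EvidenceKind.HOMOLOGUE_PRESENT in kinds


class TestAssignLevel:
    def test_full_standard_match_with_homologue_evidence_is_level_1(self, profile):
        rec = _standard_record()
        feature = _matching_feature(rec)
        ledger = compile_ledger(
            feature,
            [rec],
            profile,
            extra_evidence=[EvidenceItem(kind=EvidenceKind.HOMOLOGUE_PRESENT,
                                         description="series detected")],
            formula_search=False,
        )
        a = assign_level(ledger, profile)
        assert a.level == 1
        assert a.retained == ("std",)

    def test_ms2_mismatch_downgrades_confirmation(self, profile):
        spectrum = MobilitySpectrum(peaks=((80.0, 1.0), (120.0, 0.5)))
        rec = _standard_record(spectrum=spectrum)
        other = MobilitySpectrum(peaks=((95.0, 1.0), (133.0, 0.5)))
        feature = _matching_feature(rec, ms2=other)
        ledger = compile_ledger(feature, [rec], profile, formula_search=False)
        a = assign_level(ledger, profile)
        assert a.level != 1  # a contradicting dimension blocks confirmation

    def test_support_only_feature_is_level_5(self, profile):
        feature = Feature(
            feature_id="f", mz_measured=512.9668, ccs_measured=190.0
        )
        ledger = compile_ledger(feature, [], profile, formula_search=False)
        a = assign_level(ledger, profile)
        assert a.level == 5  # m/z + CCS + negative mass defect evidence

    def test_no_evidence_gives_no_level(self, profile):
        feature = Feature(
            feature_id="f", mz_measured=331.1410, ccs_measured=0.30 * 331.14 + 95.0
        )
        ledger = compile_ledger(feature, [], profile, formula_search=False)
        a = assign_level(ledger, profile)
        assert a.level is None

    def test_feature_level_conflict_downgrades_with_record(self, profile):
        rec = _standard_record()
        feature = _matching_feature(rec)
        conflict = EvidenceItem(
            kind=EvidenceKind.OTHER,
            description="blank contamination suspected",
            polarity=Polarity.CONFLICTING,
        )
        ledger = compile_ledger(
            feature,
            [rec],
            profile,
            extra_evidence=[
                EvidenceItem(kind=EvidenceKind.HOMOLOGUE_PRESENT, description="series"),
                conflict,
            ],
            formula_search=False,
        )
        a = assign_level(ledger, profile)
        assert a.level == 3
        assert a.downgraded_from == 1

    def test_candidate_conflict_eliminates_candidate(self, profile):
        rec = _standard_record()
        feature = _matching_feature(rec)
        against = EvidenceItem(
            kind=EvidenceKind.OTHER,
            description="fragment excludes this structure",
            supports="std",
            polarity=Polarity.CONFLICTING,
        )
        ledger = compile_ledger(
            feature, [rec], profile, extra_evidence=[against], formula_search=False
        )
        a = assign_level(ledger, profile)
        assert "std" not in a.retained


class TestNomination:
    def _feature_x_assignment(self, profile):
        feature = Feature(
            feature_id="x", mz_measured=500.0, rt_measured=6.5, ccs_measured=200.1
        )
        records = [
            ReferenceRecord(
                candidate=CandidateStructure(candidate_id=cid),
                tier=Tier.LIBRARY, exact_mz=500.0, rt_ref=6.5, ccs_ref=ccs,
            )
            for cid, ccs in (("isomer_a", 199.7), ("isomer_b", 200.0))
        ]
        ledger = compile_ledger(feature, records, profile, formula_search=False)
        return assign_level(ledger, profile), ledger

    def test_closer_ccs_is_nominated(self, profile):
        a, ledger = self._feature_x_assignment(profile)
        assert a.level == 3
        a = nominate_most_likely(a, ledger, profile)
        assert a.most_likely == "isomer_b"
        assert a.level == 3  # nomination never changes the level

    def test_exact_tie_gives_no_nominee(self, profile):
        feature = Feature(
            feature_id="x", mz_measured=500.0, rt_measured=6.5, ccs_measured=200.0
        )
        records = [
            ReferenceRecord(
                candidate=CandidateStructure(candidate_id=cid),
                tier=Tier.LIBRARY, exact_mz=500.0, rt_ref=6.5, ccs_ref=ccs,
            )
            for cid, ccs in (("p", 200.0), ("q", 200.0))
        ]
        ledger = compile_ledger(feature, records, profile, formula_search=False)
        a = nominate_most_likely(assign_level(ledger, profile), ledger, profile)
        assert a.most_likely is None

    def test_single_candidate_nominates_itself(self, profile):
        feature = Feature(
            feature_id="x", mz_measured=500.004, rt_measured=6.5, ccs_measured=200.1
        )
        records = [
            ReferenceRecord(
                candidate=CandidateStructure(candidate_id="only"),
                tier=Tier.LIBRARY, exact_mz=500.0, rt_ref=6.5, ccs_ref=200.0,
            )
        ]
        ledger = compile_ledger(feature, records, profile, formula_search=False)
        a = assign_level(ledger, profile)
        assert a.level == 3  # isotope unavailable: match/support on the rest
        a = nominate_most_likely(a, ledger, profile)
        assert a.most_likely == "only"


class TestContextualEvidence:
    def _level3_two_candidates(self, profile, support_one_dim=False):
        feature = Feature(
            feature_id="f",
            mz_measured=500.0,
            rt_measured=6.5 + (0.7 if support_one_dim else 0.0),
            ccs_measured=200.1,
        )
        records = [
            ReferenceRecord(
                candidate=CandidateStructure(candidate_id=cid),
                tier=Tier.LIBRARY, exact_mz=500.0, rt_ref=6.5, ccs_ref=ccs,
            )
            for cid, ccs in (("p", 200.0), ("q", 200.2))
        ]
        ledger = compile_ledger(feature, records, profile, formula_search=False)
        return assign_level(ledger, profile), ledger

    def test_promotion_to_level_2(self, profile):
        a, ledger = self._level3_two_candidates(profile)
        assert a.level == 3
        item = EvidenceItem(
            kind=EvidenceKind.USER_CONTEXTUAL,
            description="only candidate p is manufactured upstream",
            supports="q",
            polarity=Polarity.CONFLICTING,
        )
        promoted = apply_contextual_evidence(a, ledger, item, profile)
        assert promoted.level == 2
        assert promoted.retained == ("p",)

    def test_promotion_refused_when_dimension_only_supports(self, profile):
        # RT is 0.7 min off: support, not match, so level 2 is out of reach
        a, ledger = self._level3_two_candidates(profile, support_one_dim=True)
        assert a.level == 3
        item = EvidenceItem(
            kind=EvidenceKind.USER_CONTEXTUAL,
            description="only candidate p is manufactured upstream",
            supports="q",
            polarity=Polarity.CONFLICTING,
        )
        kept = apply_contextual_evidence(a, ledger, item, profile)
        assert kept.level == 3
        assert any("refused" in r for r in kept.rationale)

    def test_non_level3_unchanged(self, profile):
        feature = Feature(feature_id="f", mz_measured=512.9668, ccs_measured=190.0)
        ledger = compile_ledger(feature, [], profile, formula_search=False)
        a = assign_level(ledger, profile)
        item = EvidenceItem(
            kind=EvidenceKind.USER_CONTEXTUAL, description="context", supports="x",
            polarity=Polarity.CONFLICTING,
        )
        assert apply_contextual_evidence(a, ledger, item, profile).level == a.level


class TestScreenOverlaps:
    def test_worked_example_mini_library(self, worked_profile):
        pairs = screen_overlaps(worked_example_library(), worked_profile)
        assert len(pairs) == 1
        assert set(pairs[0]) == {"82fts", "82ftpa"}

    def test_empty_library(self, worked_profile):
        assert screen_overlaps([], worked_profile) == []

    def test_branched_isomers_excluded(self, worked_profile):
        lib = [r.model_copy(update={"branched_isomer": True}) for r in worked_example_library()]
        assert screen_overlaps(lib, worked_profile) == []


class TestDeterminismAndMonotonicity:
    def test_identical_inputs_identical_output(self, profile):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ledger = random_ledger(rng, profile)
            a1 = assign_level(ledger, profile)
            a2 = assign_level(ledger, profile)
            assert a1.model_dump_json() == a2.model_dump_json()

    def test_evidence_monotonicity_sample(self, profile):
        rng = np.random.default_rng(6)
        for _ in range(200):
            ledger = random_ledger(rng, profile)
            base = level_rank(assign_level(ledger, profile).level)
            corro = [
                e for e in ledger.evidence
                if e.polarity is Polarity.CORROBORATING
            ]
            if corro:
                drop = int(rng.integers(0, len(corro)))
                pruned = ledger.model_copy(
                    update={"evidence": tuple(
                        e for e in ledger.evidence if e is not corro[drop]
                    )}
                )
                assert level_rank(assign_level(pruned, profile).level) >= base
            extra = EvidenceItem(
                kind=EvidenceKind.SUSPECT_LIST_MATCH, description="suspect hit"
            )
            grown = ledger.model_copy(
                update={"evidence": ledger.evidence + (extra,)}
            )
            assert level_rank(assign_level(grown, profile).level) <= base
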