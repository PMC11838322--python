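import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

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
from pfaslevels.errors import DomainError
from pfaslevels.matching import (
    ccs_percent_error,
    evaluate_dimension,
    isotope_match,
    ppm_error,
    spectral_cosine,
)


class TestPpmError:
    @pytest.mark.parametrize(
        "measured, reference, expected, tol",
        [
            (426.9679, 426.9679, 0.0, 1e-9),
            # the two worked-example pairs, from their 4-decimal masses
            (526.9705, 526.9615, 17.0788, 5e-4),
            (426.9679, 426.9651, 6.5579, 5e-4),
        ],
    )
    def test_values(self, measured, reference, expected, tol):
        assert ppm_error(measured, reference) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            ppm_error(-1.0, 400.0)
        with pytest.raises(DomainError):
            ppm_error(400.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(1.0, 2000.0), b=st.floats(1.0, 2000.0))
    def test_sign_antisymmetry(self, a, b):
        fwd, back = ppm_error(a, b), ppm_error(b, a)
        assert (fwd == 0) == (a == b)
        assert math.copysign(1, fwd) == -math.copysign(1, back) or fwd == back == 0


class TestCcsPercentError:
    @pytest.mark.parametrize(
        "measured, reference, expected",
        [
            (200.0, 200.0, 0.0),
            (200.1, 200.0, 0.05),     # Feature X vs Isomer B
            (168.1, 151.2, 11.1772),  # the fully IMS-resolved pair
        ],
    )
    def test_values(self, measured, reference, expected):
        assert ccs_percent_error(measured, reference) == pytest.approx(expected, abs=5e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            ccs_percent_error(0.0, 150.0)


class TestIsotopeMatch:
    def test_identical_envelopes_match(self, profile):
        env = (1.0, 0.1, 0.05)
        assert isotope_match(env, env, profile, 1e5).status is Status.MATCH

    def test_deviation_beyond_threshold_fails(self, profile):
        # M+1 observed 0.25 vs theoretical 0.10: deviation 0.15 > 0.10
        r = isotope_match((1.0, 0.25), (1.0, 0.10), profile, 10_000)
        assert r.status is Status.NO_MATCH
        assert r.signed_error == pytest.approx(0.15)

    def test_low_abundance_exemption(self, profile):
        r = isotope_match((1.0,), (1.0, 0.1), profile, 3_000)
        assert r.status is Status.MATCH
        assert "exempt" in r.note

    def test_high_abundance_without_envelope_fails(self, profile):
        r = isotope_match((1.0,), (1.0, 0.3), profile, 50_000)
        assert r.status is Status.NO_MATCH

    def test_empty_theoretical_is_domain_error(self, profile):
        with pytest.raises(DomainError):
            isotope_match((1.0, 0.1), (), profile, 1e5)


def _spec(*peaks):
    return MobilitySpectrum(peaks=tuple(sorted(peaks)))


class TestSpectralCosine:
    def test_identical_is_one(self):
        s = _spec((100.0, 1.0), (150.0, 0.5), (200.0, 0.1))
        assert spectral_cosine(s, s, 0.01) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        a = _spec((100.0, 1.0), (150.0, 0.5))
        b = _spec((120.0, 1.0), (170.0, 0.5))
        assert spectral_cosine(a, b, 0.01) == 0.0

    def test_hand_computed_example(self):
        a = _spec((100.0, 1.0), (150.0, 0.5))
        b = _spec((100.0, 0.5), (150.0, 1.0))
        assert spectral_cosine(a, b, 0.01) == pytest.approx(0.8)

    def test_nonpositive_tolerance_rejected(self):
        s = _spec((100.0, 1.0))
        with pytest.raises(DomainError):
            spectral_cosine(s, s, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        def rand_spec():
            n = int(rng.integers(1, 8))
            mzs = np.sort(rng.uniform(50, 500, n))
            mzs += np.arange(n) * 1e-3  # enforce strict ascent
            return MobilitySpectrum(
                peaks=tuple((float(m), float(i)) for m, i in
                            zip(mzs, rng.uniform(0, 1, n)))
            )
        a, b = rand_spec(), rand_spec()
        fwd = spectral_cosine(a, b, 0.5)
        assert fwd == pytest.approx(spectral_cosine(b, a, 0.5), abs=1e-12)
        assert 0.0 <= fwd <= 1.0

    def test_agrees_with_matchms_cosine_greedy(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            mzs = np.sort(rng.uniform(50, 500, n)) + np.arange(n) * 0.01
            ia = rng.uniform(0.05, 1.0, n)
            m = int(rng.integers(2, 9))
            mzb = np.sort(rng.uniform(50, 500, m)) + np.arange(m) * 0.01
            ib = rng.uniform(0.05, 1.0, m)
            ours = spectral_cosine(
                MobilitySpectrum(peaks=tuple(zip(map(float, mzs), map(float, ia)))),
                MobilitySpectrum(peaks=tuple(zip(map(float, mzb), map(float, ib)))),
                0.05,
            )
            score = CosineGreedy(tolerance=0.05).pair(
                matchms.Spectrum(mz=mzs, intensities=ia, metadata_harmonization=False),
                matchms.Spectrum(mz=mzb, intensities=ib, metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(score["score"]), abs=1e-6)


def _feature(**kw):
    defaults = dict(feature_id="f", mz_measured=500.0)
    defaults.update(kw)
    return Feature(**defaults)


def _record(**kw):
    defaults = dict(
        candidate=CandidateStructure(candidate_id="c"),
        tier=Tier.LIBRARY,
        exact_mz=500.0,
    )
    defaults.update(kw)
    return ReferenceRecord(**defaults)


class TestEvaluateDimension:
    def test_library_ccs_match(self, profile):
        f = _feature(ccs_measured=200.1)
        r = _record(ccs_ref=200.0)
        res = evaluate_dimension(f, r, Dimension.CCS, profile)
        assert res.status is Status.MATCH
        assert res.signed_error == pytest.approx(0.05, abs=1e-6)
        assert res.tier is Tier.LIBRARY

    def test_mz_support_band(self, profile):
        # +17.08 ppm: outside +-10 ppm but inside the 2x support band
        f = _feature(mz_measured=526.9705)
        r = _record(exact_mz=526.9615)
        res = evaluate_dimension(f, r, Dimension.MZ, profile)
        assert res.status is Status.SUPPORT

    def test_mz_support_at_five_ppm(self):
        # the closer worked-example pair is no longer a match at +-5 ppm
        tight = ToleranceProfile(mz_ppm=5.0)
        f = _feature(mz_measured=426.9679)
        r = _record(exact_mz=426.9651)
        res = evaluate_dimension(f, r, Dimension.MZ, tight)
        assert res.status is Status.SUPPORT

    def test_missing_dimension_is_not_available(self, profile):
        f = _feature()
        r = _record()
        assert evaluate_dimension(f, r, Dimension.CCS, profile).status is Status.NOT_AVAILABLE
        assert evaluate_dimension(f, r, Dimension.RT, profile).status is Status.NOT_AVAILABLE
        assert evaluate_dimension(f, r, Dimension.MS2, profile).status is Status.NOT_AVAILABLE

    def test_predicted_rt_deferred_to_series_monotonicity(self, profile):
        f = _feature(rt_measured=5.0)
        r = _record(tier=Tier.PREDICTED, rt_ref=5.0)
        res = evaluate_dimension(f, r, Dimension.RT, profile)
        assert res.status is Status.NOT_AVAILABLE
        assert "monotonicity" in res.note

    def test_adduct_mismatch_blocks_comparison(self, profile):
        f = _feature(adduct="[M+H]+")
        r = _record()
        res = evaluate_dimension(f, r, Dimension.MZ, profile)
        assert res.status is Status.NOT_AVAILABLE

    def test_status_partition_is_exclusive(self, profile):
        # sweep the error magnitude across the three bands
        for mz, want in [
            (500.0040, Status.MATCH),    # 8 ppm
            (500.0075, Status.SUPPORT),  # 15 ppm
            (500.0150, Status.NO_MATCH), # 30 ppm
        ]:
            res = evaluate_dimension(_feature(mz_measured=mz), _record(), Dimension.MZ, profile)
            assert res.status is want
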