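"""Seeded synthetic fixture generator with known ground-truth levels.

The generator emulates the *evidence structure* of an LC-IMS-HRMS PFAS
screen at the feature level, not raw signals: homologous fluorotelomer
series whose CCS and RT follow linear trends in m/z, reference-standard
or library records per member, unresolvable isomer pairs, bare features
of interest, and non-PFAS decoys. With zero noise every generated
feature's evidence satisfies its ground-truth level exactly; Gaussian
noise per dimension then degrades recovery in a controlled, seeded way.

A canned fixture encodes two classic worked-example scenarios for
IMS-based annotation: the Hydro-EVE / 6:2 FTS pair (m/z 426.9651 / 426.9679,
CCS 151.2 / 168.1 Å²), the 8:2 FTS / 8:2 FTPA pair (m/z 526.9615 /
526.9705), and "Feature X" (measured CCS 200.1 Å² against isomers at
199.7 and 200.0 Å² on a drift tube with resolving power 50).
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import chem
from .core import (
    CandidateStructure,
    Feature,
    MobilitySpectrum,
    ReferenceRecord,
    StructureResolution,
    Tier,
    ToleranceProfile,
)
from .errors import ConfigurationError


class FixtureSpec(BaseModel):
    """Parameters of one synthetic screen; the seed fixes all randomness."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_series: int = 2
    members_per_series: int = 5
    ccs_trend: tuple[float, float] = (0.21, 78.4)  # Å² per Th, Å²
    rt_trend: tuple[float, float] = (0.016, -1.03)  # min per Th, min
    noise_ppm: float = 0.0
    noise_ccs_pct: float = 0.0
    noise_rt_min: float = 0.0
    n_isomer_pairs: int = 1
    delta_ccs_pct: float = 0.3  # pair CCS split; unresolvable below ~Rp 330
    coeluting: bool = True
    n_interest: int = 1
    n_decoys: int = 2
    with_spectra: bool = True

    @property
    def n_features(self) -> int:
        return (
            self.n_series * self.members_per_series
            + self.n_isomer_pairs
            + self.n_interest
            + self.n_decoys
        )


class FixtureSet(NamedTuple):
    features: list[Feature]
    library: list[ReferenceRecord]
    spectra: dict[str, MobilitySpectrum]
    ground_truth: dict[str, Optional[int]]


def _fts_formula(n: int, extra_h: int = 0) -> dict[str, int]:
    """n:2 fluorotelomer-sulfonate-like composition C(n+2)H5F(2n+1)O3S."""
    return {"C": n + 2, "H": 5 + extra_h, "F": 2 * n + 1, "O": 3, "S": 1}


def _spectrum_for(mz: float) -> MobilitySpectrum:
    # characteristic sulfonate fragments: SO3- (79.9573), loss of SO3/HF
    peaks = sorted(
        [(79.9573, 0.6), (mz - 97.9674, 0.4), (mz - 79.9568, 1.0)]
    )
    return MobilitySpectrum(peaks=tuple(peaks), mobility_aligned=True)


def generate(spec: FixtureSpec) -> FixtureSet:
    """Generate a deterministic synthetic screen with ground-truth levels.

    Even-indexed series carry same-platform reference-standard records
    (ground truth Level 1, homologue evidence and, optionally, matching
    MS/MS); odd-indexed series carry external library records (Level 2).
    Isomer pairs are two coeluting library candidates whose CCS split is
    below the platform's resolving power (Level 3). Features of interest
    have a negative mass defect and a fluorinated-space CCS but no
    candidates (Level 5); decoys have neither (no level).
    """
    if spec.noise_ppm < 0 or spec.noise_ccs_pct < 0 or spec.noise_rt_min < 0:
        raise ConfigurationError("noise standard deviations must be >= 0")
    if spec.members_per_series < 2 and not spec.with_spectra:
        raise ConfigurationError(
            "level-1 ground truth requires homologue evidence (>= 2 members "
            "per series) or reference spectra"
        )
    if spec.members_per_series > 5:
        raise ConfigurationError(
            "members_per_series > 5 collides with the isomer-pair mass range"
        )
    ccs_slope, ccs_icpt = spec.ccs_trend
    rt_slope, rt_icpt = spec.rt_trend

    features: list[Feature] = []
    library: list[ReferenceRecord] = []
    spectra: dict[str, MobilitySpectrum] = {}
    truth: dict[str, Optional[int]] = {}

    for s in range(spec.n_series):
        tier = Tier.REFERENCE_STANDARD if s % 2 == 0 else Tier.LIBRARY
        level = 1 if tier is Tier.REFERENCE_STANDARD else 2
        for m in range(spec.members_per_series):
            n = 4 + m
            formula = _fts_formula(n, extra_h=2 * s)
            mz = chem.ion_mz(chem.monoisotopic_mass(formula))
            ccs = ccs_slope * mz + ccs_icpt
            rt = rt_slope * mz + rt_icpt
            fid = f"series{s:02d}_m{m}"
            cid = f"cand_{fid}"
            envelope = None
            from .formula import theoretical_envelope

            envelope = theoretical_envelope(formula)
            spectrum = _spectrum_for(mz) if spec.with_spectra and level == 1 else None
            features.append(
                Feature(
                    feature_id=fid,
                    mz_measured=mz,
                    rt_measured=rt,
                    ccs_measured=ccs,
                    isotope_envelope=envelope,
                    peak_area=1e5,
                    ms2=spectrum,
                )
            )
            library.append(
                ReferenceRecord(
                    candidate=CandidateStructure(
                        candidate_id=cid,
                        name=f"{n}:2 FTS analog (series {s})",
                        formula=formula,
                    ),
                    tier=tier,
                    exact_mz=mz,
                    rt_ref=rt,
                    ccs_ref=ccs,
                    spectrum_ref=spectrum,
                    provenance="synthetic fixture",
                    same_platform=tier is Tier.REFERENCE_STANDARD,
                    in_house=tier is Tier.REFERENCE_STANDARD,
                )
            )
            if spectrum is not None:
                spectra[cid] = spectrum
            truth[fid] = level

    for p in range(spec.n_isomer_pairs):
        mz = 700.9600 + 3.016 * p
        fid = f"pair{p:02d}"
        c0 = 0.24 * mz + 70.0
        c1 = c0 * (1 + spec.delta_ccs_pct / 100.0)
        rt = rt_slope * mz + rt_icpt
        rt_b = rt if spec.coeluting else rt + 0.1
        features.append(
            Feature(
                feature_id=fid,
                mz_measured=mz,
                rt_measured=rt,
                ccs_measured=(c0 + c1) / 2.0,
                peak_area=5e4,
            )
        )
        for tag, cmz, ccs, crt in (
            ("a", mz * (1 - 4e-6), c0, rt),
            ("b", mz * (1 + 4e-6), c1, rt_b),
        ):
            library.append(
                ReferenceRecord(
                    candidate=CandidateStructure(
                        candidate_id=f"cand_{fid}{tag}",
                        name=f"isomer {tag} of pair {p}",
                    ),
                    tier=Tier.LIBRARY,
                    exact_mz=cmz,
                    rt_ref=crt,
                    ccs_ref=ccs,
                    provenance="synthetic fixture",
                )
            )
        truth[fid] = 3

    for k in range(spec.n_interest):
        mz = 640.9500 + 2.13 * k
        fid = f"interest{k:02d}"
        features.append(
            Feature(
                feature_id=fid,
                mz_measured=mz,
                rt_measured=6.0 + 0.05 * k,
                ccs_measured=0.27 * mz + 60.0,  # fluorinated space
                peak_area=2e4,
            )
        )
        truth[fid] = 5

    for k in range(spec.n_decoys):
        # formula-dense positive-defect region, off the CF2/CF2O/CH2CF2
        # spacing lattices of all other generated features: never mistaken
        # for a homologue, a PFAS of interest, or a single unequivocal formula
        mz = 331.0500 + 1.0113 * k
        fid = f"decoy{k:02d}"
        features.append(
            Feature(
                feature_id=fid,
                mz_measured=mz,
                rt_measured=3.0 + 0.05 * k,
                ccs_measured=0.30 * mz + 95.0,  # biomolecule-like CCS
                peak_area=2e4,
            )
        )
        truth[fid] = None

    features = perturb(
        features,
        noise_ppm=spec.noise_ppm,
        noise_ccs_pct=spec.noise_ccs_pct,
        noise_rt_min=spec.noise_rt_min,
        seed=spec.seed,
    )
    return FixtureSet(features, library, spectra, truth)


def perturb(
    features: list[Feature],
    noise_ppm: float = 0.0,
    noise_ccs_pct: float = 0.0,
    noise_rt_min: float = 0.0,
    seed: int = 0,
) -> list[Feature]:
    """Apply seeded Gaussian noise per dimension; zero noise is identity."""
    if min(noise_ppm, noise_ccs_pct, noise_rt_min) < 0:
        raise ConfigurationError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for f in features:
        z_mz, z_ccs, z_rt = rng.standard_normal(3)
        update: dict = {
            "mz_measured": float(f.mz_measured * (1 + z_mz * noise_ppm * 1e-6))
        }
        if f.ccs_measured is not None:
            update["ccs_measured"] = float(
                f.ccs_measured * (1 + z_ccs * noise_ccs_pct / 100.0)
            )
        if f.rt_measured is not None:
            update["rt_measured"] = float(f.rt_measured + z_rt * noise_rt_min)
        out.append(f.model_copy(update=update))
    return out


# ---------------------------------------------------------------------------
# Canned worked-example fixture


def worked_example_profile() -> ToleranceProfile:
    """Tolerances used in the worked examples: ±10 ppm m/z, ±0.5 % CCS
    against reference standards, drift-tube platform resolving power 50."""
    base = ToleranceProfile()
    ccs = dict(base.ccs_pct)
    ccs[Tier.REFERENCE_STANDARD] = 0.5
    return base.model_copy(update={"ccs_pct": ccs, "platform_rp": 50.0})


#: Reference values of the two worked-example pairs ([M-H]-, Å², min).
#: RTs and the 8:2 pair's CCS values (210.0 / 210.6, close enough to be
#: unresolvable at Rp 50) are synthetic stand-ins: those two molecules
#: are only known to coelute with close CCS values on this platform.
_WORKED_PAIRS = {
    "62fts": dict(
        name="6:2 FTS", mz=426.9679, ccs=168.1, rt=5.8, formula="C8H5F13O3S"
    ),
    "hydroeve": dict(
        name="Hydro-EVE", mz=426.9651, ccs=151.2, rt=5.6, formula="C8H2F14O4"
    ),
    "82fts": dict(
        name="8:2 FTS", mz=526.9615, ccs=210.0, rt=7.4, formula="C10H5F17O3S"
    ),
    "82ftpa": dict(
        name="8:2 FTPA", mz=526.9705, ccs=210.6, rt=7.4, formula="C10H6F17O3P"
    ),
}


def worked_example_library(tier: Tier = Tier.REFERENCE_STANDARD) -> list[ReferenceRecord]:
    """The four-entry worked-example mini-library."""
    records = []
    for cid, d in _WORKED_PAIRS.items():
        records.append(
            ReferenceRecord(
                candidate=CandidateStructure(
                    candidate_id=cid,
                    name=d["name"],
                    formula=chem.parse_formula(d["formula"]),
                ),
                tier=tier,
                exact_mz=d["mz"],
                rt_ref=d["rt"],
                ccs_ref=d["ccs"],
                provenance="in-house authenticated standard"
                if tier is Tier.REFERENCE_STANDARD
                else "external library",
                same_platform=tier is Tier.REFERENCE_STANDARD,
                in_house=tier is Tier.REFERENCE_STANDARD,
            )
        )
    return records


def worked_example_fixture() -> FixtureSet:
    """Canned fixture of the worked-example scenarios.

    Four features: the 6:2 FTS and Hydro-EVE features matched against
    same-platform reference standards in all dimensions (expected Level
    1, with CF2-homologue / mass-defect diagnostic evidence and no
    fragmentation); one feature falling between the 8:2 FTS and 8:2
    FTPA library entries, coeluting and CCS-unresolvable (expected
    Level 3 retaining both); and Feature X against the two isomer
    library entries at CCS 199.7 / 200.0 Å² (expected Level 3,
    most-likely Isomer B).
    """
    from .formula import theoretical_envelope

    features = [
        Feature(
            feature_id="feat_62fts",
            mz_measured=_WORKED_PAIRS["62fts"]["mz"],
            rt_measured=_WORKED_PAIRS["62fts"]["rt"],
            ccs_measured=_WORKED_PAIRS["62fts"]["ccs"],
            isotope_envelope=theoretical_envelope(
                chem.parse_formula(_WORKED_PAIRS["62fts"]["formula"])
            ),
            peak_area=8e4,
        ),
        Feature(
            feature_id="feat_hydroeve",
            mz_measured=_WORKED_PAIRS["hydroeve"]["mz"],
            rt_measured=_WORKED_PAIRS["hydroeve"]["rt"],
            ccs_measured=_WORKED_PAIRS["hydroeve"]["ccs"],
            isotope_envelope=theoretical_envelope(
                chem.parse_formula(_WORKED_PAIRS["hydroeve"]["formula"])
            ),
            peak_area=6e4,
        ),
        # one measured feature halfway between the two 8:2 library masses
        Feature(
            feature_id="feat_82",
            mz_measured=526.9660,
            rt_measured=7.4,
            ccs_measured=210.3,
            peak_area=4e4,
        ),
        Feature(
            feature_id="feature_x",
            mz_measured=500.0000,
            rt_measured=6.5,
            ccs_measured=200.1,
            peak_area=3e4,
        ),
    ]
    library = worked_example_library() + [
        ReferenceRecord(
            candidate=CandidateStructure(candidate_id="isomer_a", name="Isomer A"),
            tier=Tier.LIBRARY,
            exact_mz=500.0000,
            rt_ref=6.5,
            ccs_ref=199.7,
            provenance="external DTIMS library",
        ),
        ReferenceRecord(
            candidate=CandidateStructure(candidate_id="isomer_b", name="Isomer B"),
            tier=Tier.LIBRARY,
            exact_mz=500.0000,
            rt_ref=6.5,
            ccs_ref=200.0,
            provenance="external DTIMS library",
        ),
    ]
    truth: dict[str, Optional[int]] = {
        "feat_62fts": 1,
        "feat_hydroeve": 1,
        "feat_82": 3,
        "feature_x": 3,
    }
    return FixtureSet(features, library, {}, truth)
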