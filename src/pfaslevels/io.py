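"""Readers and writers for feature tables, libraries, spectra and reports.

Feature tables and libraries are plain CSV; spectra are MGF or MSP;
reports are JSON (full rationale, raw values) or CSV (one row per
feature-candidate, values rounded to the reporting precision: m/z 4
decimals, CCS 1, RT 2). Every report embeds the resolved tolerance
profile so results are audit-reproducible.
"""

from __future__ import annotations

import json
import math
import tomllib
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    CandidateStructure,
    Dimension,
    Feature,
    MobilitySpectrum,
    ReferenceRecord,
    Status,
    StructureResolution,
    Tier,
    ToleranceProfile,
    validate_profile,
)
from . import chem
from .errors import ConfigurationError, FormatError
from .levels import EvidenceLedger, LevelAssignment

REPORT_SCHEMA_VERSION = "1"

#: Reporting precision per quantity (decimals).
_DECIMALS = {"mz": 4, "ccs": 1, "rt": 2}


class FeatureTableDialect(BaseModel):
    """Column mapping and CSV conventions for feature tables."""

    model_config = ConfigDict(frozen=True)

    columns: dict[str, str] = Field(
        default_factory=lambda: {
            "feature_id": "feature_id",
            "mz": "mz",
            "adduct": "adduct",
            "rt": "rt",
            "ri": "ri",
            "ccs": "ccs",
            "area": "area",
            "m1": "M1",
            "m2": "M2",
        }
    )
    delimiter: str = ","
    decimal: str = "."


_REQUIRED = ("feature_id", "mz", "adduct")


def _cell(row, col):
    if col is None or col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def read_features(
    path, dialect: Optional[FeatureTableDialect] = None
) -> tuple[list[Feature], list[str]]:
    """Read a feature table CSV.

    Returns the validated features plus a list of row-level error
    messages (1-based file line numbers); a missing required column
    raises :class:`~pfaslevels.errors.FormatError` immediately.
    """
    dialect = dialect or FeatureTableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    for key in _REQUIRED:
        if dialect.columns[key] not in df.columns:
            raise FormatError(f"missing required column {dialect.columns[key]!r}")
    cols = dialect.columns
    features: list[Feature] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            mz = float(row[cols["mz"]])
        except (TypeError, ValueError):
            errors.append(f"line {line}: unparsable m/z {row[cols['mz']]!r}")
            continue
        m1 = _cell(row, cols.get("m1"))
        m2 = _cell(row, cols.get("m2"))
        envelope = None
        if m1 is not None or m2 is not None:
            envelope = (1.0, float(m1 or 0.0))
            if m2 is not None:
                envelope = envelope + (float(m2),)
        try:
            features.append(
                Feature(
                    feature_id=str(row[cols["feature_id"]]),
                    mz_measured=mz,
                    adduct=str(row[cols["adduct"]]),
                    rt_measured=_cell(row, cols.get("rt")),
                    ri_measured=_cell(row, cols.get("ri")),
                    ccs_measured=_cell(row, cols.get("ccs")),
                    peak_area=float(_cell(row, cols.get("area")) or 0.0),
                    isotope_envelope=envelope,
                )
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    return features, errors


_LIB_REQUIRED = ("candidate_id", "tier", "exact_mz")


def _truthy(v) -> bool:
    if v is None:
        return False
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):
        return bool(v) and not (isinstance(v, float) and math.isnan(v))
    return str(v).strip().lower() in ("1", "true", "yes", "y")


def read_library(path) -> list[ReferenceRecord]:
    """Read a candidate/reference library CSV.

    Expected columns: candidate_id, tier, exact_mz; optional: name,
    formula, adduct, rt, ccs, provenance, same_platform,
    similar_instrument, in_house, branched_isomer, structure_resolution.
    """
    df = pd.read_csv(path)
    for col in _LIB_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    records: list[ReferenceRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            formula = chem.parse_formula(str(_cell(row, "formula") or ""))
            resolution = str(
                _cell(row, "structure_resolution") or "exact_structure"
            )
            candidate = CandidateStructure(
                candidate_id=str(row["candidate_id"]),
                name=str(_cell(row, "name") or row["candidate_id"]),
                formula=formula,
                structure_resolution=StructureResolution(resolution),
            )
            records.append(
                ReferenceRecord(
                    candidate=candidate,
                    tier=Tier(str(row["tier"])),
                    exact_mz=float(row["exact_mz"]),
                    adduct=str(_cell(row, "adduct") or "[M-H]-"),
                    rt_ref=_cell(row, "rt"),
                    ccs_ref=_cell(row, "ccs"),
                    provenance=str(_cell(row, "provenance") or ""),
                    same_platform=_truthy(_cell(row, "same_platform")),
                    similar_instrument=_truthy(_cell(row, "similar_instrument")),
                    in_house=_truthy(_cell(row, "in_house")),
                    branched_isomer=_truthy(_cell(row, "branched_isomer")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"library line {line}: {exc}") from exc
    return records


def read_spectra(path, fmt: Optional[str] = None) -> dict[str, MobilitySpectrum]:
    """Read centroided spectra from an MGF or MSP file.

    Returns a map from spectrum title / compound name to spectrum.
    ``mobility_aligned`` is taken from an optional metadata field of the
    same name and defaults to true, the IMS-workflow norm.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("mgf", "msp"):
        raise FormatError(f"unsupported spectrum format {fmt!r}")
    # matchms is imported lazily: spectra are optional inputs
    from matchms.importing import load_from_mgf, load_from_msp

    loader = load_from_mgf if fmt == "mgf" else load_from_msp
    out: dict[str, MobilitySpectrum] = {}
    if path.stat().st_size == 0:
        return out
    for i, spectrum in enumerate(loader(str(path))):
        if spectrum is None:
            continue
        name = (
            spectrum.get("title")
            or spectrum.get("compound_name")
            or spectrum.get("name")
            or f"spectrum_{i}"
        )
        aligned = spectrum.get("mobility_aligned")
        peaks = tuple(
            (float(m), float(x))
            for m, x in zip(spectrum.peaks.mz, spectrum.peaks.intensities)
        )
        if not peaks:
            raise FormatError(f"spectrum block {i} ({name}): no peaks")
        out[str(name)] = MobilitySpectrum(
            peaks=peaks,
            mobility_aligned=True if aligned is None else _truthy(aligned),
        )
    return out


def load_profile(
    path=None, preset: Optional[str] = None
) -> ToleranceProfile:
    """Load a tolerance profile from a TOML file or a named preset."""
    if path is not None and preset is not None:
        raise ConfigurationError("give either a config path or a preset, not both")
    if path is None:
        preset = preset or "table1-agilent6560"
        ref = resources.files("pfaslevels").joinpath(f"presets/{preset}.toml")
        if not ref.is_file():
            raise ConfigurationError(f"unknown preset {preset!r}")
        cfg = tomllib.loads(ref.read_text())
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    return profile_from_config(cfg)


def profile_from_config(cfg: dict) -> ToleranceProfile:
    """Build a ToleranceProfile from the layered config mapping."""
    kwargs: dict = {}
    if "mz" in cfg:
        kwargs["mz_ppm"] = cfg["mz"].get("ppm", 10.0)
    iso = cfg.get("isotope", {})
    if "reldev_max" in iso:
        kwargs["isotope_reldev_max"] = iso["reldev_max"]
    if "exempt_area" in iso:
        kwargs["isotope_exempt_area"] = iso["exempt_area"]
    if "ccs" in cfg:
        try:
            kwargs["ccs_pct"] = {Tier(k): v for k, v in cfg["ccs"].items()}
        except ValueError as exc:
            raise ConfigurationError(f"[ccs] section: {exc}") from exc
    if "rt" in cfg:
        try:
            kwargs["rt_min"] = {Tier(k): v for k, v in cfg["rt"].items()}
        except ValueError as exc:
            raise ConfigurationError(f"[rt] section: {exc}") from exc
    ms2 = dict(cfg.get("ms2", {}))
    if "fragment_tol" in ms2:
        kwargs["ms2_fragment_tol"] = ms2.pop("fragment_tol")
    if ms2:
        kwargs["cosine_min"] = ms2
    if "support" in cfg and "multiplier" in cfg["support"]:
        kwargs["support_multiplier"] = cfg["support"]["multiplier"]
    if "platform" in cfg and "rp" in cfg["platform"]:
        kwargs["platform_rp"] = cfg["platform"]["rp"]
    return validate_profile(kwargs)


def profile_to_config(profile: ToleranceProfile) -> dict:
    """Inverse of :func:`profile_from_config` (lossless round trip)."""
    return {
        "mz": {"ppm": profile.mz_ppm},
        "isotope": {
            "reldev_max": profile.isotope_reldev_max,
            "exempt_area": profile.isotope_exempt_area,
        },
        "ccs": {t.value: v for t, v in profile.ccs_pct.items()},
        "rt": {t.value: v for t, v in profile.rt_min.items()},
        "ms2": {**profile.cosine_min, "fragment_tol": profile.ms2_fragment_tol},
        "support": {"multiplier": profile.support_multiplier},
        "platform": {"rp": profile.platform_rp},
    }


def _round(v: Optional[float], kind: str) -> Optional[float]:
    return None if v is None else round(v, _DECIMALS[kind])


def _assignment_payload(
    assignment: LevelAssignment, ledger: Optional[EvidenceLedger]
) -> dict:
    payload = {
        "feature_id": assignment.feature_id,
        "level": assignment.level,
        "retained": list(assignment.retained),
        "most_likely": assignment.most_likely,
        "downgraded_from": assignment.downgraded_from,
        "rationale": list(assignment.rationale),
    }
    if ledger is not None:
        payload["feature"] = {
            "mz": ledger.feature.mz_measured,
            "adduct": ledger.feature.adduct,
            "rt": ledger.feature.retention,
            "ccs": ledger.feature.ccs_measured,
        }
        payload["matches"] = {
            cid: {
                dim.value: {
                    "tier": r.tier.value if r.tier else None,
                    "status": r.status.value,
                    "signed_error": r.signed_error,
                    "note": r.note,
                }
                for dim, r in sorted(entry.items(), key=lambda kv: kv[0].value)
            }
            for cid, entry in sorted(ledger.results.items())
        }
        payload["evidence"] = [
            {
                "kind": e.kind.value,
                "polarity": e.polarity.value,
                "supports": e.supports,
                "description": e.description,
            }
            for e in ledger.evidence
        ]
        payload["collapse_groups"] = [list(g) for g in ledger.collapse_groups]
        payload["formula_unequivocal"] = ledger.formula_unequivocal
        payload["formula_survivors"] = list(ledger.formula_survivors)
    return payload


def write_report(
    assignments: Sequence[LevelAssignment],
    path,
    fmt: str = "json",
    profile: Optional[ToleranceProfile] = None,
    ledgers: Optional[Sequence[EvidenceLedger]] = None,
) -> None:
    """Write an assignment report.

    JSON carries the complete rationale ledger and raw unrounded values;
    CSV emits one row per feature-candidate with statuses and rounded
    errors, prefixed by ``#`` metadata lines echoing the tolerances.
    """
    path = Path(path)
    if ledgers is not None and len(ledgers) != len(assignments):
        raise ValueError("ledgers must parallel assignments")
    if fmt == "json":
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "tolerances": profile_to_config(profile) if profile else None,
            "assignments": [
                _assignment_payload(a, ledgers[i] if ledgers else None)
                for i, a in enumerate(assignments)
            ],
        }
        path.write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")
        return
    if fmt != "csv":
        raise ValueError(f"unsupported report format {fmt!r}")

    rows = []
    for i, a in enumerate(assignments):
        ledger = ledgers[i] if ledgers else None
        cids = list(a.retained) or [None]
        for cid in cids:
            row = {
                "feature_id": a.feature_id,
                "level": "none" if a.level is None else a.level,
                "candidate_id": cid or "",
                "most_likely": a.most_likely or "",
                "downgraded_from": a.downgraded_from or "",
            }
            if ledger is not None and cid is not None:
                for dim, r in sorted(
                    ledger.results[cid].items(), key=lambda kv: kv[0].value
                ):
                    row[f"{dim.value}_status"] = r.status.value
                    row[f"{dim.value}_tier"] = r.tier.value if r.tier else ""
                    err = r.signed_error
                    if err is not None and dim in (Dimension.MZ, Dimension.CCS):
                        err = round(err, 4)
                    elif err is not None and dim is Dimension.RT:
                        err = round(err, 2)
                    row[f"{dim.value}_error"] = "" if err is None else err
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pfaslevels report schema {REPORT_SCHEMA_VERSION}\n")
        if profile is not None:
            fh.write(f"# tolerances: {json.dumps(profile_to_config(profile))}\n")
        df.to_csv(fh, index=False)


def write_features(features: Sequence[Feature], path) -> None:
    """Write features back to CSV (lossless for all supported fields)."""
    rows = []
    for f in features:
        env = f.isotope_envelope or ()
        rows.append(
            {
                "feature_id": f.feature_id,
                "mz": repr(float(f.mz_measured)),
                "adduct": f.adduct,
                "rt": f.rt_measured,
                "ri": f.ri_measured,
                "ccs": f.ccs_measured,
                "area": f.peak_area,
                "M1": env[1] if len(env) > 1 else None,
                "M2": env[2] if len(env) > 2 else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_library(records: Sequence[ReferenceRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "candidate_id": r.candidate_id,
                "name": r.candidate.name,
                "formula": chem.hill_formula(r.candidate.formula),
                "structure_resolution": r.candidate.structure_resolution.value,
                "tier": r.tier.value,
                "exact_mz": repr(float(r.exact_mz)),
                "adduct": r.adduct,
                "rt": r.rt_ref,
                "ccs": r.ccs_ref,
                "provenance": r.provenance,
                "same_platform": r.same_platform,
                "similar_instrument": r.similar_instrument,
                "in_house": r.in_house,
                "branched_isomer": r.branched_isomer,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
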