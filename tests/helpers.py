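"""Shared test helpers: independent oracles and random-ledger generation."""

from __future__ import annotations

import itertools

import numpy as np
from pyteomics import mass as pmass

from pfaslevels.core import (
    CandidateStructure,
    Dimension,
    Feature,
    MatchResult,
    Status,
    Tier,
    ToleranceProfile,
)
from pfaslevels.formula import ElementBounds, dbe_value
from pfaslevels.levels import EvidenceItem, EvidenceKind, EvidenceLedger, Polarity

# ---------------------------------------------------------------------------
# Brute-force formula enumeration oracle (independent of the DFS search)


def brute_force_formulas(
    neutral_mass: float, tol_ppm: float, bounds: ElementBounds
) -> set[str]:
    """Exhaustively enumerate the lattice with itertools; returns Hill strings."""
    elements = sorted(bounds.bounds)
    ranges = [range(lo, hi + 1) for lo, hi in (bounds.bounds[e] for e in elements)]
    lo = neutral_mass * (1 - tol_ppm * 1e-6)
    hi = neutral_mass * (1 + tol_ppm * 1e-6)
    out = set()
    for counts in itertools.product(*ranges):
        comp = {e: c for e, c in zip(elements, counts) if c > 0}
        if not comp:
            continue
        m = sum(pmass.nist_mass[e][0][0] * c for e, c in comp.items())
        if not (lo <= m <= hi):
            continue
        h = comp.get("H", 0)
        f = comp.get("F", 0)
        n = comp.get("N", 0)
        c = comp.get("C", 0)
        if (n - h - f) % 2 != 0:
            continue
        if dbe_value(comp) < 0:
            continue
        if h + f > 2 * c + 2 + n:
            continue
        parts = []
        for e in ("C", "H"):
            if e in comp:
                k = comp[e]
                parts.append(e if k == 1 else f"{e}{k}")
        for e in sorted(set(comp) - {"C", "H"}):
            k = comp[e]
            parts.append(e if k == 1 else f"{e}{k}")
        out.add("".join(parts))
    return out


def envelope_oracle(composition: dict[str, int]) -> dict[int, float]:
    """Aggregate pyteomics isotopologue abundances by nominal mass shift."""
    comp = pmass.Composition(composition)
    mono = pmass.calculate_mass(comp)
    agg: dict[int, float] = {}
    for iso, ab in pmass.isotopologues(
        comp, report_abundance=True, isotope_threshold=1e-6, overall_threshold=1e-9
    ):
        shift = round(pmass.calculate_mass(iso) - mono)
        agg[shift] = agg.get(shift, 0.0) + ab
    base = max(agg.values())
    return {k: v / base for k, v in agg.items()}


# ---------------------------------------------------------------------------
# Randomized evidence ledgers for determinism / monotonicity properties

_NUMERIC_DIMS = (Dimension.MZ, Dimension.CCS, Dimension.RT)


def _tol(dim: Dimension, tier: Tier, profile: ToleranceProfile) -> float:
    if dim is Dimension.MZ:
        return profile.mz_ppm
    if dim is Dimension.CCS:
        return profile.ccs_pct[tier]
    tol = profile.rt_min[tier]
    return 0.5 if tol == "monotonic" else tol


def _pick(rng, options, p):
    return options[int(rng.choice(len(options), p=p))]


def _random_result(
    rng: np.random.Generator, dim: Dimension, profile: ToleranceProfile
) -> MatchResult:
    if dim in (Dimension.ISOTOPE, Dimension.MS2):
        status = _pick(
            rng, [Status.MATCH, Status.NO_MATCH, Status.NOT_AVAILABLE], [0.5, 0.2, 0.3]
        )
        if status is Status.NOT_AVAILABLE:
            return MatchResult(dimension=dim, status=status)
        tier = _pick(rng, [Tier.REFERENCE_STANDARD, Tier.LIBRARY], [0.5, 0.5])
        err = (
            float(rng.uniform(0.0, 0.08))
            if dim is Dimension.ISOTOPE
            else float(rng.uniform(0.91, 1.0) if status is Status.MATCH else rng.uniform(0.1, 0.6))
        )
        return MatchResult(dimension=dim, tier=tier, signed_error=err, status=status)
    status = _pick(
        rng,
        [Status.MATCH, Status.SUPPORT, Status.NO_MATCH, Status.NOT_AVAILABLE],
        [0.45, 0.15, 0.2, 0.2],
    )
    if status is Status.NOT_AVAILABLE:
        return MatchResult(dimension=dim, status=status)
    tier = _pick(rng, list(Tier), [1 / 3] * 3)
    if dim is Dimension.RT and tier is Tier.PREDICTED:
        tier = Tier.LIBRARY
    tol = _tol(dim, tier, profile)
    if status is Status.MATCH:
        err = float(rng.uniform(-tol, tol))
    elif status is Status.SUPPORT:
        err = float(rng.choice([-1, 1])) * float(rng.uniform(tol, 2 * tol))
    else:
        err = float(rng.choice([-1, 1])) * float(rng.uniform(2.5 * tol, 6 * tol))
    return MatchResult(dimension=dim, tier=tier, signed_error=err, status=status)


def random_ledger(
    rng: np.random.Generator, profile: ToleranceProfile
) -> EvidenceLedger:
    n_cand = int(rng.integers(0, 4))
    feature = Feature(
        feature_id="F",
        mz_measured=float(rng.uniform(200, 800)),
        ccs_measured=float(rng.uniform(120, 260)) if rng.random() < 0.8 else None,
        rt_measured=float(rng.uniform(1, 12)),
        peak_area=float(rng.uniform(1e3, 1e6)),
    )
    candidates = []
    results = {}
    for i in range(n_cand):
        cid = f"C{i}"
        candidates.append(CandidateStructure(candidate_id=cid, name=cid))
        entry = {}
        # reference-standard ledgers occasionally use a uniform std tier
        all_std = rng.random() < 0.25
        for dim in Dimension:
            r = _random_result(rng, dim, profile)
            if all_std and r.tier is not None:
                r = r.model_copy(update={"tier": Tier.REFERENCE_STANDARD})
            entry[dim] = r
        results[cid] = entry
    evidence = []
    corroborating_kinds = [
        EvidenceKind.HOMOLOGUE_PRESENT,
        EvidenceKind.NEGATIVE_MASS_DEFECT,
        EvidenceKind.FLUORINATED_SPACE,
        EvidenceKind.SUSPECT_LIST_MATCH,
    ]
    for kind in corroborating_kinds:
        if rng.random() < 0.35:
            evidence.append(EvidenceItem(kind=kind, description=kind.value))
    if rng.random() < 0.15:
        evidence.append(
            EvidenceItem(
                kind=EvidenceKind.OTHER,
                description="inconsistent observation",
                polarity=Polarity.CONFLICTING,
            )
        )
    if n_cand and rng.random() < 0.15:
        evidence.append(
            EvidenceItem(
                kind=EvidenceKind.OTHER,
                description="evidence against one candidate",
                supports=f"C{int(rng.integers(0, n_cand))}",
                polarity=Polarity.CONFLICTING,
            )
        )
    return EvidenceLedger(
        feature=feature,
        candidates=tuple(candidates),
        results=results,
        evidence=tuple(evidence),
        collapse_groups=tuple((c.candidate_id,) for c in candidates),
        formula_unequivocal=bool(rng.random() < 0.15),
        formula_survivors=("CHNO",) if rng.random() < 0.5 else (),
    )


def level_rank(level) -> int:
    """Numeric order with 'no level' ranked below Level 5."""
    return 6 if level is None else level
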