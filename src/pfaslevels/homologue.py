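"""Homologous-series detection, trendline fitting and member prediction.

PFAS homologous series are chains of compounds differing by integer
repeats of a structural unit (CF2, CH2CF2, CF2O, ...). Members share an
m/z spacing equal to multiples of the unit's exact mass, and their CCS
and retention values vary smoothly with m/z, so an ordinary
least-squares line fitted through at least three members yields
predicted-tier reference values for putative further members. Predicted
retention carries monotonicity-only semantics: within a series RT must
increase with m/z; no minute-scale tolerance is applied.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict
from scipy import stats

from . import chem
from .core import (
    CandidateStructure,
    Dimension,
    Feature,
    ReferenceRecord,
    StructureResolution,
    Tier,
    ToleranceProfile,
)
from .errors import DomainError, InsufficientDataError


class RepeatUnit(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    composition: dict[str, int]
    exact_mass: Optional[float] = None

    def mass(self) -> float:
        calc = chem.monoisotopic_mass(self.composition)
        if self.exact_mass is not None and abs(self.exact_mass - calc) > 1e-5:
            raise DomainError(
                f"exact_mass of {self.label} inconsistent with composition"
            )
        return self.exact_mass if self.exact_mass is not None else calc


#: The repeat units most commonly seen in PFAS homologous series.
STANDARD_UNITS: tuple[RepeatUnit, ...] = (
    RepeatUnit(label="CF2", composition={"C": 1, "F": 2}),
    RepeatUnit(label="CF2O", composition={"C": 1, "F": 2, "O": 1}),
    RepeatUnit(label="CH2CF2", composition={"C": 2, "H": 2, "F": 2}),
)


class Trendline(BaseModel):
    """OLS fit of a dimension (CCS or RT) against member m/z."""

    model_config = ConfigDict(frozen=True)

    dimension: Dimension
    slope: float
    intercept: float
    residual_sd: float
    stderr_slope: float
    n: int
    mz_span: tuple[float, float]
    unit_mass: float

    def value_at(self, mz: float) -> float:
        return self.slope * mz + self.intercept


class HomologousSeries(BaseModel):
    model_config = ConfigDict(frozen=True)

    repeat_unit: RepeatUnit
    features: tuple[Feature, ...]  # ascending m/z
    unit_counts: tuple[int, ...]  # repeats relative to the lightest member
    trend_ccs: Optional[Trendline] = None
    trend_rt: Optional[Trendline] = None

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(f.feature_id for f in self.features)

    def __len__(self) -> int:
        return len(self.features)


def detect_series(
    features: Sequence[Feature],
    units: Sequence[RepeatUnit] = STANDARD_UNITS,
    profile: Optional[ToleranceProfile] = None,
) -> list[HomologousSeries]:
    """Find maximal chains of features spaced by repeat-unit multiples.

    Two features belong to the same chain when their m/z difference is
    an integer number (>= 1) of unit masses within the profile's m/z ppm
    tolerance (evaluated at the heavier member). A feature may appear in
    several series (one per unit). Output order is deterministic: by
    unit label, then by the lightest member m/z.
    """
    profile = profile or ToleranceProfile()
    out: list[HomologousSeries] = []
    feats = sorted(features, key=lambda f: (f.mz_measured, f.feature_id))
    n = len(feats)
    for unit in sorted(units, key=lambda u: u.label):
        u = unit.mass()
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                delta = feats[j].mz_measured - feats[i].mz_measured
                k = round(delta / u)
                if k < 1:
                    continue
                tol = profile.mz_ppm * 1e-6 * feats[j].mz_measured
                if abs(delta - k * u) <= tol:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for idxs in groups.values():
            if len(idxs) < 2:
                continue
            members = [feats[i] for i in idxs]
            base = members[0].mz_measured
            counts = tuple(round((f.mz_measured - base) / u) for f in members)
            out.append(
                HomologousSeries(
                    repeat_unit=unit, features=tuple(members), unit_counts=counts
                )
            )
    out.sort(key=lambda s: (s.repeat_unit.label, s.features[0].mz_measured))
    return out


def fit_trendline(series: HomologousSeries, dimension: Dimension) -> Trendline:
    """Ordinary least-squares line of CCS or RT versus member m/z."""
    if dimension is Dimension.CCS:
        pts = [
            (f.mz_measured, f.ccs_measured)
            for f in series.features
            if f.ccs_measured is not None
        ]
    elif dimension is Dimension.RT:
        pts = [
            (f.mz_measured, f.retention)
            for f in series.features
            if f.retention is not None
        ]
    else:
        raise DomainError(f"no trendline for dimension {dimension!r}")
    if len(pts) < 3:
        raise InsufficientDataError(
            f"trendline fitting requires >= 3 members with {dimension.value}; "
            f"got {len(pts)}"
        )
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    fit = stats.linregress(xs, ys)
    resid = [y - (fit.slope * x + fit.intercept) for x, y in pts]
    dof = len(pts) - 2
    residual_sd = (sum(r * r for r in resid) / dof) ** 0.5 if dof > 0 else 0.0
    return Trendline(
        dimension=dimension,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=residual_sd,
        stderr_slope=float(fit.stderr) if fit.stderr is not None else 0.0,
        n=len(pts),
        mz_span=(min(xs), max(xs)),
        unit_mass=series.repeat_unit.mass(),
    )


def predict_member(
    trend: Trendline, mz: float, profile: Optional[ToleranceProfile] = None
) -> ReferenceRecord:
    """Predicted-tier reference record for a putative series member.

    The predicted CCS is the trendline value at ``mz``; the predicted
    tier tolerance from the profile applies when the record is matched.
    Queries beyond the fitted m/z span by more than one repeat unit are
    flagged as extrapolation in the provenance text.
    """
    if mz <= 0:
        raise DomainError("m/z must be positive")
    lo, hi = trend.mz_span
    extrapolated = mz < lo - trend.unit_mass or mz > hi + trend.unit_mass
    provenance = (
        f"homologous-series {trend.dimension.value} trendline "
        f"({trend.n} members, residual sd {trend.residual_sd:.4g})"
    )
    if extrapolated:
        provenance += "; extrapolation beyond fitted span + 1 repeat unit"
    candidate = CandidateStructure(
        candidate_id=f"series-prediction@{mz:.4f}",
        name=f"predicted homologue at m/z {mz:.4f}",
        structure_resolution=StructureResolution.ISOMER_CLASS,
    )
    return ReferenceRecord(
        candidate=candidate,
        tier=Tier.PREDICTED,
        exact_mz=mz,
        ccs_ref=trend.value_at(mz) if trend.dimension is Dimension.CCS else None,
        provenance=provenance,
    )


def rt_monotonic(series: HomologousSeries) -> bool:
    """True iff retention strictly increases with unit count.

    Vacuously true for a single member with retention; members without a
    retention value are skipped.
    """
    pts = [
        (c, f.retention)
        for c, f in zip(series.unit_counts, series.features)
        if f.retention is not None
    ]
    pts.sort()
    return all(b[1] > a[1] for a, b in zip(pts, pts[1:]))
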