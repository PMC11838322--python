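# Methods

This note documents the model implemented by `pfaslevels`, the
tolerance semantics, the numerical choices, and the places where the
design was genuinely open.

## Evidence model

Each detected feature carries a measured *m/z* (monoisotopic peak of
one adduct, deprotonated by default), optionally a retention value (RT
in minutes for LC, RI for GC — one generic retention dimension,
selected per experiment and never mixed), a CCS (Å²), a base-peak
normalized isotope envelope (M, M+1, M+2), a peak area, and optionally
a centroided, mobility-aligned MS/MS spectrum.

Candidates enter through `ReferenceRecord`s at one of three tiers —
`reference_standard` (same-platform, in-house authenticated standard),
`library` (reputable external repository), `predicted` (computed, e.g.
homologous-series trendlines). When a candidate offers several tiers
for one dimension the best tier wins (standard > library > predicted).
Comparisons are only made between like adducts.

### Error conventions

* ppm error = (measured − reference)/reference × 10⁶; the denominator
  is always the reference value because tolerances are phrased as
  "± x of the exact / reference value". Same convention for CCS
  percent error.
* Isotope envelopes are compared by the maximum absolute deviation of
  base-peak-normalized relative abundances (0–1 scale); the default
  threshold 0.10 operationalizes "visually matches within 10 %".
  Whether that phrase means absolute or per-isotopologue relative
  deviation is not defined anywhere we know of; absolute deviation was
  chosen because relative deviation explodes for trace isotopologues.
  Features below 5000 peak area with no observed M+1/M+2 are exempt
  (matched with an "exempt" note).
* Spectral similarity is the cosine of greedily paired peak
  intensities: all cross-spectrum peak pairs within the fragment
  tolerance (default 0.01 Th; nothing in the guidance fixes this) are
  sorted by |Δm/z| (ties by m/z) and accepted while both peaks are
  unused. Sorting globally rather than scanning one spectrum makes the
  score symmetric. Unpaired peaks contribute to the norms only. No
  intensity weighting, no modified/hybrid cosine, no noise filtering.

### Match / support

A numeric error within tolerance is a `match`. Within
`support_multiplier × tolerance` (default 2.0) it is `support`:
evidence that aligns but misses the strict tolerance, usable only at
Level 3 and below. The guidance defines support qualitatively; the
doubled tolerance is the narrowest non-degenerate band and every
support-status result is flagged in the output. Support applies to the
m/z, CCS and retention dimensions; isotope and MS/MS comparisons are
binary.

## Ion-mobility resolvability

The resolving power required to separate two CCS values is
Rp = CCS/ΔCCS with the pair midpoint as numerator (for 199.7 vs
200.0 Å² the requirement, ≈ 666, is > 660 whichever of midpoint,
endpoint or mean is used; the midpoint is the symmetric choice). Identical CCS values yield an infinite
requirement (a sentinel, never an exception). Platform defaults:
drift-tube IMS 60, traveling-wave 300; high-resolution demultiplexing
is modeled only as a user-raised platform Rp.

Candidates whose pairwise required Rp exceeds the platform Rp *and*
whose match statuses agree in every other dimension are collapsed into
one unresolved group (union-find over unresolvable pairs). Whether
"indistinguishable" should be judged by match status or by raw value
overlap is open; match status is used because it is the unit every
other rule operates in. Raising the platform Rp can only split groups,
never merge them.

## Homologous series

Series detection links features whose m/z spacing is an integer
multiple (≥ 1) of a repeat-unit mass within the m/z ppm tolerance
evaluated at the heavier member (the spacing tolerance deliberately
reuses `mz_ppm`; no separate knob). Built-in units, with monoisotopic
masses from the NIST atomic tables: CF₂ 49.99681, CH₂CF₂ 64.01246,
CF₂O 65.99172 Da. Chains are maximal under union-find, a feature may
belong to one series per unit, and output order is deterministic (unit
label, then lightest member).

CCS-vs-m/z and RT-vs-m/z trendlines are ordinary least squares over
members with the dimension present; three members are the minimum (a
two-point line has no residual), and the residual standard deviation
(dof = n − 2) is recorded with every fit and echoed in prediction
provenance. Two-member chains still count as homologue diagnostic
evidence. Predictions carry the predicted-tier tolerance band (±5 %
CCS); the regression confidence band is reported but not used for
acceptance, since the tolerance is the pre-declared quantity. Queries
beyond the fitted span by more than one repeat unit are flagged as
extrapolation. Predicted-tier retention is monotonicity-only: RT must
strictly increase with unit count.

## Molecular formulas

Formula enumeration searches neutral-mass space (ion m/z converted via
the proton mass, 1.00728 Da for [M−H]⁻) over a bounded composition
lattice, default elements C, H, N, O, S, F with PFAS-sized caps.
Filters: rings-plus-double-bonds equivalent
DBE = C + 1 + (N − H − F)/2 must be a non-negative integer for an
even-electron neutral (halogens monovalent), and H + F ≤ 2C + 2 + N.
The depth-first search prunes on attainable suffix mass and is
verified against a brute-force lattice oracle in the tests. Tightening
the tolerance never adds candidates.

"Unequivocal formula" means exactly one candidate survives the mass
window *and* every available filter (theoretical-envelope comparison
when the feature has an isotope envelope). A top-ranked formula among
several is never unequivocal. The guidance allows formula
determination without envelope or fragments; the engine therefore
requires uniqueness after whatever filters are available and records
which filters were active.

Theoretical envelopes come from truncated polynomial expansion of
per-element natural isotope abundances (nominal shifts > +2 Da
dropped), cross-checked against an independent isotopologue
enumeration in the tests.

The "fluorinated space" flag marks features whose CCS falls below a
linear CCS-vs-m/z boundary. No community-agreed numeric boundary exists; the
default line CCS = 0.285·(m/z) + 75 is the midline between the
synthetic PFAS (CCS ≈ 0.24–0.27·m/z + 60–70) and biomolecule-like
(CCS ≈ 0.30·m/z + 95) populations of the fixture generator and must be
overridden with experiment-specific populations for real data.

## Level assignment

Levels are tested 1 → 5; the first satisfied wins, with an ordered,
machine-readable rationale. Two structural choices deserve comment:

* **"Ruled out" semantics.** The single-structure levels (1 and 2)
  require that no *rival* remain: any other live candidate with no
  contradicting (`no_match`) dimension blocks them, including a
  candidate known only by m/z. This makes assignment monotone in the
  evidence — removing a matched dimension or a corroborating item can
  never raise a level, adding one can never lower it — at the price of
  strictness when the candidate library contains sparse entries.
* **Conflicting evidence.** A conflicting item that targets a specific
  candidate eliminates that candidate everywhere. A feature-level
  conflicting item blocks Levels 1 and 2 and records the blocked level
  in `downgraded_from`; Levels 3 and 5 tolerate imperfectly aligned
  evidence by definition and are not blocked. A literal "blocks every
  level tested" rule would cascade all conflicted features to no
  level, which contradicts the role of Level 3 as the destination of
  downgraded identifications.

Level 1 accepts a matching same-platform MS/MS *or* at least one
corroborating diagnostic item in its place (fragments are not
obtainable for every low-abundance feature; the added CCS dimension
justifies the substitution). Level 3 retains all surviving candidates,
including whole unresolved collapse groups, and nominates a "most
likely" candidate minimizing the tolerance-normalized L1 error sum
over the numeric dimensions — the simplest monotone combination of the
many scoring lines the guidance lists, and deliberately pluggable.
Exact ties produce no nominee, and nomination never changes the level.
Sub-levels (2a/2b/2c, 5a/5b) are not representable; the historical 5a
vs 5b distinction maps onto evidence kinds (`suspect_list_match` vs
the experimental kinds).

User-contextual knowledge (e.g. which candidate a local manufacturer
produces) may promote Level 3 → 2 only when exactly one candidate
remains after the elimination *and* that candidate already matches
(not merely supports) mass, CCS and RT; an unmeasured isotope envelope
does not block promotion. No other promotion exists, and both
promotions and refusals are logged with the user's justification.

The library overlap screen reports pairs of entries whose ±tolerance
error bars intersect in m/z (ppm difference ≤ 2× the ppm tolerance —
two entries 17 ppm apart can both claim one feature at ±10 ppm) and RT,
and whose CCS difference exceeds the platform's resolving power.
Branched-isomer entries are excluded by flag.

## Synthetic data generator

The generator emulates the *evidence structure* of an LC-IMS-HRMS PFAS
screen at the feature level — it does not simulate chromatographic peak
shapes, drift spectra, or matrix chemistry. A seeded spec produces:

* homologous fluorotelomer-sulfonate-like series (members n = 4…, one
  CF₂ apart) whose CCS and RT follow exact linear trends
  (defaults CCS = 0.21·m/z + 78.4 Å², RT = 0.016·m/z − 1.03 min,
  matching the worked-example 6:2/8:2 values); even-indexed series carry
  same-platform standards with matching MS/MS (ground truth Level 1),
  odd-indexed series carry external library records (Level 2);
* coeluting isomer pairs split by 0.3 % CCS — required Rp ≈ 333, well
  beyond a drift tube (Level 3);
* bare features with negative mass defect and fluorinated-space CCS
  (Level 5), and decoys in a formula-dense positive-defect region off
  every repeat-unit lattice (no level);
* Gaussian noise per dimension (m/z in ppm, CCS in %, RT in min),
  seeded, with zero noise the exact identity. The CCS noise default
  reflects reported same-platform reproducibility of ≤ 0.3 %.

Because the generator writes the evidence directly, passing tests show
that the *rules* behave as specified under controlled evidence; they do
not validate peak detection, CCS calibration, adduct assignment, or any
other upstream processing on real data. Problem sizes used by the test
suite (≈ 200 features for the noise-recovery check, 10³ randomized
ledgers for the determinism/monotonicity properties, brute-force
formula oracles on lattices ≤ 10⁶ points) were chosen to exercise every
rule while keeping the suite fast on one CPU.

## Known limitations

* Only singly charged [M−H]⁻ / [M+H]⁺ adducts have built-in mass
  arithmetic; multimers and multiply charged species are out of scope.
* No CCS calibration, drift-time conversion, or FAIMS modeling (a
  compensation-voltage separation is additional evidence, not a CCS).
* Isotope envelopes stop at M+2 and ignore fine structure.
* The most-likely score ignores MS/MS similarity (it is not an error
  magnitude); alternative scorers can be plugged in at nomination.
* The fluorinated-space boundary is a synthetic default, not a
  measured population boundary.
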