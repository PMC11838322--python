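# pfaslevels

Objective, automatable confidence-level assignment for per- and
polyfluoroalkyl substances (PFAS) identified by non-targeted analysis
(NTA) on LC- or GC-IMS-HRMS platforms.

## The problem

NTA screens detect thousands of features per sample; each annotated
feature must carry an identification confidence level so results can be
compared across studies and platforms. In practice levels are assigned
by hand against prose guidance, which invites subjectivity and
overestimation. `pfaslevels` encodes the unified Level 1–5 scheme for
IMS-enabled PFAS workflows as a deterministic rule engine: every
comparison is made against a pre-declared tolerance, every decision is
logged in a machine-readable evidence ledger, and the same inputs always
produce the same levels.

## The scheme

A feature is compared to candidate reference values in up to five
dimensions — exact *m/z*, isotopic envelope, collision cross section
(CCS), retention time (RT, or retention index for GC), and MS/MS
spectrum — at one of three evidence tiers with tier-specific tolerances
(defaults for a drift-tube IMS-QTOF platform):

| dimension | reference standard | external library | predicted |
|---|---|---|---|
| *m/z* | ±10 ppm | ±10 ppm | ±10 ppm |
| isotope envelope | ±0.10 abs. (area < 5000 exempt) | same | same |
| CCS | ±0.2 % | ±2.0 % | ±5.0 % (series trendline) |
| RT | ±0.5 min | ±0.5 min | must increase with *m/z* in series |
| MS/MS cosine | ≥ 0.9 | ≥ 0.8 / 0.7 (similar / other instrument) | — |

An error within tolerance is a **match**; within twice the tolerance it
is **support**, usable only at Level 3 and below. Levels, tested in
order:

1. **Confirmed structure** — all four core dimensions match
   same-platform reference-standard values for exactly one structure,
   plus a matching MS/MS spectrum *or* corroborating diagnostic
   evidence (e.g. CF₂ homologues — mobility-aligned fragments are not
   mandatory).
2. **Probable structure** — all dimensions match library/predicted
   values and every alternative candidate is ruled out.
3. **Tentative candidates** — one or more candidates satisfy every
   available dimension at match-or-support; isomers the ion-mobility
   platform cannot resolve (required resolving power CCS/ΔCCS above
   the platform's) are retained together, optionally with a
   "most likely" nominee.
4. **Unequivocal molecular formula** — exactly one bounded-composition
   formula survives the exact-mass window and all available filters.
5. **Feature of interest** — measured *m/z* and CCS plus at least one
   piece of corroborating evidence of PFAS character (negative mass
   defect, CCS in fluorinated space, homologues, suspect-list match).

Everything else receives no level. Conflicting evidence blocks the
single-structure levels and is recorded as a downgrade.

## Worked example

The package ships a canned fixture of two example pairs plus
the "Feature X" isomer scenario:

```python
from pfaslevels import run_assignment
from pfaslevels.simulate import paper_fixture, paper_profile

features, library, _, _ = paper_fixture()
for assignment, ledger in run_assignment(features, library, paper_profile()):
    print(f"{assignment.feature_id:14s} level={assignment.level} "
          f"retained={list(assignment.retained)} most_likely={assignment.most_likely}")
```

prints

```
feat_62fts     level=1 retained=['62fts'] most_likely=62fts
feat_hydroeve  level=1 retained=['hydroeve'] most_likely=hydroeve
feat_82        level=3 retained=['82ftpa', '82fts'] most_likely=82ftpa
feature_x      level=3 retained=['isomer_a', 'isomer_b'] most_likely=isomer_b
```

6:2 FTS and Hydro-EVE ([M−H]⁻ at *m/z* 426.9679 and 426.9651, only
6.56 ppm apart) are confirmed at **Level 1**: their CCS values (168.1
vs 151.2 Å², 11.2 % apart, required resolving power ≈ 9.4) make them
trivially separable by ion mobility even if they coelute, and each
matches its same-platform standard in all dimensions. The 8:2 FTS /
8:2 FTPA pair (*m/z* 526.9615 vs 526.9705, 17 ppm) overlaps within
±10 ppm error bars, coelutes, and is CCS-indistinguishable, so without
fragmentation the feature is reported at **Level 3** as
"8:2 FTS or 8:2 FTPA". Feature X (CCS 200.1 Å²) matches two isomers at
199.7 and 200.0 Å²; splitting them would need resolving power ≈ 666,
far beyond a drift tube at 50, so both isomers are retained at
**Level 3** with Isomer B nominated most likely — explicitly *not* a
Level 2 probable structure.

The same operations are available from the shell:

```bash
pfaslevels simulate --seed 4 --out demo/          # synthetic screen + ground truth
pfaslevels assign demo/features.csv demo/library.csv --out report.json
pfaslevels screen-overlaps demo/library.csv --out pairs.json
pfaslevels homologues demo/features.csv --out series.json
pfaslevels formulas 426.9679 --tol-ppm 5 --out formulas.json
```

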