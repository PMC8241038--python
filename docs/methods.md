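# Methods

## Scope and data model

The pipeline operates on plain-text "final reports", one file per case, in
a fixed line-oriented dialect: a `CASE:` header, a `SIGNED: <date> BY
<pathologist>` header, named uppercase section headers (`SOURCE OF
SPECIMEN`, `GROSS PATHOLOGY`, `DIAGNOSIS`, `MICROSCOPIC`, `CANCER CARE
SUMMARY`, `CONSULTATION`, `PATHOLOGY PROCEDURES`) and coded procedure
lines `<CODE> x<n>`. Real laboratory-information-system exports are
proprietary and vary by vendor; this dialect is a documented stand-in that
preserves the two properties the analysis actually needs — named free-text
sections and per-container procedure codes. L86x tier codes are emitted
one line per coded container, in container order, which lets the parser
re-associate codes with the parts listed under `SOURCE OF SPECIMEN`.

Excluded case types (cancer reviews, external consults, non-fetal
autopsies) are out of scope throughout: the generator never produces them
and no scorer handles them.

## Scoring

**L4E (2018).** Ordering of the adjustment chain: per-part base points and
count increments → micro-only discount → additive points (ancillary,
frozen sections, synoptic, informal consults) → ×1.5 formal-consult
multiplier → ×1.3 teaching multiplier → cap at 50. The discount precedes
the additive points by definition of the micro-only rule; the cap is
applied last because the per-case maxima exist as a data-cleaning guard
against coding errors, not as a scoring element. A base of exactly 10
units receives the milder 5% discount: the rule is stated as strict
inequalities on both sides of 10, so the boundary is unassigned and the
conservative reading is used. The two multipliers commute, so their
relative order is immaterial (asserted in tests to guard refactors).

**Informal consults.** Detected as case-insensitive `dr.` followed by a
capitalised surname token in the diagnosis/microscopic sections; unique
individuals are keyed by lower-cased surname. One unique doctor adds 0.5
L4E, two or more add 1.0.

**W2Q.** Sum of per-code weights over *all* billable code occurrences
plus adjustments for IHC, special stains, molecular tests, frozen
sections, synoptic reports (1 W2Q) and internal/external consults; capped
at 50; never multiplied by the teaching factor.

**Fees.** Every billable code occurrence is priced under the March-2020
Ontario Schedule of Benefits; consults add nothing; capped at $1,500 per
case. All currency arithmetic is in integer cents; division results
(pure-practice conversions) are rounded to the nearest cent.

**IHC proxy.** Immunostains are counted as HR (heat-retrieval) procedure
codes, clamped at 99 per case (two digits): isolated coding errors have
produced three-digit HR counts on single cases.

**Classification.** The reporting stratum is the highest L86x code
present; L861–L863 are lumped for reporting only — scoring and billing
always use the individual codes. Cases with no L86x code form the
cytology-without-cell-block stratum.

**FTE.** For each pathologist and calendar year, the set of distinct ISO
week labels `(iso_year, iso_week)` containing a final signature is
collected; FTE is 1.0 above 41 weeks, else `weeks/48`. The 42/48 week
constants reflect full-time entitlements (up to 8 weeks vacation + 2 CME)
versus temporary staffing (3 + 1). A late-December date may carry the ISO
label of the following ISO year; it is still a distinct label inside its
calendar-year bucket, so week 1 of two ISO years can never be conflated.
Cases are attributed to the calendar year of sign-out.

## Configuration

All tunables live in one `ScoringConfig` (YAML round-trippable, versioned
schema). Parameters that matter most:

| parameter | default | units | why |
|---|---|---|---|
| `discount.threshold / high_rate / low_rate` | 10 / 0.10 / 0.05 | L4E / – | micro-only rule |
| `multipliers.formal_consult / teaching` | 1.5 / 1.3 (on) | – | consult & teaching adjustments; teaching togglable for non-teaching sites |
| `caps.l4e_max / w2q_max / fee_max_cents / ihc_max` | 50 / 50 / 150000 / 99 | units / units / cents / stains | guards against coding-error outliers |
| `l4e.synoptic` / `w2q.synoptic` | 3.0 / 1.0 | units | synoptic report weights in the two systems |
| `sob_fees_cents` | tier fees = published per-stratum median fees | cents | >50% of each tier's cases carry exactly one billable code under the default mix, so the median fee per stratum equals the single-code fee |
| `l4e.base`, `w2q.base` | calibrated (see below) | units/code | the full L4E manual and W2Q catalogue are external documents |

The cytology fee code (`L805`, $4.60) is a single representative
placeholder for the schedule's cytology code family.

## Calibration of the default point tables

The published study reports per-stratum *medians* of L4E, W2Q and fees,
not the underlying per-code point catalogues. The default tables are
therefore calibrated: per-code L4E base points and W2Q weights were
solved by bisection so that scoring the default synthetic corpus (nine
years × 2,000 cases/year, seed 1) end-to-end reproduces the published
stratum medians. The solved constants (L4E 0.4 / 0.8 / 0.7789473684 /
4.65 per L861-3 / L864 / L865 / L866 part, cytology 1.0; W2Q 0.29 / 1.7 /
2.54 / 5.49 / 0.56) are shipped in the default config, making the config
the single source of truth — the generator performs no rejection
sampling. At the calibration conditions the medians are recovered
exactly; across other seeds and corpus sizes the worst relative error
observed is ~4%, against a 10% acceptance band.

## What the synthetic corpus emulates — and what it does not

Emulated, per year: a six-tier case mix drifting away from cytology
(35.5% → 26%) and toward intermediate/large resections; per-tier part
counts, fragment/core counts (biopsies) and block counts (resections);
IHC intensity that rises then falls (mean 0.61 → 1.29 → 0.98 HR/case),
drawn as panels of 2 + Poisson(2.5) stains on a minority of cases, as
stains are ordered in practice; tier-dependent special-stain rates;
synoptic adoption rising from 25% to 55% on cancer resections (all L866;
the malignant ~25% of L865); informal (`Dr. <Surname>`) and formal
consultation rates; diagnosis sections lengthening and microscopic
sections shortening over the years; and a 15-pathologist roster (11
full-time, 4 part-time at 20–36 allowed signing weeks) whose sign-out
dates are drawn only within each pathologist's allowed ISO weeks, making
FTE recovery exact.

Each case consumes an independent pseudo-random stream keyed by
`(seed, case index)`, so corpora are byte-identical across runs and
insensitive to generation order.

Not emulated: realistic clinical narrative (section text is drawn from
small phrase pools; line/character counts are meaningful, prose is not);
patient or physician identities; corrupted or truncated exports (parsing
is total on generated corpora by construction, so the parse-error paths
are exercised only by hand-written malformed fixtures); billing-code
errors; addenda; absolute scale (the default corpus is 18,000 cases
against 574,093 in the study, and the yearly case count is held constant,
so only per-case and normalised quantities — not absolute totals — are
comparable). Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic and the recoverability of the calibrated
distributional structure, not robustness to real-world LIS noise.

## Numerical choices

* Line metrics count non-empty lines; character metrics count non-space
  characters. Any monotone convention would show the same trends; fixing
  one makes round-trip tests exact.
* Unparseable fragment/core counts default to one fragment; count words
  "one"–"ten" are recognised before `core(s)`/`fragment(s)`.
* Percent changes are rounded half away from zero to integers, matching
  the presentation of the published trend figures.
* Audit agreement uses |machine − manual| ≤ 0.05 L4E (one quantisation
  step of the point tables), with a 1e-9 epsilon against float
  representation error at the boundary.
* `normalize_series` raises on a zero reference-year metric rather than
  emitting inf; the CLI drops such metrics with a notice (they occur on
  tiny corpora, e.g. no synoptic lines in the reference year).
* Unknown procedure codes are preserved by the parser and ignored by
  scorers; *billable* codes missing from the active tables raise a
  scoring error naming the code.

## Problem sizes

The default test corpus is the calibration corpus (nine years × 2,000
cases/year, seed 1), generated, parsed and scored once per test session
in roughly ten seconds; the audit-uniformity checks use a few hundred
seeded draws on subsamples. The acceptance script is pure desk-scale
arithmetic over the shipped published tables and runs in under a second.

## Known limitations

* The per-code point defaults are calibrated to reproduce medians, not
  transcriptions of the L4E manual or W2Q catalogue; absolute per-code
  values should not be quoted from the default config.
* Only final signatures drive FTE; addenda-only activity is invisible,
  and part-week absences are not modelled (whole-ISO-week granularity).
* The fee schedule is the March-2020 snapshot; historical fee changes and
  cost-of-living adjustment are deliberately out of scope.
* High-grade-dysplasia polyp points and clinician case-conference points
  are not implemented in the L4E chain.
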