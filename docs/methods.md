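# Methods

This note documents the models, conventions and design choices behind
`icukit`: what the harmonization engine computes, what the synthetic cohort
generator emulates (and does not), and where the design was genuinely open.

## Table model and time representation

All harmonized data live in one of three table kinds. `IdTbl` is keyed by
ID columns only (static concepts such as sex). `TsTbl` adds a time-index
column on a regular grid: the `interval` (default 60 minutes) divides every
index value, and indices may be negative, since events before ICU admission
exist in real extracts. `WinTbl` adds a non-negative duration column
(ventilation episodes).

Every duration and time index is an integer number of minutes internally;
hours are a display concern. Absolute timestamps (ISO-8601) are converted
to minutes since a fixed epoch on read; relative sources store integer
minutes from the ICU admission directly. Binning floors toward minus
infinity — an event 61 minutes before admission bins to −120 at a
60-minute grid — so that pre-admission events never leak into
post-admission bins.

Aggregation within a bin defaults by value type: numeric → median,
logical → any, categorical/string → first; a concept may override this
(insulin and urine output declare `sum`, since several administrations in
one hour must add, not average). A group whose values are all missing
aggregates to missing. Plausibility-bounds filtering (inclusive: a heart
rate of exactly 300 bpm survives a [0, 300] range) runs *before*
aggregation, so a 350 bpm artifact cannot contaminate an hourly median;
this ordering is asserted by a test with a planted artifact.

## ID-system conversion

A source declares its ID hierarchy (ranks 1..n, coarse to fine). Converting
a table finer → coarser re-keys rows through the stay-window map and shifts
the time index by the difference of stay origins. Coarser → finer assigns
each row to the stay whose half-open `[admit, discharge)` window contains
its absolute time; rows outside every window are dropped with a logged
count rather than snapped to the nearest stay (an explicit choice — silent
reassignment is the harder bug to find). A missing discharge time leaves
the window right-open until the next stay of the same coarser ID, or +∞.
ID-only tables broadcast coarser → finer to every contained stay. After a
shift whose offset is not a multiple of the grid, the result drops to a
1-minute grid rather than re-flooring, which is what makes the
fine → coarse → fine round trip an exact identity for in-window rows.

## Units

Rows whose unit string is among the concept's acceptable units pass
unchanged; units with a registered conversion are rescaled (conversions are
registered per concept where the factor depends on the analyte — e.g.
creatinine µmol/L → mg/dL at 1/88.42 — plus generic entries such as
°F → °C); unknown units are kept, logged, and reported as flagged in the
result rather than silently dropped or trusted.

## The concept dictionary

The shipped dictionary holds 119 concepts: 92 atomic and 27 recursive,
grouped into the categories Blood gas (10), Chemistry (21), Hematology
(20), Neurological (7), Output (2), Respiratory (10), Vitals (6),
Medications (17), Microbiology (1), Demographics (6) and Outcome (19).
Atomic concepts carry per-source extraction items — row selection by code
(`sel_itm`) or whole-column reads (`col_itm`), optionally post-processed by
a callback — for eight source names: the three synthetic dialects (all 92
atomic concepts each) and five large public-database names with 89, 87,
85, 74 and 87 atomic concepts available respectively. Which concepts fill
the category cells, and the item codes for sources we do not ship data
for, are this package's editorial choices; the heart-rate items for the
absolute EAV dialect use the classic chartevents codes 211 and 220045.
OMOP vocabulary IDs are stored as opaque integers and only where a mapping
exists (heart rate 4239408, lactate 4191725, sex 37116947); most concepts
are deliberately left unmapped.

Callbacks are stored in JSON as reference strings — a bare registered name
or one factory application like `transform_fun(grep_diab)` — resolved
against a named registry at validation time. No code is ever evaluated
from JSON. User dictionaries are discovered through the
`ICUKIT_CONFIG_PATH` path variable and override shipped concepts by name,
with provenance recorded.

## Clinical scores

SOFA components are scored on the standard thresholds: coagulation by
platelets (<150/<100/<50/<20 ×10³/µL → 1–4), liver by bilirubin
(1.2/2.0/6.0/12.0 mg/dL), renal by creatinine (1.2/2.0/3.5/5.0 mg/dL), CNS
by GCS (13–14/10–12/6–9/<6), cardiovascular by MAP < 70 and catecholamine
doses in µg/kg/min (dopamine ≤5 or any dobutamine → 2; dopamine >5 or
norepinephrine/epinephrine ≤0.1 → 3; dopamine >15 or
norepinephrine/epinephrine >0.1 → 4), respiratory by PaO₂/FiO₂
(<400/<300 → 1/2; <200/<100 with ventilatory support → 3/4). Each
component takes the worst value over the preceding 24 h, evaluated hourly
on a densified grid; the total counts a missing component as 0 — an
explicit, auditable choice (scores are otherwise incomparable across
sources with different measurement panels) — and therefore lies in
[0, 24]. Note one consequence exercised by the worked example in the test
suite: a patient with no blood-gas or ventilation data has a missing
respiratory component, so platelets 45, bilirubin 3.0 mg/dL, MAP 60
without vasopressors, GCS 14 and creatinine 2.2 mg/dL total
3+2+1+1+2+0 = 9.

Suspected infection pairs antibiotics and culture sampling: a culture
within 24 h after an antibiotic (onset at the antibiotic) or an antibiotic
within 72 h after a culture (onset at the culture); the earliest qualifying
onset per stay is kept. The Sepsis-3 label fires at the first hour in
[onset − 48 h, onset + 24 h] where SOFA exceeds the running minimum of the
window so far by at least 2 points. GCS totals eye+motor+verbal, falling
back to a charted total when a component is missing. First-day insulin
(`ins24`) sums administrations binned into hours 0–24 inclusive and cuts
the total at the left-closed breaks 0, 1, 10, 20, 40, ∞.

## The synthetic cohort

The generator emulates the *structural* heterogeneity of public ICU
databases, not their physiology. It plants, deterministically per seed:
nested hospital/ICU stays (patient 1 always has two ICU stays in one
hospital admission, exercising coarse-to-fine ID ambiguity); vital signs
every 30 min, GCS every 4 h, labs roughly every 8 h with lactate gaps;
~1% of heart-rate rows replaced by out-of-bounds artifacts (at least one
>300 whenever heart-rate data exist); insulin events; diagnosis codes
including dotted and undotted diabetes codes; ventilation windows with
FiO₂ charting; deaths (~15% of patients) inside the last ICU stay; and
septic stays (~12% of patients) with an antibiotic at a planted onset
hour, a culture 2 h later, and a platelet crash at the onset producing a
SOFA jump of 3 over a flat baseline of 0 — which makes the expected
Sepsis-3 label hour exactly the onset hour.

One cohort renders losslessly into three dialects — long EAV with absolute
ISO timestamps and three-level IDs (labs keyed at the hospital-stay level
to force ID conversion); wide periodic vitals with relative offsets and a
flat stay ID; long EAV with relative offsets (creatinine stored in µmol/L
to force unit conversion). Because renderers emit the same observation
multiset, harmonized output must be identical across dialects up to
ID-column naming, and an engine-independent oracle (`truth_lookup`)
recomputes each concept's expected series from the truth alone. A single
sampling regime is a property of the truth, not the dialect: per-dialect
sampling rates would make hourly medians differ across renderings and
destroy the equivalence guarantee that the whole test strategy rests on.

What passing these tests does *not* show: fidelity to real databases' full
schemas, realistic inter-signal correlation, measurement error models, or
any claim about real-world Sepsis-3 prevalence. The generator's defaults
are qualitative ICU-like rates chosen once; they are test conditions, not
claims.

## Numerical choices and degenerate inputs

Time indices and durations are int64; a unit round-trip such as
`(v*88.42)/88.42` may differ from `v` by an ulp, so cross-dialect
comparisons in tests use an absolute tolerance of 1e-9 on float values and
exact equality on IDs and indices. Empty inputs flow through every verb
and callback (an empty window in `slide` yields missing; recursive
callbacks return typed empty tables). LOCF leaves leading missings in
place and is idempotent; `fill_gaps` is idempotent. `WinTbl` durations are
required non-negative at construction. Ties within an aggregation group
cannot survive aggregation by construction; `first` respects stable input
order.

## Problem sizes

The canonical test cohort is 200 patients (seed 20230615), rendered once
per test session into all three dialects; the full suite runs in under two
minutes and the acceptance script in about one, both on a single CPU.
These sizes were chosen as the point where every code path (multi-stay
patients, deaths, septic stays, artifacts, all three dialects) is
exercised with comfortable margin.

## Known limitations

Extraction is a table scan over registered CSV files — appropriate at
fixture scale, with no query pushdown or columnar caching. Only `sel_itm`
and `col_itm` item classes exist (no regex items). The five real-database
source entries in the dictionary carry synthetic item codes and are there
to document per-source availability, not to load real data. The SOFA
cardiovascular component assumes catecholamine rates already arrive in
µg/kg/min and does not weight-normalize doses itself.
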