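# icukit

Harmonized loading of heterogeneous ICU electronic-health-record databases
through a clinical *concept dictionary*.

Public ICU databases are structurally incompatible: some store long
entity–attribute–value (EAV) event tables keyed by integer item codes with
absolute timestamps and a nested patient > hospital-stay > ICU-stay
identifier hierarchy; others store wide periodic tables with
minutes-from-admission offsets and a single flat stay ID; units of
measurement and sampling rates differ too.  As a result, even routine tasks
— an hourly heart-rate series, a SOFA score, a Sepsis-3 label — must be
re-implemented per database, and published labels disagree.

`icukit` is for clinical-data researchers who want to write
dataset-agnostic analysis code.  It provides:

* **Source configurations** (JSON): a declarative description of a
  database's ID systems, tables and column roles, parsed and validated by
  `parse_source_config` / `register_source`.
* **A concept dictionary** (JSON, shipped, user-extensible): 119 clinical
  concepts — 92 *atomic* (heart rate, lactate, platelets, ...) with
  per-source extraction items, plausibility bounds and units, and 27
  *recursive* (GCS, PaO₂/FiO₂, SOFA and its six components, suspected
  infection, Sepsis-3, first-day insulin, ...) computed source-agnostically
  from other concepts.  Concepts carry OMOP vocabulary IDs where mapped and
  can be loaded by abbreviation (`"lact"`) or OMOP ID (`4191725`).
* **The loading engine** `load_concepts`: item extraction → callbacks →
  unit synchronization → bounds filtering → ID-system conversion → time
  binning → aggregation → recursive resolution → merge.  Output comes as
  one of three table kinds: `IdTbl` (id-keyed), `TsTbl` (regular time grid,
  integer minutes), `WinTbl` (start + duration).
* **Table verbs**: `fill_gaps`, `replace_na` (LOCF/constant), `slide`
  (windowed min/max/sum), `expand`, `change_interval`, `change_id`,
  `truncate_at_first`, `merge_concepts`.
* **A synthetic cohort generator** (`generate_cohort`, `render_source`)
  that plants ground-truth trajectories and renders the *same* cohort into
  three schema dialects (`eav_absolute`, `wide_relative`, `eav_relative`),
  so every feature is testable without credentialed data: harmonized output
  is provably identical across dialects.

## The core computations

Time indices live on a regular grid: a raw event at minute *t* is binned to
`floor(t / interval) * interval` (interval 60 by default), and values
sharing a bin are aggregated (numeric → median, logical → any, overridable
per concept; out-of-bounds values such as a 350 bpm heart rate are removed
*before* aggregation).

SOFA scores each organ system 0–4 on the worst value over the preceding
24 h (platelets, bilirubin, creatinine, MAP + catecholamine doses, GCS,
PaO₂/FiO₂), sums hourly with missing components counting 0, so the total is
in [0, 24].  Suspected infection is an antibiotic with a culture drawn
within 24 h after it, or a culture with an antibiotic within 72 h after it;
the Sepsis-3 label fires at the first hour in [onset − 48 h, onset + 24 h]
where SOFA exceeds the running window minimum by ≥ 2.

## Worked example

```sh
$ icukit gen --out cohort --seed 3 --n 6
eav_absolute: 10 tables (patients, admissions, icustays, chartevents, ...)
wide_relative: 9 tables (...)
eav_relative: 6 tables (...)

$ icukit load cohort/eav_absolute hr,lact --out out.csv --interval 1h
wrote out.csv: 316 rows, 9 ids, missing fraction 0.467

$ head -3 out.csv
icustay_id,charttime,hr,lact
2000,0,79.35,
2000,60,83.8,0.7
```

Each row is one ICU stay at one hour of the stay (`charttime` in minutes
from ICU admission): stay 2000 had a median heart rate of 79.35 bpm in its
first hour, no lactate drawn, then 83.8 bpm and 1 lactate of 0.7 mmol/L in
hour two.  Missing cells are hours without a measurement — impute
explicitly (`replace_na`, `fill_gaps`) if your model needs density.  The
same two commands against `cohort/wide_relative` or `cohort/eav_relative`
give the same numbers with that dialect's ID column name.

In Python:

```python
import icukit
from icukit.load import load_concepts

truth = icukit.generate_cohort(seed=3, n_patients=6)
cfg = icukit.render_source(truth, "eav_absolute", "cohort/eav_absolute")
handle = icukit.register_source(cfg, "cohort/eav_absolute")
d = icukit.load_dictionary()
res = load_concepts(d, handle, ["lact", "death", "sofa"])
res.df.head()
```

`icukit dict stats` prints the dictionary composition (119 concepts; 92
atomic + 27 recursive; per-category and per-source availability counts),
`icukit dict validate my_concepts.json` checks a user dictionary, and the
`ICUKIT_CONFIG_PATH` environment variable adds user dictionary folders that
override or extend the shipped concepts.

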