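"""Synthetic ICU cohort with ground truth, rendered into three schema
dialects.

Public ICU databases differ structurally: some store long entity-attribute-
value (EAV) event tables keyed by item codes with absolute timestamps and a
nested patient > hospital stay > ICU stay ID hierarchy; others store wide
periodic tables with minutes-from-admission offsets and a single flat stay
ID.  This module generates a ground-truth cohort (planted vital-sign and
lab trajectories, medication events, ventilation windows, diagnosis codes,
death times, suspected-infection episodes with a planted SOFA jump) and
renders the *same* truth into three dialects:

* ``eav_absolute``  -- long item-coded events, ISO timestamps, 3-level IDs;
* ``wide_relative`` -- wide periodic vitals, minute offsets, flat stay ID;
* ``eav_relative``  -- long item-coded events, minute offsets, flat stay ID.

Renderers are lossless: every planted observation appears exactly once in
some table of every dialect, so harmonized output must agree across
dialects (the package's flagship invariant) and :func:`truth_lookup`
provides an engine-independent oracle for what each concept must return.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .clinical import DIAB_RE, DKA_RE, cut_insulin
from .sources import EPOCH, SourceConfig, parse_source_config

#: calendar origin of the simulated cohort (absolute-dialect timestamps)
SIM_T0 = pd.Timestamp("2019-01-01 00:00:00")
_T0_MIN = int((SIM_T0 - EPOCH) / pd.Timedelta(minutes=1))

DIALECTS = ("eav_absolute", "wide_relative", "eav_relative")

#: canonical fixture used throughout the test-suite
FIXTURE_SEED = 20230615
FIXTURE_N = 200

HOUR, DAY = 60, 1440

# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class IcuStayTruth:
    icustay_id: int
    admit: int   # minutes from SIM_T0
    disch: int


@dataclass
class HospStayTruth:
    hadm_id: int
    admit: int
    disch: int
    icu_stays: list[IcuStayTruth] = field(default_factory=list)
    icd_codes: list[str] = field(default_factory=list)


@dataclass
class PatientTruth:
    patient_id: int
    sex: str
    age: int
    height: float
    weight: float
    adm_type: str
    death: int | None = None   # absolute minutes, inside the last ICU stay
    hosp_stays: list[HospStayTruth] = field(default_factory=list)


@dataclass
class CohortTruth:
    """Ground truth: stay structure plus planted signals.

    ``signals`` maps concept name to a list of ``(icustay_id, offset_min,
    value)`` observations with offsets relative to the ICU admission;
    ``vent`` holds ``(start_offset, duration)`` windows per stay and
    ``sep3_onset`` the planted suspected-infection onset offset of septic
    stays.
    """

    seed: int
    patients: list[PatientTruth]
    signals: dict[str, list[tuple[int, int, float]]]
    vent: dict[int, list[tuple[int, int]]]
    sep3_onset: dict[int, int]

    def stays(self) -> Iterator[tuple[PatientTruth, HospStayTruth, IcuStayTruth]]:
        for p in self.patients:
            for h in p.hosp_stays:
                for s in h.icu_stays:
                    yield p, h, s

    def stay_index(self) -> dict[int, tuple[PatientTruth, HospStayTruth,
                                            IcuStayTruth]]:
        return {s.icustay_id: (p, h, s) for p, h, s in self.stays()}

    def to_json(self) -> str:
        d = asdict(self)
        d["vent"] = {str(k): v for k, v in self.vent.items()}
        d["sep3_onset"] = {str(k): v for k, v in self.sep3_onset.items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        patients = [
            PatientTruth(
                **{**p, "hosp_stays": [
                    HospStayTruth(
                        **{**h, "icu_stays": [IcuStayTruth(**s)
                                              for s in h["icu_stays"]]})
                    for h in p["hosp_stays"]]})
            for p in d["patients"]
        ]
        return cls(seed=d["seed"], patients=patients,
                   signals={k: [tuple(o) for o in v]
                            for k, v in d["signals"].items()},
                   vent={int(k): [tuple(w) for w in v]
                         for k, v in d["vent"].items()},
                   sep3_onset={int(k): v for k, v in d["sep3_onset"].items()})


# planted signal inventory ---------------------------------------------------

VITALS = ("hr", "sbp", "dbp", "map", "temp", "resp", "o2sat")
LABS = ("lact", "bili", "crea", "plt", "wbc", "na", "k", "cl", "bicar",
        "glu", "po2")
GCS = ("egcs", "mgcs", "vgcs", "tgcs")

#: canonical unit written into EAV unit columns (creatinine is stored in
#: umol/L by the eav_relative dialect and reconverted at load time)
UNITS = {
    "hr": "bpm", "sbp": "mmHg", "dbp": "mmHg", "map": "mmHg", "temp": "C",
    "resp": "/min", "o2sat": "%", "fio2": "%", "po2": "mmHg",
    "lact": "mmol/L", "bili": "mg/dL", "crea": "mg/dL", "plt": "K/uL",
    "wbc": "K/uL", "na": "mEq/L", "k": "mEq/L", "cl": "mEq/L",
    "bicar": "mEq/L", "glu": "mg/dL", "urine": "mL", "ins": "U",
    "egcs": "", "mgcs": "", "vgcs": "", "tgcs": "",
}

ICD_POOL = ("4019", "41401", "5849", "42731", "2501", "486", "5990",
            "25000", "250.13", "25060", "V4581")

# item-code maps per dialect (shared with the shipped dictionary)

EAV_ABS_IDS = {
    "hr": [211, 220045], "sbp": [51], "dbp": [8368], "map": [52],
    "temp": [678], "resp": [618], "o2sat": [646], "fio2": [190],
    "egcs": [184], "mgcs": [454], "vgcs": [723], "tgcs": [198],
    "lact": [50813], "bili": [50885], "crea": [50912], "plt": [51265],
    "wbc": [51301], "na": [50983], "k": [50971], "cl": [50902],
    "bicar": [50882], "glu": [50931], "po2": [50821],
    "ins": [30045], "abx": [225798], "urine": [40055], "mech_vent": [467],
}

WIDE_COLS = {
    "hr": "heartrate", "sbp": "sbp", "dbp": "dbp", "map": "map",
    "temp": "temperature", "resp": "respiration", "o2sat": "spo2",
    "fio2": "fio2", "egcs": "gcs_eye", "mgcs": "gcs_motor",
    "vgcs": "gcs_verbal", "tgcs": "gcs_total",
}

WIDE_LABNAMES = {
    "lact": "lactate", "bili": "bilirubin", "crea": "creatinine",
    "plt": "platelets", "wbc": "WBC", "na": "sodium", "k": "potassium",
    "cl": "chloride", "bicar": "bicarbonate", "glu": "glucose",
    "po2": "paO2",
}

WIDE_DRUGNAMES = {"ins": "insulin", "abx": "cefepime"}

EAV_REL_IDS = {name: 200 + i for i, name in enumerate(
    VITALS + ("fio2",) + GCS + LABS + ("urine",))}
EAV_REL_IDS.update({"ins": 300, "abx": 301})

#: plausibility bounds used by the oracle (mirrors the shipped dictionary)
ORACLE_BOUNDS = {"hr": (0.0, 300.0)}
ORACLE_AGG = {"ins": "sum", "urine": "sum", "abx": "any", "samp": "any"}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(seed: int, n_patients: int) -> CohortTruth:
    """Deterministically generate a ground-truth cohort.

    Patient 1 always has two ICU stays within one hospital stay (this
    exercises the coarse-to-fine ID-conversion ambiguity); roughly 12% of
    patients are septic with a planted suspected-infection onset and a
    platelet-driven SOFA jump of 3 points at the onset hour; about 1% of
    vital-sign rows carry an out-of-bounds artifact (at least one planted
    heart-rate value above 300 whenever heart-rate data exist).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    rng = np.random.default_rng(seed)
    patients: list[PatientTruth] = []
    signals: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in VITALS + LABS + GCS + ("fio2", "urine", "ins",
                                              "abx", "samp")}
    vent: dict[int, list[tuple[int, int]]] = {}
    sep3_onset: dict[int, int] = {}
    next_hadm, next_icu = 5000, 2000
    artifact_planted = False

    for i in range(n_patients):
        pid = 1000 + i
        sex = str(rng.choice(["Male", "Female"]))
        age = int(rng.integers(18, 96))
        height = round(float(rng.normal(170, 10)), 1)
        weight = round(float(rng.normal(78, 15)), 1)
        adm_type = str(rng.choice(["med", "surg", "other"]))
        septic = bool(rng.random() < 0.12) and i != 0
        dies = bool(rng.random() < 0.15)
        n_hosp = 1 if (i == 0 or rng.random() < 0.8) else 2
        t = int(rng.integers(0, 2 * 365 * DAY))
        hosp_stays: list[HospStayTruth] = []
        for hj in range(n_hosp):
            hadm = next_hadm
            next_hadm += 1
            h_admit = t
            n_icu = 2 if (i == 0 and hj == 0) else (
                2 if rng.random() < 0.12 else 1)
            icu_stays: list[IcuStayTruth] = []
            cursor = h_admit + int(rng.integers(0, 720))
            for sk in range(n_icu):
                los = int(np.clip(rng.lognormal(7.4, 0.5), 480, 10080))
                if septic and hj == 0 and sk == 0 and los < 2160:
                    los = 2160 + int(rng.integers(0, 1440))
                icu_stays.append(IcuStayTruth(next_icu, cursor, cursor + los))
                next_icu += 1
                cursor = cursor + los + int(rng.integers(120, 2880))
            h_disch = icu_stays[-1].disch + int(rng.integers(0, 1440))
            n_codes = int(rng.integers(1, 5))
            codes = [str(c) for c in rng.choice(ICD_POOL, size=n_codes,
                                                replace=False)]
            hosp_stays.append(HospStayTruth(hadm, h_admit, h_disch,
                                            icu_stays, codes))
            t = h_disch + int(rng.integers(DAY, 20 * DAY))
        patient = PatientTruth(pid, sex, age, height, weight, adm_type,
                               None, hosp_stays)

        septic_stay = hosp_stays[0].icu_stays[0] if septic else None
        onset = None
        if septic_stay is not None:
            los = septic_stay.disch - septic_stay.admit
            hi = min(los // HOUR - 4, 36)
            onset = HOUR * int(rng.integers(3, hi + 1))
            sep3_onset[septic_stay.icustay_id] = onset
            signals["abx"].append((septic_stay.icustay_id, onset, 1.0))
            signals["samp"].append((septic_stay.icustay_id, onset + 120, 1.0))

        if dies:
            last = hosp_stays[-1].icu_stays[-1]
            los = last.disch - last.admit
            off = int(rng.integers(los // 2, los - 10))
            patient.death = last.admit + off

        for h in hosp_stays:
            for s in h.icu_stays:
                los = s.disch - s.admit
                sid = s.icustay_id
                is_septic_stay = septic_stay is not None and sid == septic_stay.icustay_id
                vt = np.arange(0, los, 30, dtype=int)
                n = len(vt)
                base = {
                    "hr": rng.normal(85, 8), "sbp": rng.normal(120, 12),
                    "dbp": rng.normal(65, 8), "temp": rng.normal(37.0, 0.3),
                    "resp": rng.normal(17, 2), "o2sat": rng.normal(97, 1),
                }
                vals = {
                    "hr": np.clip(base["hr"] + rng.normal(0, 4, n), 40, 180),
                    "sbp": np.clip(base["sbp"] + rng.normal(0, 6, n), 95, 200)
                    if is_septic_stay else
                    np.clip(base["sbp"] + rng.normal(0, 8, n), 60, 200),
                    "dbp": np.clip(base["dbp"] + rng.normal(0, 5, n), 30, 120),
                    "temp": np.clip(base["temp"] + rng.normal(0, 0.2, n),
                                    34.0, 41.0),
                    "resp": np.clip(base["resp"] + rng.normal(0, 2, n), 5, 45),
                    "o2sat": np.clip(base["o2sat"] + rng.normal(0, 1, n),
                                     85, 100),
                }
                if is_septic_stay:
                    vals["map"] = np.clip(rng.normal(85, 4, n), 75, 110)
                else:
                    vals["map"] = np.clip(rng.normal(82, 10, n), 40, 140)
                art = rng.random(n) < 0.01
                hr = np.round(vals["hr"], 1)
                hr[art] = rng.choice([350.0, 320.0, -10.0], size=int(art.sum()),
                                     p=[0.6, 0.2, 0.2])
                if art.any() and (hr[art] > 300).any():
                    artifact_planted = True
                vals["hr"] = hr
                for c in VITALS:
                    arr = np.round(vals[c], 1)
                    signals[c].extend(
                        (sid, int(o), float(v)) for o, v in zip(vt, arr))

                gt = np.arange(60, los, 240, dtype=int)
                if is_septic_stay:
                    e = np.full(len(gt), 4.0)
                    m = np.full(len(gt), 6.0)
                    v = np.full(len(gt), 5.0)
                else:
                    low = rng.random() < 0.2
                    e = np.full(len(gt), 3.0 if low else 4.0)
                    m = np.full(len(gt), 5.0 if low else 6.0)
                    v = np.full(len(gt), 4.0 if low else 5.0)
                for c, arr in (("egcs", e), ("mgcs", m), ("vgcs", v),
                               ("tgcs", e + m + v)):
                    signals[c].extend(
                        (sid, int(o), float(x)) for o, x in zip(gt, arr))

                lt = np.arange(60, los, 480, dtype=int)
                nl = len(lt)
                if is_septic_stay:
                    bili = np.clip(rng.normal(0.5, 0.1, nl), 0.2, 0.9)
                    crea = np.clip(rng.normal(0.8, 0.1, nl), 0.5, 1.1)
                    plt_ = np.where(
                        lt >= onset,
                        np.clip(rng.normal(35, 4, nl), 20, 45),
                        np.clip(rng.normal(250, 20, nl), 180, 320))
                else:
                    bili = np.clip(rng.lognormal(np.log(0.8), 0.5, nl),
                                   0.1, 15)
                    crea = np.clip(rng.lognormal(np.log(1.0), 0.4, nl),
                                   0.2, 8)
                    plt_ = np.clip(rng.normal(240, 70, nl), 20, 900)
                lab_vals = {
                    "bili": np.round(bili, 2), "crea": np.round(crea, 2),
                    "plt": np.round(plt_, 0),
                    "wbc": np.round(np.clip(rng.normal(10, 3, nl), 1, 40), 1),
                    "na": np.round(rng.normal(140, 4, nl), 1),
                    "k": np.round(rng.normal(4.1, 0.5, nl), 2),
                    "cl": np.round(rng.normal(104, 4, nl), 1),
                    "bicar": np.round(rng.normal(24, 3, nl), 1),
                    "glu": np.round(np.clip(rng.normal(130, 40, nl),
                                            50, 500), 0),
                    "po2": np.round(np.clip(rng.normal(95, 15, nl),
                                            50, 250), 1),
                }
                if is_septic_stay and onset is not None and \
                        not (lt == onset).any():
                    # guarantee a low platelet draw exactly at the onset hour
                    lab_vals["plt"] = np.append(lab_vals["plt"],
                                                round(float(np.clip(
                                                    rng.normal(35, 4),
                                                    20, 45)), 0))
                    lt_plt = np.append(lt, onset)
                else:
                    lt_plt = lt
                for c in LABS:
                    if c == "lact":
                        continue
                    tt = lt_plt if c == "plt" else lt
                    signals[c].extend(
                        (sid, int(o), float(v))
                        for o, v in zip(tt, lab_vals[c]))
                keep = rng.random(nl) < 0.6
                lact = np.round(np.clip(rng.lognormal(np.log(1.6), 0.5, nl),
                                        0.4, 18), 1)
                signals["lact"].extend(
                    (sid, int(o), float(v))
                    for o, v, kp in zip(lt, lact, keep) if kp)

                ut = np.arange(30, los, 120, dtype=int)
                uv = np.round(np.clip(rng.normal(100, 40, len(ut)), 0, 500), 0)
                signals["urine"].extend(
                    (sid, int(o), float(v)) for o, v in zip(ut, uv))

                if rng.random() < 0.4:
                    k_ins = int(rng.integers(1, 5))
                    offs = rng.integers(0, min(los, 2820), size=k_ins)
                    amts = rng.choice([2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 15.0,
                                       20.0], size=k_ins)
                    signals["ins"].extend(
                        (sid, int(o), float(a)) for o, a in zip(offs, amts))

                if not is_septic_stay and rng.random() < 0.25:
                    start = int(rng.integers(0, max(1, los // 3)))
                    dur = int(rng.integers(600, max(601, int(los * 0.6))))
                    dur = min(dur, los - start - 1)
                    vent.setdefault(sid, []).append((start, dur))
                    ft = np.arange(start, start + dur + 1, 360, dtype=int)
                    fv = rng.choice([40.0, 50.0, 60.0], size=len(ft))
                    signals["fio2"].extend(
                        (sid, int(o), float(v)) for o, v in zip(ft, fv))

        patients.append(patient)

    if not artifact_planted and signals["hr"]:
        sid, off, _ = signals["hr"][0]
        signals["hr"][0] = (sid, off, 350.0)

    return CohortTruth(seed=seed, patients=patients, signals=signals,
                       vent=vent, sep3_onset=sep3_onset)


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def _agg_oracle(concept: str, values: list[float]):
    kind = ORACLE_AGG.get(concept, "median")
    if kind == "sum":
        return float(np.sum(values))
    if kind == "any":
        return True
    return float(np.median(values))


def truth_lookup(truth: CohortTruth, concept_name: str, id_value: int,
                 interval: int = 60):
    """The expected harmonized series for one ICU stay, computed from the
    planted truth alone (bounds filtering plus the concept's declared
    aggregation on the binned grid) -- an engine-independent oracle.

    Time-stamped concepts return a ``{bin_offset: value}`` dict; static
    concepts return a scalar (``None`` when nothing applies).
    """
    index = truth.stay_index()
    if id_value not in index:
        raise KeyError(f"unknown icustay id {id_value}")
    patient, hosp, stay = index[id_value]

    if concept_name in truth.signals:
        obs = [(o, v) for sid, o, v in truth.signals[concept_name]
               if sid == id_value]
        lo, hi = ORACLE_BOUNDS.get(concept_name, (-np.inf, np.inf))
        obs = [(o, v) for o, v in obs if lo <= v <= hi]
        bins: dict[int, list[float]] = {}
        for o, v in obs:
            bins.setdefault((o // interval) * interval, []).append(v)
        return {b: _agg_oracle(concept_name, vs)
                for b, vs in sorted(bins.items())}
    if concept_name == "death":
        if patient.death is not None and stay.admit <= patient.death < stay.disch:
            return {(patient.death - stay.admit) // interval * interval: True}
        return {}
    if concept_name == "diab":
        return any(DIAB_RE.match(c) for c in hosp.icd_codes) or None
    if concept_name == "dka":
        return any(DKA_RE.match(c) for c in hosp.icd_codes) or None
    if concept_name == "ins24":
        events = [(o, v) for sid, o, v in truth.signals["ins"]
                  if sid == id_value and 0 <= (o // interval) * interval <= DAY]
        if not events:
            return None
        total = float(np.sum([v for _, v in events]))
        return cut_insulin(pd.Series([total])).iloc[0]
    if concept_name == "sep3":
        onset = truth.sep3_onset.get(id_value)
        if onset is None:
            return {}
        return {(onset // interval) * interval: True}
    if concept_name == "mech_vent":
        return dict.fromkeys(
            ((s // interval) * interval for s, _ in truth.vent.get(id_value, [])),
            "invasive")
    raise KeyError(f"no planted truth for concept {concept_name!r}")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _iso(minutes: int) -> str:
    return (SIM_T0 + pd.Timedelta(minutes=int(minutes))).strftime(
        "%Y-%m-%dT%H:%M:%S")


def _round_days(minutes: int) -> float:
    return round(minutes / DAY, 3)


def _write(out_dir: Path, name: str, df: pd.DataFrame) -> None:
    df.to_csv(out_dir / f"{name}.csv", index=False)


def _config_eav_absolute() -> dict:
    def tbl(name, cols, **defaults):
        return {"name": name, "file": f"{name}.csv",
                "columns": [{"name": n, "type": t} for n, t in cols],
                "defaults": defaults}

    return {
        "name": "eav_absolute",
        "time_mode": "absolute",
        "id_systems": [
            {"name": "patient", "id_column": "subject_id",
             "origin_table": "patients", "start_column": "first_admittime",
             "rank": 1},
            {"name": "hadm", "id_column": "hadm_id",
             "origin_table": "admissions", "start_column": "admittime",
             "end_column": "dischtime", "rank": 2},
            {"name": "icustay", "id_column": "icustay_id",
             "origin_table": "icustays", "start_column": "intime",
             "end_column": "outtime", "rank": 3},
        ],
        "tables": [
            tbl("patients", [("subject_id", "id"), ("sex", "string"),
                             ("age", "number"), ("height", "number"),
                             ("weight", "number"),
                             ("first_admittime", "timestamp")],
                id_column="subject_id"),
            tbl("admissions", [("subject_id", "id"), ("hadm_id", "id"),
                               ("admittime", "timestamp"),
                               ("dischtime", "timestamp"),
                               ("deathtime", "timestamp"),
                               ("los_days", "number"),
                               ("admission_type", "string")],
                id_column="hadm_id"),
            tbl("icustays", [("subject_id", "id"), ("hadm_id", "id"),
                             ("icustay_id", "id"), ("intime", "timestamp"),
                             ("outtime", "timestamp"),
                             ("los_days", "number")],
                id_column="icustay_id"),
            tbl("chartevents", [("icustay_id", "id"),
                                ("charttime", "timestamp"),
                                ("itemid", "id"), ("valuenum", "number"),
                                ("valueuom", "string")],
                id_column="icustay_id", index_column="charttime",
                value_column="valuenum", unit_column="valueuom"),
            tbl("labevents", [("hadm_id", "id"), ("charttime", "timestamp"),
                              ("itemid", "id"), ("valuenum", "number"),
                              ("valueuom", "string")],
                id_column="hadm_id", index_column="charttime",
                value_column="valuenum", unit_column="valueuom"),
            tbl("inputevents", [("icustay_id", "id"),
                                ("starttime", "timestamp"), ("itemid", "id"),
                                ("amount", "number"),
                                ("amountuom", "string")],
                id_column="icustay_id", index_column="starttime",
                value_column="amount", unit_column="amountuom"),
            tbl("outputevents", [("icustay_id", "id"),
                                 ("charttime", "timestamp"),
                                 ("itemid", "id"), ("value", "number"),
                                 ("valueuom", "string")],
                id_column="icustay_id", index_column="charttime",
                value_column="value", unit_column="valueuom"),
            tbl("microbiologyevents", [("hadm_id", "id"),
                                       ("charttime", "timestamp"),
                                       ("spec_type", "string")],
                id_column="hadm_id", index_column="charttime",
                value_column="spec_type"),
            tbl("diagnoses_icd", [("hadm_id", "id"),
                                  ("icd9_code", "string")],
                id_column="hadm_id", value_column="icd9_code"),
            tbl("procedureevents", [("icustay_id", "id"),
                                    ("starttime", "timestamp"),
                                    ("duration", "duration"),
                                    ("itemid", "id"),
                                    ("ventmode", "string")],
                id_column="icustay_id", index_column="starttime",
                value_column="ventmode", dur_column="duration"),
        ],
    }


def _render_eav_absolute(truth: CohortTruth, out_dir: Path) -> dict:
    pats, adms, icus = [], [], []
    chart, lab, inp, outp, micro, diag, proc = [], [], [], [], [], [], []
    for p in truth.patients:
        pats.append((p.patient_id, p.sex, p.age, p.height, p.weight,
                     _iso(p.hosp_stays[0].admit)))
        for h in p.hosp_stays:
            death = ""
            if p.death is not None and h.admit <= p.death <= h.disch:
                death = _iso(p.death)
            adms.append((p.patient_id, h.hadm_id, _iso(h.admit),
                         _iso(h.disch), death,
                         _round_days(h.disch - h.admit), p.adm_type))
            for code in h.icd_codes:
                diag.append((h.hadm_id, code))
            for s in h.icu_stays:
                icus.append((p.patient_id, h.hadm_id, s.icustay_id,
                             _iso(s.admit), _iso(s.disch),
                             _round_days(s.disch - s.admit)))
    index = truth.stay_index()

    def abs_time(sid, off):
        return _iso(index[sid][2].admit + off)

    for c in VITALS + GCS + ("fio2",):
        ids = EAV_ABS_IDS[c]
        for row_i, (sid, off, v) in enumerate(truth.signals[c]):
            chart.append((sid, abs_time(sid, off), ids[row_i % len(ids)],
                          v, UNITS[c]))
    for c in LABS:
        iid = EAV_ABS_IDS[c][0]
        for sid, off, v in truth.signals[c]:
            lab.append((index[sid][1].hadm_id, abs_time(sid, off), iid, v,
                        UNITS[c]))
    for sid, off, v in truth.signals["ins"]:
        inp.append((sid, abs_time(sid, off), EAV_ABS_IDS["ins"][0], v, "U"))
    for sid, off, v in truth.signals["abx"]:
        inp.append((sid, abs_time(sid, off), EAV_ABS_IDS["abx"][0], 1.0,
                    "dose"))
    for sid, off, v in truth.signals["urine"]:
        outp.append((sid, abs_time(sid, off), EAV_ABS_IDS["urine"][0], v,
                     "mL"))
    for sid, off, v in truth.signals["samp"]:
        micro.append((index[sid][1].hadm_id, abs_time(sid, off),
                      "Blood Culture"))
    for sid, wins in truth.vent.items():
        for start, dur in wins:
            proc.append((sid, abs_time(sid, start), dur,
                         EAV_ABS_IDS["mech_vent"][0], "invasive"))

    _write(out_dir, "patients", pd.DataFrame(
        pats, columns=["subject_id", "sex", "age", "height", "weight",
                       "first_admittime"]))
    _write(out_dir, "admissions", pd.DataFrame(
        adms, columns=["subject_id", "hadm_id", "admittime", "dischtime",
                       "deathtime", "los_days", "admission_type"]))
    _write(out_dir, "icustays", pd.DataFrame(
        icus, columns=["subject_id", "hadm_id", "icustay_id", "intime",
                       "outtime", "los_days"]))
    _write(out_dir, "chartevents", pd.DataFrame(
        chart, columns=["icustay_id", "charttime", "itemid", "valuenum",
                        "valueuom"]))
    _write(out_dir, "labevents", pd.DataFrame(
        lab, columns=["hadm_id", "charttime", "itemid", "valuenum",
                      "valueuom"]))
    _write(out_dir, "inputevents", pd.DataFrame(
        inp, columns=["icustay_id", "starttime", "itemid", "amount",
                      "amountuom"]))
    _write(out_dir, "outputevents", pd.DataFrame(
        outp, columns=["icustay_id", "charttime", "itemid", "value",
                       "valueuom"]))
    _write(out_dir, "microbiologyevents", pd.DataFrame(
        micro, columns=["hadm_id", "charttime", "spec_type"]))
    _write(out_dir, "diagnoses_icd", pd.DataFrame(
        diag, columns=["hadm_id", "icd9_code"]))
    _write(out_dir, "procedureevents", pd.DataFrame(
        proc, columns=["icustay_id", "starttime", "duration", "itemid",
                       "ventmode"]))
    return _config_eav_absolute()


def _config_wide_relative() -> dict:
    def tbl(name, cols, **defaults):
        return {"name": name, "file": f"{name}.csv",
                "columns": [{"name": n, "type": t} for n, t in cols],
                "defaults": defaults}

    wide_cols = [(c, "number") for c in WIDE_COLS.values()]
    return {
        "name": "wide_relative",
        "time_mode": "relative",
        "id_systems": [
            {"name": "icustay", "id_column": "patientunitstayid",
             "origin_table": "patient", "rank": 1},
        ],
        "tables": [
            tbl("patient", [("patientunitstayid", "id"),
                            ("gender", "string"), ("age", "number"),
                            ("admissionheight", "number"),
                            ("admissionweight", "number"),
                            ("admissiontype", "string"),
                            ("unitdischargeoffset", "duration"),
                            ("deathoffset", "timestamp"),
                            ("icu_los_days", "number"),
                            ("hosp_los_days", "number")],
                id_column="patientunitstayid"),
            tbl("vitalperiodic", [("patientunitstayid", "id"),
                                  ("observationoffset", "timestamp")]
                + wide_cols,
                id_column="patientunitstayid",
                index_column="observationoffset"),
            tbl("lab", [("patientunitstayid", "id"),
                        ("labresultoffset", "timestamp"),
                        ("labname", "string"), ("labresult", "number")],
                id_column="patientunitstayid",
                index_column="labresultoffset", value_column="labresult"),
            tbl("nursecharting", [("patientunitstayid", "id"),
                                  ("nursingchartoffset", "timestamp"),
                                  ("nursingchartcelltypevalname", "string"),
                                  ("nursingchartvalue", "number")],
                id_column="patientunitstayid",
                index_column="nursingchartoffset",
                value_column="nursingchartvalue"),
            tbl("infusiondrug", [("patientunitstayid", "id"),
                                 ("drugstartoffset", "timestamp"),
                                 ("drugname", "string"),
                                 ("drugamount", "number")],
                id_column="patientunitstayid",
                index_column="drugstartoffset", value_column="drugamount"),
            tbl("intakeoutput", [("patientunitstayid", "id"),
                                 ("intakeoutputoffset", "timestamp"),
                                 ("celllabel", "string"),
                                 ("cellvaluenumeric", "number")],
                id_column="patientunitstayid",
                index_column="intakeoutputoffset",
                value_column="cellvaluenumeric"),
            tbl("microlab", [("patientunitstayid", "id"),
                             ("culturetakenoffset", "timestamp"),
                             ("culturesite", "string")],
                id_column="patientunitstayid",
                index_column="culturetakenoffset",
                value_column="culturesite"),
            tbl("diagnosis", [("patientunitstayid", "id"),
                              ("icd9code", "string")],
                id_column="patientunitstayid", value_column="icd9code"),
            tbl("respiratorycare", [("patientunitstayid", "id"),
                                    ("ventstartoffset", "timestamp"),
                                    ("ventduration", "duration"),
                                    ("ventmode", "string")],
                id_column="patientunitstayid",
                index_column="ventstartoffset", value_column="ventmode",
                dur_column="ventduration"),
        ],
    }


def _render_wide_relative(truth: CohortTruth, out_dir: Path) -> dict:
    index = truth.stay_index()
    pat_rows = []
    for p, h, s in truth.stays():
        death = ""
        if p.death is not None and s.admit <= p.death < s.disch:
            death = p.death - s.admit
        pat_rows.append((s.icustay_id, p.sex, p.age, p.height, p.weight,
                         p.adm_type, s.disch - s.admit, death,
                         _round_days(s.disch - s.admit),
                         _round_days(h.disch - h.admit)))
    # wide periodic table: one row per (stay, offset) carrying every
    # vital-ish observation at that offset
    cells: dict[tuple[int, int], dict[str, float]] = {}
    for c, col in WIDE_COLS.items():
        for sid, off, v in truth.signals[c]:
            cells.setdefault((sid, off), {})[col] = v
    vp_rows = []
    for (sid, off), d in sorted(cells.items()):
        vp_rows.append({"patientunitstayid": sid, "observationoffset": off,
                        **d})
    lab_rows = [(sid, off, WIDE_LABNAMES[c], v)
                for c in LABS for sid, off, v in truth.signals[c]]
    drug_rows = [(sid, off, WIDE_DRUGNAMES["ins"], v)
                 for sid, off, v in truth.signals["ins"]]
    drug_rows += [(sid, off, WIDE_DRUGNAMES["abx"], 1.0)
                  for sid, off, v in truth.signals["abx"]]
    io_rows = [(sid, off, "Urine", v)
               for sid, off, v in truth.signals["urine"]]
    micro_rows = [(sid, off, "Blood Culture")
                  for sid, off, v in truth.signals["samp"]]
    diag_rows = [(s.icustay_id, code)
                 for p, h, s in truth.stays() for code in h.icd_codes]
    resp_rows = [(sid, start, dur, "invasive")
                 for sid, wins in truth.vent.items()
                 for start, dur in wins]

    _write(out_dir, "patient", pd.DataFrame(
        pat_rows, columns=["patientunitstayid", "gender", "age",
                           "admissionheight", "admissionweight",
                           "admissiontype", "unitdischargeoffset",
                           "deathoffset", "icu_los_days", "hosp_los_days"]))
    vp = pd.DataFrame(vp_rows, columns=["patientunitstayid",
                                        "observationoffset"]
                      + list(WIDE_COLS.values()))
    _write(out_dir, "vitalperiodic", vp)
    _write(out_dir, "lab", pd.DataFrame(
        lab_rows, columns=["patientunitstayid", "labresultoffset",
                           "labname", "labresult"]))
    _write(out_dir, "nursecharting", pd.DataFrame(
        [], columns=["patientunitstayid", "nursingchartoffset",
                     "nursingchartcelltypevalname", "nursingchartvalue"]))
    _write(out_dir, "infusiondrug", pd.DataFrame(
        drug_rows, columns=["patientunitstayid", "drugstartoffset",
                            "drugname", "drugamount"]))
    _write(out_dir, "intakeoutput", pd.DataFrame(
        io_rows, columns=["patientunitstayid", "intakeoutputoffset",
                          "celllabel", "cellvaluenumeric"]))
    _write(out_dir, "microlab", pd.DataFrame(
        micro_rows, columns=["patientunitstayid", "culturetakenoffset",
                             "culturesite"]))
    _write(out_dir, "diagnosis", pd.DataFrame(
        diag_rows, columns=["patientunitstayid", "icd9code"]))
    _write(out_dir, "respiratorycare", pd.DataFrame(
        resp_rows, columns=["patientunitstayid", "ventstartoffset",
                            "ventduration", "ventmode"]))
    return _config_wide_relative()


def _config_eav_relative() -> dict:
    def tbl(name, cols, **defaults):
        return {"name": name, "file": f"{name}.csv",
                "columns": [{"name": n, "type": t} for n, t in cols],
                "defaults": defaults}

    return {
        "name": "eav_relative",
        "time_mode": "relative",
        "id_systems": [
            {"name": "icustay", "id_column": "admissionid",
             "origin_table": "general", "rank": 1},
        ],
        "tables": [
            tbl("general", [("admissionid", "id"), ("sex", "string"),
                            ("age", "number"), ("height", "number"),
                            ("weight", "number"),
                            ("admissiontype", "string"),
                            ("dischargeoffset", "duration"),
                            ("deathoffset", "timestamp"),
                            ("icu_los_days", "number"),
                            ("hosp_los_days", "number")],
                id_column="admissionid"),
            tbl("observations", [("admissionid", "id"),
                                 ("measuredat", "timestamp"),
                                 ("itemid", "id"), ("value", "number"),
                                 ("unit", "string")],
                id_column="admissionid", index_column="measuredat",
                value_column="value", unit_column="unit"),
            tbl("drugitems", [("admissionid", "id"), ("start", "timestamp"),
                              ("itemid", "id"), ("dose", "number")],
                id_column="admissionid", index_column="start",
                value_column="dose"),
            tbl("diagnoses", [("admissionid", "id"),
                              ("icd9code", "string")],
                id_column="admissionid", value_column="icd9code"),
            tbl("micro", [("admissionid", "id"),
                          ("measuredat", "timestamp"), ("site", "string")],
                id_column="admissionid", index_column="measuredat",
                value_column="site"),
            tbl("ventilation", [("admissionid", "id"),
                                ("start", "timestamp"),
                                ("duration", "duration"),
                                ("mode", "string")],
                id_column="admissionid", index_column="start",
                value_column="mode", dur_column="duration"),
        ],
    }


def _render_eav_relative(truth: CohortTruth, out_dir: Path) -> dict:
    gen_rows = []
    for p, h, s in truth.stays():
        death = ""
        if p.death is not None and s.admit <= p.death < s.disch:
            death = p.death - s.admit
        gen_rows.append((s.icustay_id, p.sex, p.age, p.height, p.weight,
                         p.adm_type, s.disch - s.admit, death,
                         _round_days(s.disch - s.admit),
                         _round_days(h.disch - h.admit)))
    obs_rows = []
    for c in VITALS + GCS + ("fio2",) + LABS + ("urine",):
        iid = EAV_REL_IDS[c]
        for sid, off, v in truth.signals[c]:
            if c == "crea":
                obs_rows.append((sid, off, iid, v * 88.42, "umol/L"))
            else:
                obs_rows.append((sid, off, iid, v, UNITS[c]))
    drug_rows = [(sid, off, EAV_REL_IDS["ins"], v)
                 for sid, off, v in truth.signals["ins"]]
    drug_rows += [(sid, off, EAV_REL_IDS["abx"], 1.0)
                  for sid, off, v in truth.signals["abx"]]
    diag_rows = [(s.icustay_id, code)
                 for p, h, s in truth.stays() for code in h.icd_codes]
    micro_rows = [(sid, off, "Blood Culture")
                  for sid, off, v in truth.signals["samp"]]
    vent_rows = [(sid, start, dur, "invasive")
                 for sid, wins in truth.vent.items()
                 for start, dur in wins]

    _write(out_dir, "general", pd.DataFrame(
        gen_rows, columns=["admissionid", "sex", "age", "height", "weight",
                           "admissiontype", "dischargeoffset",
                           "deathoffset", "icu_los_days", "hosp_los_days"]))
    _write(out_dir, "observations", pd.DataFrame(
        obs_rows, columns=["admissionid", "measuredat", "itemid", "value",
                           "unit"]))
    _write(out_dir, "drugitems", pd.DataFrame(
        drug_rows, columns=["admissionid", "start", "itemid", "dose"]))
    _write(out_dir, "diagnoses", pd.DataFrame(
        diag_rows, columns=["admissionid", "icd9code"]))
    _write(out_dir, "micro", pd.DataFrame(
        micro_rows, columns=["admissionid", "measuredat", "site"]))
    _write(out_dir, "ventilation", pd.DataFrame(
        vent_rows, columns=["admissionid", "start", "duration", "mode"]))
    return _config_eav_relative()


_RENDERERS = {
    "eav_absolute": _render_eav_absolute,
    "wide_relative": _render_wide_relative,
    "eav_relative": _render_eav_relative,
}


def render_source(truth: CohortTruth, dialect: str,
                  out_dir: str | Path) -> SourceConfig:
    """Render the truth into one schema dialect: writes the dialect's CSV
    tables plus a matching ``source_config.json`` and returns the parsed
    config."""
    if dialect not in _RENDERERS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {DIALECTS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = _RENDERERS[dialect](truth, out_dir)
    (out_dir / "source_config.json").write_text(json.dumps(doc, indent=1))
    return parse_source_config(doc)
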