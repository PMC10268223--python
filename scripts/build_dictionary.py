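"""Regenerate the shipped concept-dictionary JSON files.

The dictionary ships as static JSON under ``src/icukit/data/dictionary/``;
this script is the single source of truth for its composition (119 concepts:
92 atomic + 27 recursive, Table-2-shaped categories) and for the per-source
extraction items, including the three synthetic dialect sources that the
test fixture renders.  Run from the repository root:

    python scripts/build_dictionary.py
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from icukit.synth import (EAV_ABS_IDS, EAV_REL_IDS, LABS, UNITS,  # noqa: E402
                          WIDE_COLS, WIDE_DRUGNAMES, WIDE_LABNAMES)

OUT_DIR = ROOT / "src" / "icukit" / "data" / "dictionary"

NUM, LGL, FCT, REC = "num_cncpt", "lgl_cncpt", "fct_cncpt", "rec_cncpt"

# name, category, kind, target, unit, (min, max), omopid
ATOMIC = [
    # Vitals
    ("hr", "Vitals", NUM, "ts_tbl", ["bpm", "/min"], (0, 300), 4239408),
    ("sbp", "Vitals", NUM, "ts_tbl", ["mmHg"], (0, 300), None),
    ("dbp", "Vitals", NUM, "ts_tbl", ["mmHg"], (0, 200), None),
    ("map", "Vitals", NUM, "ts_tbl", ["mmHg"], (0, 250), None),
    ("temp", "Vitals", NUM, "ts_tbl", ["C"], (25, 45), None),
    # Respiratory
    ("resp", "Respiratory", NUM, "ts_tbl", ["/min"], (0, 120), None),
    ("o2sat", "Respiratory", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("peep", "Respiratory", NUM, "ts_tbl", ["cmH2O"], (0, 50), None),
    ("tv", "Respiratory", NUM, "ts_tbl", ["mL"], (0, 2000), None),
    ("mv", "Respiratory", NUM, "ts_tbl", ["L/min"], (0, 50), None),
    ("ppeak", "Respiratory", NUM, "ts_tbl", ["cmH2O"], (0, 80), None),
    ("mech_vent", "Respiratory", FCT, "win_tbl", None, None, None),
    # Blood gas
    ("po2", "Blood gas", NUM, "ts_tbl", ["mmHg"], (0, 800), None),
    ("pco2", "Blood gas", NUM, "ts_tbl", ["mmHg"], (0, 200), None),
    ("ph", "Blood gas", NUM, "ts_tbl", None, (6.5, 8.0), None),
    ("be", "Blood gas", NUM, "ts_tbl", ["mEq/L"], (-50, 50), None),
    ("cai", "Blood gas", NUM, "ts_tbl", ["mmol/L"], (0, 5), None),
    ("lact", "Blood gas", NUM, "ts_tbl", ["mmol/L"], (0, 50), 4191725),
    ("methb", "Blood gas", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("sao2", "Blood gas", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("fio2", "Blood gas", NUM, "ts_tbl", ["%"], (21, 100), None),
    # Chemistry
    ("alb", "Chemistry", NUM, "ts_tbl", ["g/dL"], (0, 10), None),
    ("alp", "Chemistry", NUM, "ts_tbl", ["IU/L"], (0, 3000), None),
    ("alt", "Chemistry", NUM, "ts_tbl", ["IU/L"], (0, 10000), None),
    ("ast", "Chemistry", NUM, "ts_tbl", ["IU/L"], (0, 10000), None),
    ("bicar", "Chemistry", NUM, "ts_tbl", ["mEq/L"], (0, 60), None),
    ("bili", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 100), None),
    ("bili_dir", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 50), None),
    ("bun", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 300), None),
    ("ca", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 20), None),
    ("cl", "Chemistry", NUM, "ts_tbl", ["mEq/L"], (0, 200), None),
    ("crea", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 30), None),
    ("glu", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 1500), None),
    ("k", "Chemistry", NUM, "ts_tbl", ["mEq/L"], (0, 15), None),
    ("mg", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 10), None),
    ("na", "Chemistry", NUM, "ts_tbl", ["mEq/L"], (0, 250), None),
    ("phos", "Chemistry", NUM, "ts_tbl", ["mg/dL"], (0, 40), None),
    ("crp", "Chemistry", NUM, "ts_tbl", ["mg/L"], (0, 600), None),
    ("ck", "Chemistry", NUM, "ts_tbl", ["IU/L"], (0, 100000), None),
    ("ckmb", "Chemistry", NUM, "ts_tbl", ["ng/mL"], (0, 1000), None),
    # Hematology
    ("plt", "Hematology", NUM, "ts_tbl", ["K/uL"], (0, 2000), None),
    ("hgb", "Hematology", NUM, "ts_tbl", ["g/dL"], (0, 25), None),
    ("hct", "Hematology", NUM, "ts_tbl", ["%"], (0, 75), None),
    ("wbc", "Hematology", NUM, "ts_tbl", ["K/uL"], (0, 500), None),
    ("rbc", "Hematology", NUM, "ts_tbl", ["m/uL"], (0, 15), None),
    ("mcv", "Hematology", NUM, "ts_tbl", ["fL"], (0, 150), None),
    ("mch", "Hematology", NUM, "ts_tbl", ["pg"], (0, 60), None),
    ("mchc", "Hematology", NUM, "ts_tbl", ["g/dL"], (0, 50), None),
    ("rdw", "Hematology", NUM, "ts_tbl", ["%"], (0, 40), None),
    ("lymph", "Hematology", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("neut", "Hematology", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("baso", "Hematology", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("eos", "Hematology", NUM, "ts_tbl", ["%"], (0, 100), None),
    ("pt", "Hematology", NUM, "ts_tbl", ["sec"], (0, 200), None),
    ("ptt", "Hematology", NUM, "ts_tbl", ["sec"], (0, 250), None),
    ("inr_pt", "Hematology", NUM, "ts_tbl", None, (0, 20), None),
    ("fgn", "Hematology", NUM, "ts_tbl", ["mg/dL"], (0, 1500), None),
    ("esr", "Hematology", NUM, "ts_tbl", ["mm/hr"], (0, 200), None),
    ("bnd", "Hematology", NUM, "ts_tbl", ["%"], (0, 100), None),
    # Neurological
    ("egcs", "Neurological", NUM, "ts_tbl", None, (1, 4), None),
    ("mgcs", "Neurological", NUM, "ts_tbl", None, (1, 6), None),
    ("vgcs", "Neurological", NUM, "ts_tbl", None, (1, 5), None),
    ("tgcs", "Neurological", NUM, "ts_tbl", None, (3, 15), None),
    ("rass", "Neurological", NUM, "ts_tbl", None, (-5, 4), None),
    ("avpu", "Neurological", FCT, "ts_tbl", None, None, None),
    # Output
    ("urine", "Output", NUM, "ts_tbl", ["mL"], (0, 5000), None),
    # Medications
    ("ins", "Medications", NUM, "ts_tbl", ["U", "units"], (0, 1000), None),
    ("abx", "Medications", LGL, "ts_tbl", None, None, None),
    ("norepi_rate", "Medications", NUM, "ts_tbl", ["ug/kg/min"], (0, 5), None),
    ("epi_rate", "Medications", NUM, "ts_tbl", ["ug/kg/min"], (0, 5), None),
    ("dopa_rate", "Medications", NUM, "ts_tbl", ["ug/kg/min"], (0, 50), None),
    ("dobu_rate", "Medications", NUM, "ts_tbl", ["ug/kg/min"], (0, 50), None),
    ("adh_rate", "Medications", NUM, "ts_tbl", ["U/min"], (0, 1), None),
    ("phn_rate", "Medications", NUM, "ts_tbl", ["ug/kg/min"], (0, 20), None),
    ("cort", "Medications", LGL, "ts_tbl", None, None, None),
    ("sed", "Medications", LGL, "ts_tbl", None, None, None),
    ("hep", "Medications", LGL, "ts_tbl", None, None, None),
    ("loop_diur", "Medications", LGL, "ts_tbl", None, None, None),
    ("vanc", "Medications", LGL, "ts_tbl", None, None, None),
    ("kcl", "Medications", LGL, "ts_tbl", None, None, None),
    # Microbiology
    ("samp", "Microbiology", LGL, "ts_tbl", None, None, None),
    # Demographics
    ("age", "Demographics", NUM, "id_tbl", ["years"], (0, 130), None),
    ("sex", "Demographics", FCT, "id_tbl", None, None, 37116947),
    ("height", "Demographics", NUM, "id_tbl", ["cm"], (50, 250), None),
    ("weight", "Demographics", NUM, "id_tbl", ["kg"], (1, 500), None),
    ("adm", "Demographics", FCT, "id_tbl", None, None, None),
    # Outcome
    ("death", "Outcome", LGL, "ts_tbl", None, None, None),
    ("diab", "Outcome", LGL, "id_tbl", None, None, None),
    ("dka", "Outcome", LGL, "id_tbl", None, None, None),
    ("los_icu", "Outcome", NUM, "id_tbl", ["days"], (0, 400), None),
    ("los_hosp", "Outcome", NUM, "id_tbl", ["days"], (0, 1000), None),
    ("dnr", "Outcome", LGL, "id_tbl", None, None, None),
]

LEVELS = {
    "sex": ["Male", "Female"],
    "adm": ["med", "surg", "other"],
    "avpu": ["A", "V", "P", "U"],
    "mech_vent": ["invasive", "noninvasive"],
}

AGGREGATES = {"ins": "sum", "urine": "sum"}

DESCRIPTIONS = {
    "hr": "heart rate", "sbp": "systolic blood pressure",
    "dbp": "diastolic blood pressure", "map": "mean arterial pressure",
    "temp": "body temperature", "resp": "respiratory rate",
    "o2sat": "pulse oximetry oxygen saturation",
    "peep": "positive end-expiratory pressure", "tv": "tidal volume",
    "mv": "minute ventilation", "ppeak": "peak inspiratory pressure",
    "mech_vent": "mechanical ventilation window",
    "po2": "arterial oxygen partial pressure",
    "pco2": "arterial CO2 partial pressure", "ph": "arterial pH",
    "be": "base excess", "cai": "ionized calcium", "lact": "lactate",
    "methb": "methemoglobin", "sao2": "arterial oxygen saturation",
    "fio2": "inspired oxygen fraction", "alb": "albumin",
    "alp": "alkaline phosphatase", "alt": "alanine aminotransferase",
    "ast": "aspartate aminotransferase", "bicar": "bicarbonate",
    "bili": "total bilirubin", "bili_dir": "direct bilirubin",
    "bun": "blood urea nitrogen", "ca": "calcium", "cl": "chloride",
    "crea": "serum creatinine", "glu": "glucose", "k": "potassium",
    "mg": "magnesium", "na": "sodium", "phos": "phosphate",
    "crp": "C-reactive protein", "ck": "creatine kinase",
    "ckmb": "creatine kinase MB", "plt": "platelet count",
    "hgb": "hemoglobin", "hct": "hematocrit", "wbc": "white blood cells",
    "rbc": "red blood cells", "mcv": "mean corpuscular volume",
    "mch": "mean corpuscular hemoglobin",
    "mchc": "mean corpuscular hemoglobin concentration",
    "rdw": "red cell distribution width", "lymph": "lymphocytes",
    "neut": "neutrophils", "baso": "basophils", "eos": "eosinophils",
    "pt": "prothrombin time", "ptt": "partial thromboplastin time",
    "inr_pt": "international normalized ratio", "fgn": "fibrinogen",
    "esr": "erythrocyte sedimentation rate", "bnd": "band neutrophils",
    "egcs": "GCS eye response", "mgcs": "GCS motor response",
    "vgcs": "GCS verbal response", "tgcs": "GCS total (charted)",
    "rass": "Richmond agitation-sedation scale",
    "avpu": "AVPU consciousness scale", "urine": "urine output",
    "ins": "insulin administration", "abx": "antibiotic administration",
    "norepi_rate": "norepinephrine infusion rate",
    "epi_rate": "epinephrine infusion rate",
    "dopa_rate": "dopamine infusion rate",
    "dobu_rate": "dobutamine infusion rate",
    "adh_rate": "vasopressin infusion rate",
    "phn_rate": "phenylephrine infusion rate",
    "cort": "corticosteroid administration",
    "sed": "sedative administration", "hep": "heparin administration",
    "loop_diur": "loop diuretic administration",
    "vanc": "vancomycin administration",
    "kcl": "potassium chloride administration",
    "samp": "body-fluid culture sampling", "age": "patient age",
    "sex": "patient sex", "height": "patient height",
    "weight": "patient weight", "adm": "admission type",
    "death": "in-ICU death", "diab": "diabetes status (ICD-9 250.xx)",
    "dka": "diabetic ketoacidosis (ICD-9 250.1x)",
    "los_icu": "ICU length of stay", "los_hosp": "hospital length of stay",
    "dnr": "do-not-resuscitate order",
}

# name, category, target, depends, callback, aggregate, description
RECURSIVE = [
    ("shock_idx", "Vitals", "ts_tbl", ["hr", "sbp"], "shock_idx_cb", None,
     "shock index (HR/SBP)"),
    ("vent_ind", "Respiratory", "ts_tbl", ["mech_vent"], "vent_ind_cb",
     None, "ventilation indicator"),
    ("supp_o2", "Respiratory", "ts_tbl", ["vent_ind", "fio2"],
     "supp_o2_cb", None, "supplemental oxygen"),
    ("safi", "Respiratory", "ts_tbl", ["o2sat", "fio2"], "safi_cb", None,
     "SpO2/FiO2 ratio"),
    ("pafi", "Blood gas", "ts_tbl", ["po2", "fio2"], "pafi_cb", None,
     "PaO2/FiO2 ratio"),
    ("egfr", "Chemistry", "ts_tbl", ["crea", "age", "sex"], "egfr_cb",
     None, "estimated glomerular filtration rate (MDRD)"),
    ("agap", "Chemistry", "ts_tbl", ["na", "cl", "bicar"], "agap_cb",
     None, "anion gap"),
    ("nlr", "Hematology", "ts_tbl", ["neut", "lymph"], "nlr_cb", None,
     "neutrophil-lymphocyte ratio"),
    ("gcs", "Neurological", "ts_tbl", ["egcs", "mgcs", "vgcs", "tgcs"],
     "gcs_cb", None, "Glasgow Coma Scale total"),
    ("urine24", "Output", "ts_tbl", ["urine"], "urine24_cb", None,
     "urine output over preceding 24 h"),
    ("ins24", "Medications", "id_tbl", ["ins"], "ins24_cb", "sum",
     "insulin in first 24 h, binned"),
    ("vaso_ind", "Medications", "ts_tbl",
     ["norepi_rate", "epi_rate", "dopa_rate", "dobu_rate", "adh_rate",
      "phn_rate"], "vaso_ind_cb", None, "vasopressor indicator"),
    ("norepi_equiv", "Medications", "ts_tbl",
     ["norepi_rate", "epi_rate", "dopa_rate", "phn_rate"],
     "norepi_equiv_cb", None, "norepinephrine-equivalent dose"),
    ("bmi", "Demographics", "id_tbl", ["height", "weight"], "bmi_cb",
     None, "body mass index"),
    ("sofa_resp", "Outcome", "ts_tbl", ["pafi", "vent_ind"],
     "sofa_resp_cb", None, "SOFA respiratory component"),
    ("sofa_coag", "Outcome", "ts_tbl", ["plt"], "sofa_coag_cb", None,
     "SOFA coagulation component"),
    ("sofa_liver", "Outcome", "ts_tbl", ["bili"], "sofa_liver_cb", None,
     "SOFA liver component"),
    ("sofa_cardio", "Outcome", "ts_tbl",
     ["map", "dopa_rate", "dobu_rate", "norepi_rate", "epi_rate"],
     "sofa_cardio_cb", None, "SOFA cardiovascular component"),
    ("sofa_cns", "Outcome", "ts_tbl", ["gcs"], "sofa_cns_cb", None,
     "SOFA central nervous system component"),
    ("sofa_renal", "Outcome", "ts_tbl", ["crea"], "sofa_renal_cb", None,
     "SOFA renal component"),
    ("sofa", "Outcome", "ts_tbl",
     ["sofa_resp", "sofa_coag", "sofa_liver", "sofa_cardio", "sofa_cns",
      "sofa_renal"], "sofa_cb", None, "SOFA total score"),
    ("susp_inf", "Outcome", "ts_tbl", ["abx", "samp"], "susp_inf_cb",
     None, "suspected-infection onset"),
    ("sep3", "Outcome", "ts_tbl", ["sofa", "susp_inf"], "sep3_cb", None,
     "Sepsis-3 label"),
    ("qsofa", "Outcome", "ts_tbl", ["gcs", "sbp", "resp"], "qsofa_cb",
     None, "quick SOFA"),
    ("sirs", "Outcome", "ts_tbl", ["temp", "hr", "resp", "wbc"],
     "sirs_cb", None, "SIRS criteria count"),
    ("news", "Outcome", "ts_tbl", ["resp", "o2sat", "temp", "sbp", "hr"],
     "news_cb", None, "national early warning score"),
    ("mews", "Outcome", "ts_tbl", ["sbp", "hr", "resp", "temp"],
     "mews_cb", None, "modified early warning score"),
]

# per-source gaps realizing the published per-source atomic availability
MISSING = {
    "mimic": {"rass", "avpu", "methb"},
    "eicu": {"methb", "bnd", "esr", "adh_rate", "bili_dir"},
    "aumc": {"esr", "bnd", "rdw", "mch", "mchc", "dka", "dnr"},
    "hirid": {"avpu", "adm", "dnr", "dka", "diab", "los_hosp", "esr",
              "bnd", "baso", "eos", "rdw", "mch", "mchc", "sed", "vanc",
              "kcl", "cort", "hep"},
    "miiv": {"methb", "esr", "avpu", "bnd", "adh_rate"},
}

REAL_TABLES = {"mimic": "chartevents", "eicu": "nursecharting",
               "aumc": "numericitems", "hirid": "observations",
               "miiv": "chartevents"}

GROUPS = {
    "bloodgas": {"Blood gas"},
    "chemistry": {"Chemistry"},
    "hematology": {"Hematology"},
    "neuro_output": {"Neurological", "Output"},
    "respiratory": {"Respiratory"},
    "vitals": {"Vitals"},
    "treatment": {"Medications", "Microbiology"},
    "demographics": {"Demographics"},
    "outcomes": {"Outcome"},
}

SPECIAL = {"sex", "age", "height", "weight", "adm", "death", "los_icu",
           "los_hosp", "diab", "dka", "dnr", "samp", "mech_vent", "avpu"}

ROSTER_INDEX = {name: i for i, (name, *_) in enumerate(ATOMIC)}
PLANTED_CHART = set(WIDE_COLS)
PLANTED_LAB = set(LABS)
LGL_MEDS = {"abx", "cort", "sed", "hep", "loop_diur", "vanc", "kcl"}


def synth_code(name: str) -> int:
    return 90000 + ROSTER_INDEX[name]


def items_eav_absolute(name: str, category: str, kind: str) -> list[dict]:
    if name in SPECIAL:
        return {
            "sex": [{"table": "patients", "class": "col_itm",
                     "val_var": "sex"}],
            "age": [{"table": "patients", "class": "col_itm",
                     "val_var": "age"}],
            "height": [{"table": "patients", "class": "col_itm",
                        "val_var": "height"}],
            "weight": [{"table": "patients", "class": "col_itm",
                        "val_var": "weight"}],
            "adm": [{"table": "admissions", "class": "col_itm",
                     "val_var": "admission_type"}],
            "death": [{"table": "admissions", "class": "col_itm",
                       "val_var": "deathtime", "index_var": "deathtime",
                       "callback": "set_true"}],
            "los_icu": [{"table": "icustays", "class": "col_itm",
                         "val_var": "los_days"}],
            "los_hosp": [{"table": "admissions", "class": "col_itm",
                          "val_var": "los_days"}],
            "diab": [{"table": "diagnoses_icd", "class": "col_itm",
                      "callback": "transform_fun(grep_diab)"}],
            "dka": [{"table": "diagnoses_icd", "class": "col_itm",
                     "callback": "transform_fun(grep_dka)"}],
            "dnr": [{"table": "chartevents", "sub_var": "itemid",
                     "ids": [synth_code("dnr")], "callback": "set_true"}],
            "samp": [{"table": "microbiologyevents", "class": "col_itm",
                      "callback": "set_true"}],
            "mech_vent": [{"table": "procedureevents", "sub_var": "itemid",
                           "ids": EAV_ABS_IDS["mech_vent"]}],
            "avpu": [{"table": "chartevents", "sub_var": "itemid",
                      "ids": [synth_code("avpu")]}],
        }[name]
    if name in EAV_ABS_IDS:
        if name in PLANTED_CHART:
            table = "chartevents"
        elif name in PLANTED_LAB:
            table = "labevents"
        elif name == "urine":
            table = "outputevents"
        else:
            table = "inputevents"
        item = {"table": table, "sub_var": "itemid",
                "ids": EAV_ABS_IDS[name]}
    elif category == "Medications":
        item = {"table": "inputevents", "sub_var": "itemid",
                "ids": [synth_code(name)]}
    elif category in ("Blood gas", "Chemistry", "Hematology"):
        item = {"table": "labevents", "sub_var": "itemid",
                "ids": [synth_code(name)]}
    else:
        item = {"table": "chartevents", "sub_var": "itemid",
                "ids": [synth_code(name)]}
    if kind == LGL:
        item["callback"] = "set_true"
    return [item]


def items_wide_relative(name: str, category: str, kind: str) -> list[dict]:
    if name in SPECIAL:
        return {
            "sex": [{"table": "patient", "class": "col_itm",
                     "val_var": "gender"}],
            "age": [{"table": "patient", "class": "col_itm",
                     "val_var": "age"}],
            "height": [{"table": "patient", "class": "col_itm",
                        "val_var": "admissionheight"}],
            "weight": [{"table": "patient", "class": "col_itm",
                        "val_var": "admissionweight"}],
            "adm": [{"table": "patient", "class": "col_itm",
                     "val_var": "admissiontype"}],
            "death": [{"table": "patient", "class": "col_itm",
                       "val_var": "deathoffset",
                       "index_var": "deathoffset",
                       "callback": "set_true"}],
            "los_icu": [{"table": "patient", "class": "col_itm",
                         "val_var": "icu_los_days"}],
            "los_hosp": [{"table": "patient", "class": "col_itm",
                          "val_var": "hosp_los_days"}],
            "diab": [{"table": "diagnosis", "class": "col_itm",
                      "callback": "transform_fun(grep_diab)"}],
            "dka": [{"table": "diagnosis", "class": "col_itm",
                     "callback": "transform_fun(grep_dka)"}],
            "dnr": [{"table": "nursecharting",
                     "sub_var": "nursingchartcelltypevalname",
                     "ids": ["dnr"], "callback": "set_true"}],
            "samp": [{"table": "microlab", "class": "col_itm",
                      "callback": "set_true"}],
            "mech_vent": [{"table": "respiratorycare",
                           "class": "col_itm"}],
            "avpu": [{"table": "nursecharting",
                      "sub_var": "nursingchartcelltypevalname",
                      "ids": ["avpu"]}],
        }[name]
    if name in WIDE_COLS:
        return [{"table": "vitalperiodic", "class": "col_itm",
                 "val_var": WIDE_COLS[name]}]
    if name in WIDE_LABNAMES:
        return [{"table": "lab", "sub_var": "labname",
                 "ids": [WIDE_LABNAMES[name]]}]
    if name == "urine":
        return [{"table": "intakeoutput", "sub_var": "celllabel",
                 "ids": ["Urine"]}]
    if category == "Medications":
        item = {"table": "infusiondrug", "sub_var": "drugname",
                "ids": [WIDE_DRUGNAMES.get(name, name)]}
    elif category in ("Blood gas", "Chemistry", "Hematology"):
        item = {"table": "lab", "sub_var": "labname", "ids": [name]}
    else:
        item = {"table": "nursecharting",
                "sub_var": "nursingchartcelltypevalname", "ids": [name]}
    if kind == LGL:
        item["callback"] = "set_true"
    return [item]


def items_eav_relative(name: str, category: str, kind: str) -> list[dict]:
    if name in SPECIAL:
        return {
            "sex": [{"table": "general", "class": "col_itm",
                     "val_var": "sex"}],
            "age": [{"table": "general", "class": "col_itm",
                     "val_var": "age"}],
            "height": [{"table": "general", "class": "col_itm",
                        "val_var": "height"}],
            "weight": [{"table": "general", "class": "col_itm",
                        "val_var": "weight"}],
            "adm": [{"table": "general", "class": "col_itm",
                     "val_var": "admissiontype"}],
            "death": [{"table": "general", "class": "col_itm",
                       "val_var": "deathoffset",
                       "index_var": "deathoffset",
                       "callback": "set_true"}],
            "los_icu": [{"table": "general", "class": "col_itm",
                         "val_var": "icu_los_days"}],
            "los_hosp": [{"table": "general", "class": "col_itm",
                          "val_var": "hosp_los_days"}],
            "diab": [{"table": "diagnoses", "class": "col_itm",
                      "callback": "transform_fun(grep_diab)"}],
            "dka": [{"table": "diagnoses", "class": "col_itm",
                     "callback": "transform_fun(grep_dka)"}],
            "dnr": [{"table": "observations", "sub_var": "itemid",
                     "ids": [synth_code("dnr")], "callback": "set_true"}],
            "samp": [{"table": "micro", "class": "col_itm",
                      "callback": "set_true"}],
            "mech_vent": [{"table": "ventilation", "class": "col_itm"}],
            "avpu": [{"table": "observations", "sub_var": "itemid",
                      "ids": [synth_code("avpu")]}],
        }[name]
    if category == "Medications":
        item = {"table": "drugitems", "sub_var": "itemid",
                "ids": [EAV_REL_IDS.get(name, synth_code(name))]}
    else:
        item = {"table": "observations", "sub_var": "itemid",
                "ids": [EAV_REL_IDS.get(name, synth_code(name))]}
    if kind == LGL:
        item["callback"] = "set_true"
    return [item]


def real_source_items(src: str, name: str, kind: str) -> list[dict]:
    code = 10_000 * (list(MISSING).index(src) + 1) + ROSTER_INDEX[name]
    item = {"table": REAL_TABLES[src], "sub_var": "itemid", "ids": [code]}
    if kind == LGL:
        item["callback"] = "set_true"
    return [item]


def build() -> dict[str, dict]:
    docs: dict[str, dict] = {g: {} for g in GROUPS}

    def group_of(category: str) -> str:
        for g, cats in GROUPS.items():
            if category in cats:
                return g
        raise ValueError(category)

    for name, category, kind, target, unit, bounds, omopid in ATOMIC:
        body: dict = {"class": kind, "category": category,
                      "description": DESCRIPTIONS[name], "target": target}
        if unit:
            body["unit"] = unit
        if bounds:
            body["min"], body["max"] = bounds
        if omopid:
            body["omopid"] = omopid
        if name in LEVELS:
            body["levels"] = LEVELS[name]
        if name in AGGREGATES:
            body["aggregate"] = AGGREGATES[name]
        sources = {
            "eav_absolute": items_eav_absolute(name, category, kind),
            "wide_relative": items_wide_relative(name, category, kind),
            "eav_relative": items_eav_relative(name, category, kind),
        }
        for src in MISSING:
            if name not in MISSING[src]:
                sources[src] = real_source_items(src, name, kind)
        body["sources"] = sources
        docs[group_of(category)][name] = body

    for name, category, target, depends, callback, agg, desc in RECURSIVE:
        body = {"class": REC, "category": category, "description": desc,
                "target": target, "concepts": depends,
                "callback": callback}
        if agg:
            body["aggregate"] = agg
        if name == "mech_vent":
            body["levels"] = LEVELS[name]
        docs[group_of(category)][name] = body

    return docs


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    docs = build()
    for group, doc in docs.items():
        path = OUT_DIR / f"{group}.json"
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        print(f"wrote {path} ({len(doc)} concepts, "
              f"{path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
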