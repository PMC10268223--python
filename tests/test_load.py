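"""The load_concepts engine: items, units, bounds, ID conversion,
aggregation, recursion."""

import numpy as np
import pandas as pd
import pytest

from helpers import series_of
from icukit import change_id
from icukit.concepts import Concept, Item, parse_dictionary
from icukit.errors import (AvailabilityError, ConceptLookupError,
                           ExtractionError)
from icukit.load import (LoadRequest, enforce_bounds, harmonize_units,
                         load_atomic_concept, load_concepts, load_item)
from icukit.synth import truth_lookup
from icukit.tabular import TsTbl, WinTbl


def hr_concept(dictionary):
    return dictionary.find("hr")


# -- load_item ---------------------------------------------------------------


def test_load_item_filters_by_itemid(small_truth, small_handle, dictionary):
    item = hr_concept(dictionary).sources["eav_absolute"][0]
    rows = load_item(small_handle, item, concept="hr")
    assert len(rows) == len(small_truth.signals["hr"])
    assert set(rows.columns) >= {"id", "time", "value", "unit"}


def test_load_item_col_itm_with_transform(small_truth, small_handle,
                                          dictionary):
    item = dictionary.find("diab").sources["eav_absolute"][0]
    rows = load_item(small_handle, item, concept="diab")
    diags = small_handle.table("diagnoses_icd")
    assert len(rows) == len(diags)
    assert rows["value"].map(lambda v: isinstance(v, (bool, np.bool_))).all()


def test_load_item_no_match_warns_and_returns_empty(small_handle, caplog):
    item = Item(table="chartevents", sub_var="itemid", ids=[987654])
    with caplog.at_level("WARNING", logger="icukit"):
        rows = load_item(small_handle, item, concept="ghost")
    assert len(rows) == 0
    assert any("no rows match" in r.message for r in caplog.records)


def test_load_item_missing_column_names_item(small_handle):
    item = Item(table="chartevents", sub_var="itemid", ids=[211],
                value_column="nonexistent")
    with pytest.raises(ExtractionError, match="nonexistent"):
        load_item(small_handle, item, concept="hr")


# -- bounds ------------------------------------------------------------------


def _rows(values):
    return pd.DataFrame({"id": 1, "time": range(len(values)),
                         "value": values})


def test_bounds_remove_artifact_values(dictionary):
    out = enforce_bounds(_rows([80.0, 350.0, -10.0]), hr_concept(dictionary))
    assert out["value"].tolist() == [80.0]


def test_bounds_are_inclusive(dictionary):
    out = enforce_bounds(_rows([0.0, 300.0]), hr_concept(dictionary))
    assert out["value"].tolist() == [0.0, 300.0]


def test_missing_bounds_are_no_op():
    c = Concept(name="x", kind="num_cncpt",
                sources={"s": [Item(table="t", kind="col_itm")]})
    rows = _rows([1e9, -1e9])
    assert enforce_bounds(rows, c) is rows


# -- units -------------------------------------------------------------------


def test_accepted_unit_passes_unchanged(dictionary):
    rows = _rows([80.0])
    rows["unit"] = "bpm"
    out, flagged = harmonize_units(rows, hr_concept(dictionary))
    assert out["value"].tolist() == [80.0] and not flagged


def test_creatinine_umol_per_l_rescaled(dictionary):
    rows = _rows([88.42])
    rows["unit"] = "umol/L"
    out, flagged = harmonize_units(rows, dictionary.find("crea"))
    assert out["value"].iloc[0] == pytest.approx(1.0)
    assert not flagged


def test_unknown_unit_kept_and_flagged(dictionary, caplog):
    rows = _rows([80.0])
    rows["unit"] = "???"
    with caplog.at_level("WARNING", logger="icukit"):
        out, flagged = harmonize_units(rows, hr_concept(dictionary))
    assert out["value"].tolist() == [80.0]
    assert flagged == ["???"]


# -- atomic pipeline ---------------------------------------------------------


def test_heart_rate_matches_truth_for_every_stay(small_truth, small_handle,
                                                 dictionary):
    res = load_concepts(dictionary, small_handle, ["hr"])
    for sid in small_truth.stay_index():
        expected = truth_lookup(small_truth, "hr", sid)
        got = series_of(res.df, sid, "hr")
        assert got == pytest.approx(expected)


def test_bounds_filter_precedes_aggregation(small_truth, small_handle,
                                            dictionary):
    """A planted 350-bpm artifact must not contaminate the hourly median."""
    sid, off, v = next((s, o, v) for s, o, v in small_truth.signals["hr"]
                       if v > 300)
    res = load_concepts(dictionary, small_handle, ["hr"])
    got = series_of(res.df, sid, "hr")
    assert all(val <= 300 for val in got.values())


def test_sex_loads_as_id_table(small_handle, dictionary):
    res = load_concepts(dictionary, small_handle, ["sex"])
    assert not isinstance(res.table, TsTbl)
    assert set(res.df["sex"]) <= {"Male", "Female"}
    assert res.df["icustay_id"].is_unique


def test_mech_vent_loads_as_win_table(small_truth, small_handle, dictionary):
    res = load_concepts(dictionary, small_handle, ["mech_vent"])
    assert isinstance(res.table, WinTbl)
    n_windows = sum(len(w) for w in small_truth.vent.values())
    assert len(res.df) == n_windows
    assert set(res.df["mech_vent"]) == {"invasive"}


def test_availability_error_names_source(small_handle, dictionary):
    doc = {"exotic": {"class": "num_cncpt",
                      "sources": {"some_other_db": [
                          {"table": "t", "class": "col_itm",
                           "val_var": "v"}]}}}
    d2 = parse_dictionary([dictionary.to_json(), doc])
    with pytest.raises(AvailabilityError, match="eav_absolute"):
        load_concepts(d2, small_handle, ["exotic"])


def test_declared_item_with_no_rows_gives_empty_result(small_handle,
                                                       dictionary):
    # peep is declared for the dialect but the generator plants no data
    res = load_concepts(dictionary, small_handle, ["peep"])
    assert len(res.df) == 0
    assert list(res.df.columns) == ["icustay_id", "charttime", "peep"]


def test_unknown_concepts_listed_together(small_handle, dictionary):
    with pytest.raises(ConceptLookupError) as exc:
        load_concepts(dictionary, small_handle, ["hr", "nope1", "nope2"])
    assert "nope1" in str(exc.value) and "nope2" in str(exc.value)


def test_repeated_loads_are_identical(small_handle, dictionary):
    a = load_concepts(dictionary, small_handle, ["lact", "death"])
    b = load_concepts(dictionary, small_handle, ["lact", "death"])
    assert a.df.to_csv() == b.df.to_csv()


def test_omop_query_names_columns_omop(small_handle, dictionary):
    res = load_concepts(dictionary, small_handle, [4191725, "hr"])
    assert "omop_4191725" in res.df.columns
    assert "hr" in res.df.columns


def test_patient_id_filter_restricts_output(small_truth, small_handle,
                                            dictionary):
    age = load_concepts(dictionary, small_handle, ["age"])
    keep = age.df.loc[(age.df["age"] > 20) & (age.df["age"] < 90),
                      "icustay_id"]
    res = load_concepts(dictionary, small_handle,
                        LoadRequest(concepts=["hr"],
                                    patient_ids=keep.tolist()))
    assert set(res.df["icustay_id"]) <= set(keep)
    assert len(set(res.df["icustay_id"])) == len(set(keep))


def test_aggregate_override_changes_aggregation(small_truth, small_handle,
                                                dictionary):
    res_med = load_concepts(dictionary, small_handle,
                            LoadRequest(concepts=["hr"],
                                        aggregate_overrides={"hr": "max"}))
    res_def = load_concepts(dictionary, small_handle, ["hr"])
    assert (res_med.df["hr"] >= res_def.df["hr"] - 1e-12).all()


def test_multi_concept_merge_shapes(small_handle, dictionary):
    res = load_concepts(dictionary, small_handle, ["lact", "death", "sofa"])
    assert isinstance(res.table, TsTbl)
    assert {"lact", "death", "sofa"} <= set(res.df.columns)


# -- ID-system conversion ----------------------------------------------------


def test_change_id_round_trip_is_identity(small_handle, dictionary):
    hr = load_concepts(dictionary, small_handle, ["hr"]).table
    hadm = change_id(hr, small_handle, "hadm")
    back = change_id(hadm, small_handle, "icustay")
    a = hr.df.sort_values(["icustay_id", "charttime"]).reset_index(drop=True)
    b = back.df.sort_values(["icustay_id", "charttime"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_change_id_drops_out_of_window_rows(small_handle):
    win = small_handle.id_windows()
    row = win.iloc[0]
    df = pd.DataFrame({
        "hadm_id": [int(row["hadm_id"])],
        "charttime": [int(row["icustay_id__start"] - row["hadm_id__start"]
                          - 30)],
        "v": [1.0]})
    tbl = TsTbl(df, id_vars=["hadm_id"], index_var="charttime", interval=1)
    out = change_id(tbl, small_handle, "icustay")
    # event 30 min before any ICU stay of this admission is dropped unless
    # an earlier stay of the same admission covers it
    starts = win[win["hadm_id"] == row["hadm_id"]]
    abs_t = row["hadm_id__start"] + df["charttime"].iloc[0]
    contained = ((starts["icustay_id__start"] <= abs_t)
                 & (abs_t < starts["icustay_id__end"])).any()
    assert (len(out.df) == 1) == bool(contained)


def test_two_stay_admission_assigns_by_containment(small_handle,
                                                   small_truth):
    # patient 1000 has two ICU stays in one hospital admission
    p = small_truth.patients[0]
    h = p.hosp_stays[0]
    s2 = h.icu_stays[1]
    t_abs = s2.admit + 90
    df = pd.DataFrame({"hadm_id": [h.hadm_id],
                       "charttime": [t_abs - h.admit], "v": [1.0]})
    tbl = TsTbl(df, id_vars=["hadm_id"], index_var="charttime", interval=1)
    out = change_id(tbl, small_handle, "icustay")
    assert out.df["icustay_id"].tolist() == [s2.icustay_id]
    assert out.df["charttime"].tolist() == [90]
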