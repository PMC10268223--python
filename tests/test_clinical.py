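"""SOFA scoring, suspected infection, Sepsis-3, GCS and insulin binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icukit.clinical import (Sep3Rule, score_cardio, score_cns, score_coag,
                             score_liver, score_renal, score_resp,
                             sep3_label, suspected_infection)
from icukit.load import load_concepts
from icukit.tabular import TsTbl

H = 60


def s(*vals):
    return pd.Series(list(vals), dtype=float)


# -- component threshold tables ----------------------------------------------


@pytest.mark.parametrize("plt,expected", [
    (300, 0), (150, 0), (149, 1), (100, 1), (99, 2), (50, 2), (49, 3),
    (45, 3), (20, 3), (19, 4),
])
def test_coagulation_thresholds(plt, expected):
    assert score_coag(s(plt)).iloc[0] == expected


@pytest.mark.parametrize("bili,expected", [
    (1.0, 0), (1.19, 0), (1.2, 1), (1.9, 1), (2.0, 2), (3.0, 2), (5.9, 2),
    (6.0, 3), (11.9, 3), (12.0, 4),
])
def test_liver_thresholds(bili, expected):
    assert score_liver(s(bili)).iloc[0] == expected


@pytest.mark.parametrize("crea,expected", [
    (1.0, 0), (1.2, 1), (1.9, 1), (2.0, 2), (2.2, 2), (3.4, 2), (3.5, 3),
    (4.9, 3), (5.0, 4),
])
def test_renal_thresholds(crea, expected):
    assert score_renal(s(crea)).iloc[0] == expected


@pytest.mark.parametrize("gcs,expected", [
    (15, 0), (14, 1), (13, 1), (12, 2), (10, 2), (9, 3), (6, 3), (5, 4),
    (3, 4),
])
def test_cns_thresholds(gcs, expected):
    assert score_cns(s(gcs)).iloc[0] == expected


@pytest.mark.parametrize("pafi,vented,expected", [
    (450, False, 0), (400, False, 0), (399, False, 1), (350, False, 1),
    (299, False, 2), (199, False, 2), (199, True, 3), (99, True, 4),
    (99, False, 2),
])
def test_respiratory_thresholds(pafi, vented, expected):
    out = score_resp(s(pafi), pd.Series([vented]))
    assert out.iloc[0] == expected


def test_cardiovascular_thresholds():
    # MAP only
    assert score_cardio(s(75), s(np.nan), s(np.nan), s(np.nan),
                        s(np.nan)).iloc[0] == 0
    assert score_cardio(s(60), s(np.nan), s(np.nan), s(np.nan),
                        s(np.nan)).iloc[0] == 1
    # low-dose dopamine or any dobutamine
    assert score_cardio(s(60), s(3.0), s(np.nan), s(np.nan),
                        s(np.nan)).iloc[0] == 2
    assert score_cardio(s(80), s(np.nan), s(5.0), s(np.nan),
                        s(np.nan)).iloc[0] == 2
    # mid-range catecholamines
    assert score_cardio(s(60), s(10.0), s(np.nan), s(np.nan),
                        s(np.nan)).iloc[0] == 3
    assert score_cardio(s(60), s(np.nan), s(np.nan), s(0.05),
                        s(np.nan)).iloc[0] == 3
    # high-dose
    assert score_cardio(s(60), s(20.0), s(np.nan), s(np.nan),
                        s(np.nan)).iloc[0] == 4
    assert score_cardio(s(60), s(np.nan), s(np.nan), s(0.2),
                        s(np.nan)).iloc[0] == 4


@given(st.floats(1, 1000), st.floats(0, 15), st.floats(0.1, 10),
       st.integers(3, 15))
def test_component_scores_stay_in_range(plt, bili, crea, gcs):
    for fn, v in ((score_coag, plt), (score_liver, bili),
                  (score_renal, crea), (score_cns, gcs)):
        assert 0 <= fn(s(v)).iloc[0] <= 4


def test_worsening_component_never_decreases_scores():
    plts = np.linspace(400, 5, 50)
    scores = score_coag(pd.Series(plts))
    assert (np.diff(scores) >= 0).all()


# -- suspected infection -----------------------------------------------------


def _events(times, name):
    df = pd.DataFrame({"id": 1, "charttime": [t * H for t in times],
                       name: True})
    if not times:
        df = pd.DataFrame({"id": pd.Series([], dtype="int64"),
                           "charttime": pd.Series([], dtype="int64"),
                           name: pd.Series([], dtype="boolean")})
    return TsTbl(df, id_vars=["id"], index_var="charttime")


def test_culture_within_24h_after_abx_marks_onset_at_abx():
    out = suspected_infection(_events([10], "abx"), _events([20], "samp"))
    assert out.df["charttime"].tolist() == [10 * H]


def test_abx_more_than_72h_after_culture_is_no_onset():
    out = suspected_infection(_events([80], "abx"), _events([0], "samp"))
    assert len(out.df) == 0


def test_abx_within_72h_after_culture_marks_onset_at_culture():
    out = suspected_infection(_events([60], "abx"), _events([0], "samp"))
    assert out.df["charttime"].tolist() == [0]


def test_no_antibiotics_no_onset():
    out = suspected_infection(_events([], "abx"), _events([5], "samp"))
    assert len(out.df) == 0


# -- Sepsis-3 ----------------------------------------------------------------


def _sofa(times_scores):
    df = pd.DataFrame({"id": 1,
                       "charttime": [t * H for t, _ in times_scores],
                       "sofa": [v for _, v in times_scores]})
    return TsTbl(df, id_vars=["id"], index_var="charttime")


def _susp(hour):
    df = pd.DataFrame({"id": 1, "charttime": [hour * H], "susp_inf": True})
    return TsTbl(df, id_vars=["id"], index_var="charttime")


def test_sofa_jump_after_onset_fires_label():
    sofa = _sofa([(0, 2), (5, 2), (11, 5), (12, 5)])
    out = sep3_label(sofa, _susp(10))
    assert out.df["charttime"].tolist() == [11 * H]


def test_flat_sofa_never_fires():
    sofa = _sofa([(t, 3) for t in range(0, 30)])
    out = sep3_label(sofa, _susp(10))
    assert len(out.df) == 0


def test_jump_outside_window_ignored():
    sofa = _sofa([(0, 0), (40, 0), (80, 4)])
    out = sep3_label(sofa, _susp(2))   # window ends at hour 26
    assert len(out.df) == 0


def test_rule_rejects_negative_delta():
    with pytest.raises(ValueError):
        Sep3Rule(delta=-1)


# -- fixture-level recovery --------------------------------------------------


def test_planted_septic_patients_recovered(fixture_truth, rendered,
                                           dictionary):
    res = load_concepts(dictionary, rendered["eav_absolute"], ["sep3"])
    got = dict(zip(res.df["icustay_id"], res.df["charttime"]))
    assert len(fixture_truth.sep3_onset) > 0
    for sid, onset in fixture_truth.sep3_onset.items():
        assert got.get(sid) == onset // H * H, f"stay {sid}"


def test_gcs_total_equals_component_sum(small_truth, small_handle,
                                        dictionary):
    res = load_concepts(dictionary, small_handle, ["gcs"])
    comp = load_concepts(dictionary, small_handle,
                         ["egcs", "mgcs", "vgcs"])
    merged = comp.df.merge(res.df, on=["icustay_id", "charttime"])
    total = merged["egcs"] + merged["mgcs"] + merged["vgcs"]
    ok = total.notna()
    assert ok.any()
    assert (merged.loc[ok, "gcs"] == total[ok]).all()


def test_diab_equals_direct_regex_over_diagnoses(small_handle, dictionary):
    import re
    res = load_concepts(dictionary, small_handle, ["diab"])
    diags = small_handle.table("diagnoses_icd")
    pat = re.compile(r"^250\.?[0-9]{2}$")
    by_hadm = diags.groupby("hadm_id")["icd9_code"].apply(
        lambda c: bool(c.astype(str).map(pat.match).any()))
    win = small_handle.id_windows()
    expect = {int(r["icustay_id"]): bool(by_hadm.get(r["hadm_id"], False))
              for _, r in win.iterrows()}
    got = dict(zip(res.df["icustay_id"], res.df["diab"].astype(bool)))
    assert got == {k: v for k, v in expect.items() if k in got}
    assert all(expect[k] == got[k] for k in got)
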