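"""Synthetic-cohort generator, dialect renderers, and the truth oracle."""

import pandas as pd
import pytest

import icukit
from icukit.clinical import cut_insulin
from icukit.synth import (DIALECTS, CohortTruth, generate_cohort,
                          render_source, truth_lookup)


def test_single_patient_has_a_stay():
    truth = generate_cohort(1, 1)
    assert len(truth.patients) == 1
    stays = list(truth.stays())
    assert len(stays) >= 1


def test_generation_is_deterministic():
    a, b = generate_cohort(1, 50), generate_cohort(1, 50)
    assert a.to_json() == b.to_json()


def test_out_of_bounds_heart_rate_planted():
    truth = generate_cohort(2, 50)
    assert sum(1 for _, _, v in truth.signals["hr"] if v > 300) >= 1


def test_invalid_patient_count_rejected():
    with pytest.raises(ValueError):
        generate_cohort(1, 0)


def test_stay_nesting_and_non_overlap():
    truth = generate_cohort(5, 40)
    for p in truth.patients:
        spans = []
        for h in p.hosp_stays:
            for s in h.icu_stays:
                assert h.admit <= s.admit < s.disch <= h.disch
                spans.append((s.admit, s.disch))
        spans.sort()
        for (a1, d1), (a2, _) in zip(spans, spans[1:]):
            assert d1 <= a2


def test_multi_icu_stay_patient_exists():
    truth = generate_cohort(3, 1)
    h = truth.patients[0].hosp_stays[0]
    assert len(h.icu_stays) >= 2


def test_death_inside_last_icu_stay():
    truth = generate_cohort(7, 60)
    died = [p for p in truth.patients if p.death is not None]
    assert died
    for p in died:
        s = p.hosp_stays[-1].icu_stays[-1]
        assert s.admit <= p.death < s.disch


def test_truth_round_trips_through_json():
    truth = generate_cohort(9, 5)
    again = CohortTruth.from_json(truth.to_json())
    assert again.to_json() == truth.to_json()


# -- renderers ---------------------------------------------------------------


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ValueError, match="dialect"):
        render_source(generate_cohort(1, 1), "star_schema", tmp_path)


def test_eav_absolute_heart_rate_itemids(tmp_path):
    truth = generate_cohort(4, 4)
    render_source(truth, "eav_absolute", tmp_path)
    chart = pd.read_csv(tmp_path / "chartevents.csv")
    hr_rows = chart[chart["itemid"].isin([211, 220045])]
    assert len(hr_rows) == len(truth.signals["hr"])
    assert set(hr_rows["itemid"]) <= {211, 220045}


def test_eav_absolute_writes_death_timestamp(tmp_path):
    truth = generate_cohort(7, 60)
    render_source(truth, "eav_absolute", tmp_path)
    adm = pd.read_csv(tmp_path / "admissions.csv")
    n_died = sum(1 for p in truth.patients if p.death is not None)
    assert adm["deathtime"].notna().sum() == n_died


@pytest.mark.parametrize("dialect", DIALECTS)
def test_renderers_are_lossless_for_lactate(tmp_path, dialect):
    """Every planted observation appears exactly once in some table."""
    truth = generate_cohort(6, 6)
    render_source(truth, dialect, tmp_path / dialect)
    if dialect == "eav_absolute":
        df = pd.read_csv(tmp_path / dialect / "labevents.csv")
        n = (df["itemid"] == 50813).sum()
    elif dialect == "wide_relative":
        df = pd.read_csv(tmp_path / dialect / "lab.csv")
        n = (df["labname"] == "lactate").sum()
    else:
        df = pd.read_csv(tmp_path / dialect / "observations.csv")
        from icukit.synth import EAV_REL_IDS
        n = (df["itemid"] == EAV_REL_IDS["lact"]).sum()
    assert n == len(truth.signals["lact"])


# -- truth oracle ------------------------------------------------------------


def test_truth_lookup_excludes_planted_artifact():
    truth = generate_cohort(2, 50)
    sid, off, v = next((s, o, v) for s, o, v in truth.signals["hr"]
                       if v > 300)
    series = truth_lookup(truth, "hr", sid)
    bin_ = off // 60 * 60
    if bin_ in series:          # other in-range values share the bin
        assert series[bin_] <= 300
    raw = [v for s, o, v in truth.signals["hr"]
           if s == sid and o // 60 * 60 == bin_ and 0 <= v <= 300]
    assert (bin_ in series) == bool(raw)


def test_truth_lookup_death_survivor_empty():
    truth = generate_cohort(7, 60)
    survivor = next(p for p in truth.patients if p.death is None)
    sid = survivor.hosp_stays[0].icu_stays[0].icustay_id
    assert truth_lookup(truth, "death", sid) == {}


def test_truth_lookup_insulin_binning():
    truth = generate_cohort(1, 1)
    sid = truth.patients[0].hosp_stays[0].icu_stays[0].icustay_id
    truth.signals["ins"] = [(sid, 100, 3.0), (sid, 900, 9.0)]
    assert truth_lookup(truth, "ins24", sid) == "[10,20)"


def test_truth_lookup_unknown_concept_errors():
    truth = generate_cohort(1, 1)
    sid = truth.patients[0].hosp_stays[0].icu_stays[0].icustay_id
    with pytest.raises(KeyError):
        truth_lookup(truth, "astrology", sid)


def test_insulin_cut_bins():
    s = pd.Series([0.5, 1.0, 12.0, 20.0, 39.9, 40.0, 200.0])
    assert cut_insulin(s).tolist() == [
        "[0,1)", "[1,10)", "[10,20)", "[20,40)", "[20,40)", "[40,Inf)",
        "[40,Inf)"]
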