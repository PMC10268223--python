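"""Concept-dictionary parsing, merging, querying and callbacks."""

import json
import os

import pandas as pd
import pytest

import icukit
from icukit.concepts import (CONFIG_PATH_VAR, load_dictionary,
                             make_transform_callback, parse_dictionary,
                             resolve_callback, transform_fun)
from icukit.errors import (ConceptLookupError, DependencyError,
                           DictionaryError)

# the published way of declaring a heart-rate concept as user JSON
HR_DOC = """
{
 "hr": {
  "unit": ["bpm", "/min"],
  "min": 0,
  "max": 300,
  "omopid": 4239408,
  "description": "heart rate",
  "category": "routine vital signs",
  "sources": {
   "mimic_demo": [
    {
     "ids": [211, 220045],
     "table": "chartevents",
     "sub_var": "itemid"
    }
   ]
  }
 }
}
"""


def test_parse_heart_rate_document():
    d = parse_dictionary(HR_DOC)
    c = d.find("hr")
    assert c.kind == "num_cncpt"
    assert c.sources["mimic_demo"][0].ids == [211, 220045]
    assert c.sources["mimic_demo"][0].sub_var == "itemid"
    assert (c.min, c.max) == (0, 300)
    assert c.omopid == 4239408
    assert c.unit == ["bpm", "/min"]


def test_later_document_overrides_with_provenance():
    override = {"hr": {"class": "num_cncpt", "min": 10, "max": 250,
                       "sources": {"s": [{"table": "t", "sub_var": "c",
                                          "ids": [1]}]}}}
    d = parse_dictionary([HR_DOC, override], origins=["base", "user"])
    assert d.find("hr").max == 250
    assert d.provenance["hr"] == "user"


def test_recursive_cycle_detected():
    doc = {"a": {"class": "rec_cncpt", "concepts": ["b"], "callback": "identity"},
           "b": {"class": "rec_cncpt", "concepts": ["a"], "callback": "identity"}}
    with pytest.raises(DependencyError, match="cycle"):
        parse_dictionary(doc)


def test_rec_concept_requires_depends_and_no_sources():
    with pytest.raises(DictionaryError):
        parse_dictionary({"x": {"class": "rec_cncpt", "callback": "identity"}})


def test_lgl_concept_rejects_bounds():
    with pytest.raises(DictionaryError):
        parse_dictionary({"x": {"class": "lgl_cncpt", "min": 0,
                                "sources": {"s": [{"table": "t",
                                                   "class": "col_itm"}]}}})


def test_find_by_name_and_omopid(dictionary):
    by_name = dictionary.find("lact")
    assert by_name.description.lower().startswith("lactate")
    assert dictionary.find(4191725) is by_name
    assert dictionary.find(37116947).name == "sex"


def test_find_unknown_lists_near_matches(dictionary):
    with pytest.raises(ConceptLookupError, match="lact"):
        dictionary.find("lactt")


def test_duplicate_omopid_rejected():
    doc = {"a": {"omopid": 7, "sources": {"s": [{"table": "t",
                                                 "class": "col_itm"}]}},
           "b": {"omopid": 7, "sources": {"s": [{"table": "t",
                                                 "class": "col_itm"}]}}}
    with pytest.raises(DictionaryError, match="omopid"):
        parse_dictionary(doc)


def test_empty_dictionary_stats_all_zero():
    st = parse_dictionary({}).stats()
    assert (st.total, st.n_atomic, st.n_recursive) == (0, 0, 0)
    assert st.by_category == {} and st.per_source == {}


def test_stats_totals_are_consistent(dictionary):
    st = dictionary.stats()
    assert st.n_atomic + st.n_recursive == st.total
    assert sum(st.by_category.values()) == st.total


def test_round_trip_identity(dictionary):
    again = parse_dictionary(dictionary.to_json())
    assert again.to_json() == dictionary.to_json()
    assert again.names() == dictionary.names()


def test_every_shipped_callback_resolves(dictionary):
    for name in dictionary.names():
        dictionary.find(name).validate_callbacks()  # raises on dangling refs


# -- callback registry -------------------------------------------------------


@pytest.mark.parametrize("code,expected", [
    ("25013", True),      # 250 + two trailing digits
    ("250.13", True),     # dotted form
    ("2501", False),      # only one trailing digit
    ("4019", False),
    ("250134", False),
])
def test_diabetes_regex_transform(code, expected):
    fn = resolve_callback("transform_fun(grep_diab)")
    assert bool(fn(pd.Series([code])).iloc[0]) == expected


def test_identity_transform_keeps_values():
    fn = transform_fun(lambda x: x)
    s = pd.Series([1.0, 2.5])
    assert fn(s).tolist() == [1.0, 2.5]


def test_make_transform_callback_registers_reference():
    ref = make_transform_callback("is_big_test_only", lambda v: v > 10)
    assert ref == "transform_fun(is_big_test_only)"
    assert resolve_callback(ref)(pd.Series([5, 15])).tolist() == [False, True]
    with pytest.raises(DictionaryError, match="already registered"):
        make_transform_callback("is_big_test_only", lambda v: v)


def test_malformed_callback_reference_rejected():
    with pytest.raises(DictionaryError):
        resolve_callback("__import__('os')")


# -- user dictionary discovery ----------------------------------------------


def test_unset_env_var_keeps_shipped_dictionary_only():
    d = load_dictionary(env={})
    assert len(d) == 119


def test_user_folder_overrides_shipped_bounds(tmp_path):
    (tmp_path / "my.json").write_text(json.dumps(
        {"hr": {"class": "num_cncpt", "min": 5, "max": 250,
                "unit": ["bpm"],
                "sources": {"eav_absolute": [
                    {"table": "chartevents", "sub_var": "itemid",
                     "ids": [211, 220045]}]}}}))
    d = load_dictionary(env={CONFIG_PATH_VAR: str(tmp_path)})
    assert d.find("hr").max == 250
    assert len(d) == 119  # override, not addition


def test_user_folder_adds_new_concept(tmp_path):
    (tmp_path / "new.json").write_text(json.dumps(
        {"myconc": {"class": "num_cncpt",
                    "sources": {"eav_absolute": [
                        {"table": "chartevents", "sub_var": "itemid",
                         "ids": [424242]}]}}}))
    d = load_dictionary(env={CONFIG_PATH_VAR: str(tmp_path)})
    assert "myconc" in d
    assert len(d) == 120
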