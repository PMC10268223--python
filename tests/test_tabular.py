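"""Table-kind invariants and the manipulation verbs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icukit.tabular import (IdTbl, TsTbl, WinTbl, aggregate_by, bin_index,
                            change_interval, expand, fill_gaps,
                            merge_concepts, replace_na, slide,
                            truncate_at_first)


def ts(rows, interval=60, cols=("id", "charttime", "val")):
    df = pd.DataFrame(rows, columns=list(cols))
    return TsTbl(df, id_vars=[cols[0]], index_var=cols[1], interval=interval)


# ---------------------------------------------------------------------------
# construction invariants
# ---------------------------------------------------------------------------


def test_index_must_be_multiple_of_interval():
    with pytest.raises(ValueError, match="multiples"):
        ts([(1, 61, 1.0)], interval=60)


def test_interval_must_be_positive():
    with pytest.raises(ValueError):
        ts([(1, 0, 1.0)], interval=0)


def test_missing_id_rejected():
    df = pd.DataFrame({"id": [1, None], "v": [1.0, 2.0]})
    with pytest.raises(ValueError, match="missing"):
        IdTbl(df, id_vars=["id"])


def test_negative_durations_rejected():
    df = pd.DataFrame({"id": [1], "start": [0], "dur": [-5], "v": ["x"]})
    with pytest.raises(ValueError):
        WinTbl(df, id_vars=["id"], index_var="start", dur_var="dur")


# ---------------------------------------------------------------------------
# bin_index
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("raw,interval,expected", [
    (61, 60, 60),
    (-61, 60, -120),   # floor toward minus infinity
    (0, 60, 0),
    (59, 60, 0),
    (-1, 60, -60),
])
def test_bin_index_floors(raw, interval, expected):
    out = bin_index(ts([(1, raw, 1.0)], interval=1), interval)
    assert out.df["charttime"].iloc[0] == expected
    assert out.interval == interval


@given(st.lists(st.integers(min_value=-10000, max_value=10000), min_size=1,
                max_size=100),
       st.integers(min_value=1, max_value=240))
def test_bin_index_matches_floor_oracle(times, interval):
    tbl = ts([(1, t, 1.0) for t in times], interval=1)
    out = bin_index(tbl, interval)
    oracle = [int(np.floor(t / interval)) * interval for t in times]
    assert list(out.df["charttime"]) == oracle


def test_bin_index_rejects_nonpositive_interval():
    with pytest.raises(ValueError):
        bin_index(ts([(1, 0, 1.0)]), 0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_median_of_two_heart_rates():
    out = aggregate_by(ts([(1, 0, 80.0), (1, 0, 90.0)]), "median")
    assert out.df["val"].tolist() == [85.0]


def test_aggregate_sum_of_insulin_doses():
    out = aggregate_by(ts([(1, 0, 3.0), (1, 0, 9.0)]), "sum")
    assert out.df["val"].tolist() == [12.0]


def test_aggregate_any_for_logicals():
    df = pd.DataFrame({"id": [1, 1, 2, 2], "charttime": [0, 0, 0, 0],
                       "flag": pd.array([False, True, False, False],
                                        dtype="boolean")})
    out = aggregate_by(TsTbl(df, id_vars=["id"], index_var="charttime"),
                       "any")
    assert out.df["flag"].tolist() == [True, False]


def test_aggregate_all_missing_stays_missing():
    out = aggregate_by(ts([(1, 0, np.nan), (1, 0, np.nan)]), "median")
    assert np.isnan(out.df["val"].iloc[0])


def test_aggregate_unknown_name_errors():
    with pytest.raises(ValueError, match="unknown aggregation"):
        aggregate_by(ts([(1, 0, 1.0)]), "mode-ish")


# ---------------------------------------------------------------------------
# change_interval
# ---------------------------------------------------------------------------


def test_change_interval_identity_and_composition():
    tbl = ts([(1, t, float(t)) for t in (0, 60, 120, 180)])
    same = change_interval(tbl, 60, "median")
    assert same.df.equals(tbl.df)
    # equals bin_index then aggregate_by
    direct = change_interval(tbl, 120, "median")
    composed = aggregate_by(bin_index(tbl, 120), "median")
    assert direct.df.equals(composed.df)
    assert direct.df["charttime"].nunique() == 2


# ---------------------------------------------------------------------------
# fill_gaps
# ---------------------------------------------------------------------------


def test_fill_gaps_makes_grid_dense():
    out = fill_gaps(ts([(1, 0, 1.7), (1, 180, 2.2)]))
    assert out.df["charttime"].tolist() == [0, 60, 120, 180]
    assert np.isnan(out.df["val"].iloc[1])


def test_fill_gaps_idempotent():
    once = fill_gaps(ts([(1, 0, 1.0), (1, 240, 2.0), (2, -60, 0.5),
                         (2, 60, 0.7)]))
    twice = fill_gaps(once)
    assert once.df.equals(twice.df)


@given(st.dictionaries(st.integers(min_value=1, max_value=5),
                       st.lists(st.integers(-50, 50), min_size=1,
                                max_size=20), min_size=1, max_size=5))
def test_fill_gaps_row_count_closed_form(per_id):
    rows = [(i, 60 * t, 1.0) for i, times in per_id.items()
            for t in sorted(set(times))]
    out = fill_gaps(ts(rows))
    expected = sum(
        (60 * max(set(ts_)) - 60 * min(set(ts_))) // 60 + 1
        for ts_ in per_id.values())
    assert len(out.df) == expected


# ---------------------------------------------------------------------------
# replace_na
# ---------------------------------------------------------------------------


def test_locf_carries_last_observation_forward():
    tbl = ts([(1, 60 * k, v) for k, v in
              enumerate([1.7, np.nan, np.nan, 2.2])])
    out = replace_na(tbl, np.nan, "locf", vars=["val"])
    assert out.df["val"].tolist() == [1.7, 1.7, 1.7, 2.2]


def test_locf_keeps_leading_missing():
    out = replace_na(ts([(1, 0, np.nan), (1, 60, 5.0)]), np.nan, "locf",
                     vars=["val"])
    assert np.isnan(out.df["val"].iloc[0])
    assert out.df["val"].iloc[1] == 5.0


def test_locf_respects_grouping():
    out = replace_na(ts([(1, 0, 9.0), (2, 0, np.nan)]), np.nan, "locf",
                     vars=["val"])
    assert np.isnan(out.df["val"].iloc[1])


def test_const_fill_sets_missing_death_false():
    df = pd.DataFrame({"id": [1, 1, 1], "charttime": [0, 60, 120],
                       "death": pd.array([None, None, True],
                                         dtype="boolean")})
    tbl = TsTbl(df, id_vars=["id"], index_var="charttime")
    out = replace_na(tbl, False, "const", vars=["death"])
    assert out.df["death"].tolist() == [False, False, True]


def test_locf_idempotent():
    tbl = ts([(1, 60 * k, v) for k, v in
              enumerate([np.nan, 1.0, np.nan, 3.0, np.nan])])
    once = replace_na(tbl, np.nan, "locf", vars=["val"])
    twice = replace_na(once, np.nan, "locf", vars=["val"])
    assert once.df.equals(twice.df)


def test_replace_na_unknown_type_errors():
    with pytest.raises(ValueError, match="unknown replace_na type"):
        replace_na(ts([(1, 0, 1.0)]), 0, "interpolate", vars=["val"])


# ---------------------------------------------------------------------------
# expand
# ---------------------------------------------------------------------------


def win(rows, interval=60):
    df = pd.DataFrame(rows, columns=["id", "start", "dur", "val"])
    return WinTbl(df, id_vars=["id"], index_var="start", dur_var="dur",
                  interval=interval)


def test_expand_ventilation_window():
    out = expand(win([(1, 0, 159, "invasive")]))
    assert out.df["start"].tolist() == [0, 60, 120]
    assert set(out.df["val"]) == {"invasive"}


def test_expand_zero_duration_single_row():
    out = expand(win([(1, 300, 0, "x")]))
    assert out.df["start"].tolist() == [300]


@given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 600)),
                min_size=1, max_size=20))
def test_expand_row_count_closed_form(windows):
    rows = [(1, 60 * s, d, "v") for s, d in windows]
    out = expand(win(rows))
    assert len(out.df) == sum(d // 60 + 1 for _, d in windows)


# ---------------------------------------------------------------------------
# slide
# ---------------------------------------------------------------------------


def test_slide_zero_window_is_identity_for_max():
    tbl = ts([(1, 0, 5.0), (1, 60, 3.0)])
    out = slide(tbl, 0, 0, "max")
    assert out.df["val"].tolist() == [5.0, 3.0]


def test_slide_empty_window_yields_missing():
    tbl = ts([(1, 0, np.nan), (1, 60, 2.0)])
    out = slide(tbl, 0, 0, "max")
    assert np.isnan(out.df["val"].iloc[0])


@given(st.lists(st.tuples(st.integers(1, 3), st.integers(0, 48),
                          st.floats(0, 500, allow_nan=False)),
                min_size=1, max_size=60),
       st.integers(0, 1440), st.integers(0, 240))
def test_slide_matches_bruteforce_window_scan(rows, before, after):
    uniq = {(i, 60 * t): v for i, t, v in rows}
    tbl = ts([(i, t, v) for (i, t), v in sorted(uniq.items())])
    out = slide(tbl, before, after, "max")
    for _, r in out.df.iterrows():
        window = [v for (i, t), v in uniq.items()
                  if i == r["id"] and r["charttime"] - before <= t
                  <= r["charttime"] + after]
        assert r["val"] == max(window)


# ---------------------------------------------------------------------------
# truncate_at_first
# ---------------------------------------------------------------------------


def flag_tbl(flags, ids=None):
    ids = ids or [1] * len(flags)
    df = pd.DataFrame({"id": ids, "charttime": 60 * np.arange(len(flags)),
                       "death": pd.array(flags, dtype="boolean")})
    return TsTbl(df, id_vars=["id"], index_var="charttime")


def test_truncate_keeps_through_first_true():
    out = truncate_at_first(flag_tbl([False, False, True, False]), "death")
    assert len(out.df) == 3


def test_truncate_never_true_keeps_all():
    out = truncate_at_first(flag_tbl([False, False, False]), "death")
    assert len(out.df) == 3


def test_truncate_first_row_true():
    out = truncate_at_first(flag_tbl([True, False]), "death")
    assert len(out.df) == 1


def test_truncate_missing_flag_column_errors():
    with pytest.raises(ValueError):
        truncate_at_first(flag_tbl([False]), "nope")


# ---------------------------------------------------------------------------
# merge_concepts
# ---------------------------------------------------------------------------


def test_merge_two_ts_tables_outer():
    a = ts([(1, 0, 1.7), (1, 120, 2.2)], cols=("id", "charttime", "lact"))
    b = ts([(1, 60, 9.0)], cols=("id", "charttime", "sofa"))
    out = merge_concepts([a, b])
    assert list(out.df.columns) == ["id", "charttime", "lact", "sofa"]
    assert len(out.df) == 3


def test_merge_single_input_unchanged():
    a = ts([(1, 0, 1.0)])
    out = merge_concepts([a])
    assert out.df.equals(a.df)


def test_merge_id_table_broadcasts_over_time():
    hr = ts([(1, 0, 80.0), (1, 60, 90.0)], cols=("id", "charttime", "hr"))
    sex = IdTbl(pd.DataFrame({"id": [1], "sex": ["Female"]}), id_vars=["id"])
    out = merge_concepts([hr, sex])
    assert len(out.df) == 2
    assert set(out.df["sex"]) == {"Female"}


def test_merge_interval_mismatch_errors():
    a = ts([(1, 0, 1.0)], interval=60)
    b = ts([(1, 0, 1.0)], interval=30, cols=("id", "charttime", "x"))
    with pytest.raises(ValueError, match="change_interval"):
        merge_concepts([a, b])


def test_merge_expands_win_inputs():
    w = win([(1, 0, 120, "invasive")])
    hr = ts([(1, 0, 80.0)], cols=("id", "charttime", "hr"))
    out = merge_concepts([w, hr])
    assert len(out.df) == 3  # 0, 60, 120
    assert not isinstance(out, WinTbl)
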