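"""ID-keyed, time-stamped, and windowed clinical tables plus their verbs.

Three table kinds carry harmonized ICU data:

* :class:`IdTbl` -- rows keyed by one or more ID columns (e.g. ICU stay id),
  no time information.  Used for static concepts such as patient sex.
* :class:`TsTbl` -- additionally carries a time-index column on a regular
  grid: every index value is an integer multiple of the table ``interval``
  (in minutes).  Index values may be negative (events before ICU admission).
* :class:`WinTbl` -- a time-stamped table whose rows additionally carry a
  non-negative duration (e.g. mechanical-ventilation windows).

All durations and time indices are integer minutes internally; presentation
layers may render hours.  The verbs in this module (binning, aggregation,
gap filling, imputation, window expansion, rolling windows, ID-system
conversion, merging) are the manipulation surface the loading engine and
end users rely on.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("icukit")

__all__ = [
    "IdTbl",
    "TsTbl",
    "WinTbl",
    "bin_index",
    "aggregate_by",
    "change_interval",
    "change_id",
    "fill_gaps",
    "replace_na",
    "expand",
    "slide",
    "truncate_at_first",
    "merge_concepts",
    "AGG_FUNS",
]


# ---------------------------------------------------------------------------
# table kinds
# ---------------------------------------------------------------------------


class IdTbl:
    """A rectangular table keyed by ID columns.

    Parameters
    ----------
    df:
        The underlying data.  A defensive copy is *not* taken; verbs never
        mutate their inputs and always return fresh objects.
    id_vars:
        Ordered ID column names (coarse to fine).  Must be present and
        non-missing in every row.
    units:
        Optional mapping of value-column name to unit string.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        id_vars: Sequence[str] | str,
        units: Mapping[str, str] | None = None,
        validate: bool = True,
    ):
        if isinstance(id_vars, str):
            id_vars = [id_vars]
        self.df = df.reset_index(drop=True)
        self.id_vars = list(id_vars)
        self.units = dict(units or {})
        if validate:
            self.validate()

    # -- metadata ----------------------------------------------------------

    @property
    def meta_vars(self) -> list[str]:
        return list(self.id_vars)

    @property
    def value_vars(self) -> list[str]:
        meta = set(self.meta_vars)
        return [c for c in self.df.columns if c not in meta]

    def validate(self) -> None:
        for c in self.id_vars:
            if c not in self.df.columns:
                raise ValueError(f"id column {c!r} missing from table")
            if self.df[c].isna().any():
                raise ValueError(f"id column {c!r} contains missing values")

    def with_df(self, df: pd.DataFrame, validate: bool = True) -> "IdTbl":
        return self.__class__(df, **self._meta_kwargs(), validate=validate)

    def _meta_kwargs(self) -> dict:
        return {"id_vars": self.id_vars, "units": self.units}

    def rename(self, mapping: Mapping[str, str]) -> "IdTbl":
        out = self.with_df(self.df.rename(columns=mapping), validate=False)
        out._rename_meta(mapping)
        out.validate()
        return out

    def _rename_meta(self, mapping: Mapping[str, str]) -> None:
        self.id_vars = [mapping.get(c, c) for c in self.id_vars]
        self.units = {mapping.get(k, k): v for k, v in self.units.items()}

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = type(self).__name__
        lines = [f"# A `{kind}`: {len(self.df)} x {self.df.shape[1]}",
                 f"# Id vars: {self.id_vars}"]
        if isinstance(self, TsTbl):
            lines.append(f"# Index var: `{self.index_var}` ({self.interval} mins)")
        if isinstance(self, WinTbl):
            lines.append(f"# Duration var: `{self.dur_var}`")
        if self.units:
            lines.append(f"# Units: {self.units}")
        return "\n".join(lines) + "\n" + repr(self.df)

    # -- serialization -----------------------------------------------------

    def meta_dict(self) -> dict:
        return {"kind": type(self).__name__, "id_vars": self.id_vars,
                "units": self.units}


class TsTbl(IdTbl):
    """An :class:`IdTbl` with a regular time index (integer minutes)."""

    def __init__(
        self,
        df: pd.DataFrame,
        id_vars: Sequence[str] | str,
        index_var: str,
        interval: int = 60,
        units: Mapping[str, str] | None = None,
        validate: bool = True,
    ):
        self.index_var = index_var
        self.interval = int(interval)
        super().__init__(df, id_vars, units=units, validate=validate)

    @property
    def meta_vars(self) -> list[str]:
        return list(self.id_vars) + [self.index_var]

    def validate(self) -> None:
        super().validate()
        if self.interval <= 0:
            raise ValueError("interval must be a positive number of minutes")
        if self.index_var not in self.df.columns:
            raise ValueError(f"index column {self.index_var!r} missing")
        idx = self.df[self.index_var]
        if idx.isna().any():
            raise ValueError("index column contains missing values")
        if len(idx) and (np.asarray(idx, dtype=np.int64) % self.interval != 0).any():
            raise ValueError(
                f"index values must be multiples of the interval ({self.interval} min)"
            )

    def _meta_kwargs(self) -> dict:
        return {"id_vars": self.id_vars, "index_var": self.index_var,
                "interval": self.interval, "units": self.units}

    def _rename_meta(self, mapping: Mapping[str, str]) -> None:
        super()._rename_meta(mapping)
        self.index_var = mapping.get(self.index_var, self.index_var)

    def meta_dict(self) -> dict:
        d = super().meta_dict()
        d.update(index_var=self.index_var, interval=self.interval)
        return d


class WinTbl(TsTbl):
    """A :class:`TsTbl` whose rows carry a non-negative duration (minutes)."""

    def __init__(
        self,
        df: pd.DataFrame,
        id_vars: Sequence[str] | str,
        index_var: str,
        dur_var: str,
        interval: int = 60,
        units: Mapping[str, str] | None = None,
        validate: bool = True,
    ):
        self.dur_var = dur_var
        super().__init__(df, id_vars, index_var, interval, units=units,
                         validate=validate)

    @property
    def meta_vars(self) -> list[str]:
        return super().meta_vars + [self.dur_var]

    def validate(self) -> None:
        super().validate()
        if self.dur_var not in self.df.columns:
            raise ValueError(f"duration column {self.dur_var!r} missing")
        dur = self.df[self.dur_var]
        if dur.isna().any() or (len(dur) and (np.asarray(dur) < 0).any()):
            raise ValueError("durations must be present and non-negative")

    def _meta_kwargs(self) -> dict:
        d = super()._meta_kwargs()
        d["dur_var"] = self.dur_var
        return d

    def _rename_meta(self, mapping: Mapping[str, str]) -> None:
        super()._rename_meta(mapping)
        self.dur_var = mapping.get(self.dur_var, self.dur_var)

    def meta_dict(self) -> dict:
        d = super().meta_dict()
        d["dur_var"] = self.dur_var
        return d


# ---------------------------------------------------------------------------
# aggregation functions
# ---------------------------------------------------------------------------


def _agg_median(s: pd.Series):
    s = s.dropna()
    return s.median() if len(s) else np.nan


def _agg_sum(s: pd.Series):
    s = s.dropna()
    return s.sum() if len(s) else np.nan


def _agg_min(s: pd.Series):
    s = s.dropna()
    return s.min() if len(s) else np.nan


def _agg_max(s: pd.Series):
    s = s.dropna()
    return s.max() if len(s) else np.nan


def _agg_any(s: pd.Series):
    s = s.dropna()
    return bool(s.astype(bool).any()) if len(s) else pd.NA


def _agg_first(s: pd.Series):
    s = s.dropna()
    return s.iloc[0] if len(s) else np.nan


def _agg_count(s: pd.Series):
    return int(s.notna().sum())


AGG_FUNS: dict[str, Callable[[pd.Series], object]] = {
    "median": _agg_median,
    "sum": _agg_sum,
    "min": _agg_min,
    "max": _agg_max,
    "any": _agg_any,
    "first": _agg_first,
    "count": _agg_count,
}


def default_aggregate(dtype) -> str:
    """Aggregation default by value type: numeric -> median, logical -> any,
    everything else -> first."""
    if isinstance(dtype, pd.BooleanDtype) or dtype == bool:
        return "any"
    if pd.api.types.is_numeric_dtype(dtype):
        return "median"
    return "first"


def _resolve_agg(fun) -> Callable[[pd.Series], object]:
    if callable(fun):
        return fun
    try:
        return AGG_FUNS[fun]
    except KeyError:
        raise ValueError(
            f"unknown aggregation {fun!r}; known: {sorted(AGG_FUNS)}"
        ) from None


# ---------------------------------------------------------------------------
# verbs
# ---------------------------------------------------------------------------


def bin_index(tbl: TsTbl, interval: int) -> TsTbl:
    """Bin the raw time index onto a regular grid.

    Each index value becomes ``floor(time / interval) * interval``; flooring
    is toward minus infinity, so an event 61 minutes *before* the origin
    bins to -120 at a 60-minute grid.
    """
    interval = int(interval)
    if interval <= 0:
        raise ValueError("interval must be positive")
    df = tbl.df.copy()
    idx = np.asarray(df[tbl.index_var], dtype=np.int64)
    df[tbl.index_var] = (idx // interval) * interval
    kw = tbl._meta_kwargs()
    kw["interval"] = interval
    return type(tbl)(df, **kw)


def aggregate_by(tbl: IdTbl, value_fun=None) -> IdTbl:
    """Collapse to one row per (id_vars[, index]) group.

    ``value_fun`` is a single aggregation (name or callable) applied to all
    value columns, or a mapping column -> aggregation.  Missing values are
    ignored; a group whose values are all missing aggregates to missing.
    """
    by = tbl.meta_vars
    if isinstance(tbl, WinTbl):
        by = tbl.id_vars + [tbl.index_var, tbl.dur_var]
    vcols = [c for c in tbl.df.columns if c not in by]
    if isinstance(value_fun, Mapping):
        funs = {c: _resolve_agg(value_fun.get(c, default_aggregate(tbl.df[c].dtype)))
                for c in vcols}
    else:
        funs = {
            c: _resolve_agg(value_fun) if value_fun is not None
            else _resolve_agg(default_aggregate(tbl.df[c].dtype))
            for c in vcols
        }
    if not len(tbl.df):
        return tbl.with_df(tbl.df.copy())
    grouped = tbl.df.groupby(by, sort=True, dropna=False)
    pieces = {c: grouped[c].apply(funs[c]) for c in vcols}
    out = pd.DataFrame(pieces).reset_index()
    # groupby.apply may upcast nullable booleans to object; restore dtype
    for c in vcols:
        if isinstance(tbl.df[c].dtype, pd.BooleanDtype):
            out[c] = out[c].astype("boolean")
    return tbl.with_df(out)


def change_interval(tbl: TsTbl, new_interval: int, value_fun=None) -> TsTbl:
    """Re-bin to a new grid step and re-aggregate (composition of
    :func:`bin_index` and :func:`aggregate_by`)."""
    return aggregate_by(bin_index(tbl, new_interval), value_fun)


def fill_gaps(tbl: TsTbl, limits: Mapping | pd.DataFrame | None = None) -> TsTbl:
    """Make the per-id time grid dense.

    For each id, every multiple of ``interval`` between the observed minimum
    and maximum index (or explicit per-id ``limits`` ``(start, end)``) is
    present afterwards; introduced rows carry missing values.  Idempotent.
    """
    if isinstance(tbl, WinTbl):
        raise TypeError("fill_gaps applies to ts tables, not win tables")
    step = tbl.interval
    lim: Mapping | None = None
    if limits is not None:
        if isinstance(limits, pd.DataFrame):
            need = tbl.id_vars + ["start", "end"]
            if not all(c in limits.columns for c in need):
                raise ValueError(f"limits frame must have columns {need}")
            lim = {tuple(r[c] for c in tbl.id_vars): (r["start"], r["end"])
                   for _, r in limits.iterrows()}
        elif isinstance(limits, Mapping):
            lim = limits
        else:
            raise ValueError("limits must be a mapping or a data frame")
    pieces = []
    for key, grp in tbl.df.groupby(tbl.id_vars, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        if lim is not None:
            if key not in lim and len(key) == 1 and key[0] in lim:
                lo, hi = lim[key[0]]
            elif key in lim:
                lo, hi = lim[key]
            else:
                lo, hi = grp[tbl.index_var].min(), grp[tbl.index_var].max()
            lo = int(math.floor(lo / step) * step)
            hi = int(math.floor(hi / step) * step)
        else:
            lo, hi = int(grp[tbl.index_var].min()), int(grp[tbl.index_var].max())
        grid = pd.DataFrame({tbl.index_var: np.arange(lo, hi + 1, step, dtype=np.int64)})
        for c, v in zip(tbl.id_vars, key):
            grid[c] = v
        merged = grid.merge(grp, on=tbl.id_vars + [tbl.index_var], how="outer")
        pieces.append(merged)
    if not pieces:
        return tbl.with_df(tbl.df.copy())
    out = pd.concat(pieces, ignore_index=True)
    out = out[list(tbl.df.columns)].sort_values(tbl.meta_vars, kind="stable")
    out[tbl.index_var] = out[tbl.index_var].astype(np.int64)
    return tbl.with_df(out)


def replace_na(
    tbl: IdTbl,
    values,
    types: Sequence[str] | str = "const",
    vars: Sequence[str] | None = None,
    by: Sequence[str] | None = None,
) -> IdTbl:
    """Impute missing values per variable.

    ``types`` entries are ``"locf"`` (last observation carried forward
    within the ``by`` group, ordered by the time index; leading missings
    remain) or ``"const"`` (missing replaced by the matching entry of
    ``values``).
    """
    if vars is None:
        vars = tbl.value_vars
    if isinstance(vars, str):
        vars = [vars]
    if isinstance(types, str):
        types = [types] * len(vars)
    if not isinstance(values, (list, tuple)):
        values = [values] * len(vars)
    if len(types) != len(vars) or len(values) != len(vars):
        raise ValueError("values/types must align with vars")
    by = list(by) if by is not None else list(tbl.id_vars)
    df = tbl.df.copy()
    order = None
    if isinstance(tbl, TsTbl):
        df = df.sort_values(by + [tbl.index_var], kind="stable")
    for var, typ, val in zip(vars, types, values):
        if var not in df.columns:
            raise ValueError(f"unknown variable {var!r}")
        if typ == "locf":
            df[var] = df.groupby(by, sort=False)[var].transform(
                lambda s: s.ffill())
        elif typ == "const":
            df[var] = df[var].fillna(val)
        else:
            raise ValueError(f"unknown replace_na type {typ!r}")
    return tbl.with_df(df.reset_index(drop=True))


def expand(tbl: WinTbl) -> TsTbl:
    """Unroll windows onto the regular grid.

    A row starting at ``s`` with duration ``d`` becomes rows at
    ``s, s+interval, ..., s + floor(d/interval)*interval``, all carrying the
    row's values (``floor(d/interval) + 1`` rows; a zero duration yields a
    single row at the start time).
    """
    if not isinstance(tbl, WinTbl):
        raise TypeError("expand applies to win tables")
    step = tbl.interval
    durs = np.asarray(tbl.df[tbl.dur_var], dtype=np.int64)
    reps = durs // step + 1
    df = tbl.df.loc[tbl.df.index.repeat(reps)].reset_index(drop=True)
    offsets = np.concatenate([np.arange(r, dtype=np.int64) * step for r in reps]) \
        if len(reps) else np.array([], dtype=np.int64)
    df[tbl.index_var] = np.asarray(df[tbl.index_var], dtype=np.int64) + offsets
    df = df.drop(columns=[tbl.dur_var])
    return TsTbl(df, id_vars=tbl.id_vars, index_var=tbl.index_var,
                 interval=step, units=tbl.units)


def slide(tbl: TsTbl, before: int, after: int, fun) -> TsTbl:
    """Windowed aggregation: the value at time ``t`` becomes ``fun`` over the
    observations of the same id in ``[t - before, t + after]``.  Missing
    observations are ignored; an empty window yields missing."""
    if before < 0 or after < 0:
        raise ValueError("window extents must be non-negative")
    f = _resolve_agg(fun)
    vcols = tbl.value_vars
    pieces = []
    for _, grp in tbl.df.groupby(tbl.id_vars, sort=True):
        grp = grp.sort_values(tbl.index_var, kind="stable")
        idx = np.asarray(grp[tbl.index_var], dtype=np.int64)
        out = grp.copy()
        for c in vcols:
            vals = grp[c]
            lo = np.searchsorted(idx, idx - before, side="left")
            hi = np.searchsorted(idx, idx + after, side="right")
            res = [f(vals.iloc[a:b]) for a, b in zip(lo, hi)]
            out[c] = pd.Series(res, index=grp.index, dtype=object)
            try:
                out[c] = out[c].astype(vals.dtype)
            except (TypeError, ValueError):
                pass
        pieces.append(out)
    df = pd.concat(pieces, ignore_index=True) if pieces else tbl.df.copy()
    return tbl.with_df(df)


def truncate_at_first(tbl: TsTbl, flag_var: str) -> TsTbl:
    """Per id, keep rows up to and including the first true ``flag_var``
    (all rows when the flag never becomes true)."""
    if flag_var not in tbl.df.columns:
        raise ValueError(f"unknown flag column {flag_var!r}")
    df = tbl.df.sort_values(tbl.id_vars + [tbl.index_var], kind="stable")

    def _cut(grp: pd.DataFrame) -> pd.DataFrame:
        flags = grp[flag_var].fillna(False).astype(bool).to_numpy()
        pos = np.argmax(flags) if flags.any() else len(flags) - 1
        return grp.iloc[: pos + 1]

    pieces = [_cut(g) for _, g in df.groupby(tbl.id_vars, sort=True)]
    out = pd.concat(pieces, ignore_index=True) if pieces else df
    return tbl.with_df(out)


def merge_concepts(tables: Sequence[IdTbl]) -> IdTbl:
    """Full-outer-join several concept tables into one.

    Windowed inputs are expanded onto the grid first.  Time-stamped inputs
    must share the same interval (use :func:`change_interval` otherwise).
    ID-only inputs broadcast per id over the joined time index.  Unit
    metadata is merged.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("nothing to merge")
    tables = [expand(t) if isinstance(t, WinTbl) else t for t in tables]
    ts = [t for t in tables if isinstance(t, TsTbl)]
    if ts:
        intervals = {t.interval for t in ts}
        if len(intervals) > 1:
            raise ValueError(
                f"interval mismatch {sorted(intervals)}; align with change_interval first"
            )
        idx_names = {t.index_var for t in ts}
        if len(idx_names) > 1:
            canonical = ts[0].index_var
            tables = [t.rename({t.index_var: canonical})
                      if isinstance(t, TsTbl) else t for t in tables]
            ts = [t for t in tables if isinstance(t, TsTbl)]
    id_sets = {tuple(t.id_vars) for t in tables}
    if len(id_sets) > 1:
        raise ValueError(f"incompatible id columns among inputs: {id_sets}")
    if len(tables) == 1:
        t = tables[0]
        return t.with_df(t.df.copy())
    id_vars = tables[0].id_vars
    units: dict[str, str] = {}
    for t in tables:
        units.update(t.units)
    out = None
    for t in tables:
        keys = t.meta_vars if isinstance(t, TsTbl) else t.id_vars
        df = t.df
        if out is None:
            out = df.copy()
            out_keys = list(keys)
            continue
        join_on = [k for k in keys if k in out_keys] or id_vars
        out = out.merge(df, on=join_on, how="outer")
        for k in keys:
            if k not in out_keys:
                out_keys.append(k)
    if ts:
        t0 = ts[0]
        out = out.sort_values(id_vars + [t0.index_var], kind="stable")
        out[t0.index_var] = out[t0.index_var].astype(np.int64)
        return TsTbl(out.reset_index(drop=True), id_vars=id_vars,
                     index_var=t0.index_var, interval=t0.interval, units=units)
    out = out.sort_values(id_vars, kind="stable")
    return IdTbl(out.reset_index(drop=True), id_vars=id_vars, units=units)


# ---------------------------------------------------------------------------
# ID-system conversion
# ---------------------------------------------------------------------------


def change_id(tbl: IdTbl, handle, target: str) -> IdTbl:
    """Convert a table between ID systems of one source.

    Finer -> coarser: rows are re-keyed through the stay-window map and the
    time index is shifted by the difference of stay origins.  Coarser ->
    finer: each row is assigned to the target stay whose half-open
    ``[admit, discharge)`` window contains its absolute time; rows outside
    every window are dropped (count logged).  ID-only tables map directly
    (coarser -> finer broadcasts to all contained stays).
    """
    cfg = handle.config
    systems = {s.name: s for s in cfg.id_systems}
    if target not in systems:
        raise ValueError(f"unknown id system {target!r} for source {cfg.name!r}")
    cur_col = tbl.id_vars[-1]
    cur = None
    for s in cfg.id_systems:
        if s.id_column == cur_col:
            cur = s
    if cur is None:
        raise ValueError(f"id column {cur_col!r} matches no declared id system")
    tgt = systems[target]
    if cur.name == target:
        return tbl.with_df(tbl.df.copy())
    win = handle.id_windows()
    cur_c, tgt_c = cur.id_column, tgt.id_column
    has_time = isinstance(tbl, TsTbl)
    units = tbl.units

    if not has_time:
        sub = win[[cur_c, tgt_c]].drop_duplicates()
        df = tbl.df.merge(sub, on=cur_c, how="inner")
        df = df.drop(columns=[cur_c])
        cols = [tgt_c] + [c for c in df.columns if c != tgt_c]
        df = df[cols].drop_duplicates().reset_index(drop=True)
        return IdTbl(df, id_vars=[tgt_c], units=units)

    idx = tbl.index_var
    if cur.rank < tgt.rank:
        # coarser -> finer: window containment on absolute times
        sub = win[[cur_c, tgt_c, f"{tgt_c}__start", f"{tgt_c}__end",
                   f"{cur_c}__start"]].drop_duplicates()
        src = tbl.df.copy()
        src["__row"] = np.arange(len(src))
        df = src.merge(sub, on=cur_c, how="left")
        abs_t = df[idx] + df[f"{cur_c}__start"]
        keep = ((abs_t >= df[f"{tgt_c}__start"]) & (abs_t < df[f"{tgt_c}__end"]))
        keep = keep.fillna(False)
        n_drop = len(src) - df.loc[keep, "__row"].nunique()
        df = df.loc[keep].copy()
        if n_drop:
            logger.info("change_id %s->%s dropped %d row(s) outside all stay windows",
                        cur.name, target, n_drop)
        df[idx] = (abs_t[keep] - df[f"{tgt_c}__start"]).astype(np.int64)
        df = df.drop(columns="__row")
    else:
        # finer -> coarser: every fine stay maps to exactly one coarse stay
        sub = win[[cur_c, tgt_c, f"{cur_c}__start", f"{tgt_c}__start"]].drop_duplicates()
        df = tbl.df.merge(sub, on=cur_c, how="inner")
        df[idx] = (df[idx] + df[f"{cur_c}__start"] - df[f"{tgt_c}__start"]).astype(np.int64)
    helper = [c for c in df.columns if c.endswith("__start") or c.endswith("__end")]
    df = df.drop(columns=helper + [cur_c])
    cols = [tgt_c] + [c for c in df.columns if c != tgt_c]
    df = df[cols].reset_index(drop=True)
    interval = tbl.interval
    if len(df) and (np.asarray(df[idx], dtype=np.int64) % interval != 0).any():
        interval = 1
    kw = dict(id_vars=[tgt_c], index_var=idx, interval=interval, units=units)
    if isinstance(tbl, WinTbl):
        return WinTbl(df, dur_var=tbl.dur_var, **kw)
    return TsTbl(df, **kw)
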