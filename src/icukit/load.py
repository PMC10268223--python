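"""The concept-loading engine.

``load_concepts`` is the main workhorse: for each requested concept it
extracts raw rows per the source's items, applies item callbacks,
harmonizes units of measurement, filters implausible values against the
concept's bounds, converts to the requested ID system, bins the time index
onto the requested grid, aggregates per (id, time bin), resolves recursive
concepts through their callbacks, and finally merges everything into one
harmonized table.

Bounds are inclusive (a heart-rate of exactly 300 bpm survives a [0, 300]
range) and bounds filtering happens *before* aggregation, so an artifact
reading cannot contaminate an hourly median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import tabular
from .concepts import Concept, ConceptDict, resolve_callback
from .errors import (AvailabilityError, ConceptLookupError, ExtractionError)
from .concepts import Item
from .sources import SourceHandle
from .tabular import IdTbl, TsTbl, WinTbl

logger = logging.getLogger("icukit")

#: uniform name of the time-index column in harmonized output
INDEX_COL = "charttime"
DUR_COL = "dur_var"


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

#: (concept name or None, lowercase source unit) -> (target unit, transform)
UNIT_CONVERSIONS: dict[tuple[str | None, str], tuple[str, Callable]] = {}


def register_unit_conversion(from_unit: str, to_unit: str,
                             transform: Callable | float,
                             concept: str | None = None) -> None:
    """Register a unit conversion; ``transform`` is a scale factor or a
    callable on a value series.  Concept-specific entries take precedence
    over generic ones (a µmol/L -> mg/dL factor depends on the analyte)."""
    if not callable(transform):
        factor = float(transform)
        transform = lambda v, f=factor: v * f  # noqa: E731
    UNIT_CONVERSIONS[(concept, from_unit.lower())] = (to_unit, transform)


register_unit_conversion("umol/l", "mg/dl", 1.0 / 88.42, concept="crea")
register_unit_conversion("f", "c", lambda v: (v - 32.0) * 5.0 / 9.0,
                         concept="temp")
register_unit_conversion("lbs", "kg", 0.45359237, concept="weight")


# ---------------------------------------------------------------------------
# request / result containers
# ---------------------------------------------------------------------------


@dataclass
class LoadRequest:
    """What to load and how to shape it."""

    concepts: Sequence[str | int]
    id_type: str = "icustay"
    interval: int = 60
    patient_ids: Iterable | IdTbl | None = None
    aggregate_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.concepts:
            raise ValueError("request at least one concept")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


@dataclass
class ConceptResult:
    """A harmonized table plus per-column unit metadata."""

    table: IdTbl
    units: dict[str, str] = field(default_factory=dict)
    flagged_units: dict[str, list[str]] = field(default_factory=dict)

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df


# ---------------------------------------------------------------------------
# item extraction
# ---------------------------------------------------------------------------


def _resolve_item_columns(handle: SourceHandle, item: Item):
    tdef = handle.config.table(item.table)
    d = tdef.defaults
    id_col = item.id_column or d.id_column
    if id_col is None:
        ids = [c.name for c in tdef.columns if c.type == "id"]
        id_col = ids[-1] if ids else None
    index_col = item.index_column or d.index_column
    value_col = item.value_column or d.value_column
    unit_col = item.unit_column or d.unit_column
    dur_col = item.dur_column or d.dur_column
    return id_col, index_col, value_col, unit_col, dur_col


def load_item(handle: SourceHandle, item: Item,
              concept: str = "?") -> pd.DataFrame:
    """Extract raw rows for one item.

    Returns a frame with columns ``id``, optional ``time`` (integer minutes,
    absolute or stay-relative per the source's time mode), ``value``,
    optional ``unit`` and ``dur``.  ``sel_itm`` keeps rows whose ``sub_var``
    matches one of the item's codes; ``col_itm`` reads the whole table.  The
    item callback, if any, is applied to the value column last; rows whose
    value is missing afterwards are dropped.
    """
    try:
        tdef = handle.config.table(item.table)
    except Exception as exc:
        raise ExtractionError(
            f"concept {concept!r}: item table {item.table!r} not in source "
            f"{handle.config.name!r}"
        ) from exc
    df = handle.table(item.table)
    id_col, index_col, value_col, unit_col, dur_col = _resolve_item_columns(
        handle, item)
    declared = tdef.column_names()
    for role, col in (("id", id_col), ("index", index_col),
                      ("value", value_col), ("unit", unit_col),
                      ("dur", dur_col)):
        if col is not None and col not in declared:
            raise ExtractionError(
                f"concept {concept!r}: {role} column {col!r} absent from "
                f"table {item.table!r}"
            )
    if id_col is None:
        raise ExtractionError(
            f"concept {concept!r}: no id column resolvable for table "
            f"{item.table!r}"
        )
    if item.kind == "sel_itm":
        sub = df[item.sub_var]
        ids = list(item.ids)
        mask = sub.isin(ids)
        if not mask.any():
            str_ids = {str(i) for i in ids}
            mask = sub.astype(str).isin(str_ids)
        if not mask.any():
            logger.warning("concept %r: no rows match ids %s in %s.%s",
                           concept, ids, item.table, item.sub_var)
        df = df.loc[mask]
        if value_col is None:
            raise ExtractionError(
                f"concept {concept!r}: sel_itm on {item.table!r} needs a "
                f"value column"
            )
    else:
        if value_col is None:
            raise ExtractionError(
                f"concept {concept!r}: col_itm on {item.table!r} needs a "
                f"value column"
            )
    out = pd.DataFrame({"id": df[id_col], "value": df[value_col]})
    if index_col is not None:
        out.insert(1, "time", df[index_col])
    if unit_col is not None:
        out["unit"] = df[unit_col]
    if dur_col is not None:
        out["dur"] = df[dur_col]
    out = out.loc[out["id"].notna()].reset_index(drop=True)
    if item.callback:
        fn = resolve_callback(item.callback)
        out["value"] = fn(out["value"])
    out = out.loc[out["value"].notna()].reset_index(drop=True)
    if "time" in out.columns:
        out = out.loc[out["time"].notna()].reset_index(drop=True)
        out["time"] = out["time"].astype("int64")
    if "dur" in out.columns:
        out["dur"] = out["dur"].astype("int64")
    return out


def enforce_bounds(rows: pd.DataFrame, concept: Concept) -> pd.DataFrame:
    """Remove values outside the concept's inclusive [min, max] range;
    no-op when no bounds are declared."""
    if concept.min is None and concept.max is None:
        return rows
    vals = pd.to_numeric(rows["value"], errors="coerce")
    keep = pd.Series(True, index=rows.index)
    if concept.min is not None:
        keep &= vals >= concept.min
    if concept.max is not None:
        keep &= vals <= concept.max
    keep &= vals.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("concept %r: removed %d value(s) outside [%s, %s]",
                    concept.name, n_drop, concept.min, concept.max)
    return rows.loc[keep].reset_index(drop=True)


def harmonize_units(rows: pd.DataFrame, concept: Concept
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Synchronize units of measurement.

    Rows whose unit string is among the concept's acceptable units pass
    unchanged; units with a registered conversion into an acceptable unit
    are rescaled; unknown units are kept with a warning and reported as
    flagged.
    """
    if "unit" not in rows.columns or not concept.unit:
        return rows, []
    accepted = {u.lower() for u in concept.unit}
    units = rows["unit"].astype(str).str.lower()
    flagged: list[str] = []
    out = rows.copy()
    for u in units.dropna().unique():
        if u in accepted or u == "nan":
            continue
        conv = UNIT_CONVERSIONS.get((concept.name, u)) \
            or UNIT_CONVERSIONS.get((None, u))
        mask = units == u
        if conv and conv[0].lower() in accepted:
            to_unit, fn = conv
            out.loc[mask, "value"] = fn(
                pd.to_numeric(out.loc[mask, "value"]))
            out.loc[mask, "unit"] = to_unit
        else:
            flagged.append(u)
            logger.warning("concept %r: unknown unit %r kept unconverted",
                           concept.name, u)
    return out, flagged


# ---------------------------------------------------------------------------
# id conversion of raw rows
# ---------------------------------------------------------------------------


def _raw_to_table(handle: SourceHandle, rows: pd.DataFrame, item: Item,
                  concept: Concept, id_type: str) -> IdTbl:
    """Turn extracted raw rows into a table keyed by the requested ID
    system with stay-relative integer-minute times."""
    cfg = handle.config
    tgt = cfg.id_system(id_type)
    id_col, *_ = _resolve_item_columns(handle, item)
    cur = None
    for s in cfg.id_systems:
        if s.id_column == id_col:
            cur = s
    if cur is None:
        raise ExtractionError(
            f"concept {concept.name!r}: id column {id_col!r} of table "
            f"{item.table!r} matches no declared id system"
        )
    has_time = "time" in rows.columns
    df = rows.rename(columns={"id": cur.id_column})
    if not has_time:
        tbl: IdTbl = IdTbl(df, id_vars=[cur.id_column])
        if cur.name != tgt.name:
            tbl = tabular.change_id(tbl, handle, tgt.name)
        return tbl
    df = df.rename(columns={"time": INDEX_COL})
    if cfg.time_mode == "relative":
        if cur.name != tgt.name:
            raise ExtractionError(
                f"source {cfg.name!r} is relative-time with a flat id "
                f"hierarchy; only id system {cur.name!r} is loadable"
            )
    else:
        # absolute times -> minutes relative to the row's own stay origin
        win = handle.id_windows()
        start = f"{cur.id_column}__start"
        sub = win[[cur.id_column, start]].drop_duplicates()
        df = df.merge(sub, on=cur.id_column, how="inner")
        df[INDEX_COL] = (df[INDEX_COL] - df[start]).astype("int64")
        df = df.drop(columns=[start])
    if "dur" in df.columns:
        df = df.rename(columns={"dur": DUR_COL})
        tbl = WinTbl(df, id_vars=[cur.id_column], index_var=INDEX_COL,
                     dur_var=DUR_COL, interval=1)
    else:
        tbl = TsTbl(df, id_vars=[cur.id_column], index_var=INDEX_COL,
                    interval=1)
    if cur.name != tgt.name:
        tbl = tabular.change_id(tbl, handle, tgt.name)
    return tbl


# ---------------------------------------------------------------------------
# concept loading
# ---------------------------------------------------------------------------


def _coerce_values(df: pd.DataFrame, concept: Concept) -> tuple[pd.DataFrame, int]:
    dropped = 0
    if concept.kind == "num_cncpt":
        df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)
        dropped = int(df["value"].isna().sum())
        df = df.loc[df["value"].notna()]
    elif concept.kind == "lgl_cncpt":
        df["value"] = df["value"].map(
            lambda v: bool(v) if not pd.isna(v) else pd.NA).astype("boolean")
    elif concept.kind == "fct_cncpt" and concept.levels:
        ok = df["value"].isin(concept.levels)
        dropped = int((~ok).sum())
        if dropped:
            logger.info("concept %r: dropped %d value(s) outside levels %s",
                        concept.name, dropped, concept.levels)
        df = df.loc[ok]
    return df.reset_index(drop=True), dropped


def _empty_result(handle: SourceHandle, concept: Concept, id_type: str,
                  interval: int) -> IdTbl:
    id_col = handle.config.id_system(id_type).id_column
    if concept.target == "id_tbl":
        df = pd.DataFrame({id_col: pd.Series([], dtype="int64"),
                           concept.name: pd.Series([], dtype=object)})
        return IdTbl(df, id_vars=[id_col])
    if concept.target == "win_tbl":
        df = pd.DataFrame({id_col: pd.Series([], dtype="int64"),
                           INDEX_COL: pd.Series([], dtype="int64"),
                           DUR_COL: pd.Series([], dtype="int64"),
                           concept.name: pd.Series([], dtype=object)})
        return WinTbl(df, id_vars=[id_col], index_var=INDEX_COL,
                      dur_var=DUR_COL, interval=interval)
    df = pd.DataFrame({id_col: pd.Series([], dtype="int64"),
                       INDEX_COL: pd.Series([], dtype="int64"),
                       concept.name: pd.Series([], dtype=float)})
    return TsTbl(df, id_vars=[id_col], index_var=INDEX_COL, interval=interval)


def load_atomic_concept(handle: SourceHandle, concept: Concept,
                        request: LoadRequest) -> ConceptResult:
    """Run the full single-concept pipeline: items -> callbacks -> unit
    harmonization -> bounds -> ID conversion -> time binning ->
    aggregation -> target-kind packaging."""
    src = handle.config.name
    items = concept.sources.get(src)
    if not items:
        raise AvailabilityError(
            f"concept {concept.name!r} has no items for source {src!r}"
        )
    flagged: list[str] = []
    parts: list[IdTbl] = []
    for item in items:
        rows = load_item(handle, item, concept=concept.name)
        rows, flags = harmonize_units(rows, concept)
        flagged += flags
        if concept.kind == "num_cncpt":
            rows = enforce_bounds(rows, concept)
        rows = rows.drop(columns=[c for c in ("unit",) if c in rows.columns])
        rows, _ = _coerce_values(rows, concept)
        if not len(rows):
            continue
        parts.append(_raw_to_table(handle, rows, item, concept,
                                   request.id_type))
    units = {concept.name: concept.unit[0]} if concept.unit else {}
    if not parts:
        tbl = _empty_result(handle, concept, request.id_type, request.interval)
        tbl.units = units
        return ConceptResult(tbl, units,
                             {concept.name: flagged} if flagged else {})
    id_col = handle.config.id_system(request.id_type).id_column
    frames = [p.df for p in parts]
    df = pd.concat(frames, ignore_index=True)
    agg = request.aggregate_overrides.get(concept.name,
                                          concept.default_aggregate())
    if concept.target == "id_tbl" or not isinstance(parts[0], TsTbl):
        if INDEX_COL in df.columns:
            df = df.drop(columns=[INDEX_COL])
        tbl = IdTbl(df, id_vars=[id_col], units=units)
        tbl = tabular.aggregate_by(tbl, agg)
    elif concept.target == "win_tbl":
        tbl = WinTbl(df, id_vars=[id_col], index_var=INDEX_COL,
                     dur_var=DUR_COL, interval=1, units=units)
        tbl = tabular.bin_index(tbl, request.interval)
        tbl = tabular.aggregate_by(tbl, agg)
    else:
        tbl = TsTbl(df, id_vars=[id_col], index_var=INDEX_COL, interval=1,
                    units=units)
        tbl = tabular.bin_index(tbl, request.interval)
        tbl = tabular.aggregate_by(tbl, agg)
    tbl = tbl.rename({"value": concept.name})
    tbl.df = tbl.df.sort_values(tbl.meta_vars, kind="stable").reset_index(
        drop=True)
    return ConceptResult(tbl, units, {concept.name: flagged} if flagged else {})


@dataclass
class CallbackContext:
    """Handed to recursive-concept callbacks alongside their dependency
    tables."""

    dictionary: ConceptDict
    handle: SourceHandle
    request: LoadRequest
    concept: Concept

    @property
    def interval(self) -> int:
        return self.request.interval

    @property
    def id_col(self) -> str:
        return self.handle.config.id_system(self.request.id_type).id_column


def resolve_recursive(dictionary: ConceptDict, handle: SourceHandle,
                      concept: Concept, request: LoadRequest) -> ConceptResult:
    """Load a recursive concept: topologically load its dependencies
    (propagating interval and ID system), hand the name -> table mapping to
    the concept's callback, package the output per the declared target."""
    deps: dict[str, IdTbl] = {}
    for dep_name in concept.depends:
        dep = dictionary.find(dep_name)
        sub = LoadRequest(concepts=[dep_name], id_type=request.id_type,
                          interval=request.interval,
                          aggregate_overrides=request.aggregate_overrides)
        try:
            res = _load_single(dictionary, handle, dep, sub)
        except AvailabilityError as exc:
            raise AvailabilityError(
                f"recursive concept {concept.name!r}: dependency "
                f"{dep_name!r} unavailable for source "
                f"{handle.config.name!r} ({exc})"
            ) from None
        deps[dep_name] = res.table
    fn = resolve_callback(concept.callback) if concept.callback else None
    if fn is None:
        raise AvailabilityError(
            f"recursive concept {concept.name!r} declares no callback")
    ctx = CallbackContext(dictionary, handle, request, concept)
    tbl = fn(deps, ctx)
    units = {concept.name: concept.unit[0]} if concept.unit else {}
    tbl.units = {**tbl.units, **units}
    tbl.df = tbl.df.sort_values(tbl.meta_vars, kind="stable").reset_index(
        drop=True)
    return ConceptResult(tbl, tbl.units)


def _load_single(dictionary: ConceptDict, handle: SourceHandle,
                 concept: Concept, request: LoadRequest) -> ConceptResult:
    if concept.is_recursive:
        return resolve_recursive(dictionary, handle, concept, request)
    return load_atomic_concept(handle, concept, request)


def _apply_patient_filter(tbl: IdTbl, patient_ids) -> IdTbl:
    if patient_ids is None:
        return tbl
    if isinstance(patient_ids, IdTbl):
        wanted = patient_ids.df[patient_ids.id_vars[-1]]
    else:
        wanted = pd.Series(list(patient_ids))
    keep = tbl.df[tbl.id_vars[-1]].isin(set(wanted.tolist()))
    return tbl.with_df(tbl.df.loc[keep].reset_index(drop=True))


def load_concepts(dictionary: ConceptDict, handle: SourceHandle,
                  request: LoadRequest | Sequence[str | int] | str | None = None,
                  **kwargs) -> ConceptResult:
    """Load one or more concepts and merge them into a single harmonized
    table.

    ``request`` may be a :class:`LoadRequest` or simply the concept name(s);
    keyword arguments then fill the remaining request fields.  Concepts
    queried by abbreviated name yield columns named by the abbreviation;
    concepts queried by integer OMOP ID yield ``omop_<id>`` columns.
    """
    if not isinstance(request, LoadRequest):
        if request is None:
            raise ValueError("specify the concepts to load")
        if isinstance(request, (str, int)):
            request = [request]
        request = LoadRequest(concepts=list(request), **kwargs)
    misses = []
    resolved: list[tuple[str | int, Concept]] = []
    for key in request.concepts:
        try:
            resolved.append((key, dictionary.find(key)))
        except ConceptLookupError as exc:
            misses.append(str(exc))
    if misses:
        raise ConceptLookupError("; ".join(misses))
    results = []
    units: dict[str, str] = {}
    flagged: dict[str, list[str]] = {}
    for key, concept in resolved:
        res = _load_single(dictionary, handle, concept, request)
        tbl = res.table
        if isinstance(key, int) and not isinstance(key, bool):
            new = f"omop_{concept.omopid}"
            tbl = tbl.rename({concept.name: new})
        units.update(tbl.units)
        flagged.update(res.flagged_units)
        results.append(tbl)
    merged = tabular.merge_concepts(results) if len(results) > 1 else results[0]
    merged.units = {**units, **merged.units}
    merged = _apply_patient_filter(merged, request.patient_ids)
    merged.df = merged.df.sort_values(merged.meta_vars, kind="stable"
                                      ).reset_index(drop=True)
    return ConceptResult(merged, merged.units, flagged)
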