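"""Declarative source configurations and registered source handles.

A *source configuration* describes one ICU database well enough for the
loading engine to operate dataset-agnostically: its ID systems (a nested
hierarchy such as patient > hospital stay > ICU stay, or a single flat stay
ID), its tables with column semantics, and per-table column defaults
(which column is the time index, the value, the unit, the row ID).

Two time modes exist, mirroring how public ICU databases actually differ:

* ``absolute`` -- timestamp columns hold ISO-8601 date-times (internally
  converted to integer minutes since a fixed epoch);
* ``relative`` -- timestamp columns hold integer minutes from the finest
  ID system's admission.

Data tables are RFC 4180 CSV with a header row, UTF-8, ``.`` decimal and
empty fields for missing values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ValidationError, field_validator

from .errors import ConfigError, SchemaError

logger = logging.getLogger("icukit")

#: epoch for the internal integer-minute representation of absolute times
EPOCH = pd.Timestamp("2000-01-01 00:00:00")

COLUMN_TYPES = ("id", "timestamp", "duration", "number", "string")


class ColumnDef(BaseModel):
    name: str
    type: Literal["id", "timestamp", "duration", "number", "string"]


class TableDefaults(BaseModel):
    index_column: Optional[str] = None
    value_column: Optional[str] = None
    unit_column: Optional[str] = None
    id_column: Optional[str] = None
    dur_column: Optional[str] = None


class TableDef(BaseModel):
    name: str
    file: str
    columns: list[ColumnDef]
    defaults: TableDefaults = TableDefaults()

    @field_validator("columns")
    @classmethod
    def _unique_columns(cls, v):
        names = [c.name for c in v]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names")
        return v

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column_type(self, name: str) -> str:
        for c in self.columns:
            if c.name == name:
                return c.type
        raise KeyError(name)


class IdSystemDef(BaseModel):
    name: str
    id_column: str
    origin_table: str
    start_column: Optional[str] = None
    end_column: Optional[str] = None
    rank: int


class SourceConfig(BaseModel):
    name: str
    time_mode: Literal["absolute", "relative"]
    id_systems: list[IdSystemDef]
    tables: list[TableDef]

    # -- invariants --------------------------------------------------------

    def check(self) -> "SourceConfig":
        names = [t.name for t in self.tables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate table name(s): {dupes}")
        ranks = sorted(s.rank for s in self.id_systems)
        if ranks != list(range(1, len(ranks) + 1)):
            raise ConfigError(
                f"id-system ranks must be 1..n, distinct and consecutive; got {ranks}"
            )
        tbl_by_name = {t.name: t for t in self.tables}
        for s in self.id_systems:
            if s.origin_table not in tbl_by_name:
                raise ConfigError(
                    f"id system {s.name!r}: origin table {s.origin_table!r} not declared"
                )
            origin = tbl_by_name[s.origin_table]
            cols = origin.column_names()
            for attr in ("id_column", "start_column", "end_column"):
                col = getattr(s, attr)
                if col is not None and col not in cols:
                    raise ConfigError(
                        f"id system {s.name!r}: {attr} {col!r} absent from "
                        f"table {s.origin_table!r}"
                    )
        for t in self.tables:
            cols = t.column_names()
            for attr, col in self.defaults_items(t):
                if col is not None and col not in cols:
                    raise ConfigError(
                        f"table {t.name!r}: defaults.{attr} references "
                        f"undeclared column {col!r}"
                    )
        return self

    @staticmethod
    def defaults_items(t: TableDef):
        d = t.defaults
        return [(k, getattr(d, k)) for k in
                ("index_column", "value_column", "unit_column", "id_column",
                 "dur_column")]

    # -- convenience -------------------------------------------------------

    def id_hierarchy(self) -> list[IdSystemDef]:
        """ID systems sorted coarse (rank 1) to fine."""
        return sorted(self.id_systems, key=lambda s: s.rank)

    def id_system(self, name: str) -> IdSystemDef:
        for s in self.id_systems:
            if s.name == name:
                return s
        raise ConfigError(f"unknown id system {name!r} in source {self.name!r}")

    def finest(self) -> IdSystemDef:
        return self.id_hierarchy()[-1]

    def table(self, name: str) -> TableDef:
        for t in self.tables:
            if t.name == name:
                return t
        raise ConfigError(f"unknown table {name!r} in source {self.name!r}")

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=1)


def parse_source_config(document: str | dict) -> SourceConfig:
    """Parse and validate a JSON source-configuration document."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed JSON: {exc}") from exc
    try:
        cfg = SourceConfig.model_validate(document)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = ".".join(str(p) for p in first["loc"])
        raise ConfigError(
            f"invalid source config at {path or '<root>'}: {first['msg']}"
        ) from exc
    return cfg.check()


# ---------------------------------------------------------------------------
# registered sources
# ---------------------------------------------------------------------------


def _parse_timestamps(series: pd.Series) -> pd.Series:
    """ISO-8601 -> integer minutes since :data:`EPOCH` (nullable)."""
    ts = pd.to_datetime(series, format="ISO8601", errors="raise")
    mins = (ts - EPOCH) / pd.Timedelta(minutes=1)
    return mins.round().astype("Int64")


class SourceHandle:
    """A source configuration bound to a directory of CSV tables.

    Tables are read lazily and cached; timestamp columns are normalized to
    integer minutes (since the epoch in absolute mode, from the finest
    stay's admission in relative mode).
    """

    def __init__(self, config: SourceConfig, data_dir: str | Path):
        self.config = config
        self.data_dir = Path(data_dir)
        self._cache: dict[str, pd.DataFrame] = {}
        self._windows: pd.DataFrame | None = None
        self._check_files()

    # -- validation at registration ----------------------------------------

    def _check_files(self) -> None:
        missing = [t.name for t in self.config.tables
                   if not (self.data_dir / t.file).exists()]
        if missing:
            raise IOError(
                f"source {self.config.name!r}: missing data file(s) for "
                f"table(s) {missing} under {self.data_dir}"
            )
        for t in self.config.tables:
            header = pd.read_csv(self.data_dir / t.file, nrows=0)
            have = list(header.columns)
            declared = t.column_names()
            absent = [c for c in declared if c not in have]
            if absent:
                raise SchemaError(
                    f"table {t.name!r}: declared column(s) {absent} absent "
                    f"from {t.file} (found {have})"
                )
            extra = [c for c in have if c not in declared]
            if extra:
                logger.warning(
                    "table %r: undeclared column(s) %s present in %s; ignored",
                    t.name, extra, t.file,
                )

    # -- data access -------------------------------------------------------

    def tables(self) -> list[str]:
        return [t.name for t in self.config.tables]

    def table(self, name: str) -> pd.DataFrame:
        if name in self._cache:
            return self._cache[name]
        tdef = self.config.table(name)
        # string columns must not be numerically inferred ("25013" is an
        # ICD-9 code, not the number 25013.0)
        dtypes = {c.name: str for c in tdef.columns if c.type == "string"}
        df = pd.read_csv(self.data_dir / tdef.file,
                         usecols=tdef.column_names(), dtype=dtypes)
        for c in tdef.columns:
            if c.type == "timestamp":
                if self.config.time_mode == "absolute":
                    df[c.name] = _parse_timestamps(df[c.name])
                else:
                    df[c.name] = pd.to_numeric(df[c.name]).round().astype("Int64")
            elif c.type == "duration":
                df[c.name] = pd.to_numeric(df[c.name]).round().astype("Int64")
            elif c.type == "id":
                col = df[c.name]
                if col.dtype == object:
                    try:
                        col = pd.to_numeric(col)
                    except (ValueError, TypeError):
                        pass
                if pd.api.types.is_numeric_dtype(col):
                    col = col.astype("Int64")
                df[c.name] = col
            elif c.type == "number":
                df[c.name] = pd.to_numeric(df[c.name]).astype(float)
            else:
                df[c.name] = df[c.name].astype(object)
        self._cache[name] = df
        return df

    # -- stay windows ------------------------------------------------------

    def id_windows(self) -> pd.DataFrame:
        """One row per finest stay: every system's ID value plus absolute
        ``<id_col>__start`` / ``<id_col>__end`` window bounds (float,
        right-open; a missing discharge extends to the next stay of the
        same coarser ID, or +inf)."""
        if self._windows is not None:
            return self._windows
        hier = self.config.id_hierarchy()
        finest = hier[-1]
        base = self.table(finest.origin_table)
        id_cols = [s.id_column for s in hier]
        missing = [c for c in id_cols if c not in base.columns]
        if missing:
            raise SchemaError(
                f"finest origin table {finest.origin_table!r} lacks id "
                f"column(s) {missing} needed to relate the id systems"
            )
        win = base[id_cols].drop_duplicates().reset_index(drop=True)
        for depth, sysdef in enumerate(hier):
            origin = self.table(sysdef.origin_table)
            cols = [sysdef.id_column]
            start = sysdef.start_column
            end = sysdef.end_column
            sel = origin[cols + [c for c in (start, end) if c]].drop_duplicates(
                subset=cols)
            sel = sel.rename(columns={
                **({start: f"{sysdef.id_column}__start"} if start else {}),
                **({end: f"{sysdef.id_column}__end"} if end else {}),
            })
            win = win.merge(sel, on=sysdef.id_column, how="left")
            sc = f"{sysdef.id_column}__start"
            ec = f"{sysdef.id_column}__end"
            if start is None:
                win[sc] = np.nan
            if end is None:
                win[ec] = np.nan
            win[sc] = win[sc].astype(float)
            win[ec] = win[ec].astype(float)
            # missing end: right-open until the next stay of the coarser ID
            if win[ec].isna().any():
                group = [hier[depth - 1].id_column] if depth else []
                order = win.sort_values(sc, kind="stable")
                if group:
                    nxt = order.groupby(group)[sc].shift(-1)
                else:
                    nxt = order[sc].shift(-1)
                fill = nxt.reindex(win.index)
                win[ec] = win[ec].fillna(fill).fillna(np.inf)
        self._windows = win
        return win

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SourceHandle {self.config.name!r} at {self.data_dir} "
                f"({len(self.config.tables)} tables)>")


def register_source(cfg: SourceConfig | str | dict,
                    data_dir: str | Path) -> SourceHandle:
    """Bind a (parsed or raw JSON) source config to a data directory.

    File presence and header conformance are verified up front; undeclared
    extra columns are tolerated with a logged warning.
    """
    if not isinstance(cfg, SourceConfig):
        cfg = parse_source_config(cfg)
    return SourceHandle(cfg, data_dir)


def load_registered_source(source_dir: str | Path) -> SourceHandle:
    """Register the source described by ``<source_dir>/source_config.json``."""
    source_dir = Path(source_dir)
    cfg_file = source_dir / "source_config.json"
    if not cfg_file.exists():
        raise IOError(f"no source_config.json under {source_dir}")
    return register_source(cfg_file.read_text(), source_dir)
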