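"""Clinical concept dictionary: parsing, validation, merging, querying.

A *concept* is a named clinical variable (heart rate, lactate, ...) with an
optional OMOP vocabulary ID, acceptable units, plausibility bounds, a target
table kind and, per source database, a list of extraction *items*.  Concepts
come in four kinds:

* ``num_cncpt`` -- numeric, with optional ``min``/``max`` plausibility
  bounds (values outside are removed at load time) and unit strings;
* ``lgl_cncpt`` -- logical (no units or bounds);
* ``fct_cncpt`` -- categorical with an allowed level set (values outside
  the levels are dropped with a logged count);
* ``rec_cncpt`` -- recursive: computed from other concepts by a callback,
  source-agnostically (e.g. SOFA, Sepsis-3).

Items are either ``sel_itm`` (select rows of a long event table whose code
column ``sub_var`` matches one of ``ids``) or ``col_itm`` (read a whole
column), optionally post-processed by a *callback*.  Callbacks are stored in
dictionary documents as reference strings -- a bare registered name or a
single factory application such as ``"transform_fun(grep_diab)"`` -- and are
resolved against a named registry at validation time; no arbitrary code is
ever evaluated from JSON.

Dictionary documents are JSON mappings of concept name to definition.  Later
documents override earlier ones per concept name, which is how user
dictionaries (discovered through the ``ICUKIT_CONFIG_PATH`` environment
variable) extend or patch the shipped dictionary.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
import re
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from importlib import resources
from pathlib import Path
from typing import Callable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ValidationError, model_validator

from .errors import ConceptLookupError, DependencyError, DictionaryError

logger = logging.getLogger("icukit")

#: environment variable listing extra dictionary folders (path separator
#: separated), consulted by :func:`discover_user_dictionaries`
CONFIG_PATH_VAR = "ICUKIT_CONFIG_PATH"

CONCEPT_KINDS = ("num_cncpt", "lgl_cncpt", "fct_cncpt", "rec_cncpt")
TARGETS = ("id_tbl", "ts_tbl", "win_tbl")


# ---------------------------------------------------------------------------
# callback registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable] = {}
_FACTORIES: set[str] = set()

_REF_RE = re.compile(r"^\s*([A-Za-z_][\w.]*)\s*(?:\(\s*([A-Za-z_][\w.]*)\s*\))?\s*$")


def register_callback(name: str, fn: Callable, factory: bool = False,
                      overwrite: bool = False) -> str:
    """Register ``fn`` under ``name``; returns the reference string."""
    if name in _REGISTRY and not overwrite:
        raise DictionaryError(f"callback name {name!r} already registered")
    _REGISTRY[name] = fn
    if factory:
        _FACTORIES.add(name)
    return name


def resolve_callback(ref: str) -> Callable:
    """Resolve a callback reference string against the registry.

    Grammar: ``name`` or ``factory(name)``; both identifiers must be
    registered, and in the second form the outer one must be a factory.
    """
    m = _REF_RE.match(ref)
    if not m:
        raise DictionaryError(f"malformed callback reference {ref!r}")
    outer, inner = m.groups()
    if outer not in _REGISTRY:
        raise DictionaryError(f"unknown callback {outer!r}")
    if inner is None:
        return _REGISTRY[outer]
    if outer not in _FACTORIES:
        raise DictionaryError(f"{outer!r} is not a callback factory")
    if inner not in _REGISTRY:
        raise DictionaryError(f"unknown callback {inner!r} (argument of {outer!r})")
    return _REGISTRY[outer](_REGISTRY[inner])


def transform_fun(fn: Callable) -> Callable[[pd.Series], pd.Series]:
    """Factory lifting a pure elementwise function to a value-column
    transform (the ``transform_fun(grep_diab)`` mechanism)."""
    def _apply(values: pd.Series) -> pd.Series:
        return values.map(fn)
    _apply.__name__ = f"transform_fun({getattr(fn, '__name__', 'fn')})"
    return _apply


register_callback("transform_fun", transform_fun, factory=True)


def make_transform_callback(name: str, fn: Callable) -> str:
    """Register a pure elementwise function and return the reference string
    ``"transform_fun(<name>)"`` usable as an item callback."""
    register_callback(name, fn)
    return f"transform_fun({name})"


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class Item(BaseModel):
    """One extraction rule for a concept in one source."""

    kind: Literal["sel_itm", "col_itm"] = "sel_itm"
    table: str
    sub_var: Optional[str] = None
    ids: Optional[list[int | str]] = None
    value_column: Optional[str] = None
    unit_column: Optional[str] = None
    index_column: Optional[str] = None
    dur_column: Optional[str] = None
    id_column: Optional[str] = None
    callback: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "sel_itm":
            if not self.ids or self.sub_var is None:
                raise ValueError("sel_itm requires non-empty ids and a sub_var")
        else:
            if self.ids or self.sub_var is not None:
                raise ValueError("col_itm takes neither ids nor sub_var")
        return self


class Concept(BaseModel):
    name: str
    kind: Literal["num_cncpt", "lgl_cncpt", "fct_cncpt", "rec_cncpt"] = "num_cncpt"
    omopid: Optional[int] = None
    description: str = ""
    category: str = ""
    unit: list[str] = []
    min: Optional[float] = None
    max: Optional[float] = None
    levels: Optional[list[str]] = None
    target: Literal["id_tbl", "ts_tbl", "win_tbl"] = "ts_tbl"
    aggregate: Optional[str] = None
    sources: dict[str, list[Item]] = {}
    depends: list[str] = []
    callback: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "rec_cncpt":
            if not self.depends:
                raise ValueError("rec_cncpt requires a depends list")
            if self.sources:
                raise ValueError("rec_cncpt takes no sources")
        else:
            if self.depends:
                raise ValueError("only rec_cncpt may declare depends")
        if self.kind == "lgl_cncpt" and (self.unit or self.min is not None
                                         or self.max is not None):
            raise ValueError("lgl_cncpt has no unit/min/max")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("min must not exceed max")
        return self

    @property
    def is_recursive(self) -> bool:
        return self.kind == "rec_cncpt"

    def default_aggregate(self) -> str:
        if self.aggregate:
            return self.aggregate
        if self.kind == "lgl_cncpt":
            return "any"
        if self.kind == "fct_cncpt":
            return "first"
        return "median"

    def validate_callbacks(self) -> None:
        if self.callback:
            resolve_callback(self.callback)
        for items in self.sources.values():
            for it in items:
                if it.callback:
                    resolve_callback(it.callback)

    def to_document_entry(self) -> dict:
        body = self.model_dump(mode="json", exclude_none=True, exclude={"name"})
        for k in ("unit", "sources", "depends"):
            if not body.get(k):
                body.pop(k, None)
        if body.get("sources"):
            body["sources"] = {
                src: [
                    {k: v for k, v in it.items() if v is not None}
                    for it in body["sources"][src]
                ]
                for src in body["sources"]
            }
        return body


# ---------------------------------------------------------------------------
# the dictionary
# ---------------------------------------------------------------------------


@dataclass
class DictStats:
    """Composition report of a dictionary."""

    total: int
    n_atomic: int
    n_recursive: int
    by_category: dict[str, int]
    by_kind: dict[str, int]
    per_source: dict[str, int] = field(default_factory=dict)


class ConceptDict:
    """A validated set of concepts with per-concept provenance."""

    def __init__(self, concepts: Mapping[str, Concept],
                 provenance: Mapping[str, str] | None = None):
        self.concepts: dict[str, Concept] = dict(concepts)
        self.provenance: dict[str, str] = dict(provenance or {})
        self._check()

    def _check(self) -> None:
        seen_omop: dict[int, str] = {}
        for name, c in self.concepts.items():
            if c.omopid is not None:
                if c.omopid in seen_omop:
                    raise DictionaryError(
                        f"omopid {c.omopid} assigned to both "
                        f"{seen_omop[c.omopid]!r} and {name!r}"
                    )
                seen_omop[c.omopid] = name
        # recursive dependency graph must be acyclic (unknown leaves are
        # allowed at parse time; they fail with a lookup error at load time)
        graph = {n: [d for d in c.depends]
                 for n, c in self.concepts.items() if c.is_recursive}
        try:
            list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise DependencyError(
                f"cycle among recursive concepts: {exc.args[1]}"
            ) from exc
        for c in self.concepts.values():
            c.validate_callbacks()

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, name: str) -> bool:
        return name in self.concepts

    def names(self) -> list[str]:
        return sorted(self.concepts)

    def find(self, key: str | int) -> Concept:
        """Exact match on abbreviated name (str) or OMOP concept ID (int)."""
        if isinstance(key, int) and not isinstance(key, bool):
            for c in self.concepts.values():
                if c.omopid == key:
                    return c
            raise ConceptLookupError(f"no concept with OMOP id {key}")
        if key in self.concepts:
            return self.concepts[key]
        near = difflib.get_close_matches(str(key), self.concepts, n=3)
        hint = f"; did you mean {near}?" if near else ""
        raise ConceptLookupError(f"unknown concept {key!r}{hint}")

    def stats(self) -> DictStats:
        by_cat: dict[str, int] = {}
        by_kind: dict[str, int] = {}
        sources: set[str] = set()
        for c in self.concepts.values():
            by_cat[c.category] = by_cat.get(c.category, 0) + 1
            by_kind[c.kind] = by_kind.get(c.kind, 0) + 1
            sources.update(c.sources)
        per_source = {
            src: sum(1 for c in self.concepts.values()
                     if not c.is_recursive and c.sources.get(src))
            for src in sorted(sources)
        }
        n_rec = by_kind.get("rec_cncpt", 0)
        return DictStats(
            total=len(self.concepts),
            n_atomic=len(self.concepts) - n_rec,
            n_recursive=n_rec,
            by_category=by_cat,
            by_kind=by_kind,
            per_source=per_source,
        )

    # -- merging and serialization -----------------------------------------

    def merged_with(self, other: "ConceptDict") -> "ConceptDict":
        """Later dictionary wins per concept name; provenance records the
        override."""
        concepts = dict(self.concepts)
        prov = dict(self.provenance)
        for name, c in other.concepts.items():
            if name in concepts:
                logger.info("concept %r overridden by %s", name,
                            other.provenance.get(name, "<user>"))
            concepts[name] = c
            prov[name] = other.provenance.get(name, "<user>")
        return ConceptDict(concepts, prov)

    def to_document(self) -> dict:
        return {name: self.concepts[name].to_document_entry()
                for name in sorted(self.concepts)}

    def to_json(self) -> str:
        return json.dumps(self.to_document(), indent=1, sort_keys=True)


def _parse_one(document: str | dict, origin: str = "<string>") -> ConceptDict:
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise DictionaryError(f"{origin}: malformed JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise DictionaryError(f"{origin}: dictionary document must be an object")
    concepts = {}
    for name, body in document.items():
        if not isinstance(body, dict):
            raise DictionaryError(f"{origin}: concept {name!r} must be an object")
        body = dict(body)
        # accept the field spellings used in published concept JSON
        body.setdefault("kind", body.pop("class", "num_cncpt"))
        if "concepts" in body:
            body.setdefault("depends", body.pop("concepts"))
        if isinstance(body.get("depends"), str):
            body["depends"] = [body["depends"]]
        if isinstance(body.get("unit"), str):
            body["unit"] = [body["unit"]]
        srcs = body.get("sources") or {}
        norm_sources = {}
        for src, items in srcs.items():
            norm_items = []
            for it in items:
                it = dict(it)
                it.setdefault("kind", it.pop("class", None) or
                              ("sel_itm" if it.get("ids") else "col_itm"))
                if "val_var" in it:
                    it.setdefault("value_column", it.pop("val_var"))
                if "unit_var" in it:
                    it.setdefault("unit_column", it.pop("unit_var"))
                if "index_var" in it:
                    it.setdefault("index_column", it.pop("index_var"))
                norm_items.append(it)
            norm_sources[src] = norm_items
        body["sources"] = norm_sources
        try:
            concepts[name] = Concept.model_validate({"name": name, **body})
        except ValidationError as exc:
            first = exc.errors()[0]
            path = ".".join(str(p) for p in first["loc"])
            raise DictionaryError(
                f"{origin}: concept {name!r} invalid at {path or '<root>'}: "
                f"{first['msg']}"
            ) from exc
    return ConceptDict(concepts, {n: origin for n in concepts})


def parse_dictionary(documents: Sequence[str | dict] | str | dict,
                     origins: Sequence[str] | None = None) -> ConceptDict:
    """Parse one or more JSON dictionary documents into a validated
    :class:`ConceptDict`; later documents override earlier ones per
    concept name."""
    if isinstance(documents, (str, dict)):
        documents = [documents]
    if origins is None:
        origins = [f"<document {i}>" for i in range(len(documents))]
    out: ConceptDict | None = None
    for doc, origin in zip(documents, origins):
        d = _parse_one(doc, origin)
        out = d if out is None else out.merged_with(d)
    if out is None:
        out = ConceptDict({})
    return out


# ---------------------------------------------------------------------------
# shipped + user dictionaries
# ---------------------------------------------------------------------------


def shipped_documents() -> tuple[list[str], list[str]]:
    """The dictionary JSON files shipped with the package."""
    root = resources.files("icukit").joinpath("data/dictionary")
    docs, names = [], []
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            docs.append(entry.read_text())
            names.append(f"shipped:{entry.name}")
    return docs, names


def discover_user_dictionaries(env: Mapping[str, str] | None = None
                               ) -> tuple[list[str], list[str]]:
    """Dictionary documents from the folders listed in the
    ``ICUKIT_CONFIG_PATH`` environment variable (appended after the shipped
    dictionary; unreadable files are skipped with a warning)."""
    env = os.environ if env is None else env
    raw = env.get(CONFIG_PATH_VAR, "")
    docs, names = [], []
    for folder in (p for p in raw.split(os.pathsep) if p):
        path = Path(folder)
        if not path.is_dir():
            logger.warning("%s: %s is not a directory; skipped",
                           CONFIG_PATH_VAR, folder)
            continue
        for f in sorted(path.glob("*.json")):
            try:
                docs.append(f.read_text())
                names.append(str(f))
            except OSError as exc:
                logger.warning("skipping unreadable dictionary %s: %s", f, exc)
    return docs, names


def load_dictionary(env: Mapping[str, str] | None = None,
                    extra_documents: Sequence[str | dict] = ()) -> ConceptDict:
    """The shipped dictionary, extended by user dictionaries discovered via
    the environment and by ``extra_documents`` (highest precedence)."""
    docs, names = shipped_documents()
    udocs, unames = discover_user_dictionaries(env)
    docs += udocs + list(extra_documents)
    names += unames + [f"<extra {i}>" for i in range(len(extra_documents))]
    return parse_dictionary(docs, names)
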