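"""Clinical concept callbacks: SOFA, Sepsis-3, GCS and friends.

Recursive concepts are computed from already-harmonized dependency tables,
source-agnostically.  The callbacks here receive a mapping of dependency
name to table plus a :class:`~icukit.load.CallbackContext` and return a
table of the concept's declared target kind.

SOFA is scored per organ system on the worst (most severe) value over the
preceding 24 hours, evaluated on the table's regular grid; a missing
component contributes 0 toward the total, which therefore always lies in
[0, 24].  The Sepsis-3 label requires a suspected-infection episode
(antibiotics and culture sampling close in time) plus an acute SOFA
increase of at least 2 points in a window around the suspicion onset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tabular
from .concepts import register_callback
from .load import DUR_COL, INDEX_COL, CallbackContext
from .tabular import IdTbl, TsTbl, WinTbl

HOUR = 60
DAY = 24 * HOUR


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sep3Rule:
    """Suspected-infection pairing windows and the required SOFA delta.

    ``abx_to_samp``: a culture drawn no more than this long *after* an
    antibiotic marks suspicion (default 24 h); ``samp_to_abx``: an
    antibiotic no more than this long after a culture (default 72 h).  The
    SOFA evaluation window spans ``si_pre`` before to ``si_post`` after the
    suspicion onset; the label fires at the first grid time where SOFA
    exceeds the window minimum so far by at least ``delta``.
    """

    abx_to_samp: int = 24 * HOUR
    samp_to_abx: int = 72 * HOUR
    si_pre: int = 48 * HOUR
    si_post: int = 24 * HOUR
    delta: int = 2

    def __post_init__(self):
        if min(self.abx_to_samp, self.samp_to_abx, self.si_pre,
               self.si_post) < 0 or self.delta < 0:
            raise ValueError("rule windows and delta must be non-negative")


SOFA_COMPONENTS = ("sofa_resp", "sofa_coag", "sofa_liver", "sofa_cardio",
                   "sofa_cns", "sofa_renal")


# elementwise component scoring (canonical units; thresholds are the
# standard clinical definition, fixed here)

def score_coag(plt: pd.Series) -> pd.Series:
    """Platelets in 1000/uL."""
    return pd.cut(plt, [-np.inf, 20, 50, 100, 150, np.inf],
                  labels=[4, 3, 2, 1, 0], right=False).astype(float)


def score_liver(bili: pd.Series) -> pd.Series:
    """Total bilirubin in mg/dL."""
    return pd.cut(bili, [-np.inf, 1.2, 2.0, 6.0, 12.0, np.inf],
                  labels=[0, 1, 2, 3, 4], right=False).astype(float)


def score_renal(crea: pd.Series) -> pd.Series:
    """Serum creatinine in mg/dL."""
    return pd.cut(crea, [-np.inf, 1.2, 2.0, 3.5, 5.0, np.inf],
                  labels=[0, 1, 2, 3, 4], right=False).astype(float)


def score_cns(gcs: pd.Series) -> pd.Series:
    """Glasgow Coma Scale total (3-15)."""
    return pd.cut(gcs, [-np.inf, 6, 10, 13, 15, np.inf],
                  labels=[4, 3, 2, 1, 0], right=False).astype(float)


def score_resp(pafi: pd.Series, vented: pd.Series) -> pd.Series:
    """PaO2/FiO2 in mmHg; scores 3 and 4 require ventilatory support."""
    v = vented.fillna(False).astype(bool)
    out = pd.Series(np.nan, index=pafi.index)
    out[pafi >= 400] = 0.0
    out[pafi < 400] = 1.0
    out[pafi < 300] = 2.0
    out[(pafi < 200) & v] = 3.0
    out[(pafi < 100) & v] = 4.0
    return out


def score_cardio(map_: pd.Series, dopa: pd.Series, dobu: pd.Series,
                 norepi: pd.Series, epi: pd.Series) -> pd.Series:
    """MAP in mmHg, catecholamine rates in ug/kg/min."""
    dopa = dopa.fillna(0.0)
    dobu = dobu.fillna(0.0)
    norepi = norepi.fillna(0.0)
    epi = epi.fillna(0.0)
    out = pd.Series(np.nan, index=map_.index)
    out[map_ >= 70] = 0.0
    out[map_ < 70] = 1.0
    out[(dopa > 0) | (dobu > 0)] = 2.0
    out[((dopa > 5) | ((norepi > 0) & (norepi <= 0.1))
         | ((epi > 0) & (epi <= 0.1)))] = 3.0
    out[(dopa > 15) | (norepi > 0.1) | (epi > 0.1)] = 4.0
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _merge_deps(deps: dict[str, IdTbl], ctx: CallbackContext) -> TsTbl | IdTbl:
    return tabular.merge_concepts(list(deps.values()))


def _empty_ts(ctx: CallbackContext, name: str, dtype=float) -> TsTbl:
    df = pd.DataFrame({ctx.id_col: pd.Series([], dtype="int64"),
                       INDEX_COL: pd.Series([], dtype="int64"),
                       name: pd.Series([], dtype=dtype)})
    return TsTbl(df, id_vars=[ctx.id_col], index_var=INDEX_COL,
                 interval=ctx.interval)


def _empty_id(ctx: CallbackContext, name: str, dtype=object) -> IdTbl:
    df = pd.DataFrame({ctx.id_col: pd.Series([], dtype="int64"),
                       name: pd.Series([], dtype=dtype)})
    return IdTbl(df, id_vars=[ctx.id_col])


def _keep(tbl: TsTbl, name: str, values: pd.Series, drop_na: bool = True
          ) -> TsTbl:
    df = tbl.df[tbl.meta_vars].copy()
    df[name] = np.asarray(values)
    if drop_na:
        df = df.loc[df[name].notna()].reset_index(drop=True)
    return TsTbl(df, id_vars=tbl.id_vars, index_var=tbl.index_var,
                 interval=tbl.interval)


def _worst_24h(tbl: TsTbl, name: str) -> TsTbl:
    """Densify the grid per id, then take the running 24 h maximum of the
    score column (missing scores ignored; empty windows stay missing)."""
    if not len(tbl.df):
        return tbl
    filled = tabular.fill_gaps(tbl)
    return tabular.slide(filled, before=DAY, after=0, fun="max")


def _component(deps, ctx, name, compute) -> TsTbl:
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, name)
    scores = compute(merged.df)
    tbl = _keep(merged, name, scores)
    if not len(tbl.df):
        return _empty_ts(ctx, name)
    return _worst_24h(tbl, name)


# ---------------------------------------------------------------------------
# SOFA component callbacks
# ---------------------------------------------------------------------------


def sofa_coag_cb(deps, ctx):
    return _component(deps, ctx, "sofa_coag",
                      lambda df: score_coag(df["plt"]))


def sofa_liver_cb(deps, ctx):
    return _component(deps, ctx, "sofa_liver",
                      lambda df: score_liver(df["bili"]))


def sofa_renal_cb(deps, ctx):
    return _component(deps, ctx, "sofa_renal",
                      lambda df: score_renal(df["crea"]))


def sofa_cns_cb(deps, ctx):
    return _component(deps, ctx, "sofa_cns",
                      lambda df: score_cns(df["gcs"]))


def sofa_resp_cb(deps, ctx):
    def compute(df):
        vent = df["vent_ind"] if "vent_ind" in df.columns else pd.Series(
            False, index=df.index)
        return score_resp(df["pafi"], vent)
    return _component(deps, ctx, "sofa_resp", compute)


def sofa_cardio_cb(deps, ctx):
    def compute(df):
        def col(n):
            return df[n] if n in df.columns else pd.Series(np.nan,
                                                           index=df.index)
        return score_cardio(col("map"), col("dopa_rate"), col("dobu_rate"),
                            col("norepi_rate"), col("epi_rate"))
    return _component(deps, ctx, "sofa_cardio", compute)


def sofa_cb(deps, ctx):
    """Total SOFA: outer-merge the six component tables, densify the per-id
    grid, count a missing component as 0, and sum hourly."""
    merged = _merge_deps(deps, ctx)
    if not len(merged.df):
        return _empty_ts(ctx, "sofa")
    filled = tabular.fill_gaps(merged)
    df = filled.df
    total = sum(df[c].fillna(0.0) for c in SOFA_COMPONENTS if c in df.columns)
    return _keep(filled, "sofa", total, drop_na=False)


# ---------------------------------------------------------------------------
# Sepsis-3
# ---------------------------------------------------------------------------


def suspected_infection(abx: TsTbl, samp: TsTbl,
                        rule: Sep3Rule = Sep3Rule()) -> TsTbl:
    """First suspected-infection onset per id.

    An antibiotic administration pairs with a culture drawn within
    ``rule.abx_to_samp`` afterwards (onset = antibiotic time), or a culture
    pairs with an antibiotic within ``rule.samp_to_abx`` afterwards
    (onset = culture time).  The earliest qualifying onset is reported.
    """
    id_col = abx.id_vars[-1]
    a = abx.df.groupby(id_col)[abx.index_var].apply(sorted).to_dict()
    s = samp.df.groupby(id_col)[samp.index_var].apply(sorted).to_dict()
    rows = []
    for i in sorted(set(a) | set(s)):
        at = np.asarray(a.get(i, []), dtype=np.int64)
        st = np.asarray(s.get(i, []), dtype=np.int64)
        if not len(at) or not len(st):
            continue
        onsets = []
        for t in at:
            if ((st >= t) & (st <= t + rule.abx_to_samp)).any():
                onsets.append(t)
        for t in st:
            if ((at >= t) & (at <= t + rule.samp_to_abx)).any():
                onsets.append(t)
        if onsets:
            rows.append((i, min(onsets), True))
    df = pd.DataFrame(rows, columns=[id_col, abx.index_var, "susp_inf"])
    if not len(df):
        df = pd.DataFrame({id_col: pd.Series([], dtype="int64"),
                           abx.index_var: pd.Series([], dtype="int64"),
                           "susp_inf": pd.Series([], dtype="boolean")})
    df["susp_inf"] = df["susp_inf"].astype("boolean")
    return TsTbl(df, id_vars=[id_col], index_var=abx.index_var,
                 interval=abx.interval)


def sep3_label(sofa: TsTbl, susp: TsTbl,
               rule: Sep3Rule = Sep3Rule()) -> TsTbl:
    """Sepsis-3: per id, the first time in ``[onset - si_pre,
    onset + si_post]`` where SOFA exceeds the running window minimum by at
    least ``rule.delta``."""
    id_col = sofa.id_vars[-1]
    idx = sofa.index_var
    rows = []
    susp_by_id = susp.df.groupby(id_col)[susp.index_var].min().to_dict()
    for i, grp in sofa.df.groupby(id_col):
        if i not in susp_by_id:
            continue
        onset = susp_by_id[i]
        grp = grp.sort_values(idx)
        win = grp.loc[(grp[idx] >= onset - rule.si_pre)
                      & (grp[idx] <= onset + rule.si_post)]
        vals = win["sofa"].to_numpy(dtype=float)
        times = win[idx].to_numpy(dtype=np.int64)
        running = np.fmin.accumulate(np.where(np.isnan(vals), np.inf, vals))
        hit = np.nonzero(vals - running >= rule.delta)[0]
        if len(hit):
            rows.append((i, int(times[hit[0]]), True))
    df = pd.DataFrame(rows, columns=[id_col, idx, "sep3"])
    if not len(df):
        df = pd.DataFrame({id_col: pd.Series([], dtype="int64"),
                           idx: pd.Series([], dtype="int64"),
                           "sep3": pd.Series([], dtype="boolean")})
    df["sep3"] = df["sep3"].astype("boolean")
    return TsTbl(df, id_vars=[id_col], index_var=idx, interval=sofa.interval)


def susp_inf_cb(deps, ctx):
    return suspected_infection(deps["abx"], deps["samp"])


def sep3_cb(deps, ctx):
    return sep3_label(deps["sofa"], deps["susp_inf"])


# ---------------------------------------------------------------------------
# other recursive concepts
# ---------------------------------------------------------------------------


def gcs_cb(deps, ctx):
    """Total Glasgow Coma Scale: eye + motor + verbal; rows where a
    component is missing fall back to the charted total."""
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "gcs")
    df = merged.df

    def col(n):
        return df[n] if n in df.columns else pd.Series(np.nan, index=df.index)

    total = col("egcs") + col("mgcs") + col("vgcs")
    total = total.where(total.notna(), col("tgcs"))
    return _keep(merged, "gcs", total)


def _ratio_cb(name, num, den, scale=1.0):
    def cb(deps, ctx):
        merged = _merge_deps(deps, ctx)
        if not len(merged.df) or not isinstance(merged, TsTbl):
            return _empty_ts(ctx, name)
        df = merged.df
        if num not in df.columns or den not in df.columns:
            return _empty_ts(ctx, name)
        vals = scale * df[num] / df[den].replace(0, np.nan)
        return _keep(merged, name, vals)
    cb.__name__ = f"{name}_cb"
    return cb


pafi_cb = _ratio_cb("pafi", "po2", "fio2", scale=100.0)
safi_cb = _ratio_cb("safi", "o2sat", "fio2", scale=100.0)
nlr_cb = _ratio_cb("nlr", "neut", "lymph")
shock_idx_cb = _ratio_cb("shock_idx", "hr", "sbp")


def agap_cb(deps, ctx):
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "agap")
    df = merged.df
    vals = df["na"] - df["cl"] - df["bicar"]
    return _keep(merged, "agap", vals)


def egfr_cb(deps, ctx):
    """MDRD estimated GFR (mL/min/1.73m2) from creatinine, age and sex."""
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "egfr")
    df = merged.df
    if not {"crea", "age", "sex"} <= set(df.columns):
        return _empty_ts(ctx, "egfr")
    female = df["sex"].astype(str).str.lower().str.startswith("f")
    vals = (175.0 * df["crea"].astype(float).replace(0, np.nan) ** -1.154
            * df["age"].astype(float) ** -0.203
            * np.where(female, 0.742, 1.0))
    return _keep(merged, "egfr", vals)


def bmi_cb(deps, ctx):
    merged = _merge_deps(deps, ctx)
    if not len(merged.df):
        return _empty_id(ctx, "bmi", float)
    df = merged.df
    vals = df["weight"] / (df["height"] / 100.0) ** 2
    out = df[[ctx.id_col]].copy()
    out["bmi"] = vals
    out = out.loc[out["bmi"].notna()].reset_index(drop=True)
    return IdTbl(out, id_vars=[ctx.id_col])


def urine24_cb(deps, ctx):
    """Urine output summed over the preceding 24 hours."""
    urine = deps["urine"]
    if not len(urine.df):
        return _empty_ts(ctx, "urine24")
    filled = tabular.fill_gaps(urine)
    out = tabular.slide(filled, before=DAY, after=0, fun="sum")
    return out.rename({"urine": "urine24"})


def vent_ind_cb(deps, ctx):
    """Ventilation indicator: mechanical-ventilation windows unrolled onto
    the grid as a logical series."""
    mv = deps["mech_vent"]
    if isinstance(mv, WinTbl):
        mv = tabular.expand(mv)
    if not len(mv.df):
        return _empty_ts(ctx, "vent_ind", "boolean")
    df = mv.df[[ctx.id_col, mv.index_var]].copy()
    df["vent_ind"] = pd.Series(True, index=df.index, dtype="boolean")
    df = df.drop_duplicates().reset_index(drop=True)
    return TsTbl(df, id_vars=[ctx.id_col], index_var=mv.index_var,
                 interval=mv.interval)


def supp_o2_cb(deps, ctx):
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "supp_o2", "boolean")
    df = merged.df

    def col(n, default):
        return df[n] if n in df.columns else pd.Series(default, index=df.index)

    vals = (col("vent_ind", pd.NA).astype("boolean").fillna(False)
            | (col("fio2", np.nan) > 21.0)).astype("boolean")
    return _keep(merged, "supp_o2", vals, drop_na=False)


def norepi_equiv_cb(deps, ctx):
    """Norepinephrine-equivalent catecholamine dose (ug/kg/min)."""
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "norepi_equiv")
    df = merged.df

    def col(n):
        return (df[n] if n in df.columns
                else pd.Series(np.nan, index=df.index)).fillna(0.0)

    vals = col("norepi_rate") + col("epi_rate") + col("dopa_rate") / 150.0 \
        + col("phn_rate") / 10.0
    vals[df[[c for c in ("norepi_rate", "epi_rate", "dopa_rate", "phn_rate")
             if c in df.columns]].isna().all(axis=1)] = np.nan
    return _keep(merged, "norepi_equiv", vals)


def vaso_ind_cb(deps, ctx):
    merged = _merge_deps(deps, ctx)
    if not len(merged.df) or not isinstance(merged, TsTbl):
        return _empty_ts(ctx, "vaso_ind", "boolean")
    df = merged.df
    rate_cols = [c for c in df.columns if c.endswith("_rate")]
    vals = (df[rate_cols] > 0).any(axis=1).astype("boolean")
    return _keep(merged, "vaso_ind", vals, drop_na=False)


def ins24_cb(deps, ctx):
    """Total insulin over the first 24 h of the ICU stay, binned."""
    ins = deps["ins"]
    df = ins.df
    day1 = df.loc[(df[ins.index_var] >= 0) & (df[ins.index_var] <= DAY)]
    totals = day1.groupby(ctx.id_col)["ins"].sum().reset_index()
    totals["ins24"] = cut_insulin(totals["ins"])
    out = totals[[ctx.id_col, "ins24"]]
    if not len(out):
        return _empty_id(ctx, "ins24")
    return IdTbl(out, id_vars=[ctx.id_col])


INS_BREAKS = [0.0, 1.0, 10.0, 20.0, 40.0, np.inf]
INS_LABELS = ["[0,1)", "[1,10)", "[10,20)", "[20,40)", "[40,Inf)"]


def cut_insulin(totals: pd.Series) -> pd.Series:
    """Left-closed insulin-dose bins with breaks 0, 1, 10, 20, 40, Inf."""
    return pd.cut(totals, bins=INS_BREAKS, labels=INS_LABELS,
                  right=False, include_lowest=True).astype(object)


def _points_cb(name, compute):
    def cb(deps, ctx):
        merged = _merge_deps(deps, ctx)
        if not len(merged.df) or not isinstance(merged, TsTbl):
            return _empty_ts(ctx, name)
        df = merged.df

        def col(n):
            return df[n] if n in df.columns else pd.Series(np.nan,
                                                           index=df.index)
        return _keep(merged, name, compute(col), drop_na=False)
    cb.__name__ = f"{name}_cb"
    return cb


def _qsofa(col):
    return ((col("gcs") < 15).astype(float).where(col("gcs").notna(), 0)
            + (col("sbp") <= 100).astype(float).where(col("sbp").notna(), 0)
            + (col("resp") >= 22).astype(float).where(col("resp").notna(), 0))


def _sirs(col):
    t, h, r, w = col("temp"), col("hr"), col("resp"), col("wbc")
    return (((t > 38) | (t < 36)).astype(float).where(t.notna(), 0)
            + (h > 90).astype(float).where(h.notna(), 0)
            + (r > 20).astype(float).where(r.notna(), 0)
            + ((w > 12) | (w < 4)).astype(float).where(w.notna(), 0))


def _news(col):
    r, s, t, b, h = (col("resp"), col("o2sat"), col("temp"), col("sbp"),
                     col("hr"))
    pts = pd.Series(0.0, index=r.index)
    pts += pd.cut(r, [-np.inf, 9, 12, 21, 25, np.inf],
                  labels=[3, 1, 0, 2, 3], right=False,
                  ordered=False).astype(float).where(r.notna(), 0)
    pts += pd.cut(s, [-np.inf, 92, 94, 96, np.inf],
                  labels=[3, 2, 1, 0], right=False).astype(float).where(
                      s.notna(), 0)
    pts += pd.cut(t, [-np.inf, 35.1, 36.1, 38.1, 39.1, np.inf],
                  labels=[3, 1, 0, 1, 2], right=False,
                  ordered=False).astype(float).where(t.notna(), 0)
    pts += pd.cut(b, [-np.inf, 91, 101, 111, 220, np.inf],
                  labels=[3, 2, 1, 0, 3], right=False,
                  ordered=False).astype(float).where(b.notna(), 0)
    pts += pd.cut(h, [-np.inf, 41, 51, 91, 111, 131, np.inf],
                  labels=[3, 1, 0, 1, 2, 3], right=False,
                  ordered=False).astype(float).where(h.notna(), 0)
    return pts


def _mews(col):
    s, h, r, t = col("sbp"), col("hr"), col("resp"), col("temp")
    pts = pd.Series(0.0, index=s.index)
    pts += pd.cut(s, [-np.inf, 71, 81, 101, 200, np.inf],
                  labels=[3, 2, 1, 0, 2], right=False,
                  ordered=False).astype(float).where(s.notna(), 0)
    pts += pd.cut(h, [-np.inf, 41, 51, 101, 111, 130, np.inf],
                  labels=[2, 1, 0, 1, 2, 3], right=False,
                  ordered=False).astype(float).where(h.notna(), 0)
    pts += pd.cut(r, [-np.inf, 9, 15, 21, 30, np.inf],
                  labels=[2, 0, 1, 2, 3], right=False,
                  ordered=False).astype(float).where(r.notna(), 0)
    pts += ((t < 35) | (t > 38.5)).astype(float).where(t.notna(), 0) * 2
    return pts


qsofa_cb = _points_cb("qsofa", _qsofa)
sirs_cb = _points_cb("sirs", _sirs)
news_cb = _points_cb("news", _news)
mews_cb = _points_cb("mews", _mews)


# ---------------------------------------------------------------------------
# item-level helpers
# ---------------------------------------------------------------------------

DIAB_RE = re.compile(r"^250\.?[0-9]{2}$")
DKA_RE = re.compile(r"^250\.?1[0-9]$")


def grep_diab(x) -> bool:
    """True for ICD-9 codes of diabetes mellitus (250.xx)."""
    return bool(DIAB_RE.match(str(x)))


def grep_dka(x) -> bool:
    """True for ICD-9 codes of diabetic ketoacidosis (250.1x)."""
    return bool(DKA_RE.match(str(x)))


def set_true(values: pd.Series) -> pd.Series:
    """Map every non-missing value to logical True (event-presence items
    such as death timestamps or culture draws)."""
    return values.notna().map(lambda v: True if v else None)


def identity(values: pd.Series) -> pd.Series:
    return values


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

for _name, _fn in [
    ("sofa_resp_cb", sofa_resp_cb), ("sofa_coag_cb", sofa_coag_cb),
    ("sofa_liver_cb", sofa_liver_cb), ("sofa_cardio_cb", sofa_cardio_cb),
    ("sofa_cns_cb", sofa_cns_cb), ("sofa_renal_cb", sofa_renal_cb),
    ("sofa_cb", sofa_cb), ("susp_inf_cb", susp_inf_cb), ("sep3_cb", sep3_cb),
    ("gcs_cb", gcs_cb), ("pafi_cb", pafi_cb), ("safi_cb", safi_cb),
    ("nlr_cb", nlr_cb), ("shock_idx_cb", shock_idx_cb), ("agap_cb", agap_cb),
    ("egfr_cb", egfr_cb), ("bmi_cb", bmi_cb), ("urine24_cb", urine24_cb),
    ("vent_ind_cb", vent_ind_cb), ("supp_o2_cb", supp_o2_cb),
    ("norepi_equiv_cb", norepi_equiv_cb), ("vaso_ind_cb", vaso_ind_cb),
    ("ins24_cb", ins24_cb), ("qsofa_cb", qsofa_cb), ("sirs_cb", sirs_cb),
    ("news_cb", news_cb), ("mews_cb", mews_cb),
    ("grep_diab", grep_diab), ("grep_dka", grep_dka),
    ("set_true", set_true), ("identity", identity),
]:
    register_callback(_name, _fn, overwrite=True)
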