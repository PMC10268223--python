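"""Shared comparison utilities for the suite."""

import numpy as np
import pandas as pd


def frames_equal(a: pd.DataFrame, b: pd.DataFrame, atol: float = 1e-9) -> bool:
    """Column-wise equality with float tolerance (unit round-trips may
    differ by an ulp) and NA-awareness."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for c in a.columns:
        x, y = a[c], b[c]
        if pd.api.types.is_float_dtype(x) and pd.api.types.is_float_dtype(y):
            if not np.allclose(x.fillna(-9.9e300), y.fillna(-9.9e300),
                               atol=atol, rtol=atol):
                return False
        else:
            if not x.fillna("<NA>").astype(str).equals(
                    y.fillna("<NA>").astype(str)):
                return False
    return True


def normalized(df: pd.DataFrame) -> pd.DataFrame:
    """Rename the (first) id column so tables from different sources are
    comparable modulo ID-column naming."""
    out = df.copy()
    out.columns = ["id"] + list(out.columns[1:])
    sort_cols = [c for c in out.columns if c in ("id", "charttime", "dur_var")]
    return out.sort_values(sort_cols, kind="stable").reset_index(drop=True)


def series_of(df: pd.DataFrame, sid, col) -> dict:
    sub = df[df[df.columns[0]] == sid]
    return dict(zip(sub["charttime"], sub[col]))
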