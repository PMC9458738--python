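"""Small shared helpers (report rounding)."""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round *x* half-up to *decimals* places (report convention).

    Python's built-in ``round`` is banker's rounding; trial reports use
    the half-up convention (0.125 -> 0.13 at 2 dp).
    """
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    q = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def round_frame(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Half-up round every float column of *df* (copy)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_half_up(v, decimals))
    return out
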