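"""Column-wise data pretreatment for similarity tables.

Three transforms put metric columns on a common scale before consensus
fusion: interval scaling to [0, 1], standardization (z-scores with the
sample standard deviation, n-1 denominator), and rank transformation
(ranks 1..m, average ranks on ties).  All three are monotone
non-decreasing, so they never change the ranking *within* a column; they
matter downstream because the consensus reference is the row-mean of the
pretreated columns.
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PretreatmentId",
    "interval_scale",
    "standardize",
    "rank_transform",
    "apply_pretreatment",
]

logger = logging.getLogger(__name__)


class PretreatmentId(str, Enum):
    INTERVAL = "interval"
    STANDARDIZE = "standardize"
    RANK = "rank"


def interval_scale(column: np.ndarray) -> np.ndarray:
    """Map a column affinely onto [0, 1]: min -> 0, max -> 1.

    A constant column maps to all zeros (with a warning); there is no scale
    information to preserve.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("interval scaling needs at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("interval_scale: constant column, returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def standardize(column: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale by the sample standard deviation (ddof=1)."""
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("standardize: zero-variance column, returning zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def rank_transform(column: np.ndarray) -> np.ndarray:
    """Ranks by increasing magnitude; min -> 1, max -> m; ties get average ranks."""
    x = np.asarray(column, dtype=float)
    if x.size < 1:
        raise ValueError("rank transform needs at least 1 value")
    return rankdata(x, method="average")


_TRANSFORMS = {
    PretreatmentId.INTERVAL: interval_scale,
    PretreatmentId.STANDARDIZE: standardize,
    PretreatmentId.RANK: rank_transform,
}


def apply_pretreatment(table: pd.DataFrame,
                       pretreatment: PretreatmentId | str) -> pd.DataFrame:
    """Apply one pretreatment to every column of a similarity table."""
    pid = PretreatmentId(pretreatment)
    f = _TRANSFORMS[pid]
    out = table.apply(lambda col: pd.Series(f(col.to_numpy()), index=col.index))
    out.attrs = dict(table.attrs)
    out.attrs["pretreatment"] = pid.value
    return out
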