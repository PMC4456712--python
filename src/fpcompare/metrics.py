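"""Similarity and distance coefficients for binary fingerprints.

Eight coefficients are supported, all expressible through the dichotomous
counts ``a`` (on bits in molecule A), ``b`` (on bits in molecule B) and ``c``
(on bits shared by both):

========================  =======================  ==============
metric                    formula                  native kind
========================  =======================  ==============
manhattan                 a + b - 2c               distance
euclidean                 sqrt(a + b - 2c)         distance
cosine                    c / sqrt(ab)             similarity
dice                      2c / (a + b)             similarity
tanimoto                  c / (a + b - c)          similarity
soergel                   1 - c / (a + b - c)      distance
substructure              c / a                    similarity
superstructure            c / b                    similarity
========================  =======================  ==============

Native distances are mapped onto the ``[0, 1]`` similarity scale by
``s = 1 / (1 + d)``.  Substructure/superstructure are bit-containment scores:
the fraction of the query's (reference's) on bits present in the candidate,
and conversely; they are the only asymmetric pair (swapping the arguments
swaps the two scores).

Degenerate denominators (all-zero fingerprints) yield a similarity of 0 with
a logged warning: an empty fingerprint shares no feature with anything, and
in this package such inputs normally signal a generator bug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprints import BinaryFingerprint, to_dense_matrix

__all__ = [
    "BitStatistics",
    "MetricId",
    "ALL_METRICS",
    "bit_statistics",
    "metric_value",
    "to_similarity",
    "similarity_table",
    "write_similarity_table",
    "read_similarity_table",
]

logger = logging.getLogger(__name__)


class MetricId(str, Enum):
    """Identifier of one of the eight coefficients."""

    MANHATTAN = "manhattan"
    EUCLIDEAN = "euclidean"
    COSINE = "cosine"
    DICE = "dice"
    TANIMOTO = "tanimoto"
    SOERGEL = "soergel"
    SUBSTRUCTURE = "substructure"
    SUPERSTRUCTURE = "superstructure"

    @property
    def is_distance(self) -> bool:
        """True when the coefficient is natively a distance (needs conversion)."""
        return self in _NATIVE_DISTANCES


_NATIVE_DISTANCES = frozenset(
    {MetricId.MANHATTAN, MetricId.EUCLIDEAN, MetricId.SOERGEL}
)

#: All eight metrics in canonical column order.
ALL_METRICS: tuple[MetricId, ...] = tuple(MetricId)


@dataclass(frozen=True)
class BitStatistics:
    """Dichotomous counts for a fingerprint pair: a, b and common on bits c."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError(f"bit counts must be non-negative: {self}")
        if self.c > min(self.a, self.b):
            raise ValueError(f"common count c exceeds min(a, b): {self}")


def bit_statistics(fpA: BinaryFingerprint, fpB: BinaryFingerprint) -> BitStatistics:
    """Count on bits of A, of B, and of their intersection."""
    if fpA.length != fpB.length:
        raise ValueError(
            f"fingerprint length mismatch: {fpA.id} has {fpA.length} bits, "
            f"{fpB.id} has {fpB.length}"
        )
    return BitStatistics(
        a=len(fpA.on_bits),
        b=len(fpB.on_bits),
        c=len(fpA.on_bits & fpB.on_bits),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("degenerate denominator in %s (all-zero fingerprint?); returning 0", what)
        return 0.0
    return num / den


def metric_value(metric: MetricId | str, s: BitStatistics) -> float:
    """Native value of one coefficient (similarity or distance, per its kind)."""
    metric = MetricId(metric)
    a, b, c = s.a, s.b, s.c
    if metric is MetricId.MANHATTAN:
        return float(a + b - 2 * c)
    if metric is MetricId.EUCLIDEAN:
        return float(np.sqrt(a + b - 2 * c))
    if metric is MetricId.COSINE:
        return _safe_div(c, float(np.sqrt(a * b)), "cosine")
    if metric is MetricId.DICE:
        return _safe_div(2.0 * c, float(a + b), "dice")
    if metric is MetricId.TANIMOTO:
        return _safe_div(float(c), float(a + b - c), "tanimoto")
    if metric is MetricId.SOERGEL:
        if a + b - c == 0:
            logger.warning("degenerate denominator in soergel; returning distance 1")
            return 1.0
        return 1.0 - c / (a + b - c)
    if metric is MetricId.SUBSTRUCTURE:
        return _safe_div(float(c), float(a), "substructure")
    if metric is MetricId.SUPERSTRUCTURE:
        return _safe_div(float(c), float(b), "superstructure")
    raise ValueError(f"unknown metric {metric!r}")


def to_similarity(distance: float | np.ndarray) -> float | np.ndarray:
    """Convert a non-negative distance to a similarity in ``(0, 1]``.

    Uses ``s = 1 / (1 + d)``, so identical objects (distance 0) map to 1 and
    the conversion is strictly decreasing (order-reversing) in the distance.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + d)
    return float(out) if np.isscalar(distance) or out.ndim == 0 else out


def _table_values(ref_row: np.ndarray, lib: np.ndarray,
                  metrics: Sequence[MetricId]) -> np.ndarray:
    """Vectorized similarity table: rows = library molecules, cols = metrics."""
    a = float(ref_row.sum())
    b = lib.sum(axis=1).astype(float)
    c = lib @ ref_row.astype(float)
    if a == 0 or np.any(b == 0):
        logger.warning("all-zero fingerprint encountered in similarity table")

    cols = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in metrics:
            if m is MetricId.MANHATTAN:
                v = to_similarity(a + b - 2 * c)
            elif m is MetricId.EUCLIDEAN:
                v = to_similarity(np.sqrt(a + b - 2 * c))
            elif m is MetricId.COSINE:
                v = np.where(a * b > 0, c / np.sqrt(a * b), 0.0)
            elif m is MetricId.DICE:
                v = np.where(a + b > 0, 2 * c / (a + b), 0.0)
            elif m is MetricId.TANIMOTO:
                v = np.where(a + b - c > 0, c / (a + b - c), 0.0)
            elif m is MetricId.SOERGEL:
                d = np.where(a + b - c > 0, 1.0 - c / (a + b - c), 1.0)
                v = to_similarity(d)
            elif m is MetricId.SUBSTRUCTURE:
                v = np.where(a > 0, c / a, 0.0)
            elif m is MetricId.SUPERSTRUCTURE:
                v = np.where(b > 0, c / b, 0.0)
            else:  # pragma: no cover
                raise ValueError(f"unknown metric {m!r}")
            cols.append(np.nan_to_num(np.asarray(v, dtype=float)))
    return np.column_stack(cols)


def similarity_table(
    reference: BinaryFingerprint,
    library: Sequence[BinaryFingerprint],
    metrics: Sequence[MetricId | str] = ALL_METRICS,
    *,
    allow_reference_in_library: bool = False,
) -> pd.DataFrame:
    """Similarities of every library molecule to one reference, per metric.

    Returns a DataFrame indexed by molecule id with one column per metric
    (post-conversion: all values in ``[0, 1]``).  Substructure treats the
    reference as the query.

    The reference must not be contained in the library (each dataset draws
    molecules without replacement); pass ``allow_reference_in_library=True``
    only in tests of the identity case.
    """
    metrics = [MetricId(m) for m in metrics]
    if not metrics:
        raise ValueError("at least one metric required")
    ids = [fp.id for fp in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids in library")
    if not allow_reference_in_library and reference.id in set(ids):
        raise ValueError(
            f"reference {reference.id!r} also appears in the library; "
            "datasets must not repeat molecules"
        )
    lib = to_dense_matrix(list(library))
    if reference.length != lib.shape[1]:
        raise ValueError("reference length differs from library fingerprints")
    values = _table_values(reference.to_dense(), lib, metrics)
    df = pd.DataFrame(values, index=pd.Index(ids, name="molecule"),
                      columns=[m.value for m in metrics])
    df.attrs["reference_id"] = reference.id
    return df


def write_similarity_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a similarity table as TSV (first column molecule id)."""
    table.to_csv(path, sep="\t", index=True)


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV similarity table written by :func:`write_similarity_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)
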