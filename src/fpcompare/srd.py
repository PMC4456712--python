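"""Sum of ranking differences (SRD) with consensus fusion and validation.

SRD compares methods (here: similarity metrics) by how closely each one's
ranking of the objects (molecules) matches a reference ranking.  When no
golden standard exists, the row-wise average of all methods is the reference
(equivalent to SUM fusion).  For each method the objects are ranked by
increasing magnitude and the absolute rank differences against the reference
ranking are summed; smaller is closer to the consensus.

Raw SRD values are normalized to [0, 100] by the maximum attainable SRD for
the given reference ranking (``SRD_nor = 100 * SRD / SRD_max``).  Two
validation steps accompany the statistic:

* a randomization test comparing each SRD against the distribution of SRD
  under uniformly random rankings, summarized by its 5% (XX1), median and
  95% (XX19) quantiles — a method below XX1 is distinguishable from random;
* a bootstrap-like cross-validation: leave-one-out when the number of
  objects is below 14, seven-fold (SRD recomputed on each 6/7 portion)
  otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "consensus_reference",
    "srd_value",
    "srd_max",
    "normalize_srd",
    "NullDistribution",
    "null_distribution",
    "classify_vs_random",
    "cross_validate",
    "SRDResult",
    "srd_analysis",
]

ACCEPTABLE = "acceptable"
RANDOM_LIKE = "random-like"

#: Exact enumeration is limited to m! <= 10! permutations.
EXACT_M_LIMIT = 10


def consensus_reference(table: pd.DataFrame) -> np.ndarray:
    """Row-wise mean across the metric columns (SUM/average fusion)."""
    if table.isna().any().any():
        raise ValueError("similarity table contains missing cells")
    return table.to_numpy(dtype=float).mean(axis=1)


def srd_value(column_ranks: np.ndarray, reference_ranks: np.ndarray) -> float:
    """Sum over objects of |rank by the method - rank by the reference|."""
    r = np.asarray(column_ranks, dtype=float)
    q = np.asarray(reference_ranks, dtype=float)
    if r.shape != q.shape:
        raise ValueError(f"rank vector length mismatch: {r.shape} vs {q.shape}")
    return float(np.abs(r - q).sum())


def srd_max(reference_ranks: np.ndarray) -> float:
    """Maximum attainable SRD against a given reference ranking.

    Maximized over tie-free rankings (permutations of 1..m) by the extremal
    pairing argument: sort the reference ranks ascending and pair them with
    m, m-1, ..., 1.  For a tie-free reference this equals m^2/2 for even m
    and (m^2 - 1)/2 for odd m.
    """
    q = np.sort(np.asarray(reference_ranks, dtype=float))
    m = q.size
    if m < 2:
        raise ValueError("srd_max needs at least 2 objects")
    return float(np.abs(np.arange(m, 0, -1) - q).sum())


def normalize_srd(srd: float, srd_maximum: float) -> float:
    """Scale a raw SRD to [0, 100]: ``100 * SRD / SRD_max``."""
    if srd_maximum <= 0:
        raise ValueError("srd_max must be positive")
    if srd < 0 or srd > srd_maximum:
        raise ValueError(f"SRD {srd} outside [0, {srd_maximum}] — ranking bug?")
    return 100.0 * srd / srd_maximum


@dataclass
class NullDistribution:
    """Distribution of SRD_nor under uniformly random tie-free rankings.

    ``values``/``probs`` hold the exact probability mass (method "exact") or
    the sampled values with equal weights (method "montecarlo"), on the
    normalized 0-100 scale.
    """

    m: int
    method: str
    values: np.ndarray
    probs: np.ndarray
    srd_maximum: float
    xx1: float = field(init=False)
    median: float = field(init=False)
    xx19: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.values)
        self.values = np.asarray(self.values, dtype=float)[order]
        self.probs = np.asarray(self.probs, dtype=float)[order]
        if not math.isclose(self.probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("null distribution probabilities must sum to 1")
        self.xx1 = self.quantile(0.05)
        self.median = self.quantile(0.50)
        self.xx19 = self.quantile(0.95)

    def quantile(self, q: float) -> float:
        """Smallest support value whose CDF reaches ``q``."""
        cdf = np.cumsum(self.probs)
        idx = int(np.searchsorted(cdf, q - 1e-12))
        return float(self.values[min(idx, self.values.size - 1)])

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    def raw_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities on the raw (unnormalized) SRD scale."""
        return self.values * self.srd_maximum / 100.0, self.probs


def _exact_null_counts(m: int) -> dict[float, int]:
    """Counts of SRD values over all m! permutations against identity ranks."""
    ident = np.arange(1, m + 1)
    counts: dict[float, int] = {}
    batch: list[tuple[int, ...]] = []

    def flush() -> None:
        if not batch:
            return
        arr = np.asarray(batch)
        srds = np.abs(arr - ident).sum(axis=1)
        vals, cnts = np.unique(srds, return_counts=True)
        for v, k in zip(vals, cnts):
            counts[float(v)] = counts.get(float(v), 0) + int(k)
        batch.clear()

    for p in itertools.permutations(range(1, m + 1)):
        batch.append(p)
        if len(batch) >= 100_000:
            flush()
    flush()
    return counts


def null_distribution(m: int, method: str = "exact", n_samples: int = 100_000,
                      seed: int | None = None) -> NullDistribution:
    """SRD_nor distribution for random tie-free rankings of ``m`` objects.

    ``method="exact"`` enumerates all ``m!`` permutations (m <= 10);
    ``method="montecarlo"`` samples ``n_samples >= 10**4`` random
    permutations reproducibly from ``seed``.
    """
    if m < 2:
        raise ValueError("null distribution needs m >= 2")
    smax = srd_max(np.arange(1, m + 1))
    if method == "exact":
        if m > EXACT_M_LIMIT:
            raise ValueError(
                f"exact enumeration limited to m <= {EXACT_M_LIMIT}; "
                "use method='montecarlo'"
            )
        counts = _exact_null_counts(m)
        total = math.factorial(m)
        values = np.array(sorted(counts), dtype=float)
        probs = np.array([counts[v] / total for v in sorted(counts)])
        return NullDistribution(m=m, method="exact",
                                values=100.0 * values / smax, probs=probs,
                                srd_maximum=smax)
    if method == "montecarlo":
        if n_samples < 10_000:
            raise ValueError("montecarlo null needs n_samples >= 10**4")
        rng = np.random.default_rng(seed)
        perms = np.tile(np.arange(1, m + 1), (n_samples, 1))
        perms = rng.permuted(perms, axis=1)
        srds = np.abs(perms - np.arange(1, m + 1)).sum(axis=1)
        return NullDistribution(
            m=m, method="montecarlo",
            values=100.0 * srds.astype(float) / smax,
            probs=np.full(n_samples, 1.0 / n_samples),
            srd_maximum=smax,
        )
    raise ValueError(f"unknown method {method!r}")


def classify_vs_random(srd_nor: float, null: NullDistribution) -> str:
    """Flag an SRD_nor as 'acceptable' (below XX1, the 5% random limit) or
    'random-like' (overlapping the random-ranking distribution)."""
    return ACCEPTABLE if srd_nor < null.xx1 else RANDOM_LIKE


def _table_srd_nor(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """SRD_nor of each column of ``values`` against reference values."""
    q = rankdata(reference, method="average")
    smax = srd_max(q)
    out = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        r = rankdata(values[:, j], method="average")
        out[j] = normalize_srd(srd_value(r, q), smax)
    return out


def cross_validate(table: pd.DataFrame, reference: np.ndarray,
                   seed: int | None = None) -> pd.DataFrame:
    """Fold-wise SRD_nor per metric: LOO for m < 14, seven-fold for m > 13.

    Each fold's SRD is recomputed from scratch on the retained rows (the
    complement of the left-out block), including re-ranking and the
    fold-specific SRD_max.  Fold assignment is seeded.
    """
    m = len(table)
    if m < 3:
        raise ValueError("cross-validation needs at least 3 objects")
    values = table.to_numpy(dtype=float)
    reference = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    if m < 14:
        folds = [np.array([i]) for i in range(m)]
    else:
        perm = rng.permutation(m)
        folds = [np.sort(perm[k::7]) for k in range(7)]
    rows = []
    for k, left_out in enumerate(folds):
        keep = np.setdiff1d(np.arange(m), left_out)
        rows.append(_table_srd_nor(values[keep], reference[keep]))
    return pd.DataFrame(rows, columns=table.columns,
                        index=pd.RangeIndex(len(folds), name="fold"))


@dataclass
class SRDResult:
    """Full SRD analysis of one similarity table.

    ``summary`` has one row per metric: raw SRD, SRD_nor, the
    distinguishable-from-random flag, and cross-validation spread; ``folds``
    holds the per-fold SRD_nor values.
    """

    dataset_id: str
    summary: pd.DataFrame
    folds: pd.DataFrame | None
    srd_maximum: float
    null: NullDistribution


def srd_analysis(table: pd.DataFrame, *, dataset_id: str = "",
                 null: NullDistribution | None = None,
                 cross_validation: bool = True,
                 seed: int | None = None) -> SRDResult:
    """Rank columns, fuse the consensus, and compute validated SRD per metric.

    ``null`` may be passed in to reuse one randomization-test distribution
    across many tables of the same size; otherwise it is computed here
    (exact for small m, Monte Carlo above the enumeration limit).
    """
    values = table.to_numpy(dtype=float)
    m = values.shape[0]
    reference = consensus_reference(table)
    q = rankdata(reference, method="average")
    smax = srd_max(q)
    if null is None:
        method = "exact" if m <= EXACT_M_LIMIT else "montecarlo"
        null = null_distribution(m, method=method, seed=seed)
    elif null.m != m:
        raise ValueError(f"null distribution is for m={null.m}, table has m={m}")

    raw = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        r = rankdata(values[:, j], method="average")
        raw[j] = srd_value(r, q)
    nor = np.array([normalize_srd(v, smax) for v in raw])
    flags = [classify_vs_random(v, null) for v in nor]

    folds = cross_validate(table, reference, seed=seed) if cross_validation else None
    summary = pd.DataFrame(
        {
            "srd": raw,
            "srd_nor": nor,
            "flag": flags,
        },
        index=pd.Index(table.columns, name="metric"),
    )
    if folds is not None:
        summary["cv_mean"] = folds.mean(axis=0).to_numpy()
        summary["cv_sd"] = folds.std(axis=0, ddof=1).to_numpy()
    return SRDResult(dataset_id=dataset_id, summary=summary, folds=folds,
                     srd_maximum=smax, null=null)
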