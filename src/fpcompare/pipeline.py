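"""Batched SRD experiments over a factorial design.

The full-scale design mirrors the study: 1000 datasets of 100 molecules —
125 per cell of 4 size classes x 2 selection methods — each dataset drawn
without replacement from a class-specific library, one randomly chosen
reference per dataset, similarities of the remaining 99 molecules computed
with all eight metrics, pretreated, fused into a consensus and scored by
SRD.  The long-format result table (one row per run x metric x
pretreatment) feeds the box-whisker summary and the factorial ANOVA.

Desk-scale reruns use the identical structure with fewer runs per cell
(``runs_per_cell``); everything is a pure function of the master seed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import ALL_METRICS, MetricId, similarity_table
from .pretreatment import PretreatmentId, apply_pretreatment
from .srd import NullDistribution, SRDResult, null_distribution, srd_analysis
from .synthetic import DatasetSpec, SizeClass, generate_library, pick_diverse, pick_random

__all__ = [
    "run_single",
    "run_batch",
    "summarize_box_whisker",
    "confirmatory_subset",
]

logger = logging.getLogger(__name__)

_SELECTIONS = ("random", "diverse")


def run_single(members, pretreatment: PretreatmentId | str = PretreatmentId.INTERVAL,
               metrics: Sequence[MetricId | str] = ALL_METRICS, *,
               dataset_id: str = "", seed: int | None = None,
               null: NullDistribution | None = None,
               cross_validation: bool = True) -> SRDResult:
    """One complete SRD run on a dataset of fingerprints.

    A reference molecule is chosen uniformly at random (seeded) from the
    dataset; similarities of the remaining molecules to it are computed,
    pretreated column-wise, fused into the consensus and scored by SRD with
    the randomization test and cross-validation.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError(f"dataset {dataset_id!r} needs at least 3 molecules")
    rng = np.random.default_rng(seed)
    ref_idx = int(rng.integers(len(members)))
    reference = members[ref_idx]
    rest = members[:ref_idx] + members[ref_idx + 1:]
    try:
        table = similarity_table(reference, rest, metrics)
        treated = apply_pretreatment(table, pretreatment)
        result = srd_analysis(treated, dataset_id=dataset_id, null=null,
                              cross_validation=cross_validation,
                              seed=int(rng.integers(2**31)))
    except Exception as err:
        raise RuntimeError(f"SRD run failed for dataset {dataset_id!r}") from err
    result.summary.attrs["reference_id"] = reference.id
    return result


def _design_cells(size_classes: Iterable[SizeClass | str],
                  selections: Iterable[str]) -> list[tuple[SizeClass, str]]:
    cells = [(SizeClass(sc), sel) for sc in size_classes for sel in selections]
    for _, sel in cells:
        if sel not in _SELECTIONS:
            raise ValueError(f"unknown selection method {sel!r}")
    return cells


def run_batch(runs_per_cell: int = 8, *,
              size_classes: Iterable[SizeClass | str] = tuple(SizeClass),
              selections: Iterable[str] = _SELECTIONS,
              pretreatments: Iterable[PretreatmentId | str] = tuple(PretreatmentId),
              metrics: Sequence[MetricId | str] = ALL_METRICS,
              library_size: int = 100,
              fingerprint_length: int = 1024,
              density_profile: str = "dense",
              pool_factor: float = 2.0,
              seed: int = 0,
              n_null_samples: int = 100_000,
              srd_scope: str = "per-run") -> pd.DataFrame:
    """Run the factorial SRD experiment and return the long-format table.

    For each (size class, selection) cell a pool library of
    ``pool_factor * runs_per_cell * library_size`` molecules is generated;
    datasets are drawn from it without replacement (random draw or MaxMin
    diversity picking).  Each run contributes one SRD_nor row per metric and
    pretreatment.  ``srd_scope="per-cell"`` instead concatenates the runs of
    each design cell into one long table before scoring — the alternative
    construction for the three-way analysis.

    Deterministic given ``seed``: dataset draws, reference choices and the
    Monte Carlo null all derive from it.
    """
    if runs_per_cell < 1:
        raise ValueError("runs_per_cell must be >= 1")
    if srd_scope not in ("per-run", "per-cell"):
        raise ValueError(f"srd_scope must be 'per-run' or 'per-cell', got {srd_scope!r}")
    metrics = [MetricId(m) for m in metrics]
    pretreatments = [PretreatmentId(p) for p in pretreatments]
    cells = _design_cells(size_classes, selections)
    master = np.random.default_rng(seed)
    nulls: dict[int, NullDistribution] = {}

    def get_null(m: int) -> NullDistribution:
        if m not in nulls:
            method = "exact" if m <= 8 else "montecarlo"
            n = n_null_samples if m <= 200 else min(n_null_samples, 20_000)
            nulls[m] = null_distribution(m, method=method, n_samples=n,
                                         seed=int(master.integers(2**31)))
        return nulls[m]

    rows: list[dict] = []
    run_index = 0
    for size_class, selection in cells:
        pool_n = max(int(pool_factor * runs_per_cell * library_size),
                     runs_per_cell * library_size)
        library = generate_library(
            pool_n, size_class, fingerprint_length, density_profile,
            seed=int(master.integers(2**31)),
            id_prefix=f"{size_class.value}-{selection}")
        picker = pick_random if selection == "random" else pick_diverse
        exclude: set[str] = set()
        cell_tables: dict[PretreatmentId, list[pd.DataFrame]] = {p: [] for p in pretreatments}
        for _ in range(runs_per_cell):
            dataset_id = f"run{run_index:04d}"
            members = picker(library, library_size,
                             seed=int(master.integers(2**31)), exclude=exclude)
            run_rng = np.random.default_rng(int(master.integers(2**31)))
            ref_idx = int(run_rng.integers(len(members)))
            reference = members[ref_idx]
            rest = members[:ref_idx] + members[ref_idx + 1:]
            table = similarity_table(reference, rest, metrics)
            for pid in pretreatments:
                treated = apply_pretreatment(table, pid)
                if srd_scope == "per-cell":
                    cell_tables[pid].append(treated)
                    continue
                result = srd_analysis(treated, dataset_id=dataset_id,
                                      null=get_null(len(treated)),
                                      cross_validation=False)
                for metric, rec in result.summary.iterrows():
                    rows.append({
                        "run": run_index,
                        "size_class": size_class.value,
                        "selection": selection,
                        "pretreatment": pid.value,
                        "metric": metric,
                        "srd_nor": rec["srd_nor"],
                        "flag": rec["flag"],
                    })
            run_index += 1
        if srd_scope == "per-cell":
            for pid in pretreatments:
                combined = pd.concat(cell_tables[pid], axis=0, ignore_index=True)
                result = srd_analysis(combined,
                                      dataset_id=f"{size_class.value}-{selection}",
                                      null=get_null(len(combined)),
                                      cross_validation=False)
                for metric, rec in result.summary.iterrows():
                    rows.append({
                        "run": -1,
                        "size_class": size_class.value,
                        "selection": selection,
                        "pretreatment": pid.value,
                        "metric": metric,
                        "srd_nor": rec["srd_nor"],
                        "flag": rec["flag"],
                    })
        logger.info("completed cell %s/%s", size_class.value, selection)
    return pd.DataFrame(rows)


def summarize_box_whisker(table: pd.DataFrame,
                          pretreatment: PretreatmentId | str | None = None) -> pd.DataFrame:
    """Box-whisker summary of SRD_nor per metric.

    Whiskers span the non-outlier range (coefficient 1.0 of the
    interquartile range beyond the quartiles); points between 1.0 and 1.5
    IQR beyond a quartile are outliers, beyond 1.5 IQR extremes.
    """
    df = table
    if pretreatment is not None:
        df = df[df["pretreatment"] == PretreatmentId(pretreatment).value]
    out = []
    for metric, grp in df.groupby("metric", sort=False):
        x = grp["srd_nor"].to_numpy()
        if x.size < 5:
            raise ValueError(f"metric {metric!r} has {x.size} rows; need >= 5")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        in_range = x[(x >= q1 - iqr) & (x <= q3 + iqr)]
        lo = in_range.min() if in_range.size else q1
        hi = in_range.max() if in_range.size else q3
        outlier = ((x < q1 - iqr) & (x >= q1 - 1.5 * iqr)) | \
                  ((x > q3 + iqr) & (x <= q3 + 1.5 * iqr))
        extreme = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        out.append({
            "metric": metric, "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi,
            "n_outliers": int(outlier.sum()), "n_extremes": int(extreme.sum()),
            "n": int(x.size),
        })
    return pd.DataFrame(out).set_index("metric")


def confirmatory_subset(omit: Iterable[MetricId | str] = (
        MetricId.DICE, MetricId.SOERGEL, MetricId.MANHATTAN), **batch_kwargs) -> pd.DataFrame:
    """Re-run the batch on a metric subset to rule out consensus overweighting.

    Monotonically equivalent metric groups (tanimoto/dice/soergel and
    euclidean/manhattan) contribute identical rankings to the consensus; the
    confirmatory rerun omits the redundant members and recomputes the fusion
    from the surviving columns.  With the same seed the datasets are
    identical to the full batch, so metric orderings are directly comparable.
    """
    omit_set = {MetricId(m) for m in omit}
    metrics = [m for m in batch_kwargs.pop("metrics", ALL_METRICS)
               if MetricId(m) not in omit_set]
    if len(metrics) < 2:
        raise ValueError("confirmatory subset needs at least 2 remaining metrics")
    return run_batch(metrics=metrics, **batch_kwargs)
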