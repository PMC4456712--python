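"""Synthetic fingerprint libraries emulating the study's input data.

Real inputs were compound libraries split into size classes (fragment,
leadlike, druglike, plus "all" drawn regardless of size) and fingerprinted
with either a sparse dictionary-style fingerprint (on average 50-100 on bits
per 1024) or a denser hashed fingerprint.  The generator emulates only the
statistical structure that drives the ranking comparison:

* fixed-length bit vectors with class- and profile-dependent on-bit density
  (on-bit count ~ Binomial(length, p), positions uniform without
  replacement) — larger molecules set more bits, so mean density increases
  fragment < leadlike < druglike;
* the "all" class as a mixture of the three, weighted by the classes'
  relative abundance in a large purchasable-compound database (~3:24:73);
* dataset selection by random draw or MaxMin diversity picking, with a
  no-repeat guarantee across datasets drawn from one library.

The class/profile mean on-bit counts are emulation choices, not measured
properties of any real fingerprint; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .fingerprints import BinaryFingerprint, to_dense_matrix

__all__ = [
    "SizeClass",
    "DatasetSpec",
    "MEAN_ON_BITS",
    "ALL_CLASS_WEIGHTS",
    "generate_library",
    "pick_random",
    "pick_diverse",
    "degeneracy_fraction",
    "write_manifest",
]


class SizeClass(str, Enum):
    FRAGMENT = "fragment"
    LEADLIKE = "leadlike"
    DRUGLIKE = "druglike"
    ALL = "all"


#: Mean on-bit count at fingerprint length 1024, per (profile, class).
#: Sparse emulates a dictionary fingerprint (50-100 on bits on average);
#: dense emulates a darker hashed fingerprint.  Scaled linearly for other
#: lengths.  Ordering fragment < leadlike < druglike holds in both profiles.
MEAN_ON_BITS: dict[str, dict[SizeClass, float]] = {
    "sparse": {
        SizeClass.FRAGMENT: 55.0,
        SizeClass.LEADLIKE: 75.0,
        SizeClass.DRUGLIKE: 95.0,
    },
    "dense": {
        SizeClass.FRAGMENT: 150.0,
        SizeClass.LEADLIKE: 250.0,
        SizeClass.DRUGLIKE: 350.0,
    },
}

#: Mixture weights of the "all" class (fragment, leadlike, druglike),
#: the approximate relative abundance of the classes in the source database.
ALL_CLASS_WEIGHTS: tuple[float, float, float] = (0.03, 0.24, 0.73)

_BASE_LENGTH = 1024


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset of the experimental design."""

    dataset_id: str
    size_class: SizeClass
    selection: str  # "random" | "diverse"
    library_size: int = 100
    fingerprint_length: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in ("random", "diverse"):
            raise ValueError(f"selection must be 'random' or 'diverse', got {self.selection!r}")
        if self.library_size < 2:
            raise ValueError("library_size must be >= 2")


def _class_means(size_class: SizeClass, length: int,
                 density_profile: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule class mean choices: (means, mixture weights)."""
    try:
        table = MEAN_ON_BITS[density_profile]
    except KeyError:
        raise ValueError(f"density_profile must be 'sparse' or 'dense', got {density_profile!r}")
    scale = length / _BASE_LENGTH
    base = [table[c] * scale for c in
            (SizeClass.FRAGMENT, SizeClass.LEADLIKE, SizeClass.DRUGLIKE)]
    if size_class is SizeClass.ALL:
        return np.array(base), np.array(ALL_CLASS_WEIGHTS)
    idx = (SizeClass.FRAGMENT, SizeClass.LEADLIKE, SizeClass.DRUGLIKE).index(size_class)
    return np.array([base[idx]]), np.array([1.0])


def generate_library(n: int, size_class: SizeClass | str,
                     fingerprint_length: int = 1024,
                     density_profile: str = "dense",
                     seed: int | None = None,
                     id_prefix: str | None = None) -> list[BinaryFingerprint]:
    """Generate ``n`` synthetic fingerprints of one size class.

    On-bit counts are binomial with the class's mean density; on-bit
    positions are uniform without replacement.  Output is a pure function of
    the arguments and ``seed``; ids are unique within the library.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fingerprint_length < 64:
        raise ValueError("fingerprint_length must be >= 64")
    size_class = SizeClass(size_class)
    means, weights = _class_means(size_class, fingerprint_length, density_profile)
    if np.any(means >= fingerprint_length):
        raise ValueError("density parameters exceed fingerprint length")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(means), size=n, p=weights)
    counts = rng.binomial(fingerprint_length, means[which] / fingerprint_length)
    prefix = id_prefix or f"{size_class.value}-{density_profile}"
    out = []
    for i, k in enumerate(counts):
        bits = rng.choice(fingerprint_length, size=int(k), replace=False)
        out.append(BinaryFingerprint(id=f"{prefix}-{i:05d}",
                                     length=fingerprint_length,
                                     on_bits=frozenset(int(b) for b in bits)))
    return out


def _available(library: Sequence[BinaryFingerprint],
               exclude: set[str], k: int) -> list[int]:
    idx = [i for i, fp in enumerate(library) if fp.id not in exclude]
    if len(idx) < k:
        raise ValueError(
            f"only {len(idx)} unused molecules left in the library, need {k}"
        )
    return idx


def pick_random(library: Sequence[BinaryFingerprint], k: int,
                seed: int | None = None,
                exclude: set[str] | None = None) -> list[BinaryFingerprint]:
    """Draw ``k`` distinct molecules uniformly, never reusing excluded ids.

    ``exclude`` is updated in place so successive calls over one library
    yield disjoint datasets (no molecule is ever drawn more than once).
    """
    exclude = exclude if exclude is not None else set()
    idx = _available(library, exclude, k)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(idx), size=k, replace=False)
    picked = [library[idx[i]] for i in chosen]
    exclude.update(fp.id for fp in picked)
    return picked


def pick_diverse(library: Sequence[BinaryFingerprint], k: int,
                 seed: int | None = None,
                 exclude: set[str] | None = None) -> list[BinaryFingerprint]:
    """MaxMin diversity selection of ``k`` molecules.

    The first pick is uniform at random (seeded); each further pick
    maximizes its minimum Tanimoto distance (1 - Tanimoto) to the molecules
    already picked, ties broken by library order.  ``exclude`` is honored
    and updated as in :func:`pick_random`.
    """
    exclude = exclude if exclude is not None else set()
    idx = _available(library, exclude, k)
    cand = [library[i] for i in idx]
    mat = to_dense_matrix(cand).astype(np.float64)
    counts = mat.sum(axis=1)

    rng = np.random.default_rng(seed)
    first = int(rng.integers(len(cand)))
    picked = [first]
    # min Tanimoto distance of every candidate to the picked set
    min_dist = _tanimoto_distance_to(mat, counts, first)
    min_dist[first] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))
        picked.append(nxt)
        d = _tanimoto_distance_to(mat, counts, nxt)
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -np.inf
    out = [cand[i] for i in picked]
    exclude.update(fp.id for fp in out)
    return out


def _tanimoto_distance_to(mat: np.ndarray, counts: np.ndarray, j: int) -> np.ndarray:
    """1 - Tanimoto of every row of ``mat`` against row ``j``."""
    c = mat @ mat[j]
    denom = counts + counts[j] - c
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, c / denom, 0.0)
    return 1.0 - sim


def degeneracy_fraction(column: np.ndarray) -> float:
    """Fraction of repeated (degenerate) values: ``1 - n_distinct / m``.

    Sparse fingerprints admit few possible common-on-bit counts, so their
    similarity columns repeat values across different molecules; this
    statistic quantifies that loss of ranking resolution.
    """
    x = np.asarray(column)
    if x.size < 2:
        raise ValueError("degeneracy_fraction needs at least 2 values")
    return 1.0 - np.unique(x).size / x.size


def write_manifest(datasets: Sequence[tuple[DatasetSpec, Sequence[BinaryFingerprint], str]],
                   path: str | Path) -> None:
    """Write a dataset manifest TSV: id, size class, selection, seed,
    reference id and the member molecule ids."""
    lines = ["dataset_id\tsize_class\tselection\tseed\treference_id\tmolecule_ids\n"]
    for spec, members, reference_id in datasets:
        ids = ",".join(fp.id for fp in members)
        lines.append(
            f"{spec.dataset_id}\t{spec.size_class.value}\t{spec.selection}\t"
            f"{spec.seed}\t{reference_id}\t{ids}\n"
        )
    Path(path).write_text("".join(lines))
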