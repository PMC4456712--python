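# Methods

## The comparison procedure

Each experimental unit ("run") is one dataset of 100 fingerprints.  One
molecule is drawn uniformly at random as the reference; similarities of the
remaining m = 99 molecules to it are computed with all eight coefficients,
native distances converted by `s = 1/(1+d)` exactly once (each metric
carries its native kind, so the pipeline cannot double-convert).  The
columns are then pretreated, fused into a consensus (row-wise mean,
equivalent to SUM fusion), and each column is scored by the sum of ranking
differences against the consensus ranking, normalized by the maximum
attainable SRD.

Pretreatment is applied **before** fusion.  All three transforms are
monotone, so they never change a metric's own ranking; they matter solely
through the consensus, whose row means depend on the columns' scales.  This
is deliberate: it is the only route by which the pretreatment factor can
influence SRD at all, and it mirrors how a practitioner would fuse columns
that "cover the same range but have different scales".

### Pretreatments

* `interval` — (x − min)/(max − min), column-wise; constant columns map to
  zeros with a warning.
* `standardize` — (x − mean)/sd with the **sample** standard deviation
  (n − 1 denominator, the convention of mainstream statistics packages);
  zero-variance columns map to zeros with a warning.  Standardization is
  applied column-wise; a per-row variant would mean something entirely
  different for a molecules-by-metrics table and is not offered.
* `rank` — column-wise average ranks, min = 1, max = m on tie-free columns.

### SRD mechanics and numerical choices

* **Ties** receive average (fractional) ranks everywhere.  There is no cap
  on the number of tied objects.
* **SRD_max** is computed against the *actual* (possibly tied) consensus
  rank vector by the extremal pairing argument: sort the reference ranks
  ascending and pair with m, m−1, …, 1.  For tie-free references this
  reduces to m²/2 (m even) and (m²−1)/2 (m odd); the pairing form is
  verified against brute-force permutation enumeration in the tests,
  including tied references.
* **Randomization test**: the null is the distribution of SRD_nor for
  uniformly random tie-free permutations against the reference — exact by
  full enumeration up to m = 10, Monte Carlo (default 10⁵ seeded samples)
  above.  Decisions use empirical/exact quantiles, never a fitted normal
  curve.  Quantiles of the discrete null use the "smallest value whose CDF
  reaches q" convention, so XX1 is conservative.  A column is
  "acceptable" when SRD_nor < XX1 (the 5% limit), otherwise "random-like".
  Sampling tie-free permutations even when the data columns contain ties is
  intentional: the comparison is against random *rankings*, not against a
  tie-preserving permutation model.
* **Cross-validation**: leave-one-out when m < 14, otherwise seven folds;
  each fold's SRD_nor is recomputed from scratch on the retained 6/7 of the
  rows (re-ranking, re-deriving SRD_max for the reduced m).  Fold
  assignment is seeded and recorded via the result object.
* **Degenerate denominators** (all-zero fingerprints) yield similarity 0
  with a logged warning — an empty fingerprint shares nothing, and such
  inputs normally indicate a generator bug rather than valid data.

### Exact identities the implementation preserves

Tanimoto, Dice and the Soergel-derived similarity are monotone transforms
of one another (`tanimoto = dice/(2 − dice)`, `soergel-sim =
1/(2 − tanimoto)`), and Manhattan equals squared Euclidean on dichotomous
data.  Since SRD consumes only rankings, SRD(Tanimoto) = SRD(Dice) =
SRD(Soergel) and SRD(Euclidean) = SRD(Manhattan) hold *exactly* on every
dataset; the tests assert this bitwise on every batch run.

## Substructure and superstructure scores

The screening-oriented substructure/superstructure similarities of
commercial toolkits are defined algorithmically and cannot be reproduced
from their public descriptions.  This package implements the standard
bit-containment surrogates — substructure(R, X) = c/a (fraction of the
reference's on bits present in the library molecule) and
superstructure(R, X) = c/b — with the reference treated as the query.  They
preserve the containment semantics and the asymmetry (swapping the
arguments swaps the two scores) but are **not** claimed equivalent to any
particular vendor implementation.

## The synthetic generator

The generator emulates only the statistical structure that the ranking
comparison is sensitive to:

* **Bit density.** On-bit counts are Binomial(L, p) with positions uniform
  without replacement (L = 1024 bits by default).  The `sparse` profile
  emulates dictionary-type fingerprints with 50–100 on bits per 1024 on
  average (class means 55/75/95 for fragment/leadlike/druglike); the
  `dense` profile emulates a darker hashed fingerprint (class means
  150/250/350).  Means scale linearly with L.  The class→density coupling
  encodes that larger molecules set more bits; it is the minimal structure
  that lets size-dependence effects be exercised.  These numbers are
  emulation choices — no quantitative match to any real fingerprint's
  density is claimed.
* **The "all" class** is a 3:24:73 mixture of fragment/leadlike/druglike,
  the approximate relative abundance of the three classes in a large
  purchasable-compound database.
* **Selection.** `random` draws uniformly; `diverse` is MaxMin picking:
  first compound uniform at random under the run seed, then each pick
  maximizes its minimum Tanimoto distance to the already-picked set (ties
  broken by library order).  Both honor a shared exclusion set, so no
  molecule is ever drawn twice across the datasets of one library.
* **Degeneracy.** `degeneracy_fraction` = 1 − (distinct values)/m measures
  repeated similarity values; sparse fingerprints admit few possible
  common-bit counts, so their Tanimoto columns are measurably more
  degenerate — the motivation for running the main experiment on the dense
  profile.

What the generator does **not** emulate: molecular graphs, physicochemical
properties, bit–bit correlations of real hashed fingerprints (bits are
independent given the count), or inter-molecule structural correlation
within a vendor library.  Consequently, passing tests show that the
comparison machinery behaves as designed under controlled density/size
structure — not that any particular metric would win on a specific real
screening task.

## The batched experiment

The full-scale design is 4 size classes × 2 selection methods × 125 runs =
1000 datasets, each scored under 3 pretreatments.  The package defaults to
8 runs per cell (64 datasets, 1536 SRD values), which reproduces all the
qualitative findings in seconds; `runs_per_cell=125` restores the full
scale.  Each design cell draws its datasets without replacement from a
pool library of `pool_factor × runs_per_cell × 100` molecules (default
factor 2), so diversity picking has genuine slack to choose from.  The
whole batch — libraries, picks, references, folds, Monte Carlo nulls — is a
pure function of the master seed.

`run_batch(srd_scope="per-cell")` provides the alternative construction in
which the runs of each design cell are concatenated into one long table and
scored by a single SRD per metric; the default per-run scope is what the
box-whisker summaries and ANOVAs consume.

Box-whisker summaries use quartiles with whiskers at coefficient 1.0 of the
IQR beyond the quartiles; points between 1.0 and 1.5 IQR are counted as
outliers, beyond 1.5 IQR as extremes.

The confirmatory rerun omits Dice, Soergel and Manhattan — the redundant
members of the two monotone-equivalence groups — and recomputes the
consensus from the five surviving columns, ruling out the possibility that
the equivalent metrics win only by outvoting the others in the average.

One caveat on the random-ranking flags: in the heterogeneous "all" mixture
class, individual runs can push the Euclidean/Manhattan pair to SRD_nor
values at or above XX1 (their size-sensitivity is exactly what the ANOVA
detects).  Metric-level statements ("every metric beats random") are
therefore made on the per-metric median across runs, which sits far below
XX1 for all eight metrics at every tested scale.

## ANOVA

Fixed-effects factorial ANOVA with sum-to-zero (sigma-restricted) contrasts
via OLS; for the balanced designs produced by the pipeline the sums of
squares coincide with the classical between/within decomposition (asserted
to 1e-8 relative in the tests).  p-values come from the F distribution with
no multiple-testing correction, matching how per-effect significance is
conventionally reported for this analysis.  Normality is not enforced; the
analysis relies on large cell counts.  Cell means are reported with
symmetric 0.95 t-intervals; single-observation cells are flagged rather
than given an interval.

At the default desk scale the size-class and selection effects are strongly
significant, while the pretreatment main effect generally is not — its
effect on SRD is real but tiny, and resolving it needs the full 1000-run
design.

## Known limitations

* The substructure/superstructure surrogates are approximations (above).
* The exact distribution of SRD under *tied* reference rankings is not
  enumerated; the null always uses tie-free permutations.
* The generator's independence assumptions make synthetic datasets somewhat
  "easier" (less internally correlated) than vendor libraries; absolute
  SRD_nor levels should not be read as predictions for real data, only the
  orderings and factor effects.
* Full-scale (125 runs/cell) execution is supported but not exercised by
  the default test run.
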