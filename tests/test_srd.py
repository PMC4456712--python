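import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpcompare import (
    classify_vs_random,
    consensus_reference,
    cross_validate,
    normalize_srd,
    null_distribution,
    srd_analysis,
    srd_max,
    srd_value,
)
from fpcompare.srd import ACCEPTABLE, RANDOM_LIKE


def brute_force_srds(reference):
    """All SRD values over every tie-free ranking against a reference."""
    m = len(reference)
    return [sum(abs(p - q) for p, q in zip(perm, reference))
            for perm in itertools.permutations(range(1, m + 1))]


class TestSrdValue:
    def test_identical_rankings_give_zero(self):
        assert srd_value(np.arange(1, 10), np.arange(1, 10)) == 0.0

    def test_reversal_example(self):
        assert srd_value(np.array([3, 2, 1]), np.array([1, 2, 3])) == 4.0

    def test_mean_over_all_permutations_m3(self):
        srds = brute_force_srds([1, 2, 3])
        assert np.mean(srds) == pytest.approx(8 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            srd_value(np.arange(3), np.arange(4))

    @given(st.integers(2, 6), st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_triangle_inequality(self, m, seed):
        rng = np.random.default_rng(seed)
        x, y, z = (rng.permutation(m) + 1 for _ in range(3))
        assert srd_value(x, z) <= srd_value(x, y) + srd_value(y, z) + 1e-9


class TestSrdMax:
    @pytest.mark.parametrize("m, expected", [(3, 4), (4, 8), (99, 4900)])
    def test_tie_free_closed_form(self, m, expected):
        assert srd_max(np.arange(1, m + 1)) == expected

    @pytest.mark.parametrize("m", [3, 4, 5, 6])
    def test_matches_brute_force(self, m):
        assert srd_max(np.arange(1, m + 1)) == max(brute_force_srds(list(range(1, m + 1))))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tied_reference_matches_brute_force(self, seed):
        """Extremal pairing also maximizes against average-rank (tied) references."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(seed)
        values = rng.integers(0, 3, size=6).astype(float)  # many ties
        q = rankdata(values, method="average")
        assert srd_max(q) == max(brute_force_srds(q))

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            srd_max(np.array([1.0]))


class TestNormalize:
    def test_endpoints(self):
        assert normalize_srd(0, 10) == 0.0
        assert normalize_srd(10, 10) == 100.0

    def test_m3_reversal_hits_max(self):
        smax = srd_max(np.arange(1, 4))
        assert normalize_srd(srd_value(np.array([3, 2, 1]), np.array([1, 2, 3])), smax) == 100.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_srd(11, 10)


class TestNullDistribution:
    def test_m3_exact_mass(self):
        nd = null_distribution(3, "exact")
        raw, probs = nd.raw_support()
        np.testing.assert_allclose(raw, [0, 2, 4])
        np.testing.assert_allclose(probs, [1 / 6, 1 / 3, 1 / 2])

    @pytest.mark.parametrize("m", [3, 4, 5, 6, 7])
    def test_exact_matches_enumeration_cell_for_cell(self, m):
        nd = null_distribution(m, "exact")
        srds = brute_force_srds(list(range(1, m + 1)))
        vals, counts = np.unique(srds, return_counts=True)
        raw, probs = nd.raw_support()
        np.testing.assert_allclose(raw, vals)
        np.testing.assert_allclose(probs, counts / math.factorial(m))

    @pytest.mark.parametrize("m", [3, 5, 8])
    def test_null_mean_closed_form(self, m):
        nd = null_distribution(m, "exact")
        raw, probs = nd.raw_support()
        assert np.dot(raw, probs) == pytest.approx((m**2 - 1) / 3)

    def test_montecarlo_deterministic_from_seed(self):
        a = null_distribution(20, "montecarlo", n_samples=10_000, seed=42)
        b = null_distribution(20, "montecarlo", n_samples=10_000, seed=42)
        assert (a.xx1, a.median, a.xx19) == (b.xx1, b.median, b.xx19)

    def test_montecarlo_converges_to_exact(self):
        m = 7
        exact = null_distribution(m, "exact")
        mc = null_distribution(m, "montecarlo", n_samples=100_000, seed=1)
        support = exact.values
        p_exact = exact.probs
        p_mc = np.array([(mc.values == v).mean() for v in support])
        assert 0.5 * np.abs(p_exact - p_mc).sum() < 0.02  # total variation

    def test_exact_beyond_limit_rejected(self):
        with pytest.raises(ValueError, match="montecarlo"):
            null_distribution(12, "exact")

    def test_montecarlo_sample_floor(self):
        with pytest.raises(ValueError):
            null_distribution(20, "montecarlo", n_samples=100)

    def test_quantile_ordering(self):
        nd = null_distribution(30, "montecarlo", n_samples=20_000, seed=0)
        assert nd.xx1 <= nd.median <= nd.xx19


class TestClassify:
    def test_zero_is_acceptable(self):
        nd = null_distribution(8, "exact")
        assert classify_vs_random(0.0, nd) == ACCEPTABLE

    def test_median_is_random_like(self):
        nd = null_distribution(8, "exact")
        assert classify_vs_random(nd.median, nd) == RANDOM_LIKE


class TestCrossValidate:
    def test_loo_below_14_objects(self, rng):
        table = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        folds = cross_validate(table, consensus_reference(table), seed=0)
        assert len(folds) == 10

    def test_seven_folds_at_99_objects(self, druglike_table):
        folds = cross_validate(druglike_table, consensus_reference(druglike_table), seed=0)
        assert len(folds) == 7

    def test_identical_columns_zero_spread(self, rng):
        col = rng.random(20)
        table = pd.DataFrame({c: col for c in "abcd"})
        folds = cross_validate(table, consensus_reference(table), seed=0)
        assert np.allclose(folds.to_numpy(), 0.0)


class TestSrdAnalysis:
    def test_consensus_is_row_mean(self, rng):
        table = pd.DataFrame(rng.random((5, 8)))
        np.testing.assert_allclose(consensus_reference(table),
                                   table.to_numpy().mean(axis=1))
        two = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        np.testing.assert_allclose(consensus_reference(two), [0.5, 0.5])

    def test_identical_columns_give_zero_srd(self, rng):
        col = rng.random(30)
        table = pd.DataFrame({c: col for c in "abcd"})
        res = srd_analysis(table, seed=0)
        assert np.allclose(res.summary["srd_nor"], 0.0)
        assert (res.summary["flag"] == ACCEPTABLE).all()

    def test_rank_invariance_of_columns(self, rng):
        """Replacing a column by a strictly increasing transform leaves its
        SRD unchanged (SRD only consumes rankings) when the reference ranking
        is held fixed."""
        from scipy.stats import rankdata

        from fpcompare.srd import srd_value, srd_max, normalize_srd

        table = pd.DataFrame(rng.random((25, 4)), columns=list("abcd"))
        ref = consensus_reference(table)
        q = rankdata(ref)
        smax = srd_max(q)
        for col in table.columns:
            x = table[col].to_numpy()
            for f in (np.exp, lambda v: v**3 + v, lambda v: 10 * v - 2):
                same = normalize_srd(srd_value(rankdata(f(x)), q), smax)
                orig = normalize_srd(srd_value(rankdata(x), q), smax)
                assert same == orig

    def test_typical_dataset_all_metrics_acceptable(self, druglike_table):
        """On a typical homogeneous synthetic dataset every metric ranks far
        better than random."""
        from fpcompare import apply_pretreatment

        treated = apply_pretreatment(druglike_table, "interval")
        res = srd_analysis(treated, seed=0)
        assert (res.summary["flag"] == ACCEPTABLE).all()

    def test_wrong_size_null_rejected(self, rng):
        table = pd.DataFrame(rng.random((20, 3)))
        nd = null_distribution(10, "exact")
        with pytest.raises(ValueError, match="m=10"):
            srd_analysis(table, null=nd)
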