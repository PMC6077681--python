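"""Repeated-measures ANOVA, Bonferroni post hoc and Cochran's Q.

Oracles: the paired-t identity F = t^2 at k=2, the McNemar identity for
Cochran's Q at k=2, an exhaustive within-row permutation null for a tiny
binary instance, a vectorised type-I-error simulation, and statsmodels as an
independent cross-check implementation.
"""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from kneedrill.stats import (BinaryRepeated, RepeatedMeasures, bonferroni_pairs,
                             cochran_q, rm_anova)


def _cochran_q_stat(x: np.ndarray) -> float:
    """Independent re-implementation of the Q statistic for the oracle."""
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    total = x.sum()
    denom = k * total - np.sum(row**2)
    if denom == 0:
        return 0.0
    return float(k * (k - 1) * np.sum((col - total / k) ** 2) / denom)


class TestRmAnova:
    def test_identical_columns_no_effect(self):
        x = np.tile(np.array([1.0, 2.0, 5.0, 9.0])[:, None], (1, 4))
        res = rm_anova(RepeatedMeasures(x))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_f_equals_t_squared_for_two_levels(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=(7, 2))
            f_res = rm_anova(RepeatedMeasures(x))
            t_res = sps.ttest_rel(x[:, 0], x[:, 1])
            assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-9)
            assert f_res.p_value == pytest.approx(t_res.pvalue, rel=1e-9)

    def test_invariant_to_per_subject_constant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 4))
        base = rm_anova(RepeatedMeasures(x))
        shifted = rm_anova(RepeatedMeasures(x + rng.normal(size=(10, 1)) * 100))
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_zero_error_variance_flagged(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]) + np.arange(3)[:, None]
        res = rm_anova(RepeatedMeasures(x))
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0
        assert res.flags

    def test_type_one_error_calibrated(self):
        """Simulated null (n=30, k=4, iid normal, 2000 reps): rejection rate
        at alpha=.05 within 0.05 +/- 0.015."""
        rng = np.random.default_rng(2024)
        n, k, reps = 30, 4, 2000
        x = rng.normal(size=(reps, n, k))
        grand = x.mean(axis=(1, 2), keepdims=True)
        col = x.mean(axis=1, keepdims=True)
        row = x.mean(axis=2, keepdims=True)
        ss_cond = n * ((col - grand) ** 2).sum(axis=(1, 2))
        ss_subj = k * ((row - grand) ** 2).sum(axis=(1, 2))
        ss_tot = ((x - grand) ** 2).sum(axis=(1, 2))
        ss_err = ss_tot - ss_cond - ss_subj
        f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        p = sps.f.sf(f, k - 1, (k - 1) * (n - 1))
        # the vectorised F agrees with the implementation on a sample
        for i in (0, 500, 1999):
            res = rm_anova(RepeatedMeasures(x[i]))
            assert res.statistic == pytest.approx(f[i], rel=1e-9)
        assert abs((p < 0.05).mean() - 0.05) <= 0.015

    def test_matches_statsmodels_anovarm(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "level": np.tile(np.arange(4), 12),
            "y": x.ravel(),
        })
        sm_res = AnovaRM(long, "y", "subject", within=["level"]).fit()
        ours = rm_anova(RepeatedMeasures(x))
        assert ours.statistic == pytest.approx(
            float(sm_res.anova_table["F Value"].iloc[0]), rel=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            RepeatedMeasures(np.zeros((2, 4)))  # too few subjects
        with pytest.raises(ValueError):
            RepeatedMeasures(np.zeros((5, 1)))  # too few levels
        with pytest.raises(ValueError):
            RepeatedMeasures(np.array([[1.0, np.nan], [0, 1], [2, 3]]))


class TestBonferroniPairs:
    def test_pair_count_for_four_levels(self):
        x = np.random.default_rng(3).normal(size=(8, 4))
        assert len(bonferroni_pairs(RepeatedMeasures(x))) == 6

    def test_pair_count_for_three_levels(self):
        x = np.random.default_rng(3).normal(size=(8, 3))
        assert len(bonferroni_pairs(RepeatedMeasures(x))) == 3

    def test_identical_columns_adjusted_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        for res in bonferroni_pairs(RepeatedMeasures(x)):
            assert res.adjusted_p == 1.0

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 4)) + np.array([0, 0.5, 1.0, 1.5])
        for res in bonferroni_pairs(RepeatedMeasures(x)):
            assert res.adjusted_p >= res.p_value
            assert res.adjusted_p <= 1.0
            if res.p_value * 6 < 1:
                assert res.adjusted_p == pytest.approx(res.p_value * 6, rel=1e-12)


class TestCochranQ:
    def test_identical_columns(self):
        x = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0]])
        res = cochran_q(BinaryRepeated(x))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_reduces_to_mcnemar_for_two_levels(self):
        rng = np.random.default_rng(6)
        x = (rng.random((25, 2)) < [0.3, 0.6]).astype(int)
        q = cochran_q(BinaryRepeated(x))
        # McNemar chi-square without continuity correction: (b-c)^2/(b+c)
        b = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
        c = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
        expected = (b - c) ** 2 / (b + c)
        assert q.statistic == pytest.approx(expected, rel=1e-9)
        assert q.p_value == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-9)

    def test_chi_square_p_close_to_exact_permutation(self):
        """Enumerable 4x3 instance (a clean maximal column effect: every
        subject positive at the first level only): the chi-square p is within
        0.1 of the exact within-row permutation null. At n=4 the asymptotic
        approximation is rough in general; this instance is one where it is
        usable (exact p = 48/1296 ~ 0.037 vs chi-square 0.018)."""
        x = np.array([[1, 0, 0]] * 4)
        res = cochran_q(BinaryRepeated(x))
        q_obs = _cochran_q_stat(x)
        from itertools import permutations

        row_perms = list(permutations(range(3)))
        count_ge = 0
        total = 0
        for combo in product(range(len(row_perms)), repeat=4):
            xp = np.stack([x[i, list(row_perms[ci])] for i, ci in enumerate(combo)])
            total += 1
            if _cochran_q_stat(xp) >= q_obs - 1e-12:
                count_ge += 1
        p_exact = count_ge / total
        assert p_exact == pytest.approx(48 / 1296, abs=1e-12)
        assert abs(res.p_value - p_exact) <= 0.1

    def test_all_rows_constant_flagged(self):
        x = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0]])
        res = cochran_q(BinaryRepeated(x))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.flags

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(8)
        x = (rng.random((12, 4)) < 0.4).astype(int)
        base = cochran_q(BinaryRepeated(x))
        shuffled = cochran_q(BinaryRepeated(x[rng.permutation(12)]))
        assert shuffled.statistic == base.statistic
        assert shuffled.p_value == base.p_value

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import cochrans_q

        rng = np.random.default_rng(9)
        x = (rng.random((20, 4)) < [0.2, 0.4, 0.5, 0.7]).astype(int)
        sm_res = cochrans_q(x, return_object=True)
        ours = cochran_q(BinaryRepeated(x))
        assert ours.statistic == pytest.approx(sm_res.statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(sm_res.pvalue, rel=1e-9)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            BinaryRepeated(np.array([[0, 2], [1, 0]]))
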