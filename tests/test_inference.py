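"""Paired tests, power, Wald-type permutation inference, contingency checks."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metaface import (
    ConfigError,
    DataError,
    EstimationError,
    PowerSpec,
    contingency_tests,
    dz_from_t,
    paired_ttest,
    power_paired_t,
    within_subject_se,
    wts_permutation_test,
    wts_statistic,
)
from metaface.inference import build_hypothesis_matrix, rm_anova_partial_eta_sq


class TestPairedTTest:
    def test_hand_arithmetic(self):
        res = paired_ttest([2, 3, 4], [1, 1, 1])
        assert res.t == pytest.approx(2 / (1 / np.sqrt(3)))
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            paired_ttest([1.0], [2.0])

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=20),
           st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_dz_identity(self, x, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(x)
        y = x + rng.normal(size=x.size)
        if np.std(x - y, ddof=1) == 0:
            return
        res = paired_ttest(x, y)
        assert abs(res.dz) == pytest.approx(dz_from_t(res.t, res.n), rel=1e-12)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = power_paired_t(PowerSpec(d=0.0, n=25, alpha=0.05))
        assert spec.power == pytest.approx(0.05, abs=1e-9)

    def test_no_finite_n_for_null_effect(self):
        with pytest.raises(EstimationError):
            power_paired_t(PowerSpec(d=0.0, power=0.8))

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestPower

        oracle = TTestPower()
        for d, n in [(0.3, 20), (0.5, 12), (0.693, 19), (1.0, 8)]:
            got = power_paired_t(PowerSpec(d=d, n=n)).power
            want = oracle.power(effect_size=d, nobs=n, alpha=0.05,
                                alternative="two-sided")
            assert got == pytest.approx(want, abs=1e-8)

    def test_monotone_in_n_and_d(self):
        powers_n = [power_paired_t(PowerSpec(d=0.5, n=n)).power
                    for n in range(5, 60, 5)]
        assert np.all(np.diff(powers_n) > 0)
        powers_d = [power_paired_t(PowerSpec(d=d, n=20)).power
                    for d in np.linspace(0.1, 1.5, 10)]
        assert np.all(np.diff(powers_d) > 0)

    def test_sample_size_is_exact_integer_ceiling(self):
        spec = power_paired_t(PowerSpec(d=0.4, power=0.9))
        assert power_paired_t(PowerSpec(d=0.4, n=spec.n)).power >= 0.9
        assert power_paired_t(PowerSpec(d=0.4, n=spec.n - 1)).power < 0.9

    def test_both_or_neither_field_rejected(self):
        with pytest.raises(ConfigError):
            power_paired_t(PowerSpec(d=0.5, n=10, power=0.8))
        with pytest.raises(ConfigError):
            PowerSpec(d=0.5)


def _oracle_wts(y, h):
    """Generic quadratic-form computation, written independently."""
    n = y.shape[0]
    ybar = y.mean(axis=0)
    dev = y - ybar
    sigma = dev.T @ dev / (n - 1)
    v = h @ ybar
    return float(n * v @ np.linalg.pinv(h @ sigma @ h.T) @ v)


class TestWTSStatistic:
    def test_zero_when_projection_vanishes(self):
        # constant cells within subject plus subject offsets: every effect
        # contrast of the mean vector vanishes exactly
        y = np.stack([np.full(12, off) for off in (0.0, 3.0, -1.0, 5.0)])
        for effect in ("site", "contrast", "interaction"):
            w, _ = wts_statistic(y, effect)
            assert w == pytest.approx(0.0, abs=1e-12)

    def test_hand_2x2_toy_design(self):
        y = np.array([[1.0, 2.0, 3.0, 5.0],
                      [0.0, 1.0, 1.0, 4.0],
                      [2.0, 2.0, 4.0, 5.0]])
        p2 = np.eye(2) - 0.25 * 0 - np.ones((2, 2)) / 2
        h_int = np.kron(p2, p2)
        w, df = wts_statistic(y, "interaction", levels=(2, 2))
        assert w == pytest.approx(_oracle_wts(y, h_int), rel=1e-10)
        assert df == 1

    def test_agrees_with_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(5, 15)
            y = rng.normal(size=(n, 12))
            for effect in ("site", "contrast", "interaction"):
                h = build_hypothesis_matrix((2, 6), effect)
                w, _ = wts_statistic(y, effect)
                assert w == pytest.approx(_oracle_wts(y, h), rel=1e-8)

    def test_invariant_to_subject_constants(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 12))
        shifted = y + rng.normal(size=(10, 1))
        for effect in ("site", "contrast", "interaction"):
            assert wts_statistic(y, effect)[0] == pytest.approx(
                wts_statistic(shifted, effect)[0], rel=1e-8)

    def test_three_factor_extension(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(14, 24))  # 2 tasks x 2 sites x 6 contrasts
        w, df = wts_statistic(y, (0, 1), levels=(2, 2, 6))
        h = build_hypothesis_matrix((2, 2, 6), (0, 1))
        assert w == pytest.approx(_oracle_wts(y, h), rel=1e-8)
        assert df == 1

    def test_degenerate_input_rejected(self):
        with pytest.raises(DataError):
            wts_statistic(np.zeros((1, 12)), "site")


class TestWTSPermutation:
    def test_deterministic_and_in_range(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(12, 12))
        a = wts_permutation_test(y, "interaction", n_perm=500, seed=9)
        b = wts_permutation_test(y, "interaction", n_perm=500, seed=9)
        assert a.p_perm == b.p_perm
        assert 1 / 501 <= a.p_perm <= 1.0
        assert 0 <= a.eta_p2 <= 1
        assert a.W >= 0

    def test_null_p_uniform_on_grid(self):
        # discrete-uniform permutation p under exchangeable null cells
        rng = np.random.default_rng(123)
        pvals = []
        for i in range(400):
            y = rng.normal(size=(8, 4))
            res = wts_permutation_test(y, (0, 1), levels=(2, 2), n_perm=199,
                                       seed=int(rng.integers(2**31 - 1)),
                                       warn_small_n=False)
            pvals.append(res.p_perm)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_injected_interaction(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(27, 12))
        y[:, 2:4] += 1.5  # site-1-only bump at intermediate contrasts
        res = wts_permutation_test(y, "interaction", n_perm=1000, seed=1)
        assert res.p_perm < 0.05


class TestEtaPartial:
    def test_matches_classical_two_way_decomposition(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(9, 12))
        cells = y.reshape(9, 2, 6)
        grand = cells.mean()
        cell_means = cells.mean(axis=0)
        a_means = cells.mean(axis=(0, 2))
        b_means = cells.mean(axis=(0, 1))
        inter = cell_means - a_means[:, None] - b_means[None, :] + grand
        ss_int = 9 * float((inter ** 2).sum())
        resid = (cells - cells.mean(axis=(1, 2), keepdims=True)
                 - cell_means[None] + grand)
        subj_a = cells.mean(axis=2) - cells.mean(axis=(1, 2), keepdims=False)[:, None] \
            - a_means[None, :] + grand
        subj_b = cells.mean(axis=1) - cells.mean(axis=(1, 2))[:, None] \
            - b_means[None, :] + grand
        ss_err = float((resid ** 2).sum()) - 6 * float((subj_a ** 2).sum()) \
            - 2 * float((subj_b ** 2).sum())
        want = ss_int / (ss_int + ss_err)
        got = rm_anova_partial_eta_sq(y, "interaction")
        assert got == pytest.approx(want, rel=1e-8)


class TestWithinSubjectSE:
    def test_zero_for_parallel_profiles(self):
        base = np.linspace(0, 1, 12)
        y = np.stack([base + k for k in range(5)])
        assert np.allclose(within_subject_se(y), 0.0)

    def test_hand_two_by_two(self):
        y = np.array([[0.0, 1.0], [3.0, 1.0]])
        # centered rows: [0.75, 1.75], [2.25, 0.25]; per-cell sd/sqrt(2)
        # times sqrt(2/1) = sd; sd = |2.25-0.75|/sqrt(2) = 1.0607
        got = within_subject_se(y)
        assert got == pytest.approx([1.5 / np.sqrt(2), 1.5 / np.sqrt(2)])

    def test_invariant_to_subject_shift(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(6, 12))
        shifted = y.copy()
        shifted[2] += 7.5
        assert np.allclose(within_subject_se(y), within_subject_se(shifted))


def _oracle_freeman_halton(table):
    """Independent exact-test enumeration for a 2xM table."""
    from math import comb

    table = np.asarray(table)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()

    def prob(cells):
        num = 1.0
        for c, x in zip(col, cells):
            num *= comb(c, x)
        return num / comb(n, row[0])

    p_obs = prob(table[0])
    total = 0.0
    for cells in product(*[range(c + 1) for c in col]):
        if sum(cells) == row[0] and prob(cells) <= p_obs * (1 + 1e-9):
            total += prob(cells)
    return total


class TestContingency:
    def test_identical_rows_give_p_one(self):
        res = contingency_tests([[4, 3, 2], [4, 3, 2]])
        assert res["p_exact"] == pytest.approx(1.0)

    def test_diagonal_2x2_by_enumeration(self):
        res = contingency_tests([[5, 0], [0, 5]])
        # only 2 of C(10,5) = 252 margin-fixed tables are as extreme
        assert res["p_exact"] == pytest.approx(2 / 252)

    def test_2x3_matches_enumeration_oracle(self):
        for table in ([[3, 2, 1], [1, 2, 3]], [[4, 1, 3], [0, 2, 5]],
                      [[6, 0, 1], [1, 5, 2]]):
            res = contingency_tests(table)
            assert res["p_exact"] == pytest.approx(
                _oracle_freeman_halton(table), rel=1e-9)

    def test_row_and_column_permutation_invariance(self):
        t = np.array([[5, 1, 3], [2, 4, 0]])
        base = contingency_tests(t)["p_exact"]
        assert contingency_tests(t[::-1])["p_exact"] == pytest.approx(base)
        assert contingency_tests(t[:, [2, 0, 1]])["p_exact"] == pytest.approx(base)

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            contingency_tests([[0, 0], [0, 0]])
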