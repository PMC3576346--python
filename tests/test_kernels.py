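"""Likelihood kernels: closed forms, quadrature oracles, background estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iaseq import (estimate_background, dataset_log_likelihoods, log_f0,
                   log_f1, log_f2, make_table)
from iaseq.kernels import BackgroundEstimationError, BackgroundParams
from .conftest import quad_f0, quad_f1, quad_f2


class TestClosedForms:
    def test_f0_uniform_beta_prior_gives_discrete_uniform(self):
        # alpha = beta = 1 makes every count 0..n equally likely
        x = np.arange(6)
        np.testing.assert_allclose(np.exp(log_f0(x, 5, 1.0, 1.0)), 1 / 6,
                                   atol=1e-12)

    def test_f0_beta22_example(self):
        vals = np.exp(log_f0(np.arange(3), 2, 2.0, 2.0))
        np.testing.assert_allclose(vals, [0.3, 0.4, 0.3], atol=1e-12)

    def test_f0_zero_total_is_certain(self):
        assert log_f0(0, 0, 3.0, 4.0) == pytest.approx(0.0, abs=1e-12)
        assert log_f1(0, 0, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert log_f2(0, 0, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_f1_f2_single_read_closed_forms(self):
        # 2 * int_{1/2}^{1} p dp = 3/4 and its complements
        assert np.exp(log_f1(1, 1, 0.5)) == pytest.approx(0.75, abs=1e-12)
        assert np.exp(log_f1(0, 1, 0.5)) == pytest.approx(0.25, abs=1e-12)
        assert np.exp(log_f2(1, 1, 0.5)) == pytest.approx(0.25, abs=1e-12)
        assert np.exp(log_f2(0, 1, 0.5)) == pytest.approx(0.75, abs=1e-12)


@pytest.mark.parametrize("p0", [0.3, 0.5, 0.62])
@pytest.mark.parametrize("n", [1, 4, 12])
def test_f1_f2_match_quadrature_and_normalize(n, p0):
    x = np.arange(n + 1)
    f1 = np.exp(log_f1(x, n, p0))
    f2 = np.exp(log_f2(x, n, p0))
    assert f1.sum() == pytest.approx(1.0, abs=1e-10)
    assert f2.sum() == pytest.approx(1.0, abs=1e-10)
    for xi in range(n + 1):
        assert f1[xi] == pytest.approx(quad_f1(xi, n, p0), abs=1e-10)
        assert f2[xi] == pytest.approx(quad_f2(xi, n, p0), abs=1e-10)


@pytest.mark.parametrize("alpha,beta", [(0.5, 0.5), (2.0, 2.0), (5.0, 1.5)])
def test_f0_matches_quadrature(alpha, beta):
    n = 9
    for xi in range(n + 1):
        assert np.exp(log_f0(xi, n, alpha, beta)) == pytest.approx(
            quad_f0(xi, n, alpha, beta), abs=1e-10)


def test_reflection_symmetry():
    # f2(x | n, p0) = f1(n - x | n, 1 - p0)
    n = 7
    x = np.arange(n + 1)
    for p0 in (0.2, 0.5, 0.73):
        np.testing.assert_allclose(log_f2(x, n, p0), log_f1(n - x, n, 1 - p0),
                                   atol=1e-10)


def test_skew_evidence_monotone_in_imbalance():
    # f1/f0 non-decreasing and f2/f0 non-increasing in x for fixed n
    n = 15
    x = np.arange(n + 1)
    lr1 = log_f1(x, n, 0.45) - log_f0(x, n, 9.0, 11.0)
    lr2 = log_f2(x, n, 0.45) - log_f0(x, n, 9.0, 11.0)
    assert (np.diff(lr1) >= -1e-12).all()
    assert (np.diff(lr2) <= 1e-12).all()


def test_log_space_stability_at_extreme_counts():
    # no overflow/underflow up to n = 1e5, including the far tails
    n = 100_000
    for x in (0, 1, n // 2, n - 1, n):
        for f in (lambda a, b: log_f0(a, b, 20.0, 20.0),
                  lambda a, b: log_f1(a, b, 0.5),
                  lambda a, b: log_f2(a, b, 0.5)):
            val = f(x, n)
            assert np.isfinite(val), (x, n)
            assert val < 1e-6


@settings(derandomize=True, max_examples=30, deadline=None)
@given(n=st.integers(0, 20),
       p0=st.floats(0.05, 0.95),
       conc=st.floats(0.5, 50.0))
def test_kernels_are_proper_distributions(n, p0, conc):
    x = np.arange(n + 1)
    for lf in (log_f0(x, n, conc * p0, conc * (1 - p0)),
               log_f1(x, n, p0), log_f2(x, n, p0)):
        assert np.exp(lf).sum() == pytest.approx(1.0, abs=1e-10)


def test_domain_errors():
    with pytest.raises(ValueError):
        log_f0(3, 2, 1.0, 1.0)
    with pytest.raises(ValueError):
        log_f1(1, 2, 1.0)
    with pytest.raises(ValueError):
        log_f2(1, 2, 0.0)
    with pytest.raises(ValueError):
        log_f0(1, 2, -1.0, 1.0)


class TestBackgroundEstimation:
    def test_recovers_beta_parameters(self, rng):
        # p ~ Beta(5, 5), n = 50, I = 50,000 -> (alpha, beta) within 10%
        I = 50_000
        p = rng.beta(5, 5, size=I)
        n = np.full(I, 50)
        x = rng.binomial(n, p)
        t = make_table(x[:, None], n[:, None], ["d1"], [1])
        bg = estimate_background(t)
        assert bg.alpha[0] == pytest.approx(5.0, rel=0.10)
        assert bg.beta[0] == pytest.approx(5.0, rel=0.10)
        assert bg.p0[0] == pytest.approx(0.5, abs=0.01)

    def test_exact_half_ratios_give_symmetric_background(self):
        n = np.full(100, 10_000)
        x = n // 2
        t = make_table(x[:, None], n[:, None], ["d1"], [1])
        bg = estimate_background(t)
        assert bg.p0[0] == pytest.approx(0.5, abs=1e-12)

    def test_subbinomial_variance_falls_back_to_tight_beta(self):
        # observed ratio variance below the pure-binomial floor
        n = np.full(200, 20)
        x = n // 2
        t = make_table(x[:, None], n[:, None], ["d1"], [1])
        bg = estimate_background(t)
        assert bg.p0[0] == pytest.approx(0.5, abs=1e-9)
        assert bg.alpha[0] + bg.beta[0] == pytest.approx(1e4)

    def test_too_few_informative_snps_raises(self):
        t = make_table(np.array([[1], [0]]), np.array([[2], [1]]), ["d1"], [1])
        with pytest.raises(BackgroundEstimationError, match="d1_rep1"):
            estimate_background(t, min_total=2)


class TestDatasetLogLikelihoods:
    def test_single_replicate_equals_per_replicate_values(self, tiny_table,
                                                          tiny_background):
        logL = dataset_log_likelihoods(tiny_table, tiny_background)
        # dataset tfB has one replicate (sample index 2)
        a, b = tiny_background.alpha[2], tiny_background.beta[2]
        p0 = a / (a + b)
        x, n = tiny_table.x[:, 2], tiny_table.n[:, 2]
        np.testing.assert_allclose(logL[:, 1, 0], log_f0(x, n, a, b), atol=1e-12)
        np.testing.assert_allclose(logL[:, 1, 1], log_f1(x, n, p0), atol=1e-12)
        np.testing.assert_allclose(logL[:, 1, 2], log_f2(x, n, p0), atol=1e-12)

    def test_duplicate_replicates_double_the_log_likelihood(self):
        x = np.array([[2, 2], [1, 1]])
        n = np.array([[3, 3], [4, 4]])
        t = make_table(x, n, ["d1"], [2])
        bg = BackgroundParams(alpha=[2.0, 2.0], beta=[3.0, 3.0])
        logL = dataset_log_likelihoods(t, bg)
        single = dataset_log_likelihoods(
            make_table(x[:, :1], n[:, :1], ["d1"], [1]),
            BackgroundParams(alpha=[2.0], beta=[3.0]))
        np.testing.assert_allclose(logL, 2 * single, atol=1e-12)

    def test_matches_brute_force_per_cell_sums(self, rng, tiny_background):
        from .conftest import random_small_table
        t = random_small_table(rng)
        logL = dataset_log_likelihoods(t, tiny_background)
        expected = np.zeros_like(logL)
        for d in range(t.D):
            sl = t.dataset_slice(d)
            for s in range(sl.start, sl.stop):
                a, b = tiny_background.alpha[s], tiny_background.beta[s]
                p0 = a / (a + b)
                for i in range(t.I):
                    xi, ni = int(t.x[i, s]), int(t.n[i, s])
                    expected[i, d, 0] += np.log(quad_f0(xi, ni, a, b)) if ni else 0.0
                    expected[i, d, 1] += np.log(quad_f1(xi, ni, p0)) if ni else 0.0
                    expected[i, d, 2] += np.log(quad_f2(xi, ni, p0)) if ni else 0.0
        np.testing.assert_allclose(logL, expected, atol=1e-9)

    def test_zero_coverage_rows_contribute_zero(self, tiny_table, tiny_background):
        logL = dataset_log_likelihoods(tiny_table, tiny_background)
        # SNP 1 has n = 0 in dataset tfB
        np.testing.assert_allclose(logL[1, 1, :], 0.0, atol=1e-12)
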