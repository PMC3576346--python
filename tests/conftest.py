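"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import betaln, gammaln

from iaseq import make_table
from iaseq.kernels import BackgroundParams


# ---------------------------------------------------------------------------
# independent likelihood oracles (numeric quadrature, no incomplete-beta path)
# ---------------------------------------------------------------------------

def quad_f0(x: int, n: int, alpha: float, beta: float) -> float:
    """Beta-binomial probability by adaptive quadrature of the integrand."""
    logC = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    val, _ = quad(lambda p: p ** (x + alpha - 1) * (1 - p) ** (n - x + beta - 1),
                  0, 1, epsabs=1e-14, epsrel=1e-13)
    return float(np.exp(logC - betaln(alpha, beta)) * val)


def quad_f1(x: int, n: int, p0: float) -> float:
    """SR kernel by quadrature: C(n,x)/(1-p0) * int_{p0}^{1} p^x (1-p)^(n-x) dp."""
    logC = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    val, _ = quad(lambda p: p ** x * (1 - p) ** (n - x), p0, 1,
                  epsabs=1e-14, epsrel=1e-13)
    return float(np.exp(logC) / (1 - p0) * val)


def quad_f2(x: int, n: int, p0: float) -> float:
    """SN kernel by quadrature: C(n,x)/p0 * int_0^{p0} p^x (1-p)^(n-x) dp."""
    logC = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    val, _ = quad(lambda p: p ** x * (1 - p) ** (n - x), 0, p0,
                  epsabs=1e-14, epsrel=1e-13)
    return float(np.exp(logC) / p0 * val)


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle for the joint mixture posteriors
# ---------------------------------------------------------------------------

def enumerate_posteriors(table, background: BackgroundParams, pi, v, w):
    """Brute-force posteriors by summing over every (a, b, c) configuration.

    Returns (class_post (I, K+1), sr_post (I, D), sn_post (I, D)), computed
    with the quadrature kernels above — fully independent of the package's
    E-step and incomplete-beta code paths.
    """
    pi = np.asarray(pi, float)
    v = np.atleast_2d(np.asarray(v, float))
    w = np.atleast_2d(np.asarray(w, float))
    K, D = v.shape
    I = table.I
    kernels = (quad_f0, quad_f1, quad_f2)

    # per-(i, d, state) likelihoods as products over replicates
    L = np.ones((I, D, 3))
    for d in range(D):
        sl = table.dataset_slice(d)
        for s in range(sl.start, sl.stop):
            a_s, b_s = background.alpha[s], background.beta[s]
            p0 = a_s / (a_s + b_s)
            for i in range(I):
                x, n = int(table.x[i, s]), int(table.n[i, s])
                L[i, d, 0] *= quad_f0(x, n, a_s, b_s)
                L[i, d, 1] *= quad_f1(x, n, p0)
                L[i, d, 2] *= quad_f2(x, n, p0)
    del kernels

    class_post = np.zeros((I, K + 1))
    sr_post = np.zeros((I, D))
    sn_post = np.zeros((I, D))
    # state code per dataset: 0 = NS, 1 = SR, 2 = SN
    for i in range(I):
        total = 0.0
        for a in range(K + 1):
            for states in itertools.product(range(3), repeat=D):
                if a == 0:
                    if any(s != 0 for s in states):
                        continue
                    prob = pi[0] * np.prod([L[i, d, 0] for d in range(D)])
                else:
                    k = a - 1
                    prob = pi[a]
                    for d, s in enumerate(states):
                        ps = (1 - v[k, d] - w[k, d], v[k, d], w[k, d])[s]
                        prob *= ps * L[i, d, s]
                class_post[i, a] += prob
                for d, s in enumerate(states):
                    if s == 1:
                        sr_post[i, d] += prob
                    elif s == 2:
                        sn_post[i, d] += prob
                total += prob
        class_post[i] /= total
        sr_post[i] /= total
        sn_post[i] /= total
    return class_post, sr_post, sn_post


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_table():
    """I=3 SNPs, 2 datasets (J=2 and J=1 replicates), small counts."""
    x = np.array([[2, 1, 3], [0, 0, 0], [1, 4, 0]])
    n = np.array([[2, 2, 4], [3, 1, 0], [2, 4, 1]])
    return make_table(x, n, datasets=["tfA", "tfB"], replicate_counts=[2, 1])


@pytest.fixture()
def tiny_background(tiny_table):
    return BackgroundParams(alpha=np.array([2.0, 3.0, 1.5]),
                            beta=np.array([2.0, 2.0, 1.5]),
                            sample_id=list(tiny_table.sample_id))


def random_small_table(rng, I=4, D=2, reps=(2, 1), n_max=4):
    """Small random table for oracle comparisons."""
    S = sum(reps)
    n = rng.integers(0, n_max + 1, size=(I, S))
    x = rng.binomial(n, 0.5)
    return make_table(x, n, datasets=[f"d{j}" for j in range(D)],
                      replicate_counts=list(reps))
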