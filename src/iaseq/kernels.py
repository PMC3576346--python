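"""Background estimation and the three per-replicate count distributions.

Given a heterozygote SNP with total read count ``n`` in one sample, the
reference-allele count ``x`` follows one of three conditional distributions
depending on the SNP's allele-specificity state in that dataset:

* NS (not allele-specific): the reference-read probability ``p`` varies around
  a sample-specific background ratio, ``p ~ Beta(alpha, beta)`` with mean
  ``p0 = alpha / (alpha + beta)``; marginally ``x`` is beta-binomial (``f0``).
* SR (skewed to the reference allele): ``p ~ Uniform[p0, 1]`` (``f1``).
* SN (skewed to the non-reference allele): ``p ~ Uniform[0, p0]`` (``f2``).

``p0`` absorbs reference mapping bias: with unbiased alignments it sits near
0.5, and deviations shift all three kernels consistently.  All kernels are
evaluated in log space; for the uniform mixtures the binomial integral reduces
to a regularized incomplete beta function because
``C(n,x) * B(x+1, n-x+1) = 1/(n+1)``:

    f1(x) = I_{1-p0}(n-x+1, x+1) / ((n+1) (1-p0))
    f2(x) = I_{p0}(x+1, n-x+1)   / ((n+1) p0)

When the incomplete beta underflows in double precision the integer-argument
binomial-tail identity is used with a log-sum-exp, so the kernels stay finite
for totals up to at least 1e5 reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, betaln, gammaln, logsumexp

from .count_data import AlleleCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundParams",
    "BackgroundEstimationError",
    "estimate_background",
    "log_f0",
    "log_f1",
    "log_f2",
    "dataset_log_likelihoods",
]

#: alpha+beta ceiling: beyond this the Beta is numerically a point mass
_MAX_CONCENTRATION = 1.0e4


class BackgroundEstimationError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundParams:
    """Per-sample Beta background parameters (alpha_dj, beta_dj).

    ``p0 = alpha / (alpha + beta)`` is the background reference-read ratio.
    Once estimated these are treated as fixed, known constants by the model.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sample_id: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        if a.shape != b.shape:
            raise ValueError("alpha and beta shapes differ")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("alpha and beta must be strictly positive")

    @property
    def p0(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def estimate_background(table: AlleleCountTable, min_total: int = 5) -> BackgroundParams:
    """Moment-matched Beta background per sample.

    For each sample, allelic ratios ``r = x/n`` over SNPs with
    ``n >= max(min_total, 1)`` are summarized by their mean ``m`` and sample
    variance; the Beta variance is the observed variance minus the expected
    binomial noise ``mean(m(1-m)/n)``, and (alpha, beta) solve the Beta moment
    equations.  If the corrected variance is non-positive or implies
    ``alpha + beta > 1e4`` the Beta degenerates; the fallback pins
    ``alpha + beta = 1e4`` at mean ``m`` (near-constant ``p`` model).
    """
    thr = max(int(min_total), 1)
    S = table.S
    alpha = np.empty(S)
    beta = np.empty(S)
    for s in range(S):
        n = table.n[:, s]
        mask = n >= thr
        if mask.sum() < 2:
            raise BackgroundEstimationError(
                f"sample {table.sample_id[s]!r}: fewer than 2 SNPs with "
                f"total count >= {thr}"
            )
        ns = n[mask].astype(float)
        r = table.x[mask, s] / ns
        m = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))
        v_obs = float(r.var(ddof=1))
        v_beta = v_obs - float(np.mean(m * (1 - m) / ns))
        conc = m * (1 - m) / v_beta - 1 if v_beta > 0 else np.inf
        if not np.isfinite(conc) or conc <= 0 or conc > _MAX_CONCENTRATION:
            logger.info(
                "sample %r: degenerate background variance, pinning alpha+beta=%g",
                table.sample_id[s], _MAX_CONCENTRATION)
            conc = _MAX_CONCENTRATION
        alpha[s] = m * conc
        beta[s] = (1 - m) * conc
    return BackgroundParams(alpha=alpha, beta=beta, sample_id=list(table.sample_id))


def _check_counts(x: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if ((x < 0) | (x > n)).any():
        raise ValueError("counts must satisfy 0 <= x <= n")
    return x, n


def _log_binom(n: np.ndarray, x: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


def log_f0(x, n, alpha: float, beta: float) -> np.ndarray:
    """Log beta-binomial NS kernel; log_f0(0 | 0) = 0."""
    x, n = _check_counts(x, n)
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return (_log_binom(n, x)
            + betaln(x + alpha, n - x + beta) - betaln(alpha, beta))


def _log_binom_tail(k: np.ndarray, m: np.ndarray, p: float) -> np.ndarray:
    """log Pr(Bin(m, p) >= k), exact log-sum-exp over the tail.

    Fallback path for incomplete-beta underflow; element-wise, only hit for
    extreme tails so the O(m) inner sums are acceptable.
    """
    out = np.empty(k.shape)
    lp, lq = np.log(p), np.log1p(-p)
    for idx in np.ndindex(k.shape):
        ki, mi = int(k[idx]), int(m[idx])
        j = np.arange(ki, mi + 1, dtype=float)
        terms = _log_binom(np.full_like(j, mi), j) + j * lp + (mi - j) * lq
        out[idx] = logsumexp(terms)
    return out


def _log_betainc_int(a: np.ndarray, b: np.ndarray, z: float) -> np.ndarray:
    """log I_z(a, b) for integer a, b >= 1, underflow-safe.

    Uses scipy's regularized incomplete beta; where that underflows to zero it
    switches to the identity I_z(a, b) = Pr(Bin(a+b-1, z) >= a).
    """
    val = betainc(a, b, z)
    out = np.full(val.shape, -np.inf)
    pos = val > 0
    out[pos] = np.log(val[pos])
    if (~pos).any():
        m = a + b - 1
        out[~pos] = _log_binom_tail(a[~pos], m[~pos], z)
    return out


def log_f1(x, n, p0: float) -> np.ndarray:
    """Log SR kernel: binomial with p ~ Uniform[p0, 1]."""
    x, n = _check_counts(x, n)
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    # 1 - I_{p0}(x+1, n-x+1) = I_{1-p0}(n-x+1, x+1), exact complement
    return (_log_betainc_int(n - x + 1, x + 1, 1 - p0)
            - np.log(n + 1) - np.log1p(-p0))


def log_f2(x, n, p0: float) -> np.ndarray:
    """Log SN kernel: binomial with p ~ Uniform[0, p0]."""
    x, n = _check_counts(x, n)
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    return (_log_betainc_int(x + 1, n - x + 1, p0)
            - np.log(n + 1) - np.log(p0))


def dataset_log_likelihoods(table: AlleleCountTable,
                            background: BackgroundParams) -> np.ndarray:
    """Per-(SNP, dataset) log likelihoods under the three states.

    Returns an ``(I, D, 3)`` array with slices ``[..., 0] = log L_id0``
    (NS), ``[..., 1] = log L_id1`` (SR), ``[..., 2] = log L_id2`` (SN), each
    the sum of per-replicate kernel logs.  Replicates with ``n_idj = 0``
    contribute 0 under all three states.
    """
    if background.alpha.shape[0] != table.S:
        raise ValueError("background parameters do not match the table's samples")
    I, D = table.I, table.D
    out = np.zeros((I, D, 3))
    p0 = background.p0
    for d in range(D):
        sl = table.dataset_slice(d)
        for s in range(sl.start, sl.stop):
            x, n = table.x[:, s], table.n[:, s]
            out[:, d, 0] += log_f0(x, n, background.alpha[s], background.beta[s])
            out[:, d, 1] += log_f1(x, n, p0[s])
            out[:, d, 2] += log_f2(x, n, p0[s])
    return out
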