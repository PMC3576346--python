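"""Fused EM iteration.

One pass over the (SNP, dataset, class) grid computes the observed-data log
likelihood at the current parameters and the MAP-updated parameters, without
materializing the (I, D, K, 3) posterior arrays.  The arithmetic matches the
reference numpy path in :mod:`iaseq.model` (e_step followed by m_step) up to
floating-point summation order; the compiled path exists purely for speed on
large tables.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _em_step_compiled(logL, pi, v, w, eta):  # pragma: no cover - compiled
    I, D, _ = logL.shape
    K = v.shape[0]
    logpi = np.log(pi)
    logv = np.log(v)
    logw = np.log(w)
    logns = np.log(1.0 - v - w)

    gsum = np.zeros(K + 1)
    acc = np.zeros((K, D, 3))
    loglik = 0.0
    Mbuf = np.empty((D, K))
    ljoint = np.empty(K + 1)

    for i in range(I):
        l0sum = 0.0
        for d in range(D):
            l0sum += logL[i, d, 0]
        for k in range(K):
            s = 0.0
            for d in range(D):
                c0 = logL[i, d, 0] + logns[k, d]
                c1 = logL[i, d, 1] + logv[k, d]
                c2 = logL[i, d, 2] + logw[k, d]
                m = c0
                if c1 > m:
                    m = c1
                if c2 > m:
                    m = c2
                M = m + np.log(np.exp(c0 - m) + np.exp(c1 - m) + np.exp(c2 - m))
                Mbuf[d, k] = M
                s += M
            ljoint[k + 1] = logpi[k + 1] + s
        ljoint[0] = logpi[0] + l0sum
        mx = ljoint[0]
        for k in range(1, K + 1):
            if ljoint[k] > mx:
                mx = ljoint[k]
        tot = 0.0
        for k in range(K + 1):
            tot += np.exp(ljoint[k] - mx)
        log_norm = mx + np.log(tot)
        loglik += log_norm
        gsum[0] += np.exp(ljoint[0] - log_norm)
        for k in range(K):
            gk = np.exp(ljoint[k + 1] - log_norm)
            gsum[k + 1] += gk
            for d in range(D):
                M = Mbuf[d, k]
                acc[k, d, 0] += gk * np.exp(logL[i, d, 0] + logns[k, d] - M)
                acc[k, d, 1] += gk * np.exp(logL[i, d, 1] + logv[k, d] - M)
                acc[k, d, 2] += gk * np.exp(logL[i, d, 2] + logw[k, d] - M)

    new_pi = (gsum + (eta - 1.0)) / (I + (K + 1) * (eta - 1.0))
    new_v = np.empty((K, D))
    new_w = np.empty((K, D))
    for k in range(K):
        denom = gsum[k + 1] + 3.0 * (eta - 1.0)
        for d in range(D):
            new_v[k, d] = (acc[k, d, 1] + (eta - 1.0)) / denom
            new_w[k, d] = (acc[k, d, 2] + (eta - 1.0)) / denom
    return loglik, new_pi, new_v, new_w


def em_step_fused(logL, pi, v, w, eta):
    """(log likelihood at current params, MAP-updated pi, v, w)."""
    return _em_step_compiled(np.ascontiguousarray(logL), pi, v, w, float(eta))
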