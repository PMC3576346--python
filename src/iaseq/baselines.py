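"""Single-dataset ranking baselines for allele-specificity.

Five methods that analyze one dataset at a time, used as comparison points
for the joint model.  Four are closed-form statistics on replicate-pooled
counts ``x_id = sum_j x_idj``, ``n_id = sum_j n_idj``:

* ``stat_d`` — deviation of the raw allelic ratio from the dataset background
  ratio ``p_d0`` (mean ratio over SNPs with reads).
* ``stat_z`` — the same deviation standardized by its binomial null SD.
* ``stat_b`` — deviation of a ratio shrunk with a fixed pseudo-count prior
  Beta(2 p~_d0, 2 (1 - p~_d0)).
* ``stat_B`` — deviation of the posterior-mean ratio under a moment-matched
  Beta prior estimated from the pooled data.

The fifth, ``single_em``, fits the same three-state (NS/SR/SN) kernels as the
joint model, per replicate, but with free per-dataset mixing probabilities
``(v_d, w_d)`` and no class structure — the controlled comparison isolating
the value of cross-dataset information sharing.

Ranking layer: SNPs with ``n_id = 0`` carry no allelic information and are
placed at the bottom of every baseline ranking (score -inf sentinel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_data import AlleleCountTable, make_table
from .kernels import BackgroundParams, dataset_log_likelihoods, estimate_background

logger = logging.getLogger(__name__)

__all__ = ["PooledCounts", "pool_replicates", "stat_d", "stat_z", "stat_b",
           "stat_B", "single_em", "SingleEMResult", "rank_baseline",
           "BASELINE_METHODS"]

BASELINE_METHODS = ("d", "z", "b", "B", "singleEM")


@dataclass(frozen=True)
class PooledCounts:
    """Replicate-pooled counts for one dataset: x_id, n_id (I,) arrays."""

    x: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.int64)
        n = np.asarray(self.n, dtype=np.int64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "n", n)
        if ((x < 0) | (x > n)).any():
            raise ValueError("pooled counts must satisfy 0 <= x <= n")

    @property
    def informative(self) -> np.ndarray:
        return self.n > 0

    def background_ratio(self) -> float:
        """p_d0: mean allelic ratio over SNPs with n_id > 0."""
        m = self.informative
        if not m.any():
            raise ValueError("dataset has no SNPs with reads")
        return float((self.x[m] / self.n[m]).mean())


def pool_replicates(table: AlleleCountTable) -> list[PooledCounts]:
    x_id, n_id = table.pooled()
    return [PooledCounts(x=x_id[:, d], n=n_id[:, d]) for d in range(table.D)]


def _safe_ratio(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, x / np.maximum(n, 1), np.nan)


def stat_d(pooled: PooledCounts) -> tuple[np.ndarray, float]:
    """Deviation statistic |x/n - p_d0|; NaN where n = 0."""
    p_d0 = pooled.background_ratio()
    return np.abs(_safe_ratio(pooled.x, pooled.n) - p_d0), p_d0


def stat_z(pooled: PooledCounts) -> tuple[np.ndarray, float]:
    """Standardized deviation |x/n - p_d0| / sqrt(p_d0 (1-p_d0) / n)."""
    p_d0 = pooled.background_ratio()
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(p_d0 * (1 - p_d0) / np.maximum(pooled.n, 1))
        score = np.where(pooled.n > 0,
                         np.abs(pooled.x / np.maximum(pooled.n, 1) - p_d0) / se,
                         np.nan)
    return score, p_d0


def stat_b(pooled: PooledCounts) -> tuple[np.ndarray, float]:
    """Pseudo-count-shrunk deviation |(x + 2 p~_d0)/(n + 2) - p~_d0|.

    p~_d0 is the mean over *all* SNPs of (x + 2 p_d0)/(n + 2); SNPs with
    n = 0 enter that mean at their prior value p_d0 and get a defined
    (usually small) score.
    """
    p_d0 = pooled.background_ratio()
    shrunk0 = (pooled.x + 2 * p_d0) / (pooled.n + 2)
    p_tilde0 = float(shrunk0.mean())
    score = np.abs((pooled.x + 2 * p_tilde0) / (pooled.n + 2) - p_tilde0)
    return score, p_tilde0


def stat_B(pooled: PooledCounts, min_total: int = 5
           ) -> tuple[np.ndarray, float, float, float]:
    """Empirical-Bayes deviation |(x + a)/(n + a + b) - p`_d0|.

    (a, b) are moment-matched on the pooled counts with the same estimator,
    threshold and degenerate-variance fallback as the joint model's
    background; p`_d0 = a / (a + b).
    """
    t = make_table(pooled.x[:, None], pooled.n[:, None], ["pooled"], [1])
    bg = estimate_background(t, min_total=min_total)
    a, b = float(bg.alpha[0]), float(bg.beta[0])
    p_check0 = a / (a + b)
    score = np.abs((pooled.x + a) / (pooled.n + a + b) - p_check0)
    return score, a, b, p_check0


@dataclass
class SingleEMResult:
    """Three-state mixture fit for one dataset."""

    v: float
    w: float
    sr_post: np.ndarray
    sn_post: np.ndarray
    n_iter: int
    converged: bool
    log_posterior_trajectory: list[float]

    @property
    def p_tilde(self) -> np.ndarray:
        return np.maximum(self.sr_post, self.sn_post)

    @property
    def direction(self) -> np.ndarray:
        return np.where(self.sr_post >= self.sn_post, "SR", "SN")


def single_em(table: AlleleCountTable, background: BackgroundParams,
              dataset: int | str = 0, eta: float = 2.0, max_iter: int = 2000,
              tol: float = 1e-6, init: tuple[float, float] = (0.1, 0.1),
              logL: np.ndarray | None = None) -> SingleEMResult:
    """MAP-EM fit of the per-dataset NS/SR/SN mixture.

    Each SNP's state is drawn with probabilities (1 - v_d - w_d, v_d, w_d)
    and its counts follow the per-replicate kernels f0/f1/f2 (replicates are
    multiplied, not pooled).  (v_d, w_d, 1 - v_d - w_d) carries a
    Dirichlet(eta, eta, eta) prior.  Deterministic: the likelihood is
    unimodal in practice and a fixed interior start is used.
    """
    d = table.datasets.index(dataset) if isinstance(dataset, str) else int(dataset)
    if logL is None:
        sub = table.restrict_dataset(d)
        sub_bg = BackgroundParams(
            alpha=background.alpha[table.dataset_slice(d)],
            beta=background.beta[table.dataset_slice(d)])
        L = dataset_log_likelihoods(sub, sub_bg)[:, 0, :]
    else:
        L = logL[:, d, :]
    I = L.shape[0]
    v, w = init
    lp_prev = -np.inf
    trajectory: list[float] = []
    converged = False
    tau = None
    for it in range(max_iter):
        comp = np.stack([
            L[:, 0] + np.log1p(-(v + w)),
            L[:, 1] + np.log(v),
            L[:, 2] + np.log(w),
        ], axis=1)
        mx = comp.max(axis=1, keepdims=True)
        log_norm = mx[:, 0] + np.log(np.exp(comp - mx).sum(axis=1))
        tau = np.exp(comp - log_norm[:, None])
        lp = (log_norm.sum()
              + (eta - 1.0) * (np.log(v) + np.log(w) + np.log1p(-(v + w))))
        trajectory.append(float(lp))
        if np.isfinite(lp_prev) and lp - lp_prev <= tol:
            converged = True
            break
        lp_prev = lp
        s = tau.sum(axis=0) + (eta - 1.0)
        total = I + 3.0 * (eta - 1.0)
        v, w = s[1] / total, s[2] / total
    assert tau is not None
    return SingleEMResult(v=float(v), w=float(w),
                          sr_post=tau[:, 1], sn_post=tau[:, 2],
                          n_iter=len(trajectory), converged=converged,
                          log_posterior_trajectory=trajectory)


def rank_baseline(table: AlleleCountTable, method: str,
                  background: BackgroundParams | None = None,
                  min_total: int = 5, **single_em_kwargs) -> dict[str, pd.DataFrame]:
    """Ranked SNP lists per dataset for one baseline method.

    Returns dataset id -> DataFrame with columns ``snp_id, dataset_id, score,
    direction, rank``; rows sorted by descending score (ties by snp_id), with
    ``n_id = 0`` SNPs forced to the bottom.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; expected one of {BASELINE_METHODS}")
    pooled = pool_replicates(table)
    if method == "singleEM" and background is None:
        background = estimate_background(table, min_total=min_total)
    out: dict[str, pd.DataFrame] = {}
    for d, (name, pc) in enumerate(zip(table.datasets, pooled)):
        ratio = _safe_ratio(pc.x, pc.n)
        if method == "d":
            score, p0 = stat_d(pc)
            direction = np.where(ratio >= p0, "SR", "SN")
        elif method == "z":
            score, p0 = stat_z(pc)
            direction = np.where(ratio >= p0, "SR", "SN")
        elif method == "b":
            score, p_tilde0 = stat_b(pc)
            shrunk = (pc.x + 2 * p_tilde0) / (pc.n + 2)
            direction = np.where(shrunk >= p_tilde0, "SR", "SN")
        elif method == "B":
            score, a, b, p_check0 = stat_B(pc, min_total=min_total)
            post_mean = (pc.x + a) / (pc.n + a + b)
            direction = np.where(post_mean >= p_check0, "SR", "SN")
        else:  # singleEM
            fit = single_em(table, background, dataset=d, **single_em_kwargs)
            score = fit.p_tilde.astype(float)
            direction = fit.direction
        score = np.where(pc.n > 0, score, -np.inf)
        df = pd.DataFrame({
            "snp_id": table.snp_id, "dataset_id": name,
            "score": score, "direction": direction,
        })
        df = df.sort_values(["score", "snp_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        out[name] = df
    return out
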