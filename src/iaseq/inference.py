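"""Per-SNP, per-dataset allele-specificity calls from a fitted model.

The marginal skew posterior mixes class memberships with class-conditional
state posteriors:

    Pr(b_id, c_id | data) = sum_k Pr(a_i = k | data) Pr(b_id, c_id | a_i = k, data)

with class 0 contributing all of its mass to the NS state.  The ranking
statistic is P~_id = max(Pr(SR), Pr(SN)); the larger of the two posteriors
sets the reported skew direction (ties break to SR for determinism).  The
estimated FDR of a top-N list is the mean of (1 - P~) over that list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, e_step

logger = logging.getLogger(__name__)

__all__ = ["PosteriorSummary", "posterior_skew", "rank_statistic",
           "fdr_estimate", "call_class"]


@dataclass
class PosteriorSummary:
    """Marginal posteriors for every SNP and dataset.

    class_post : (I, K+1) Pr(a_i = k | data).
    sr_post, sn_post : (I, D) marginal Pr(SR), Pr(SN) per SNP and dataset.
    p_tilde : (I, D) ranking statistic max(sr_post, sn_post).
    direction : (I, D) "SR" or "SN" (the larger posterior; ties to SR).
    """

    snp_id: np.ndarray
    datasets: list[str]
    class_post: np.ndarray
    sr_post: np.ndarray
    sn_post: np.ndarray

    @property
    def p_tilde(self) -> np.ndarray:
        return np.maximum(self.sr_post, self.sn_post)

    @property
    def direction(self) -> np.ndarray:
        return np.where(self.sr_post >= self.sn_post, "SR", "SN")

    @property
    def ns_post(self) -> np.ndarray:
        return 1.0 - self.sr_post - self.sn_post


def posterior_skew(logL: np.ndarray, params: ModelParams,
                   snp_id: np.ndarray | None = None,
                   datasets: list[str] | None = None) -> PosteriorSummary:
    """Marginal SR/SN posteriors per (SNP, dataset)."""
    es = e_step(logL, params)
    g1 = es.gamma[:, 1:]                                # (I, K)
    sr = np.einsum("ik,idk->id", g1, es.tau[..., 1])
    sn = np.einsum("ik,idk->id", g1, es.tau[..., 2])
    I, D = logL.shape[:2]
    if snp_id is None:
        snp_id = np.array([f"snp{i}" for i in range(I)], dtype=object)
    if datasets is None:
        datasets = [f"d{d}" for d in range(D)]
    return PosteriorSummary(snp_id=np.asarray(snp_id, dtype=object),
                            datasets=list(datasets),
                            class_post=es.gamma, sr_post=sr, sn_post=sn)


def _dataset_index(summary: PosteriorSummary, dataset: str | int) -> int:
    if isinstance(dataset, str):
        return summary.datasets.index(dataset)
    return int(dataset)


def rank_statistic(summary: PosteriorSummary,
                   dataset: str | int | None = None) -> pd.DataFrame:
    """Ranked SNP list(s) with P~, direction and running FDR estimate.

    Rows are sorted by descending P~_id with ties broken by snp_id; the
    ``fdr`` column is the estimated FDR of the list truncated at each row
    (cumulative mean of 1 - P~).  With ``dataset=None`` all datasets are
    concatenated (each ranked within its own dataset).
    """
    if dataset is None:
        frames = [rank_statistic(summary, d) for d in summary.datasets]
        return pd.concat(frames, ignore_index=True)
    d = _dataset_index(summary, dataset)
    df = pd.DataFrame({
        "snp_id": summary.snp_id,
        "dataset_id": summary.datasets[d],
        "pr_sr": summary.sr_post[:, d],
        "pr_sn": summary.sn_post[:, d],
        "p_tilde": summary.p_tilde[:, d],
        "direction": summary.direction[:, d],
    })
    df = df.sort_values(["p_tilde", "snp_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["fdr"] = fdr_estimate(df["p_tilde"].to_numpy())
    return df


def fdr_estimate(p_tilde_sorted: np.ndarray, N: int | None = None):
    """Estimated FDR(N) = mean of (1 - P~) over the top N of a ranked list.

    With ``N`` given, returns the scalar FDR of the top-N list; otherwise
    returns the full curve for N = 1..len.  The curve is the raw cumulative
    mean and is not forced monotone.
    """
    p = np.asarray(p_tilde_sorted, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d ranked P~ array")
    curve = np.cumsum(1.0 - p) / np.arange(1, p.size + 1)
    if N is None:
        return curve
    if not 1 <= N <= p.size:
        raise ValueError(f"N={N} outside [1, {p.size}]")
    return float(curve[N - 1])


def call_class(summary: PosteriorSummary, cutoff: float = 0.9) -> np.ndarray:
    """Hard class assignment: class k iff Pr(a_i = k | data) > cutoff.

    Returns an (I,) integer array with -1 for unassigned SNPs.  For
    cutoff > 0.5 at most one class can pass per SNP; below that a warning is
    issued and ties resolve to the argmax among passing classes.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if cutoff <= 0.5:
        logger.warning("cutoff <= 0.5 does not guarantee a unique class; "
                       "assigning the argmax among passing classes")
    cp = summary.class_post
    passing = cp > cutoff
    out = np.full(cp.shape[0], -1, dtype=np.int64)
    any_pass = passing.any(axis=1)
    masked = np.where(passing, cp, -np.inf)
    out[any_pass] = masked[any_pass].argmax(axis=1)
    return out
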