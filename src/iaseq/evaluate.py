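"""Benchmark machinery: true-positive curves, truncated AUC, dAUC, FDR calibration.

A gold standard is either direction-aware (snp_id -> "SR"/"SN", e.g. from
simulation truth) or direction-free (a plain set of snp_ids, e.g. a list of
X-chromosome or expression-validated SNPs).  With a direction-aware gold
standard, a ranked SNP counts as a true positive only if its called direction
matches the truth.

The truncated AUC is the area under TP(q) vs q for q <= N (trapezoid rule),
normalized by the area of the perfect envelope min(q, G_N) with
G_N = min(N, |gold|), so a perfect ranking scores exactly 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .count_data import AlleleCountTable
from .inference import fdr_estimate
from .simulate import SimTruth

__all__ = ["GoldStandard", "read_gold_standard", "gold_from_truth",
           "tp_curve", "auc_top_n", "dauc", "fdr_calibration"]


class GoldStandard:
    """Set of true allele-specific SNPs, optionally with known directions."""

    def __init__(self, snp_ids, directions=None) -> None:
        self.snp_ids = set(map(str, snp_ids))
        if not self.snp_ids:
            raise ValueError("gold standard is empty")
        if directions is None:
            self.directions: dict[str, str] | None = None
        else:
            self.directions = {str(s): str(d) for s, d in zip(snp_ids, directions)}
            bad = set(self.directions.values()) - {"SR", "SN"}
            if bad:
                raise ValueError(f"directions must be SR or SN, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def is_hit(self, snp_id: str, called_direction: str | None = None) -> bool:
        if snp_id not in self.snp_ids:
            return False
        if self.directions is None or called_direction is None:
            return True
        return self.directions[snp_id] == called_direction


def read_gold_standard(path: str | Path) -> GoldStandard:
    """One-column (snp_id) or two-column (snp_id, direction) TSV, no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        return GoldStandard(df[0].tolist())
    return GoldStandard(df[0].tolist(), df[1].tolist())


def gold_from_truth(table: AlleleCountTable, truth: SimTruth, d: int) -> GoldStandard:
    """Direction-aware gold standard for dataset ``d`` from simulation truth."""
    skewed = np.flatnonzero(truth.b[:, d] | truth.c[:, d])
    if skewed.size == 0:
        raise ValueError(f"no truly skewed SNPs in dataset index {d}")
    ids = [str(table.snp_id[i]) for i in skewed]
    dirs = ["SR" if truth.b[i, d] else "SN" for i in skewed]
    return GoldStandard(ids, dirs)


def tp_curve(ranking: pd.DataFrame, gold: GoldStandard,
             Q: int | None = None) -> np.ndarray:
    """TP(q): number of gold SNPs among the top q of a ranked list, q = 1..Q.

    ``ranking`` needs columns ``snp_id`` and, for direction-aware gold
    standards, ``direction``; rows must already be in rank order.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    ids = ranking["snp_id"].astype(str).to_numpy()
    Q = len(ids) if Q is None else int(Q)
    if not 1 <= Q <= len(ids):
        raise ValueError(f"Q={Q} outside [1, {len(ids)}]")
    if gold.directions is not None and "direction" in ranking.columns:
        dirs = ranking["direction"].to_numpy()
        hits = np.fromiter((gold.is_hit(s, c) for s, c in zip(ids[:Q], dirs[:Q])),
                           dtype=bool, count=Q)
    else:
        hits = np.fromiter((s in gold.snp_ids for s in ids[:Q]), dtype=bool, count=Q)
    return np.cumsum(hits)


def auc_top_n(curve: np.ndarray, n: int = 2000,
              n_gold: int | None = None) -> float:
    """Truncated AUC of a TP curve over the top n ranks, perfect ranking = 1.

    Trapezoid area of TP(q) for q = 0..n (TP(0) = 0) divided by the area of
    the envelope min(q, G) with G = min(n, n_gold).  ``n_gold`` defaults to
    the curve's final value's upper bound (the curve max is a lower bound on
    the gold size; pass the true gold size when the list may not contain all
    gold SNPs).
    """
    curve = np.asarray(curve)
    if n > curve.size:
        raise ValueError(f"n={n} exceeds curve length {curve.size}")
    tp = np.concatenate([[0], curve[:n]])
    area = np.trapezoid(tp)
    G = int(curve[:n].max()) if n_gold is None else min(int(n_gold), n)
    if G == 0:
        raise ValueError("no gold SNPs reachable within the truncation")
    envelope = np.trapezoid(np.minimum(np.arange(n + 1), G))
    return float(area / envelope)


def dauc(auc_joint: float, auc_best_single: float) -> float:
    """Proportional AUC improvement (positive = the joint model wins)."""
    if auc_best_single <= 0 or auc_joint <= 0:
        raise ValueError("AUCs must be positive")
    return (auc_joint - auc_best_single) / auc_best_single


def fdr_calibration(ranking: pd.DataFrame, gold: GoldStandard,
                    max_n: int | None = None) -> pd.DataFrame:
    """Estimated vs true FDR of the top-N list for N = 1..max_n.

    The estimate is the cumulative mean of (1 - P~) (column ``p_tilde`` must
    be present, rows in rank order); the truth is the fraction of the top N
    that are not direction-correct gold SNPs.
    """
    if "p_tilde" not in ranking.columns:
        raise ValueError("ranking must carry a p_tilde column")
    ids = ranking["snp_id"].astype(str).to_numpy()
    max_n = len(ids) if max_n is None else int(max_n)
    est = fdr_estimate(ranking["p_tilde"].to_numpy()[:max_n])
    tp = tp_curve(ranking, gold, Q=max_n)
    N = np.arange(1, max_n + 1)
    true_fdr = 1.0 - tp / N
    return pd.DataFrame({"N": N, "estimated_fdr": est, "true_fdr": true_fdr})


def plot_tp_curves(curves: dict[str, np.ndarray], ax=None, title: str = ""):
    """Optional matplotlib plot of TP(q) curves per method."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for name, curve in curves.items():
        ax.plot(np.arange(1, len(curve) + 1), curve, label=name)
    ax.set_xlabel("rank cutoff q")
    ax.set_ylabel("true positives")
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
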