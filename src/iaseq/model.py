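"""Joint mixture model of allele-specificity across datasets, fitted by MAP-EM.

Each SNP ``i`` carries a latent class label ``a_i`` in ``{0, ..., K}`` drawn
from abundances ``Pi``.  Class 0 is pure background: the SNP is NS in every
dataset.  For a non-background class ``k``, the per-dataset skew indicators
``(b_id, c_id)`` are drawn independently with ``Pr(SR) = v_kd``,
``Pr(SN) = w_kd`` and ``Pr(NS) = 1 - v_kd - w_kd``, so each class is a
probabilistic skew pattern over datasets and the mixture of classes encodes
the correlation of allele-specificity among datasets.  Counts are then
generated by the state kernels f0/f1/f2 (see :mod:`iaseq.kernels`).

Parameters ``(Pi, V, W)`` receive Dirichlet(eta, ..., eta) priors (default
eta = 2, which keeps every MAP update strictly interior) and are estimated at
the posterior mode by EM with the latent ``(a, b, c)`` integrated out.  The
class number K is chosen by BIC.

The statsmodels-style entry point is :class:`IASeqModel`; the functional
pieces (``e_step``, ``m_step``, ``fit_em``, ``select_k``) are exposed for
direct use and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_data import AlleleCountTable
from .kernels import BackgroundParams, dataset_log_likelihoods, estimate_background
from ._em_core import HAVE_NUMBA as _HAVE_FUSED, em_step_fused

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams", "FitReport", "EStepResult",
    "e_step", "m_step", "log_posterior", "fit_em", "select_k",
    "IASeqModel", "IASeqResults", "KSelection",
]


@dataclass(frozen=True)
class ModelParams:
    """Mixture parameters: abundances Pi (K+1,), skew probabilities V, W (K, D)."""

    pi: np.ndarray
    v: np.ndarray
    w: np.ndarray
    eta: float = 2.0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        v = np.atleast_2d(np.asarray(self.v, dtype=float))
        w = np.atleast_2d(np.asarray(self.w, dtype=float))
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", w)
        if v.shape != w.shape or pi.shape[0] != v.shape[0] + 1:
            raise ValueError("inconsistent shapes: need pi (K+1,), v and w (K, D)")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("class abundances must sum to 1")
        if (pi < 0).any():
            raise ValueError("class abundances must be non-negative")
        # boundary values only arise in the eta = 1 (maximum likelihood)
        # limit; the default eta = 2 keeps every component strictly interior
        if (v < 0).any() or (w < 0).any() or (v + w > 1).any():
            raise ValueError("need v_kd >= 0, w_kd >= 0 and v_kd + w_kd <= 1")

    @property
    def K(self) -> int:
        return self.v.shape[0]

    @property
    def D(self) -> int:
        return self.v.shape[1]

    def n_free_parameters(self) -> int:
        """K free abundances plus 2 skew probabilities per (class, dataset)."""
        return self.K + 2 * self.K * self.D


@dataclass
class FitReport:
    """Trajectory and bookkeeping for one EM fit (best restart)."""

    log_posterior_trajectory: list[float]
    n_iter: int
    converged: bool
    seed: int | None
    best_restart: int
    log_likelihood: float
    n_restarts: int = 1
    n_snps_used: int = 0
    n_snps_dropped: int = 0


@dataclass
class EStepResult:
    """Posterior expectations given current parameters.

    gamma : (I, K+1) class posteriors Pr(a_i = k | data).
    tau : (I, D, K, 3) state posteriors Pr(state | a_i = k, data) for the
        non-background classes, state axis ordered (NS, SR, SN).
    log_lik_i : (I,) observed-data log likelihood per SNP.
    """

    gamma: np.ndarray
    tau: np.ndarray
    log_lik_i: np.ndarray

    @property
    def log_likelihood(self) -> float:
        return float(self.log_lik_i.sum())


def _class_mix_logs(logL: np.ndarray, params: ModelParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-(i, d, k) state component logs and their log-sum.

    Returns (comp, M): comp has shape (I, D, K, 3) holding
    log(state prior * L_state); M = logsumexp over the state axis.
    """
    L0 = logL[:, :, 0][:, :, None]
    L1 = logL[:, :, 1][:, :, None]
    L2 = logL[:, :, 2][:, :, None]
    ns = 1.0 - params.v - params.w
    comp = np.empty(logL.shape[:2] + (params.K, 3))
    with np.errstate(divide="ignore"):
        comp[..., 0] = L0 + np.log(ns)[None, :, :].transpose(0, 2, 1)
        comp[..., 1] = L1 + np.log(params.v)[None, :, :].transpose(0, 2, 1)
        comp[..., 2] = L2 + np.log(params.w)[None, :, :].transpose(0, 2, 1)
    mx = comp.max(axis=-1)
    M = mx + np.log(np.exp(comp - mx[..., None]).sum(axis=-1))
    return comp, M


def e_step(logL: np.ndarray, params: ModelParams,
           check_finite: bool = True) -> EStepResult:
    """Posterior class memberships and conditional state posteriors.

    ``logL`` is the ``(I, D, 3)`` array from
    :func:`iaseq.kernels.dataset_log_likelihoods`.
    """
    if check_finite and not np.isfinite(logL).all():
        bad = np.argwhere(~np.isfinite(logL))[0]
        raise FloatingPointError(f"non-finite log likelihood at SNP index {bad[0]}")
    I = logL.shape[0]
    comp, M = _class_mix_logs(logL, params)
    log_joint = np.empty((I, params.K + 1))
    with np.errstate(divide="ignore"):
        log_joint[:, 0] = np.log(params.pi[0]) + logL[:, :, 0].sum(axis=1)
        log_joint[:, 1:] = np.log(params.pi[1:])[None, :] + M.sum(axis=1)
    mx = log_joint.max(axis=1, keepdims=True)
    log_norm = mx[:, 0] + np.log(np.exp(log_joint - mx).sum(axis=1))
    gamma = np.exp(log_joint - log_norm[:, None])
    # exp(comp - M) reuses the max-shifted exponentials from the logsumexp
    comp -= M[..., None]
    tau = np.exp(comp, out=comp)
    return EStepResult(gamma=gamma, tau=tau, log_lik_i=log_norm)


def m_step(estep: EStepResult, eta: float = 2.0) -> ModelParams:
    """MAP parameter updates under Dirichlet(eta) priors."""
    gamma, tau = estep.gamma, estep.tau
    I, K1 = gamma.shape
    K = K1 - 1
    pi = (gamma.sum(axis=0) + eta - 1.0) / (I + K1 * (eta - 1.0))
    g1 = gamma[:, 1:]                                   # (I, K)
    num = np.einsum("ik,idks->kds", g1, tau) + (eta - 1.0)   # (K, D, 3)
    denom = g1.sum(axis=0)[:, None] + 3.0 * (eta - 1.0)      # (K, 1)
    ns = num[..., 0] / denom
    v = num[..., 1] / denom
    w = num[..., 2] / denom
    del ns  # normalization is exact by construction
    return ModelParams(pi=pi, v=v, w=w, eta=eta)


def _log_prior(params: ModelParams) -> float:
    """Dirichlet log prior density at the parameters, up to its constant."""
    if params.eta == 1.0:
        return 0.0
    with np.errstate(divide="ignore"):
        return (params.eta - 1.0) * (
            np.log(params.pi).sum()
            + np.log(params.v).sum() + np.log(params.w).sum()
            + np.log(1.0 - params.v - params.w).sum()
        )


def log_posterior(estep: EStepResult, params: ModelParams) -> float:
    """Observed-data log posterior of (Pi, V, W), up to the Dirichlet constant."""
    return estep.log_likelihood + _log_prior(params)


def _em_iteration(logL: np.ndarray, params: ModelParams, eta: float
                  ) -> tuple[float, ModelParams]:
    """One EM sweep: likelihood at current params plus the updated params.

    Uses the fused compiled kernel when numba is available; otherwise the
    reference e_step/m_step pair (identical arithmetic, more memory traffic).
    """
    if _HAVE_FUSED:
        loglik, pi, v, w = em_step_fused(logL, params.pi, params.v, params.w, eta)
        return loglik, ModelParams(pi=pi, v=v, w=w, eta=eta)
    es = e_step(logL, params, check_finite=False)
    return es.log_likelihood, m_step(es, eta)


def _init_params(K: int, D: int, eta: float, rng: np.random.Generator) -> ModelParams:
    pi = np.concatenate([[0.9], np.full(K, 0.1 / K)])
    v = rng.uniform(0.05, 0.45, size=(K, D))
    w = rng.uniform(0.05, 0.45, size=(K, D))
    return ModelParams(pi=pi, v=v, w=w, eta=eta)


def _canonicalize(params: ModelParams) -> ModelParams:
    """Sort non-background classes by descending total SR probability.

    Mixture labels are unidentifiable; a fixed ordering makes reported
    parameters deterministic and comparable across runs.
    """
    order = np.argsort(-params.v.sum(axis=1), kind="stable")
    pi = np.concatenate([[params.pi[0]], params.pi[1:][order]])
    return ModelParams(pi=pi, v=params.v[order], w=params.w[order], eta=params.eta)


def _em_run(logL: np.ndarray, params: ModelParams, eta: float, max_iter: int,
            tol: float) -> tuple[ModelParams, list[float], bool, float]:
    """Iterate EM from ``params`` until the log-posterior gain drops below tol."""
    if not np.isfinite(logL).all():
        bad = np.argwhere(~np.isfinite(logL))[0]
        raise FloatingPointError(f"non-finite log likelihood at SNP index {bad[0]}")
    trajectory: list[float] = []
    converged = False
    lp_prev = -np.inf
    loglik = -np.inf
    for _ in range(max_iter):
        loglik, new_params = _em_iteration(logL, params, eta)
        lp = loglik + _log_prior(params)
        trajectory.append(lp)
        if np.isfinite(lp_prev) and lp - lp_prev <= tol:
            converged = True
            break
        lp_prev = lp
        params = new_params
    return params, trajectory, converged, loglik


def fit_em(table: AlleleCountTable, background: BackgroundParams, K: int,
           eta: float = 2.0, n_restarts: int = 5, max_iter: int = 2000,
           tol: float = 1e-4, seed: int | None = 0, burnin_iter: int = 100,
           logL: np.ndarray | None = None) -> tuple[ModelParams, FitReport]:
    """MAP-EM fit for a fixed class number K, best of ``n_restarts`` starts.

    Each restart runs a short EM burn-in (``burnin_iter`` iterations); the
    restart with the highest log posterior is then iterated to convergence,
    declared when one EM step improves the log posterior by less than ``tol``
    (absolute, log-posterior units — EM on this model crawls near the mode,
    so a relative criterion stops far too early on large tables).

    SNPs with zero coverage in every sample carry no information and are
    dropped from the fit (logged); identical (seed, inputs) give identical
    output.  ``logL`` may be passed to reuse precomputed kernels.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if logL is None:
        logL = dataset_log_likelihoods(table, background)
    covered = table.covered
    n_dropped = int((~covered).sum())
    if n_dropped:
        logger.info("dropping %d SNP(s) with zero total coverage from the fit",
                    n_dropped)
    logL_fit = logL[covered]
    rng = np.random.default_rng(seed)
    D = logL_fit.shape[1]
    starts = [_init_params(K, D, eta, rng) for _ in range(n_restarts)]
    burn = [_em_run(logL_fit, p, eta, min(burnin_iter, max_iter), tol)
            for p in starts]
    best_r = int(np.argmax([b[1][-1] for b in burn]))
    params, traj, converged, loglik = burn[best_r]
    if not converged and max_iter > len(traj):
        params, traj2, converged, loglik = _em_run(
            logL_fit, params, eta, max_iter - len(traj), tol)
        traj = traj + traj2
    if not converged:
        logger.warning("EM did not converge within %d iterations (K=%d)", max_iter, K)
    report = FitReport(
        log_posterior_trajectory=traj, n_iter=len(traj), converged=converged,
        seed=seed, best_restart=best_r, log_likelihood=loglik,
        n_restarts=n_restarts,
        n_snps_used=int(covered.sum()), n_snps_dropped=n_dropped,
    )
    return _canonicalize(params), report


def select_k(table: AlleleCountTable, background: BackgroundParams,
             k_grid, **fit_kwargs
             ) -> tuple[int, pd.DataFrame, ModelParams, FitReport]:
    """Fit every K in ``k_grid`` and pick the BIC minimizer.

    BIC(K) = -2 * max observed-data log likelihood + (K + 2KD) log(I), with I
    the number of SNPs entering the fit.  Per-K fits are independent, so the
    result does not depend on grid order.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    logL = fit_kwargs.pop("logL", None)
    if logL is None:
        logL = dataset_log_likelihoods(table, background)
    I_used = int(table.covered.sum())
    D = table.D
    rows = []
    fits: dict[int, tuple[ModelParams, FitReport]] = {}
    for K in sorted(k_grid):
        try:
            params, report = fit_em(table, background, K, logL=logL, **fit_kwargs)
        except Exception as exc:  # pragma: no cover - propagation contract
            raise RuntimeError(f"EM fit failed for K={K}") from exc
        p_K = params.n_free_parameters()
        bic = -2.0 * report.log_likelihood + p_K * np.log(I_used)
        rows.append({"K": K, "log_likelihood": report.log_likelihood,
                     "n_parameters": p_K, "bic": bic,
                     "converged": report.converged})
        fits[K] = (params, report)
    bic_table = pd.DataFrame(rows)
    best_K = int(bic_table.loc[bic_table["bic"].idxmin(), "K"])
    params, report = fits[best_K]
    return best_K, bic_table, params, report


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class IASeqModel:
    """Joint allele-specificity model over a multi-dataset count table.

    Parameters
    ----------
    table : AlleleCountTable
    background : BackgroundParams, optional
        Moment-matched per-sample Beta background; estimated from the table
        when omitted.
    min_total : int
        Minimum total read count for a SNP to inform background estimation.

    Examples
    --------
    >>> model = IASeqModel(table)
    >>> res = model.fit(K=2, seed=1)
    >>> res.pi
    array([...])
    >>> print(res.summary())
    """

    def __init__(self, table: AlleleCountTable,
                 background: BackgroundParams | None = None,
                 min_total: int = 5) -> None:
        self.table = table
        self.background = (background if background is not None
                           else estimate_background(table, min_total=min_total))
        self._logL: np.ndarray | None = None

    @classmethod
    def from_files(cls, counts_path, sheet_path, **kwargs) -> "IASeqModel":
        from .count_data import read_count_table
        return cls(read_count_table(counts_path, sheet_path), **kwargs)

    @property
    def log_likelihoods(self) -> np.ndarray:
        """Cached (I, D, 3) per-(SNP, dataset) state log likelihoods."""
        if self._logL is None:
            self._logL = dataset_log_likelihoods(self.table, self.background)
        return self._logL

    def fit(self, K: int = 2, eta: float = 2.0, n_restarts: int = 5,
            max_iter: int = 2000, tol: float = 1e-4, seed: int | None = 0,
            burnin_iter: int = 100) -> "IASeqResults":
        params, report = fit_em(
            self.table, self.background, K, eta=eta, n_restarts=n_restarts,
            max_iter=max_iter, tol=tol, seed=seed, burnin_iter=burnin_iter,
            logL=self.log_likelihoods)
        return IASeqResults(self, params, report)

    def select_k(self, k_grid, **fit_kwargs) -> "KSelection":
        best_K, bic_table, params, report = select_k(
            self.table, self.background, k_grid, logL=self.log_likelihoods,
            **fit_kwargs)
        return KSelection(best_K, bic_table, IASeqResults(self, params, report))


@dataclass
class KSelection:
    """Outcome of BIC-based class-number selection."""

    best_K: int
    bic_table: pd.DataFrame
    results: "IASeqResults"


class IASeqResults:
    """Fitted joint model: parameter estimates, posteriors, rankings."""

    def __init__(self, model: IASeqModel, params: ModelParams,
                 report: FitReport) -> None:
        self.model = model
        self.params = params
        self.report = report
        self._posterior = None

    # parameter views ------------------------------------------------------
    @property
    def pi(self) -> np.ndarray:
        return self.params.pi

    @property
    def v(self) -> np.ndarray:
        return self.params.v

    @property
    def w(self) -> np.ndarray:
        return self.params.w

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def bic(self) -> float:
        I_used = self.report.n_snps_used
        return float(-2.0 * self.report.log_likelihood
                     + self.params.n_free_parameters() * np.log(I_used))

    # inference ------------------------------------------------------------
    @property
    def posterior(self):
        """Lazy :class:`iaseq.inference.PosteriorSummary` for all SNPs."""
        if self._posterior is None:
            from .inference import posterior_skew
            self._posterior = posterior_skew(
                self.model.log_likelihoods, self.params,
                snp_id=self.model.table.snp_id,
                datasets=self.model.table.datasets)
        return self._posterior

    def rank(self, dataset: str | int | None = None) -> pd.DataFrame:
        from .inference import rank_statistic
        return rank_statistic(self.posterior, dataset=dataset)

    def call_classes(self, cutoff: float = 0.9) -> np.ndarray:
        from .inference import call_class
        return call_class(self.posterior, cutoff=cutoff)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Joint allele-specificity mixture model (MAP-EM fit)",
            "=" * 55,
            f"SNPs used: {self.report.n_snps_used}"
            + (f" ({self.report.n_snps_dropped} zero-coverage dropped)"
               if self.report.n_snps_dropped else ""),
            f"Datasets: {p.D}    Classes (non-background): {p.K}",
            f"eta: {p.eta}    restarts: {self.report.n_restarts}"
            f"    converged: {self.report.converged}"
            f" in {self.report.n_iter} iterations",
            f"log posterior: {self.report.log_posterior_trajectory[-1]:.4f}"
            f"    BIC: {self.bic:.4f}",
            "",
            "Class abundances Pi:",
            "  " + "  ".join(f"Pi_{k}={pk:.4f}" for k, pk in enumerate(p.pi)),
            "",
            "Skew probabilities (rows: classes, columns: datasets):",
        ]
        datasets = self.model.table.datasets
        header = "          " + " ".join(f"{d[:9]:>9}" for d in datasets)
        lines.append(header)
        for k in range(p.K):
            lines.append(f"  V[{k + 1}]   " + " ".join(f"{x:9.3f}" for x in p.v[k]))
            lines.append(f"  W[{k + 1}]   " + " ".join(f"{x:9.3f}" for x in p.w[k]))
        return "\n".join(lines)

    def to_metadata(self) -> dict:
        return {
            "K": self.K,
            "eta": self.params.eta,
            "seed": self.report.seed,
            "converged": self.report.converged,
            "n_iter": self.report.n_iter,
            "n_restarts": self.report.n_restarts,
            "log_likelihood": self.report.log_likelihood,
            "bic": self.bic,
            "pi": self.pi.tolist(),
            "v": self.v.tolist(),
            "w": self.w.tolist(),
        }
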