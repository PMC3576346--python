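"""Synthetic allelic count data with known skew structure.

The generator follows the model's own data-generating process: a class label
per SNP from abundances Pi; per-dataset skew indicators (b, c) from the
class's (v_kd, w_kd); a reference-read probability per sample drawn from the
background Beta (NS), Uniform[p0, 1] (SR) or Uniform[0, p0] (SN); and a
binomial reference count given a total coverage drawn from a zero-inflated
negative binomial.  Coverage defaults emulate the sparsity of ChIP-seq reads
at heterozygote SNPs (mean 0.64 reads per SNP per sample).

Two benchmark presets are provided.  Scenario 1: background 90% plus two
mirror-image classes (5% each) skewed in the first 75% of datasets.
Scenario 2: background 90% plus four classes (2.5% each) — the scenario-1
pair plus a pair that mixes SR in the last half of datasets with SN in the
first quarter, and its mirror.  Both presets scale I and D proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_data import AlleleCountTable, make_table
from .kernels import BackgroundParams

__all__ = ["ClassSpec", "SimConfig", "SimTruth", "generate",
           "scenario1", "scenario2"]

#: default coverage model: mean reads per het SNP per sample and NB dispersion
DEFAULT_COVERAGE_MEAN = 0.64
DEFAULT_COVERAGE_DISPERSION = 0.5


@dataclass(frozen=True)
class ClassSpec:
    """One non-background mixture class: abundance and per-dataset skew probs."""

    proportion: float
    v: np.ndarray  # (D,) Pr(SR) per dataset
    w: np.ndarray  # (D,) Pr(SN) per dataset

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", w)
        if v.shape != w.shape:
            raise ValueError("v and w must have the same length D")
        if (v < 0).any() or (w < 0).any() or (v + w > 1).any():
            raise ValueError("need v >= 0, w >= 0, v + w <= 1 per dataset")
        if not 0 < self.proportion < 1:
            raise ValueError("class proportion must be in (0, 1)")


@dataclass
class SimConfig:
    """Full description of one simulated study."""

    I: int
    D: int
    classes: list[ClassSpec]
    replicates: int | list[int] = 2
    coverage_mean: float = DEFAULT_COVERAGE_MEAN
    coverage_dispersion: float = DEFAULT_COVERAGE_DISPERSION
    zero_inflation: float = 0.0
    background: BackgroundParams | None = None
    deterministic_counts: bool = False
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.I < 1 or self.D < 1:
            raise ValueError("need I >= 1 and D >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero inflation must be in [0, 1)")
        total = sum(c.proportion for c in self.classes)
        if total >= 1:
            raise ValueError("non-background proportions must sum to < 1")
        for c in self.classes:
            if c.v.shape[0] != self.D:
                raise ValueError("class skew vectors must have length D")

    @property
    def replicate_counts(self) -> list[int]:
        if isinstance(self.replicates, int):
            return [self.replicates] * self.D
        if len(self.replicates) != self.D:
            raise ValueError("replicates list must have length D")
        return list(self.replicates)

    @property
    def pi(self) -> np.ndarray:
        props = [c.proportion for c in self.classes]
        return np.concatenate([[1.0 - sum(props)], props])


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    a: np.ndarray            # (I,) class labels, 0 = background
    b: np.ndarray            # (I, D) SR indicators
    c: np.ndarray            # (I, D) SN indicators
    p: np.ndarray            # (I, S) drawn reference-read probabilities
    background: BackgroundParams

    def gold_standard(self, d: int) -> dict[str, str]:
        """Integer SNP index -> true direction for dataset d (skewed SNPs only).

        :func:`iaseq.evaluate.gold_from_truth` converts this to an
        id-keyed gold standard for a generated table.
        """
        out = {}
        for i in np.flatnonzero(self.b[:, d] | self.c[:, d]):
            out[int(i)] = "SR" if self.b[i, d] else "SN"
        return out


def _sample_coverage(rng: np.random.Generator, size, mean: float,
                     dispersion: float, zero_inflation: float) -> np.ndarray:
    """Zero-inflated negative binomial totals (size r = dispersion)."""
    r = dispersion
    p = r / (r + mean)
    n = rng.negative_binomial(r, p, size=size)
    if zero_inflation > 0:
        n = np.where(rng.random(size=size) < zero_inflation, 0, n)
    return n


def generate(config: SimConfig,
             rng: np.random.Generator | None = None
             ) -> tuple[AlleleCountTable, SimTruth]:
    """Draw one dataset from the generative model, with full ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    I, D = config.I, config.D
    reps = config.replicate_counts
    S = sum(reps)
    K = len(config.classes)

    if config.background is not None:
        bg = config.background
        if bg.alpha.shape[0] != S:
            raise ValueError("background parameters must cover every sample")
    else:
        conc = rng.uniform(10.0, 40.0, size=S)  # alpha = beta: symmetric background
        bg = BackgroundParams(alpha=conc, beta=conc)
    p0 = bg.p0

    # class labels
    pi = config.pi
    if config.deterministic_counts:
        counts = [int(np.floor(I * c.proportion)) for c in config.classes]
        counts = [I - sum(counts)] + counts
        a = np.repeat(np.arange(K + 1), counts)
    else:
        a = rng.choice(K + 1, size=I, p=pi)

    # skew indicators
    b = np.zeros((I, D), dtype=np.int8)
    c = np.zeros((I, D), dtype=np.int8)
    for k, cls in enumerate(config.classes, start=1):
        idx = np.flatnonzero(a == k)
        if idx.size == 0:
            continue
        u = rng.random(size=(idx.size, D))
        b[idx] = (u < cls.v[None, :]).astype(np.int8)
        c[idx] = ((u >= cls.v[None, :]) & (u < (cls.v + cls.w)[None, :])).astype(np.int8)

    # coverage, skew probabilities and counts per sample
    n = _sample_coverage(rng, (I, S), config.coverage_mean,
                         config.coverage_dispersion, config.zero_inflation)
    p = np.empty((I, S))
    s = 0
    for d in range(D):
        sr = b[:, d] == 1
        sn = c[:, d] == 1
        ns = ~(sr | sn)
        for _ in range(reps[d]):
            p[ns, s] = rng.beta(bg.alpha[s], bg.beta[s], size=ns.sum())
            p[sr, s] = rng.uniform(p0[s], 1.0, size=sr.sum())
            p[sn, s] = rng.uniform(0.0, p0[s], size=sn.sum())
            s += 1
    x = rng.binomial(n, p)

    table = make_table(x, n, datasets=[f"ds{d + 1}" for d in range(D)],
                       replicate_counts=reps)
    truth = SimTruth(a=a, b=b, c=c, p=p, background=bg)
    return table, truth


def _hard_class(I_prop: float, D: int, sr_block: np.ndarray,
                sn_block: np.ndarray) -> ClassSpec:
    """A near-deterministic skew pattern (probabilities 1 inside the blocks)."""
    v = np.zeros(D)
    w = np.zeros(D)
    v[sr_block] = 1.0
    w[sn_block] = 1.0
    return ClassSpec(proportion=I_prop, v=v, w=w)


def scenario1(I: int = 94519, D: int = 40, seed: int | None = 0,
              replicates: int | list[int] = 2,
              deterministic_counts: bool = False,
              **coverage_kwargs) -> tuple[AlleleCountTable, SimTruth, SimConfig]:
    """Background 90% plus two mirror classes skewed in the first 75% of datasets.

    At full scale (I=94519, D=40) the deterministic-count option gives class
    sizes (85069, 4725, 4725) with skew in datasets 1-30.
    """
    block = np.arange(int(np.floor(0.75 * D)))
    classes = [
        _hard_class(0.05, D, sr_block=block, sn_block=np.array([], dtype=int)),
        _hard_class(0.05, D, sr_block=np.array([], dtype=int), sn_block=block),
    ]
    config = SimConfig(I=I, D=D, classes=classes, replicates=replicates,
                       deterministic_counts=deterministic_counts, seed=seed,
                       **coverage_kwargs)
    table, truth = generate(config)
    return table, truth, config


def scenario2(I: int = 94519, D: int = 40, seed: int | None = 0,
              replicates: int | list[int] = 2,
              deterministic_counts: bool = False,
              **coverage_kwargs) -> tuple[AlleleCountTable, SimTruth, SimConfig]:
    """Background 90% plus four classes of 2.5% each.

    Classes 1 and 2 are the scenario-1 pair.  Class 3 is SR in the last half
    of datasets and SN in the first quarter; class 4 is its mirror.  At full
    scale each skewed class has 2362 SNPs with the deterministic-count option.
    """
    first34 = np.arange(int(np.floor(0.75 * D)))
    last_half = np.arange(D - int(np.ceil(0.5 * D)), D)
    first_quarter = np.arange(int(np.floor(0.25 * D)))
    empty = np.array([], dtype=int)
    classes = [
        _hard_class(0.025, D, sr_block=first34, sn_block=empty),
        _hard_class(0.025, D, sr_block=empty, sn_block=first34),
        _hard_class(0.025, D, sr_block=last_half, sn_block=first_quarter),
        _hard_class(0.025, D, sr_block=first_quarter, sn_block=last_half),
    ]
    config = SimConfig(I=I, D=D, classes=classes, replicates=replicates,
                       deterministic_counts=deterministic_counts, seed=seed,
                       **coverage_kwargs)
    table, truth = generate(config)
    return table, truth, config
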