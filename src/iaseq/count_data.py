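"""Allelic read-count tables and result I/O.

The central container is :class:`AlleleCountTable`: for every heterozygote SNP
``i``, dataset ``d`` and replicate ``j`` it stores the reference-allele read
count ``x_idj`` and the total read count ``n_idj``.  Replicate structure is
ragged (datasets may have different replicate counts), so counts are held as
``(I, S)`` matrices over flat sample columns together with a sample ->
(dataset, replicate) map.

On-disk convention: a TSV with columns ``snp_id, chrom, pos, ref, alt`` and
then, per sample, ``<sample>.ref`` and ``<sample>.total``; plus a sample sheet
TSV with columns ``sample_id, dataset_id, replicate``.  Coordinates are 1-based
(VCF convention) and gzip is handled transparently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleCountTable",
    "SampleSheet",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "write_results",
]

_META_COLS = ["snp_id", "chrom", "pos", "ref", "alt"]


class CountTableError(ValueError):
    """Malformed count table, sample sheet, or invariant violation."""


@dataclass(frozen=True)
class SampleSheet:
    """Mapping of sample columns to (dataset, replicate).

    Rows are kept in file order; samples belonging to the same dataset are
    grouped together when the table is assembled, and the dataset order of the
    sheet defines the dataset order everywhere downstream.
    """

    sample_id: list[str]
    dataset_id: list[str]
    replicate: list[int]

    def __post_init__(self) -> None:
        if len(set(self.sample_id)) != len(self.sample_id):
            raise CountTableError("duplicate sample_id in sample sheet")
        pairs = list(zip(self.dataset_id, self.replicate))
        if len(set(pairs)) != len(pairs):
            raise CountTableError("duplicate (dataset_id, replicate) pair in sample sheet")
        if any(r < 1 for r in self.replicate):
            raise CountTableError("replicate numbers must be positive integers")

    @property
    def datasets(self) -> list[str]:
        """Dataset ids in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.dataset_id:
            seen.setdefault(d)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "dataset_id": self.dataset_id,
             "replicate": self.replicate}
        )


@dataclass
class AlleleCountTable:
    """Reference / total allelic read counts for I SNPs across D datasets.

    Parameters
    ----------
    snp_id, chrom, pos
        Per-SNP metadata; ``pos`` is 1-based.
    ref_allele, nonref_allele
        Optional single-character nucleotides.
    x, n
        ``(I, S)`` integer matrices of reference-allele and total read counts
        over flat sample columns.
    sample_id
        Column labels, length S, grouped by dataset.
    datasets
        Ordered dataset ids, length D.
    sample_dataset
        Length-S integer array mapping each sample column to its dataset index.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    x: np.ndarray
    n: np.ndarray
    sample_id: list[str]
    datasets: list[str]
    sample_dataset: np.ndarray
    ref_allele: np.ndarray | None = None
    nonref_allele: np.ndarray | None = None
    _dataset_slices: list[slice] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.sample_dataset = np.asarray(self.sample_dataset, dtype=np.int64)
        self._validate()
        # contiguous slices per dataset; samples must be grouped by dataset
        self._dataset_slices = []
        start = 0
        for d in range(self.D):
            cols = np.flatnonzero(self.sample_dataset == d)
            if cols.size == 0:
                raise CountTableError(f"dataset {self.datasets[d]!r} has no samples")
            if not np.array_equal(cols, np.arange(start, start + cols.size)):
                raise CountTableError("sample columns must be grouped by dataset")
            self._dataset_slices.append(slice(start, start + cols.size))
            start += cols.size

    def _validate(self) -> None:
        I, S = self.x.shape
        if I < 1 or S < 1:
            raise CountTableError("count table must have at least one SNP and one sample")
        if self.n.shape != (I, S):
            raise CountTableError("x and n shapes differ")
        if len(self.sample_id) != S or self.sample_dataset.shape != (S,):
            raise CountTableError("sample metadata length does not match count columns")
        if len(set(map(str, self.snp_id))) != I:
            raise CountTableError("snp_id values must be unique")
        if (self.n < 0).any():
            bad = np.argwhere(self.n < 0)[0]
            raise CountTableError(
                f"negative total count at SNP {self.snp_id[bad[0]]!r}, "
                f"sample {self.sample_id[bad[1]]!r}"
            )
        over = self.x > self.n
        if over.any():
            bad = np.argwhere(over)[0]
            raise CountTableError(
                f"x > n at SNP {self.snp_id[bad[0]]!r}, sample {self.sample_id[bad[1]]!r}"
            )
        if (self.x < 0).any():
            raise CountTableError("negative reference-allele count")

    # -- structure ---------------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.x.shape[0]

    @property
    def S(self) -> int:
        return self.x.shape[1]

    @property
    def D(self) -> int:
        return len(self.datasets)

    @property
    def replicate_counts(self) -> np.ndarray:
        """J_d: number of replicate samples per dataset."""
        return np.bincount(self.sample_dataset, minlength=self.D)

    def dataset_slice(self, d: int) -> slice:
        """Column slice of dataset ``d`` in the flat sample axis."""
        return self._dataset_slices[d]

    @property
    def y(self) -> np.ndarray:
        """Non-reference allele counts, y = n - x."""
        return self.n - self.x

    @property
    def covered(self) -> np.ndarray:
        """Boolean mask of SNPs with at least one read in any sample."""
        return self.n.sum(axis=1) > 0

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-pooled counts (x_id, n_id), each ``(I, D)``."""
        x_id = np.stack([self.x[:, s].sum(axis=1) for s in self._dataset_slices], axis=1)
        n_id = np.stack([self.n[:, s].sum(axis=1) for s in self._dataset_slices], axis=1)
        return x_id, n_id

    def subset_snps(self, mask: np.ndarray) -> "AlleleCountTable":
        return AlleleCountTable(
            snp_id=self.snp_id[mask], chrom=self.chrom[mask], pos=self.pos[mask],
            x=self.x[mask], n=self.n[mask],
            sample_id=list(self.sample_id), datasets=list(self.datasets),
            sample_dataset=self.sample_dataset.copy(),
            ref_allele=None if self.ref_allele is None else np.asarray(self.ref_allele)[mask],
            nonref_allele=None if self.nonref_allele is None else np.asarray(self.nonref_allele)[mask],
        )

    def restrict_dataset(self, d: int) -> "AlleleCountTable":
        """Single-dataset view (used by the single-dataset EM baseline)."""
        s = self._dataset_slices[d]
        return AlleleCountTable(
            snp_id=self.snp_id, chrom=self.chrom, pos=self.pos,
            x=self.x[:, s], n=self.n[:, s],
            sample_id=list(self.sample_id[s.start:s.stop]),
            datasets=[self.datasets[d]],
            sample_dataset=np.zeros(s.stop - s.start, dtype=np.int64),
            ref_allele=self.ref_allele, nonref_allele=self.nonref_allele,
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "dataset_id", "replicate"):
        if col not in df.columns:
            raise CountTableError(f"sample sheet is missing column {col!r}")
    return SampleSheet(
        sample_id=df["sample_id"].tolist(),
        dataset_id=df["dataset_id"].tolist(),
        replicate=[int(r) for r in df["replicate"]],
    )


def read_count_table(counts_path: str | Path, sheet_path: str | Path) -> AlleleCountTable:
    """Read a counts TSV plus sample sheet into a validated table.

    Samples are grouped by dataset in sheet order; within a dataset they follow
    the sheet's replicate order.  A sample column missing for a declared
    replicate is an error, as is a count column whose sample is absent from
    the sheet.
    """
    sheet = read_sample_sheet(sheet_path)
    df = pd.read_csv(counts_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise CountTableError(f"counts file is missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    samples_in_file = []
    for c in sample_cols:
        if not (c.endswith(".ref") or c.endswith(".total")):
            raise CountTableError(f"unrecognized counts column {c!r}")
        samples_in_file.append(c.rsplit(".", 1)[0])
    file_samples = set(samples_in_file)
    declared = set(sheet.sample_id)
    extra = file_samples - declared
    if extra:
        raise CountTableError(f"sample(s) {sorted(extra)} in counts file absent from sheet")
    missing = declared - file_samples
    if missing:
        raise CountTableError(f"declared sample(s) {sorted(missing)} missing from counts file")

    # order samples: datasets in sheet order, replicates in sheet order
    datasets = sheet.datasets
    ordered, sample_dataset = [], []
    for d_idx, d in enumerate(datasets):
        for s, ds in zip(sheet.sample_id, sheet.dataset_id):
            if ds == d:
                ordered.append(s)
                sample_dataset.append(d_idx)
    for s in ordered:
        for suffix in (".ref", ".total"):
            col = s + suffix
            if col not in df.columns:
                raise CountTableError(f"counts file is missing column {col!r}")
            if df[col].isna().any():
                raise CountTableError(f"missing value in column {col!r}")
    x = df[[s + ".ref" for s in ordered]].to_numpy(dtype=np.int64)
    n = df[[s + ".total" for s in ordered]].to_numpy(dtype=np.int64)
    table = AlleleCountTable(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        x=x, n=n,
        sample_id=ordered, datasets=datasets,
        sample_dataset=np.asarray(sample_dataset),
        ref_allele=df["ref"].to_numpy(dtype=object),
        nonref_allele=df["alt"].to_numpy(dtype=object),
    )
    n_flagged = int((~table.covered).sum())
    if n_flagged:
        logger.info("%d SNP(s) have zero coverage in every sample (retained, flagged)",
                    n_flagged)
    return table


def write_count_table(table: AlleleCountTable, counts_path: str | Path,
                      sheet_path: str | Path | None = None) -> None:
    """Write a table (and optionally its sample sheet) back to TSV."""
    ref = table.ref_allele if table.ref_allele is not None else ["N"] * table.I
    alt = table.nonref_allele if table.nonref_allele is not None else ["N"] * table.I
    out = pd.DataFrame({
        "snp_id": table.snp_id, "chrom": table.chrom, "pos": table.pos,
        "ref": ref, "alt": alt,
    })
    for j, s in enumerate(table.sample_id):
        out[s + ".ref"] = table.x[:, j]
        out[s + ".total"] = table.n[:, j]
    out.to_csv(counts_path, sep="\t", index=False)
    if sheet_path is not None:
        reps: dict[str, int] = {}
        rows = []
        for j, s in enumerate(table.sample_id):
            d = table.datasets[table.sample_dataset[j]]
            reps[d] = reps.get(d, 0) + 1
            rows.append((s, d, reps[d]))
        pd.DataFrame(rows, columns=["sample_id", "dataset_id", "replicate"]).to_csv(
            sheet_path, sep="\t", index=False)


def write_results(ranked: dict[str, pd.DataFrame], out_prefix: str | Path,
                  metadata: dict | None = None) -> list[Path]:
    """Write per-dataset ranked result tables plus a combined table.

    ``ranked`` maps dataset id -> DataFrame with columns ``snp_id, dataset_id,
    pr_sr, pr_sn, p_tilde, direction, fdr``.  Rows are (re-)sorted by
    descending ``p_tilde`` with ties broken by ``snp_id``.  A JSON sidecar
    stores run metadata (model size, seed, convergence) when supplied.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    required = ["snp_id", "dataset_id", "pr_sr", "pr_sn", "p_tilde", "direction", "fdr"]
    paths = []
    combined = []
    for d, df in ranked.items():
        for col in required:
            if col not in df.columns:
                raise CountTableError(f"result records missing column {col!r}")
        df = df.sort_values(["p_tilde", "snp_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        p = Path(f"{out_prefix}.{d}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
        combined.append(df)
    comb = pd.concat(combined, ignore_index=True)
    p = Path(f"{out_prefix}.combined.tsv")
    comb.to_csv(p, sep="\t", index=False)
    paths.append(p)
    if metadata is not None:
        mp = Path(f"{out_prefix}.meta.json")
        mp.write_text(json.dumps(metadata, indent=2, default=float))
        paths.append(mp)
    return paths


def make_table(x: np.ndarray, n: np.ndarray, datasets: Sequence[str],
               replicate_counts: Sequence[int],
               snp_id: Sequence[str] | None = None,
               chrom: Sequence[str] | None = None,
               pos: Sequence[int] | None = None) -> AlleleCountTable:
    """Convenience constructor from raw ``(I, S)`` count matrices."""
    x = np.asarray(x)
    I = x.shape[0]
    if snp_id is None:
        snp_id = [f"snp{str(i).zfill(len(str(max(I - 1, 1))))}" for i in range(I)]
    if chrom is None:
        chrom = ["chr1"] * I
    if pos is None:
        pos = np.arange(1, I + 1)
    sample_id, sample_dataset = [], []
    for d_idx, (d, J) in enumerate(zip(datasets, replicate_counts)):
        for j in range(J):
            sample_id.append(f"{d}_rep{j + 1}")
            sample_dataset.append(d_idx)
    return AlleleCountTable(
        snp_id=np.asarray(snp_id, dtype=object), chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos), x=x, n=np.asarray(n),
        sample_id=sample_id, datasets=list(datasets),
        sample_dataset=np.asarray(sample_dataset),
    )
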