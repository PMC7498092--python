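"""Shared in-memory containers for the eQTL pipeline.

All containers keep a single sample ordering; every stage that combines
genotypes, expression, covariates and kinship first aligns on
``sample_ids`` and refuses to proceed on a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLS = ["snp_id", "chrom", "pos"]
GENE_COLS = ["gene_id", "chrom", "start", "end"]


@dataclass
class GenotypeTable:
    """Dosage matrix (SNPs x samples, values in {0,1,2}) plus SNP map.

    Dosage counts copies of the minor allele: 0 = homozygote major,
    1 = heterozygote, 2 = homozygote minor.
    """

    snps: pd.DataFrame  # columns: snp_id, chrom, pos (1-based bp)
    dosages: np.ndarray  # shape (n_snps, n_samples), int8/float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.snps), len(self.sample_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage values must be in {{0,1,2}}; found "
                f"{self.dosages[i, j]!r} at SNP {self.snps['snp_id'].iloc[i]}, "
                f"sample {self.sample_ids[j]} (missing genotypes are not supported)"
            )
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        return GenotypeTable(
            snps=self.snps.iloc[keep].reset_index(drop=True)
            if keep.dtype != bool
            else self.snps.loc[keep].reset_index(drop=True),
            dosages=self.dosages[keep],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class CountMatrix:
    """Raw RNA-seq gene counts (genes x samples) with gene coordinates."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end (1-based inclusive)
    counts: np.ndarray  # shape (n_genes, n_samples), nonnegative integers
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        genes = self.genes.loc[keep] if keep.dtype == bool else self.genes.iloc[keep]
        return CountMatrix(
            genes=genes.reset_index(drop=True),
            counts=self.counts[keep],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class NormalizedExpression:
    """log2-CPM expression after TMM scaling.

    ``effective_lib_size`` = raw library size x TMM factor; the TMM factors
    themselves have geometric mean 1 across samples.
    """

    genes: pd.DataFrame
    values: np.ndarray  # shape (n_genes, n_samples), log2 scale
    sample_ids: list[str]
    tmm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]
    effective_lib_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class StudyDesign:
    """Covariate design matrix with intercept, breed/batch indicators and
    numeric covariates (RIN, age in days)."""

    matrix: np.ndarray  # shape (n_samples, k), full column rank
    columns: list[str]
    sample_ids: list[str]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def build_design(covariates: pd.DataFrame, sample_ids: list[str] | None = None,
                 factors: tuple[str, ...] = ("breed", "batch"),
                 numeric: tuple[str, ...] = ("rin", "age_days")) -> StudyDesign:
    """Expand a covariate table into a full-rank design matrix.

    Factor columns are expanded to indicators dropping the first (reference)
    level; numeric columns enter as-is; an intercept column leads.
    """
    if sample_ids is None:
        sample_ids = [str(s) for s in covariates["sample_id"]]
    cov = covariates.set_index("sample_id").loc[sample_ids]
    cols: list[np.ndarray] = [np.ones(len(cov))]
    names = ["intercept"]
    for f in factors:
        if f not in cov.columns:
            continue
        levels = sorted(cov[f].astype(str).unique())
        for lev in levels[1:]:
            cols.append((cov[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    for c in numeric:
        if c not in cov.columns:
            continue
        cols.append(cov[c].to_numpy(float))
        names.append(c)
    mat = np.column_stack(cols)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]} "
            f"columns: {names})"
        )
    return StudyDesign(matrix=mat, columns=names, sample_ids=list(sample_ids))


def check_sample_alignment(*objs) -> list[str]:
    """Assert all inputs share the same ordered sample ids; return them."""
    ids = None
    for o in objs:
        cur = list(o.sample_ids)
        if ids is None:
            ids = cur
        elif cur != ids:
            for a, b in zip(ids, cur):
                if a != b:
                    raise ValueError(
                        f"sample misalignment: expected {a!r}, got {b!r}"
                    )
            raise ValueError(
                f"sample misalignment: lengths differ ({len(ids)} vs {len(cur)})"
            )
    return ids or []
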