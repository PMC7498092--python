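"""SNP quality control: minor-allele recoding, MAF filtering and linear
LD-block grouping with tag-SNP selection.

The LD pass walks each chromosome left to right; the current block absorbs
the next SNP only if its squared Pearson correlation with EVERY SNP already
in the block meets the threshold, otherwise a new block starts. One tag SNP
(the first member by position) represents each block downstream, shrinking
the scan's multiple-testing burden without losing distinct genetic signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    maf_min: float = 0.3
    ld_r2_min: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 < self.ld_r2_min <= 1.0:
            raise ValueError(f"ld_r2_min must be in (0, 1], got {self.ld_r2_min}")


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one dosage vector: min(f, 1-f),
    f = sum(dosages) / (2 n)."""
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def recode_minor(gt: GenotypeTable) -> GenotypeTable:
    """Flip sites where dosage counts the major allele so 2 = homozygote
    minor everywhere (allele frequency > 0.5 becomes 1 - f)."""
    freq = gt.dosages.sum(axis=1) / (2.0 * gt.n_samples)
    flip = freq > 0.5
    dos = gt.dosages.copy()
    dos[flip] = 2 - dos[flip]
    return GenotypeTable(snps=gt.snps.copy(), dosages=dos,
                         sample_ids=list(gt.sample_ids))


def filter_maf(gt: GenotypeTable, thr: QcThresholds) -> GenotypeTable:
    """Retain SNPs with MAF >= maf_min (boundary inclusive), order preserved."""
    mafs = np.array([compute_maf(gt.dosages[i]) for i in range(gt.n_snps)])
    keep = mafs >= thr.maf_min
    log.info("MAF filter (>= %.3g): retained %d of %d SNPs (removed %d)",
             thr.maf_min, int(keep.sum()), gt.n_snps, int((~keep).sum()))
    return gt.subset(keep)


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape != d2.shape or d1.size < 2:
        raise ValueError("dosage vectors must have equal length >= 2")
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError("monomorphic SNP: LD r^2 undefined for a constant vector")
    r = np.corrcoef(d1, d2)[0, 1]
    return float(r * r)


def group_ld_blocks(gt: GenotypeTable, thr: QcThresholds
                    ) -> tuple[pd.DataFrame, GenotypeTable]:
    """Single left-to-right pass per chromosome grouping SNPs into blocks
    where every pair has r^2 >= ld_r2_min; returns (block table, tag-SNP
    reduced GenotypeTable).

    Blocks never span chromosomes and members are contiguous in position
    order. The tag is the first member by position.
    """
    snps = gt.snps.reset_index(drop=True)
    blocks: list[dict] = []
    tag_rows: list[int] = []
    block_id = 0
    for chrom in snps["chrom"].drop_duplicates():
        rows = snps.index[snps["chrom"] == chrom].to_numpy()
        rows = rows[np.argsort(snps.loc[rows, "pos"].to_numpy(), kind="stable")]
        members: list[int] = []
        for i in rows:
            ok = bool(members) and all(
                ld_r2(gt.dosages[j], gt.dosages[i]) >= thr.ld_r2_min
                for j in members)
            if not ok:
                if members:
                    blocks.append(_block_row(block_id, chrom, snps, members))
                    tag_rows.append(members[0])
                    block_id += 1
                members = [i]
            else:
                members.append(i)
        if members:
            blocks.append(_block_row(block_id, chrom, snps, members))
            tag_rows.append(members[0])
            block_id += 1
    block_df = pd.DataFrame(blocks,
                            columns=["block_id", "chrom", "tag_snp_id",
                                     "n_members", "member_snp_ids"])
    reduced = gt.subset(np.array(sorted(tag_rows), dtype=int))
    log.info("LD grouping (r^2 >= %.3g): %d SNPs -> %d blocks/tags",
             thr.ld_r2_min, gt.n_snps, len(block_df))
    return block_df, reduced


def _block_row(block_id: int, chrom, snps: pd.DataFrame,
               members: list[int]) -> dict:
    ids = snps.loc[members, "snp_id"].tolist()
    return {"block_id": block_id, "chrom": chrom, "tag_snp_id": ids[0],
            "n_members": len(ids), "member_snp_ids": ",".join(ids)}


def run_qc(gt: GenotypeTable, thr: QcThresholds | None = None
           ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Full QC: minor-allele recoding, MAF filter, LD-block tagging.

    Returns (tag-SNP genotype table, block table).
    """
    thr = thr or QcThresholds()
    gt = recode_minor(gt)
    gt = filter_maf(gt, thr)
    block_df, reduced = group_ld_blocks(gt, thr)
    return reduced, block_df
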