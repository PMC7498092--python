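"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV/CSV (gzip-capable via pandas' transparent compression) so
intermediate artifacts stay diffable. Genotypes can also be read from a
minimal biallelic VCF (GT field, no missing calls).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GenotypeTable


# ---------------------------------------------------------------- genotypes

def write_genotypes(gt: GenotypeTable, path: str) -> None:
    """Rows = SNPs: snp_id, chrom, pos, then one dosage column per sample."""
    df = gt.snps.copy()
    for j, s in enumerate(gt.sample_ids):
        df[s] = gt.dosages[:, j].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    meta = df[["snp_id", "chrom", "pos"]].copy()
    sample_ids = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    dos = df[sample_ids].to_numpy()
    if not np.isin(dos, (0, 1, 2)).all():
        bad = dos[~np.isin(dos, (0, 1, 2))][0]
        raise ValueError(
            f"genotype file {path} contains dosage {bad!r}; only 0/1/2 are "
            "supported (no missing genotypes)"
        )
    meta["chrom"] = meta["chrom"].astype(str)
    return GenotypeTable(snps=meta, dosages=dos.astype(np.int8),
                         sample_ids=sample_ids)


def read_vcf_genotypes(path: str) -> GenotypeTable:
    """Read a biallelic VCF with complete GT fields into minor-allele dosages.

    Dosages are recoded per site so that they count the MINOR allele
    (0 = homozygote major), regardless of which allele is REF.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"site {var.CHROM}:{var.POS} is not biallelic (ALT={var.ALT})"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = np.asarray(var.gt_types)
        if (g == 2).any():
            raise ValueError(
                f"missing genotype at {var.CHROM}:{var.POS}; missing calls "
                "are not supported"
            )
        d = np.where(g == 3, 2, g).astype(np.int8)
        if d.mean() > 1.0:  # ALT is the major allele: flip to count minor
            d = (2 - d).astype(np.int8)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS))
        dosages.append(d)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    return GenotypeTable(snps=snps, dosages=np.array(dosages),
                         sample_ids=sample_ids)


# ------------------------------------------------------------------ counts

def write_counts(cm: CountMatrix, path: str) -> None:
    df = cm.genes.copy()
    for j, s in enumerate(cm.sample_ids):
        df[s] = cm.counts[:, j].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = df[["gene_id", "chrom", "start", "end"]].copy()
    meta["chrom"] = meta["chrom"].astype(str)
    sample_ids = [c for c in df.columns
                  if c not in ("gene_id", "chrom", "start", "end")]
    return CountMatrix(genes=meta,
                       counts=df[sample_ids].to_numpy().astype(np.int64),
                       sample_ids=sample_ids)


# ------------------------------------------------------- covariates & misc

def write_covariates(cov: pd.DataFrame, path: str) -> None:
    cov.to_csv(path, sep="\t", index=False)


def read_covariates(path: str) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    cov["sample_id"] = cov["sample_id"].astype(str)
    return cov


def write_pedigree(ped: pd.DataFrame, path: str) -> None:
    ped[["animal", "sire", "dam"]].to_csv(path, index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    ped = pd.read_csv(path)
    for c in ("animal", "sire", "dam"):
        ped[c] = ped[c].astype(str)
    return ped[["animal", "sire", "dam"]]


def write_matrix(mat: np.ndarray, ids: list[str], path: str) -> None:
    """Square matrix TSV with id header row and column."""
    pd.DataFrame(mat, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="sample_id")


def read_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.to_numpy(float), [str(c) for c in df.columns]


def read_id_list(path: str) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def read_categories(path: str) -> dict[str, set[str]]:
    """Two-column TSV (category_id, gene_id) -> category -> member set."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["category_id", "gene_id"], comment="#")
    out: dict[str, set[str]] = {}
    for cat, sub in df.groupby("category_id"):
        out[str(cat)] = set(sub["gene_id"].astype(str))
    return out


def read_bed_intervals(path: str) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive interval table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
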