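"""Surplus-based trans-eQTL selection, Fisher-exact category enrichment and
QTL-region overlap annotation.

The top pair set is sized by the surplus of low p-values over the uniform
expectation (observed count below alpha minus alpha x N). Category
enrichment then compares the genes of those pairs - counted WITH
multiplicity, one count per pair - against a background gene SET (the
analysis set or all expressed genes). The 2x2 table therefore deliberately
mixes pair counts and gene counts; that asymmetry is the construction the
reported fold changes rest on, so it is kept and documented rather than
"fixed". A deduplicated variant is available via ``dedupe=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class EnrichmentRecord:
    category_id: str
    n_matched_pairs: int
    fold: float
    p_value: float
    background_size: int
    background_in_category: int
    reason: str = ""


def surplus_low_p(pvals: np.ndarray, alpha: float = 0.01) -> int:
    """max(0, round(#{p < alpha} - alpha * N)): the excess of low p-values
    over a uniform distribution's expectation."""
    p = np.asarray(pvals, float)
    p = p[np.isfinite(p)]
    observed = int((p < alpha).sum())
    return max(0, int(round(observed - alpha * p.size)))


def select_top_pairs(records: pd.DataFrame, k: int) -> pd.DataFrame:
    """k records with smallest p-value from one (model x class) partition;
    ties broken by (snp_id, gene_id) for determinism. Gene multiplicity is
    preserved."""
    usable = records[np.isfinite(records["p_value"])]
    if k > len(usable):
        raise ValueError(
            f"requested top {k} pairs but only {len(usable)} testable "
            "records are available")
    srt = usable.sort_values(["p_value", "snp_id", "gene_id"],
                             kind="mergesort")
    return srt.head(k).reset_index(drop=True)


def fisher_enrichment(top_genes: list[str], category: set[str],
                      background: set[str], category_id: str = "",
                      dedupe: bool = False) -> EnrichmentRecord:
    """Two-sided Fisher exact test of category membership among the top
    pairs' genes versus a background gene set.

    ``top_genes`` is the pair-wise gene list (multiplicity = one entry per
    pair unless ``dedupe``). fold = (category fraction among pairs) /
    (category fraction among background).
    """
    if not top_genes or not category or not background:
        raise ValueError("top pairs, category and background must be nonempty")
    genes = list(dict.fromkeys(top_genes)) if dedupe else list(top_genes)
    n_in = sum(g in category for g in genes)
    n_out = len(genes) - n_in
    bg_in = len(background & category)
    bg_out = len(background) - bg_in
    _, p = fisher_exact([[n_in, n_out], [bg_in, bg_out]],
                        alternative="two-sided")
    if bg_in == 0:
        return EnrichmentRecord(category_id, n_in, np.nan, float(p),
                                len(background), 0,
                                reason="category absent from background")
    fold = (n_in / len(genes)) / (bg_in / len(background))
    return EnrichmentRecord(category_id, n_in, float(fold), float(p),
                            len(background), bg_in)


def enrich_categories(top_pairs: pd.DataFrame,
                      categories: dict[str, set[str]],
                      background_analysis: set[str],
                      background_expressed: set[str] | None = None,
                      dedupe: bool = False) -> pd.DataFrame:
    """Enrichment table over all categories against one or two backgrounds
    (analysis gene set; optionally the full expressed gene set)."""
    genes = top_pairs["gene_id"].astype(str).tolist()
    rows = []
    for cat_id, members in categories.items():
        rec = fisher_enrichment(genes, members, background_analysis,
                                cat_id, dedupe=dedupe)
        row = {"category_id": cat_id, "n_matched_pairs": rec.n_matched_pairs,
               "fold_vs_background": rec.fold, "p_vs_background": rec.p_value,
               "reason": rec.reason}
        if background_expressed is not None:
            rec2 = fisher_enrichment(genes, members, background_expressed,
                                     cat_id, dedupe=dedupe)
            row["fold_vs_expressed"] = rec2.fold
            row["p_vs_expressed"] = rec2.p_value
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ QTL overlap

def _interval_hits(chrom: str, lo: int, hi: int,
                   qtl_regions: pd.DataFrame) -> pd.DataFrame:
    same = qtl_regions["chrom"].astype(str) == str(chrom)
    hit = same & (qtl_regions["end"] >= lo) & (qtl_regions["start"] <= hi)
    return qtl_regions[hit]


def snp_qtl_overlap(snp_chrom: str, snp_pos: int, qtl_regions: pd.DataFrame,
                    flank: int = 100_000) -> tuple[bool, pd.DataFrame]:
    """True iff [pos - flank, pos + flank] intersects a region on the same
    chromosome (1-based inclusive ends); returns the hit rows too."""
    hits = _interval_hits(snp_chrom, snp_pos - flank, snp_pos + flank,
                          qtl_regions)
    return bool(len(hits)), hits


def gene_qtl_overlap(gene_chrom: str, gene_start: int, gene_end: int,
                     qtl_regions: pd.DataFrame) -> tuple[bool, pd.DataFrame]:
    """True iff the unextended gene interval intersects a region."""
    hits = _interval_hits(gene_chrom, gene_start, gene_end, qtl_regions)
    return bool(len(hits)), hits


def annotate_qtl_overlap(records: pd.DataFrame, snps: pd.DataFrame,
                         genes: pd.DataFrame, qtl_regions: pd.DataFrame,
                         flank: int = 100_000) -> pd.DataFrame:
    """Add snp_in_qtl / gene_in_qtl flags to scan records."""
    snp_flag = {r.snp_id: snp_qtl_overlap(r.chrom, r.pos, qtl_regions,
                                          flank)[0]
                for r in snps.itertuples()}
    gene_flag = {r.gene_id: gene_qtl_overlap(r.chrom, r.start, r.end,
                                             qtl_regions)[0]
                 for r in genes.itertuples()}
    out = records.copy()
    out["snp_in_qtl"] = out["snp_id"].map(snp_flag).fillna(False)
    out["gene_in_qtl"] = out["gene_id"].map(gene_flag).fillna(False)
    return out
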