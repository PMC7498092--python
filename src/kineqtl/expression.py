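"""Expression preparation: TMM normalization, log2-CPM, count and outlier
filters, and assembly of the analysis gene set.

The gene set is the union of a differential-expression list and a
mitochondrial-annotation list (both plain input files), restricted to genes
passing a minimum-count filter on raw counts and a single-observation
outlier filter on normalized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CountMatrix, NormalizedExpression

log = logging.getLogger(__name__)


@dataclass
class GeneFilterConfig:
    min_reads: int = 5
    min_samples: int = 11
    z_max: float = 3.0

    def __post_init__(self) -> None:
        if self.min_reads <= 0 or self.min_samples <= 0 or self.z_max <= 0:
            raise ValueError("all gene-filter thresholds must be > 0")


def tmm_factors(counts: np.ndarray, logratio_trim: float = 0.30,
                sum_trim: float = 0.05) -> np.ndarray:
    """Trimmed mean of M-values scaling factors (genes x samples input).

    Reference sample: the one whose upper-quartile count fraction is closest
    to the mean of those fractions. Per sample, M (log2 ratio of library-
    size-scaled counts vs the reference) and A (average log2 abundance) are
    computed over genes expressed in both; the most extreme 30% of M and 5%
    of A are trimmed two-sided; the factor is 2**(precision-weighted mean of
    the surviving M), with delta-method inverse-variance weights. Factors
    are rescaled so their geometric mean is 1.
    """
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    uq = np.percentile(y, 75, axis=0) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    f = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        f[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref],
                         logratio_trim, sum_trim)
    f = f / np.exp(np.mean(np.log(f)))
    return f


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if np.max(np.abs(m)) < 1e-6:  # identical composition: factor exactly 1
        return 1.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    mean_m = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(mean_m):
        return 1.0
    return float(2.0 ** mean_m)


def log_normalize(cm: CountMatrix, factors: np.ndarray | None = None
                  ) -> NormalizedExpression:
    """log2-CPM with 0.5 offset on TMM-scaled effective library sizes:
    value = log2((count + 0.5) / effective_size * 1e6)."""
    if factors is None:
        factors = tmm_factors(cm.counts)
    lib = cm.counts.sum(axis=0).astype(float)
    eff = lib * np.asarray(factors, float)
    vals = np.log2((cm.counts + 0.5) / eff[None, :] * 1e6)
    return NormalizedExpression(genes=cm.genes.copy(), values=vals,
                                sample_ids=list(cm.sample_ids),
                                tmm_factors=np.asarray(factors, float),
                                effective_lib_size=eff)


def filter_min_counts(cm: CountMatrix, cfg: GeneFilterConfig) -> CountMatrix:
    """Keep genes with count >= min_reads in at least min_samples samples."""
    keep = (cm.counts >= cfg.min_reads).sum(axis=1) >= cfg.min_samples
    log.info("count filter (>=%d reads in >=%d samples): %d of %d genes kept",
             cfg.min_reads, cfg.min_samples, int(keep.sum()), cm.n_genes)
    return cm.subset(keep)


def filter_single_outlier(expr: NormalizedExpression,
                          cfg: GeneFilterConfig) -> list[str]:
    """Genes with at least one observation further than z_max standard
    deviations from the gene's mean normalized expression.

    Returns the list of gene_ids to REMOVE. Constant genes (sd = 0) are
    kept: their z-scores are defined as 0.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("outlier filter needs >= 3 samples")
    mu = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (expr.values - mu) / sd, 0.0)
    bad = (np.abs(z) > cfg.z_max).any(axis=1)
    removed = expr.genes.loc[bad, "gene_id"].tolist()
    log.info("outlier filter (|z| > %.3g): removed %d of %d genes",
             cfg.z_max, len(removed), expr.n_genes)
    return removed


def select_gene_set(deg_ids: list[str], mito_ids: list[str],
                    filtered_ids: list[str]) -> list[str]:
    """(DEG union mito) intersected with filter survivors, in the survivors'
    order. Logs the union size and the final size."""
    union = set(deg_ids) | set(mito_ids)
    final = [g for g in filtered_ids if g in union]
    if not final:
        raise ValueError(
            "gene-set selection produced an empty set: the DEG/mitochondrial "
            "lists share no ids with the filtered expression matrix")
    log.info("gene set: union %d (DEG %d + mito %d), final after filters %d",
             len(union), len(deg_ids), len(mito_ids), len(final))
    return final


def prepare_expression(cm: CountMatrix, deg_ids: list[str] | None = None,
                       mito_ids: list[str] | None = None,
                       cfg: GeneFilterConfig | None = None
                       ) -> tuple[NormalizedExpression, pd.DataFrame]:
    """Full preparation: restrict to the union gene set, count-filter raw
    counts, TMM-normalize, drop single-observation outliers.

    Returns (normalized expression of the final gene set, audit table of
    removed genes with reasons).
    """
    cfg = cfg or GeneFilterConfig()
    audit: list[tuple[str, str]] = []

    if deg_ids is not None or mito_ids is not None:
        union = set(deg_ids or []) | set(mito_ids or [])
        in_union = cm.genes["gene_id"].isin(union).to_numpy()
        audit += [(g, "not_in_gene_set")
                  for g in cm.genes.loc[~in_union, "gene_id"]]
        cm = cm.subset(in_union)
        if cm.n_genes == 0:
            raise ValueError("no genes of the DEG/mitochondrial union are "
                             "present in the count matrix")

    kept = filter_min_counts(cm, cfg)
    lost = set(cm.genes["gene_id"]) - set(kept.genes["gene_id"])
    audit += [(g, "low_counts") for g in sorted(lost)]

    expr = log_normalize(kept)
    outliers = set(filter_single_outlier(expr, cfg))
    audit += [(g, "expression_outlier") for g in sorted(outliers)]
    keep_mask = ~kept.genes["gene_id"].isin(outliers).to_numpy()

    final = NormalizedExpression(
        genes=kept.genes.loc[keep_mask].reset_index(drop=True),
        values=expr.values[keep_mask],
        sample_ids=list(cm.sample_ids),
        tmm_factors=expr.tmm_factors,
        effective_lib_size=expr.effective_lib_size)
    return final, pd.DataFrame(audit, columns=["gene_id", "reason"])
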