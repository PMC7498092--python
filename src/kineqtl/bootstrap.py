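"""Permutation ("bootstrapping") validation of the low-p-value excess.

The null is built by shuffling each SNP's dosage vector independently
across samples while expression, covariates and kinship stay fixed, then
rerunning the full all-pairs scan. Per iteration the count of p-values
below a cutoff and the k-th smallest p-values (default k = 1, 10, 100) are
recorded per (model x cis/trans) partition. The observed count is compared
with the permutation distribution via a normal-approximation upper-tail
probability and with empirical order-statistic exceedance fractions.

Note the per-SNP shuffle also breaks LD between SNPs in the null; this is a
property of the permutation scheme itself, shared with the observed scan's
validation design, not an artifact of this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeTable, NormalizedExpression, StudyDesign
from .scan import ScanConfig, cis_trans_matrix, scan_pvalues

MIN_REPORTABLE_P = 2.2e-16  # smaller tail probabilities reported as "< 2.2e-16"


@dataclass
class BootstrapConfig:
    n_iterations: int = 1000
    alpha_low: float = 0.01
    order_ranks: tuple[int, ...] = (1, 10, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.alpha_low < 1.0:
            raise ValueError("alpha_low must be in (0, 1)")
        if list(self.order_ranks) != sorted(self.order_ranks) or \
                min(self.order_ranks) < 1:
            raise ValueError("order_ranks must be positive and ascending")


@dataclass
class BootstrapSummary:
    partitions: list[str]
    observed_counts: dict[str, int]
    null_counts: pd.DataFrame           # iterations x partitions
    observed_order_stats: dict[str, dict[int, float]]
    null_order_stats: dict[str, pd.DataFrame]  # part -> iterations x ranks
    normal_z: dict[str, float] = field(default_factory=dict)
    normal_tail_p: dict[str, float] = field(default_factory=dict)
    exceedance: dict[str, dict[int, float]] = field(default_factory=dict)
    config: BootstrapConfig | None = None


def permute_genotypes(gt: GenotypeTable, seed: int) -> GenotypeTable:
    """Independently permute each SNP's dosages across samples (per-SNP
    multiset preserved)."""
    rng = np.random.default_rng(seed)
    dos = gt.dosages.copy()
    for i in range(dos.shape[0]):
        rng.shuffle(dos[i])
    return GenotypeTable(snps=gt.snps.copy(), dosages=dos,
                         sample_ids=list(gt.sample_ids))


def normal_tail_prob(observed: float, null_counts: np.ndarray) -> float:
    """Upper-tail standard-normal probability of the observed count under a
    normal fit to the permutation counts."""
    null_counts = np.asarray(null_counts, float)
    if null_counts.size < 2:
        raise ValueError("need >= 2 permutation counts")
    sd = null_counts.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null: permutation counts are constant")
    z = (observed - null_counts.mean()) / sd
    return float(stats.norm.sf(z))


def order_stat_exceedance(observed_kth: float,
                          null_kths: np.ndarray) -> float:
    """Fraction of iterations whose k-th smallest p-value is strictly lower
    than the observed k-th smallest."""
    null_kths = np.asarray(null_kths, float)
    if null_kths.size == 0:
        raise ValueError("empty permutation vector")
    return float(np.mean(null_kths < observed_kth))


def _partition_stats(p_by_part: dict[str, np.ndarray], alpha: float,
                     ranks: tuple[int, ...]
                     ) -> tuple[dict[str, int], dict[str, dict[int, float]]]:
    counts, order = {}, {}
    for part, p in p_by_part.items():
        p = p[np.isfinite(p)]
        counts[part] = int((p < alpha).sum())
        srt = np.sort(p)
        order[part] = {k: float(srt[k - 1]) if k <= srt.size else np.nan
                       for k in ranks}
    return counts, order


def _split_partitions(out: dict, cis: np.ndarray,
                      models: tuple[str, ...]) -> dict[str, np.ndarray]:
    res = {}
    flat_cis = cis.ravel()
    for model in models:
        p = (out["lin_p"] if model == "linear" else out["anova_p"]).ravel()
        res[f"{model}:cis"] = p[flat_cis]
        res[f"{model}:trans"] = p[~flat_cis]
    return res


def bootstrap_null(expr: NormalizedExpression, gt: GenotypeTable,
                   design: StudyDesign, K: pd.DataFrame | np.ndarray,
                   scan_cfg: ScanConfig | None = None,
                   boot_cfg: BootstrapConfig | None = None
                   ) -> BootstrapSummary:
    """Run the observed scan plus ``n_iterations`` genotype-permutation
    rescans; summarize low-p counts and order statistics per partition.

    Iteration i uses the derived seed ``boot_cfg.seed + i + 1`` so any
    iteration can be reproduced in isolation.
    """
    scan_cfg = scan_cfg or ScanConfig()
    boot_cfg = boot_cfg or BootstrapConfig()
    if isinstance(K, pd.DataFrame):
        K = K.loc[expr.sample_ids, expr.sample_ids].to_numpy()
    cis = cis_trans_matrix(expr.genes, gt.snps, scan_cfg.cis_distance)

    obs_out = scan_pvalues(expr.values, gt.dosages, design.matrix, K, scan_cfg)
    obs_parts = _split_partitions(obs_out, cis, scan_cfg.models)
    observed_counts, observed_order = _partition_stats(
        obs_parts, boot_cfg.alpha_low, boot_cfg.order_ranks)
    partitions = list(obs_parts)

    null_counts = {p: [] for p in partitions}
    null_order: dict[str, dict[int, list[float]]] = {
        p: {k: [] for k in boot_cfg.order_ranks} for p in partitions}
    for it in range(boot_cfg.n_iterations):
        try:
            perm = permute_genotypes(gt, boot_cfg.seed + it + 1)
            out = scan_pvalues(expr.values, perm.dosages,
                               design.matrix, K, scan_cfg)
        except Exception as e:
            raise RuntimeError(f"permutation iteration {it} failed: {e}") from e
        parts = _split_partitions(out, cis, scan_cfg.models)
        counts, order = _partition_stats(parts, boot_cfg.alpha_low,
                                         boot_cfg.order_ranks)
        for p in partitions:
            null_counts[p].append(counts[p])
            for k in boot_cfg.order_ranks:
                null_order[p][k].append(order[p][k])

    summary = BootstrapSummary(
        partitions=partitions,
        observed_counts=observed_counts,
        null_counts=pd.DataFrame(null_counts),
        observed_order_stats=observed_order,
        null_order_stats={p: pd.DataFrame(null_order[p]) for p in partitions},
        config=boot_cfg)
    for p in partitions:
        nc = np.asarray(null_counts[p], float)
        if nc.size >= 2 and nc.std(ddof=1) > 0:
            summary.normal_z[p] = float(
                (observed_counts[p] - nc.mean()) / nc.std(ddof=1))
            summary.normal_tail_p[p] = normal_tail_prob(observed_counts[p], nc)
        else:
            summary.normal_z[p] = np.nan
            summary.normal_tail_p[p] = np.nan
        summary.exceedance[p] = {
            k: order_stat_exceedance(observed_order[p][k],
                                     np.asarray(null_order[p][k]))
            for k in boot_cfg.order_ranks}
    return summary


def format_tail_p(p: float) -> str:
    """Render a tail probability, flooring at the smallest printable value."""
    if np.isnan(p):
        return "NA"
    if p < MIN_REPORTABLE_P:
        return f"< {MIN_REPORTABLE_P:g}"
    return f"{p:.3g}"
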