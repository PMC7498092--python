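"""End-to-end pipeline: QC -> normalize -> kinship -> scan -> permutation
validation -> enrichment -> QTL annotation, driven by a YAML config.

Every stage writes plain TSV/JSON artifacts into the output directory and
the run closes with a manifest (input checksums, config echo, derived
seeds, per-stage row counts) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .bootstrap import BootstrapConfig, bootstrap_null, format_tail_p
from .datatypes import build_design
from .enrichment import (annotate_qtl_overlap, enrich_categories,
                         select_top_pairs, surplus_low_p)
from .expression import GeneFilterConfig, prepare_expression
from .genotype_qc import QcThresholds, run_qc
from .kinship import kinship_from_pedigree
from .scan import ScanConfig, pair_count, run_scan, scan_summary

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str
    counts: str
    covariates: str
    pedigree: str | None = None
    deg_list: str | None = None
    mito_list: str | None = None
    categories: str | None = None
    qtl_bed: str | None = None
    out_dir: str = "kineqtl_out"
    seed: int = 0
    maf_min: float = 0.3
    ld_r2_min: float = 0.9
    min_reads: int = 5
    min_samples: int = 11
    z_max: float = 3.0
    kinship_generations: int = 4
    cis_distance: int = 1_000_000
    models: tuple[str, ...] = ("linear", "anova")
    chunk_size: int = 512
    bootstrap_iterations: int = 1000
    bootstrap_alpha: float = 0.01
    order_ranks: tuple[int, ...] = (1, 10, 100)
    enrich_partition: str = "linear:trans"
    enrich_top_k: int | None = None     # default: surplus of low p-values
    qtl_flank: int = 100_000
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("models", "order_ranks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    t0 = time.time()
    out = kio.ensure_dir(cfg.out_dir)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(cfg).items()},
                      "inputs": {}, "stages": {}, "seeds": {}}
    for key in ("genotypes", "counts", "covariates", "pedigree",
                "deg_list", "mito_list", "categories", "qtl_bed"):
        path = getattr(cfg, key)
        if path:
            if not os.path.exists(path):
                raise FileNotFoundError(f"input {key!r} not found: {path}")
            manifest["inputs"][key] = {"path": path, "sha256": _sha256(path)}

    def stage(name):
        log.info("stage %s ...", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return manifest["stages"][name]

    # ---- genotype QC
    st = stage("qc")
    gt_raw = kio.read_genotypes(cfg.genotypes)
    gt, blocks = run_qc(gt_raw, QcThresholds(cfg.maf_min, cfg.ld_r2_min))
    kio.write_genotypes(gt, os.path.join(out, "genotypes_qc.tsv"))
    blocks.to_csv(os.path.join(out, "ld_blocks.tsv"), sep="\t", index=False)
    st.update(n_snps_in=gt_raw.n_snps, n_snps_out=gt.n_snps,
              n_blocks=len(blocks))

    # ---- expression preparation
    st = stage("normalize")
    cm = kio.read_counts(cfg.counts)
    deg = kio.read_id_list(cfg.deg_list) if cfg.deg_list else None
    mito = kio.read_id_list(cfg.mito_list) if cfg.mito_list else None
    expr, audit = prepare_expression(
        cm, deg, mito, GeneFilterConfig(cfg.min_reads, cfg.min_samples,
                                        cfg.z_max))
    audit.to_csv(os.path.join(out, "gene_filter_audit.tsv"), sep="\t",
                 index=False)
    edf = expr.genes.copy()
    for j, s in enumerate(expr.sample_ids):
        edf[s] = expr.values[:, j]
    edf.to_csv(os.path.join(out, "expression_log2cpm.tsv"), sep="\t",
               index=False, float_format="%.6g")
    st.update(n_genes_in=cm.n_genes, n_genes_out=expr.n_genes)

    # ---- align samples
    cov = kio.read_covariates(cfg.covariates)
    samples = [s for s in gt.sample_ids if s in set(expr.sample_ids)]
    if samples != list(gt.sample_ids) or samples != list(expr.sample_ids):
        raise ValueError("genotype and expression sample sets differ; "
                         "align inputs before running the pipeline")
    design = build_design(cov, samples)

    # ---- kinship
    st = stage("kinship")
    if cfg.pedigree:
        ped = kio.read_pedigree(cfg.pedigree)
        K = kinship_from_pedigree(ped, samples, cfg.kinship_generations)
    else:
        K = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    kio.write_matrix(K.to_numpy(), samples, os.path.join(out, "kinship.tsv"))
    st.update(n_samples=len(samples),
              identity=bool(np.allclose(K.to_numpy(), np.eye(len(samples)))))

    # ---- scan
    st = stage("scan")
    scan_cfg = ScanConfig(cis_distance=cfg.cis_distance, models=cfg.models,
                          chunk_size=cfg.chunk_size)
    records = run_scan(expr, gt, design, K, scan_cfg)
    records_out = records.sort_values(
        ["model", "cis_trans", "p_value"], kind="mergesort")
    records_out.to_csv(os.path.join(out, "scan_records.tsv"), sep="\t",
                       index=False, float_format="%.6g")
    summary = scan_summary(records, cfg.bootstrap_alpha)
    st.update(n_pairs_per_model=pair_count(expr.n_genes, gt.n_snps),
              n_records=len(records), partitions=summary)

    # ---- permutation validation
    st = stage("bootstrap")
    boot_cfg = BootstrapConfig(cfg.bootstrap_iterations, cfg.bootstrap_alpha,
                               cfg.order_ranks,
                               seed=_stage_seed(cfg.seed, "bootstrap"))
    boot = bootstrap_null(expr, gt, design, K, scan_cfg, boot_cfg)
    boot.null_counts.to_csv(os.path.join(out, "bootstrap_counts.tsv"),
                            sep="\t", index_label="iteration")
    for part, df in boot.null_order_stats.items():
        df.to_csv(os.path.join(out,
                               f"bootstrap_order_{part.replace(':', '_')}.tsv"),
                  sep="\t", index_label="iteration")
    boot_summary = {
        part: {"observed_count": boot.observed_counts[part],
               "normal_z": boot.normal_z[part],
               "normal_tail_p": boot.normal_tail_p[part],
               "normal_tail_p_printed": format_tail_p(boot.normal_tail_p[part]),
               "exceedance": {str(k): v
                              for k, v in boot.exceedance[part].items()}}
        for part in boot.partitions}
    with open(os.path.join(out, "bootstrap_summary.json"), "w") as fh:
        json.dump(boot_summary, fh, indent=2, default=float)
    st.update(n_iterations=cfg.bootstrap_iterations)

    # ---- enrichment
    if cfg.categories:
        st = stage("enrich")
        model, cls = cfg.enrich_partition.split(":")
        part = records[(records["model"] == model) &
                       (records["cis_trans"] == cls)]
        k = cfg.enrich_top_k
        if k is None:
            k = surplus_low_p(part["p_value"].to_numpy(), cfg.bootstrap_alpha)
        cats = kio.read_categories(cfg.categories)
        if k == 0:
            enr = pd.DataFrame()
            log.warning("no surplus of low p-values; enrichment skipped")
        else:
            top = select_top_pairs(part, k)
            background = set(expr.genes["gene_id"].astype(str))
            expressed = set(cm.genes["gene_id"].astype(str))
            enr = enrich_categories(top, cats, background, expressed)
        enr.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t", index=False,
                   float_format="%.4g")
        st.update(top_k=int(k), n_categories=len(cats))

    # ---- QTL annotation
    if cfg.qtl_bed:
        st = stage("annotate_qtl")
        regions = kio.read_bed_intervals(cfg.qtl_bed)
        flagged = annotate_qtl_overlap(records_out.head(1000), gt.snps,
                                       expr.genes, regions, cfg.qtl_flank)
        flagged.to_csv(os.path.join(out, "qtl_overlap.tsv"), sep="\t",
                       index=False, float_format="%.6g")
        st.update(n_regions=len(regions))

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if cfg.make_plots:
        report(cfg.out_dir)
    return manifest


def report(out_dir: str, top_n: int = 10) -> dict[str, str]:
    """Render human-readable outputs from a completed run: p-value
    histograms per partition, top-record tables and the bootstrap/
    enrichment summaries."""
    rec_path = os.path.join(out_dir, "scan_records.tsv")
    if not os.path.exists(rec_path):
        raise FileNotFoundError("missing stage output: scan (scan_records.tsv)")
    records = pd.read_csv(rec_path, sep="\t")
    outputs: dict[str, str] = {}

    top_rows = []
    for (model, cls), sub in records.groupby(["model", "cis_trans"]):
        top_rows.append(sub.nsmallest(top_n, "p_value"))
    top = pd.concat(top_rows)
    top_path = os.path.join(out_dir, "report_top_records.tsv")
    top.to_csv(top_path, sep="\t", index=False, float_format="%.4g")
    outputs["top_records"] = top_path

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups = list(records.groupby(["model", "cis_trans"]))
        fig, axes = plt.subplots(1, max(len(groups), 1),
                                 figsize=(4 * max(len(groups), 1), 3.2))
        axes = np.atleast_1d(axes)
        for ax, ((model, cls), sub) in zip(axes, groups):
            p = sub["p_value"].dropna()
            ax.hist(p, bins=20, color="steelblue", edgecolor="white")
            ax.axhline(len(p) / 20, color="firebrick", ls="--", lw=1)
            ax.set_title(f"{model} {cls}")
            ax.set_xlabel("p-value")
        fig.tight_layout()
        hist_path = os.path.join(out_dir, "report_pvalue_histograms.png")
        fig.savefig(hist_path, dpi=120)
        plt.close(fig)
        outputs["histograms"] = hist_path
    except Exception as e:  # plotting is best-effort
        log.warning("histogram rendering failed: %s", e)

    enr_path = os.path.join(out_dir, "enrichment.tsv")
    note_path = os.path.join(out_dir, "report_enrichment.txt")
    if os.path.exists(enr_path):
        enr = pd.read_csv(enr_path, sep="\t")
        with open(note_path, "w") as fh:
            if enr.empty:
                fh.write("no categories enriched: empty enrichment table\n")
            else:
                fh.write(enr.to_string(index=False) + "\n")
        outputs["enrichment"] = note_path
    return outputs
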