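"""Synthetic study generator with planted cis/trans genetic effects.

Emulates the statistical structure the scan assumes, at the study's
dimensions (two breed groups of 11 + 27 pigs by default): a multi-
generation pedigree with separate founder pools per breed, Mendelian
genotypes organized in high-LD blocks, a 5-level batch factor plus RIN and
age covariates, and negative-binomial RNA-seq counts whose log-mean
combines baseline, planted genotype effects, covariate effects, an
optional pedigree-polygenic term and library-size offsets. A TruthLedger
records every planted effect so downstream stages can be scored.

LD blocks are generated at the founder-haplotype level: each block member
copies the block seed SNP's founder alleles with a small flip probability
and all members share the block's transmission draws through the pedigree
(complete linkage within a block). This keeps offspring genotypes Mendelian
at every SNP while guaranteeing pairwise dosage R^2 above the target (a
copy that falls below the target is replaced by an exact copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GenotypeTable, build_design

UNKNOWN = "0"


@dataclass
class SimulationConfig:
    n_samples_group1: int = 11          # Duroc-like group
    n_samples_group2: int = 27          # Landrace-like group
    n_snps: int = 400                   # tag + redundant SNPs pre-QC
    n_genes: int = 100
    n_chromosomes: int = 5
    ld_block_size_mean: float = 2.0
    ld_flip_prob: float = 0.01
    ld_r2_target: float = 0.9
    target_maf_min: float = 0.3
    n_cis_effects: int = 0
    n_trans_effects: int = 0
    effect_size_sd: float = 2.0         # |beta| in units of per-gene noise sd
    nonadditive_fraction: float = 0.0   # fraction of planted effects that are
                                        # heterozygote-shift (ANOVA-type)
    dispersion: float = 0.1             # NB dispersion alpha (var = mu+a*mu^2)
    covariate_effect_sds: dict = field(default_factory=lambda: {
        "breed": 0.3, "batch": 0.2, "rin": 0.15, "age_days": 0.1})
    polygenic_var: float = 0.0          # polygenic variance in sigma_g^2 units
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 0.7
    library_log_sd: float = 0.3
    n_batches: int = 5
    n_generations: int = 4
    unrelated: bool = False             # all-founder pedigree -> A = identity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_group1", "n_samples_group2", "n_snps",
                     "n_genes", "n_chromosomes", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.target_maf_min <= 0.5:
            raise ValueError("target_maf_min must be in [0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.n_samples_group1 + self.n_samples_group2

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so each stage draws independently of the others."""
        h = int.from_bytes(stream.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))


@dataclass
class TruthLedger:
    planted_pairs: pd.DataFrame     # snp_id, gene_id, effect_size (log scale),
                                    # effect_multiple, cis_trans, effect_type
    covariate_effects: pd.DataFrame  # gene_id x design columns
    block_assignments: pd.DataFrame  # snp_id, block
    meta: dict = field(default_factory=dict)


# ------------------------------------------------------------- pedigree

def simulate_pedigree(cfg: SimulationConfig) -> pd.DataFrame:
    """(animal, sire, dam) table spanning ``n_generations`` of ancestry per
    breed pool; the final generation is exactly the study samples, some of
    which are full sibs. With ``cfg.unrelated`` every study animal is a
    founder (downstream A-matrix = identity)."""
    sizes = {"g1": cfg.n_samples_group1, "g2": cfg.n_samples_group2}
    sample_ids = [f"{b}_s{i}" for b, n in sizes.items() for i in range(n)]
    if cfg.unrelated:
        return pd.DataFrame({"animal": sample_ids, "sire": UNKNOWN,
                             "dam": UNKNOWN})

    rng = cfg.rng("pedigree")
    rows: list[tuple[str, str, str]] = []
    for breed, n_final in sizes.items():
        n_pool = max(6, n_final)
        prev = [f"{breed}_G0_{i}" for i in range(n_pool)]
        rows += [(a, UNKNOWN, UNKNOWN) for a in prev]
        for gen in range(1, cfg.n_generations + 1):
            final = gen == cfg.n_generations
            n_next = n_final if final else n_pool
            ids = ([s for s in sample_ids if s.startswith(breed)]
                   if final else [f"{breed}_G{gen}_{i}" for i in range(n_next)])
            sires = prev[: len(prev) // 2]
            dams = prev[len(prev) // 2:]
            i = 0
            while i < n_next:
                sire = sires[rng.integers(len(sires))]
                dam = dams[rng.integers(len(dams))]
                litter = int(rng.integers(1, 3))  # 1-2 offspring: full sibs
                for _ in range(min(litter, n_next - i)):
                    rows.append((ids[i], sire, dam))
                    i += 1
            prev = ids
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


def study_sample_ids(cfg: SimulationConfig) -> list[str]:
    return [f"g1_s{i}" for i in range(cfg.n_samples_group1)] + \
           [f"g2_s{i}" for i in range(cfg.n_samples_group2)]


# ------------------------------------------------------------ genotypes

def _snp_layout(cfg: SimulationConfig, rng: np.random.Generator
                ) -> pd.DataFrame:
    """Assign SNPs to LD blocks and chromosomes with bp positions."""
    sizes: list[int] = []
    total = 0
    while total < cfg.n_snps:
        s = 1 + rng.poisson(max(cfg.ld_block_size_mean - 1.0, 0.0))
        s = min(s, cfg.n_snps - total)
        sizes.append(s)
        total += s
    blocks_per_chrom = int(np.ceil(len(sizes) / cfg.n_chromosomes))
    rows = []
    snp_i = 0
    for b, size in enumerate(sizes):
        chrom = str(1 + b // blocks_per_chrom)
        if b % blocks_per_chrom == 0:
            pos = int(rng.integers(10_000, 100_000))
        else:
            pos += int(rng.integers(50_000, 500_000))
        for _ in range(size):
            rows.append((f"snp{snp_i}", chrom, pos, b))
            pos += int(rng.integers(1_000, 10_000))
            snp_i += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "block"])


def simulate_genotypes(cfg: SimulationConfig, pedigree: pd.DataFrame,
                       include_ancestors: bool = False
                       ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Gene-drop founder haplotypes through the pedigree.

    Returns (GenotypeTable over study samples, block assignment table).
    Founder allele frequencies are drawn in [maf_min + 0.05, 0.5] so the
    MAF filter is achievable; offspring alleles are Mendelian draws from
    parental haplotypes, with transmission shared within each LD block.
    With ``include_ancestors`` the table covers every pedigree animal (in
    topological order) instead of only the study samples, so Mendelian
    transmission can be audited directly.
    """
    rng = cfg.rng("genotypes")
    layout = _snp_layout(cfg, rng)
    samples = study_sample_ids(cfg)

    parents = {r.animal: (r.sire, r.dam) for r in pedigree.itertuples()}
    order: list[str] = []
    seen: set[str] = set()

    def visit(a: str) -> None:
        if a in seen or a == UNKNOWN or a not in parents:
            return
        s, d = parents[a]
        visit(s)
        visit(d)
        seen.add(a)
        order.append(a)

    for a in parents:
        visit(a)
    idx = {a: i for i, a in enumerate(order)}
    founders = [a for a in order if parents[a] == (UNKNOWN, UNKNOWN)]
    n_anim = len(order)
    out_ids = list(order) if include_ancestors else samples
    sample_rows = np.array([idx[s] for s in samples])
    out_rows = np.array([idx[s] for s in out_ids])

    dosages = np.zeros((cfg.n_snps, len(out_ids)), dtype=np.int8)
    for block, sub in layout.groupby("block", sort=True):
        bsize = len(sub)
        hap = np.zeros((n_anim, 2, bsize), dtype=np.int8)
        f = rng.uniform(cfg.target_maf_min + 0.05, 0.5)
        seed_alleles = {a: (rng.random(2) < f).astype(np.int8)
                        for a in founders}
        for j in range(bsize):
            if j == 0:
                for a in founders:
                    hap[idx[a], :, 0] = seed_alleles[a]
            else:
                for a in founders:
                    flips = (rng.random(2) < cfg.ld_flip_prob).astype(np.int8)
                    hap[idx[a], :, j] = seed_alleles[a] ^ flips
        # shared transmission: complete linkage within the block
        for a in order:
            s, d = parents[a]
            if s == UNKNOWN and d == UNKNOWN:
                continue
            cs, cd = rng.integers(2), rng.integers(2)
            hap[idx[a], 0, :] = hap[idx[s], cs, :]
            hap[idx[a], 1, :] = hap[idx[d], cd, :]
        dos_all = hap.sum(axis=1)           # (n_anim, bsize)
        dos = dos_all[sample_rows]          # study view drives the guarantee
        # constructive R^2 guarantee: degrade flipped copies to exact copies
        for j in range(1, bsize):
            for j0 in range(j):
                r2 = _safe_r2(dos[:, j0], dos[:, j])
                if r2 < cfg.ld_r2_target:
                    dos_all[:, j] = dos_all[:, 0]
                    dos = dos_all[sample_rows]
                    break
        rows = sub.index.to_numpy()
        dosages[rows, :] = dos_all[out_rows].T

    snps = layout[["snp_id", "chrom", "pos"]].copy()
    gt = GenotypeTable(snps=snps, dosages=dosages, sample_ids=out_ids)
    return gt, layout[["snp_id", "block"]].copy()


def _safe_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
    return float(r * r)


# ----------------------------------------------------------- covariates

def simulate_covariates(cfg: SimulationConfig,
                        samples: list[str] | None = None) -> pd.DataFrame:
    """Breed (from group membership), batch (n_batches levels), RIN and
    age-in-days covariate table."""
    samples = samples or study_sample_ids(cfg)
    rng = cfg.rng("covariates")
    breed = ["duroc" if s.startswith("g1") else "landrace" for s in samples]
    batch_pool = [f"b{i % cfg.n_batches}" for i in range(len(samples))]
    batch = list(np.array(batch_pool)[rng.permutation(len(samples))])
    rin = np.round(rng.normal(8.0, 0.5, len(samples)), 2)
    age = np.round(rng.normal(160.0, 10.0, len(samples)), 1)
    return pd.DataFrame({"sample_id": samples, "breed": breed, "batch": batch,
                         "rin": rin, "age_days": age})


# ----------------------------------------------------------- expression

def _gene_layout(cfg: SimulationConfig, snps: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on the SNP-bearing chromosomes."""
    rows = []
    chroms = snps["chrom"].drop_duplicates().to_numpy()
    span = {c: (int(snps.loc[snps["chrom"] == c, "pos"].min()),
                int(snps.loc[snps["chrom"] == c, "pos"].max()))
            for c in chroms}
    for i in range(cfg.n_genes):
        c = chroms[rng.integers(len(chroms))]
        lo, hi = span[c]
        start = int(rng.integers(max(lo - 2_000_000, 1),
                                 hi + 2_000_000))
        length = int(rng.integers(2_000, 100_000))
        rows.append((f"gene{i}", c, start, start + length))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _plant_pairs(cfg: SimulationConfig, genes: pd.DataFrame,
                 snps: pd.DataFrame, rng: np.random.Generator,
                 cis_distance: int = 1_000_000,
                 trans_gene_weights: np.ndarray | None = None
                 ) -> pd.DataFrame:
    """Choose (snp, gene) pairs for cis and trans effects; genes without a
    cis SNP are relocated next to one so cis labels hold by construction.

    At most one effect is planted per gene: stacking several strong effects
    on one gene would inflate that gene's residual variance and silently
    shrink every planted effect below its nominal noise-sd multiple.
    """
    if cfg.n_cis_effects + cfg.n_trans_effects > len(genes):
        raise ValueError(
            f"cannot plant {cfg.n_cis_effects + cfg.n_trans_effects} effects "
            f"on {len(genes)} genes with one effect per gene")
    pairs = []
    used_genes: set[str] = set()

    gene_pool = rng.permutation(len(genes))
    n_cis = 0
    for gi in gene_pool:
        if n_cis >= cfg.n_cis_effects:
            break
        g = genes.iloc[gi]
        near = snps[(snps["chrom"] == g["chrom"]) &
                    (snps["pos"] >= g["start"] - cis_distance) &
                    (snps["pos"] <= g["end"] + cis_distance)]
        if near.empty:  # relocate the gene beside a random SNP
            s = snps.iloc[rng.integers(len(snps))]
            length = int(g["end"] - g["start"])
            genes.loc[genes.index[gi], ["chrom", "start", "end"]] = \
                [s["chrom"], s["pos"] + 1_000, s["pos"] + 1_000 + length]
            g = genes.iloc[gi]
            near = snps[(snps["chrom"] == g["chrom"]) &
                        (snps["pos"] >= g["start"] - cis_distance) &
                        (snps["pos"] <= g["end"] + cis_distance)]
        s = near.iloc[rng.integers(len(near))]
        used_genes.add(g["gene_id"])
        pairs.append((s["snp_id"], g["gene_id"], "cis"))
        n_cis += 1

    w = np.ones(len(genes)) if trans_gene_weights is None \
        else np.asarray(trans_gene_weights, float).copy()
    w[genes["gene_id"].isin(used_genes).to_numpy()] = 0.0
    n_trans = 0
    while n_trans < cfg.n_trans_effects:
        if w.sum() <= 0:
            raise ValueError("ran out of unused genes while planting "
                             "trans effects")
        gi = rng.choice(len(genes), p=w / w.sum())
        g = genes.iloc[gi]
        far = snps[snps["chrom"] != g["chrom"]]
        if far.empty:
            far = snps[(snps["chrom"] == g["chrom"]) &
                       ((snps["pos"] < g["start"] - cis_distance) |
                        (snps["pos"] > g["end"] + cis_distance))]
        if far.empty:
            raise ValueError("cannot plant a trans effect: every SNP is "
                             "within the cis window of every gene")
        s = far.iloc[rng.integers(len(far))]
        used_genes.add(g["gene_id"])
        w[gi] = 0.0
        pairs.append((s["snp_id"], g["gene_id"], "trans"))
        n_trans += 1
    return pd.DataFrame(pairs, columns=["snp_id", "gene_id", "cis_trans"])


def simulate_expression(cfg: SimulationConfig, gt: GenotypeTable,
                        covariates: pd.DataFrame,
                        kinship: pd.DataFrame | None = None,
                        block_assignments: pd.DataFrame | None = None,
                        trans_gene_weights: np.ndarray | None = None
                        ) -> tuple[CountMatrix, TruthLedger]:
    """Negative-binomial counts with planted genotype effects.

    log-mean(gene g, sample j) = baseline_g + library_offset_j
      + sum(planted effects: beta * centered dosage, or a heterozygote
        shift for ANOVA-type effects) + covariate effects
      + optional polygenic term with covariance polygenic_var * sigma_g^2 * A.

    Planted |beta| = effect_size_sd x sigma_g where sigma_g =
    sqrt(1/mu_g + dispersion) approximates the gene's log-scale noise sd,
    so ``effect_size_sd`` is the planted effect in noise-sd multiples.
    """
    samples = list(gt.sample_ids)
    cov_samples = [str(s) for s in covariates["sample_id"]]
    if cov_samples != samples:
        raise ValueError(
            f"sample axis mismatch between genotypes ({len(samples)}) and "
            f"covariates ({len(cov_samples)}): first difference at "
            f"{next((a for a, b in zip(samples, cov_samples) if a != b), 'length')}")
    if kinship is not None and list(kinship.index) != samples:
        raise ValueError("sample axis mismatch between genotypes and kinship")

    rng = cfg.rng("expression")
    genes = _gene_layout(cfg, gt.snps, rng)
    planted = _plant_pairs(cfg, genes, gt.snps, rng,
                           trans_gene_weights=trans_gene_weights)

    n_g, n_s = cfg.n_genes, len(samples)
    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_g)
    sigma_g = np.sqrt(1.0 / np.exp(baseline) + cfg.dispersion)
    lib_offset = rng.normal(0.0, cfg.library_log_sd, n_s)
    log_mu = baseline[:, None] + lib_offset[None, :]

    # covariate effects on standardized covariate columns
    design = build_design(covariates, samples)
    cov_cols = [c for c in design.columns if c != "intercept"]
    C = design.matrix[:, [design.columns.index(c) for c in cov_cols]]
    C_std = (C - C.mean(axis=0)) / np.where(C.std(axis=0) > 0,
                                            C.std(axis=0), 1.0)
    sds = np.array([cfg.covariate_effect_sds.get(c.split("[")[0], 0.0)
                    for c in cov_cols])
    cov_eff = rng.normal(0.0, 1.0, (n_g, len(cov_cols))) * sds[None, :]
    log_mu += cov_eff @ C_std.T

    # planted genotype effects
    gene_idx = {g: i for i, g in enumerate(genes["gene_id"])}
    snp_idx = {s: i for i, s in enumerate(gt.snps["snp_id"])}
    eff_rows = []
    for r in planted.itertuples():
        gi, si = gene_idx[r.gene_id], snp_idx[r.snp_id]
        beta = cfg.effect_size_sd * sigma_g[gi] * rng.choice((-1.0, 1.0))
        d = gt.dosages[si].astype(float)
        nonadd = rng.random() < cfg.nonadditive_fraction
        if nonadd:
            x = (d == 1).astype(float)
        else:
            x = d
        log_mu[gi] += beta * (x - x.mean())
        eff_rows.append((r.snp_id, r.gene_id, beta, cfg.effect_size_sd,
                         r.cis_trans,
                         "het_shift" if nonadd else "additive"))

    if cfg.polygenic_var > 0:
        if kinship is None:
            raise ValueError("polygenic_var > 0 requires a kinship matrix")
        Lk = np.linalg.cholesky(kinship.to_numpy() +
                                1e-8 * np.eye(n_s))
        u = rng.normal(0.0, 1.0, (n_g, n_s)) @ Lk.T
        log_mu += np.sqrt(cfg.polygenic_var) * sigma_g[:, None] * u

    mu = np.exp(log_mu)
    if cfg.dispersion > 0:
        lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(genes=genes, counts=counts.astype(np.int64),
                     sample_ids=samples)
    ledger = TruthLedger(
        planted_pairs=pd.DataFrame(
            eff_rows, columns=["snp_id", "gene_id", "effect_size",
                               "effect_multiple", "cis_trans", "effect_type"]),
        covariate_effects=pd.DataFrame(
            cov_eff, index=genes["gene_id"], columns=cov_cols),
        block_assignments=block_assignments
        if block_assignments is not None else pd.DataFrame(
            columns=["snp_id", "block"]),
        meta={"rin_mean": 8.0, "rin_sd": 0.5, "age_mean": 160.0,
              "age_sd": 10.0, "baseline_log_mean": cfg.baseline_log_mean,
              "dispersion": cfg.dispersion, "seed": cfg.seed})
    return cm, ledger


# ------------------------------------------------------------- bundling

@dataclass
class SimulatedStudy:
    pedigree: pd.DataFrame
    genotypes: GenotypeTable
    covariates: pd.DataFrame
    counts: CountMatrix
    truth: TruthLedger


def simulate_study(cfg: SimulationConfig,
                   trans_gene_weights: np.ndarray | None = None
                   ) -> SimulatedStudy:
    """Full bundle: pedigree -> genotypes -> covariates -> expression."""
    ped = simulate_pedigree(cfg)
    gt, blocks = simulate_genotypes(cfg, ped)
    cov = simulate_covariates(cfg, gt.sample_ids)
    kin = None
    if cfg.polygenic_var > 0:
        from .kinship import kinship_from_pedigree
        kin = kinship_from_pedigree(ped, gt.sample_ids, cfg.n_generations)
    cm, truth = simulate_expression(cfg, gt, cov, kinship=kin,
                                    block_assignments=blocks,
                                    trans_gene_weights=trans_gene_weights)
    return SimulatedStudy(pedigree=ped, genotypes=gt, covariates=cov,
                          counts=cm, truth=truth)


def write_study(study: SimulatedStudy, out_dir: str) -> dict[str, str]:
    """Write all artifacts as TSV/CSV; returns path map."""
    import os

    from . import io as kio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "covariates": os.path.join(out_dir, "covariates.tsv"),
        "pedigree": os.path.join(out_dir, "pedigree.csv"),
        "truth_pairs": os.path.join(out_dir, "truth_planted_pairs.tsv"),
        "truth_blocks": os.path.join(out_dir, "truth_blocks.tsv"),
    }
    kio.write_genotypes(study.genotypes, paths["genotypes"])
    kio.write_counts(study.counts, paths["counts"])
    kio.write_covariates(study.covariates, paths["covariates"])
    kio.write_pedigree(study.pedigree, paths["pedigree"])
    study.truth.planted_pairs.to_csv(paths["truth_pairs"], sep="\t",
                                     index=False)
    study.truth.block_assignments.to_csv(paths["truth_blocks"], sep="\t",
                                         index=False)
    return paths
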