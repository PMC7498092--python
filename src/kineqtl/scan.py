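"""Kinship-whitened all-pairs cis/trans eQTL scan.

For every gene-SNP pair two association models are available:

* ``linear`` — expression regressed on minor-allele dosage (additive test),
* ``anova``  — expression regressed on genotype-class indicators (df =
  observed classes - 1), an F-test of any between-class difference.

Both adjust for a covariate design (breed, batch, RIN, age) and use the
pedigree relationship matrix K as the error covariance: all vectors are
whitened by the inverse Cholesky factor of K, after which ordinary least
squares applies. Statistics are computed batched (one matrix product per
gene-chunk x SNP set) but are contractually identical to per-pair
generalized-least-squares fits.

P-values are adjusted by Benjamini-Hochberg separately within each
(model x cis/trans) partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from statsmodels.stats.multitest import multipletests

from .datatypes import (GenotypeTable, NormalizedExpression, StudyDesign,
                        check_sample_alignment)

_COLLINEAR_TOL = 1e-8


@dataclass
class ScanConfig:
    cis_distance: int = 1_000_000
    models: tuple[str, ...] = ("linear", "anova")
    fdr_partition: str = "model_class"  # or "model": BH jointly over cis+trans
    ridge: float = 1e-8
    chunk_size: int = 512

    def __post_init__(self) -> None:
        if self.cis_distance <= 0:
            raise ValueError("cis_distance must be > 0")
        bad = set(self.models) - {"linear", "anova"}
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")


# ------------------------------------------------------------- primitives

def whiten_factor(K: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor L of K + ridge*mean(diag(K))*I (L L^T = K')."""
    K = np.asarray(K, float)
    Kr = K + ridge * np.mean(np.diag(K)) * np.eye(K.shape[0])
    try:
        return cholesky(Kr, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - scipy raises below
        raise ValueError(str(e))
    except Exception:
        w = np.linalg.eigvalsh(Kr)
        raise ValueError(
            f"kinship matrix is not positive definite after ridge "
            f"(smallest eigenvalue {w.min():.3e})")


def whiten(x: np.ndarray, K: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """L^{-1} x for L the Cholesky factor of (ridged) K; x may be a vector
    or a (n x m) matrix. Applying to K itself yields the identity."""
    L = whiten_factor(K, ridge)
    x = np.asarray(x, float)
    return solve_triangular(L, x, lower=True)


def residualize(x: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out the column space of C: x - C (C^T C)^{-1} C^T x."""
    C = np.asarray(C, float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    Q, _ = np.linalg.qr(C)
    x = np.asarray(x, float)
    return x - Q @ (Q.T @ x)


def classify_cis_trans(snp_chrom: str, snp_pos: int, gene_chrom: str,
                       gene_start: int, gene_end: int,
                       cis_distance: int = 1_000_000) -> str:
    """cis iff same chromosome and pos within [start - d, end + d]
    (1-based, boundary inclusive); else trans."""
    if str(snp_chrom) == str(gene_chrom) and \
            gene_start - cis_distance <= snp_pos <= gene_end + cis_distance:
        return "cis"
    return "trans"


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pair_count(n_genes: int, n_snps: int) -> int:
    """Number of gene-SNP tests per model in an all-pairs scan."""
    return int(n_genes) * int(n_snps)


# --------------------------------------------------------- batched engine

@dataclass
class _Prepared:
    """Whitened/residualized quantities reused across gene chunks."""
    Q: np.ndarray            # orthonormal basis of whitened design
    Gr: np.ndarray           # residualized whitened dosages (n x S)
    g_norm: np.ndarray       # column norms of Gr
    g_ok: np.ndarray         # testable for linear model
    Qd: np.ndarray | None    # (S x n x 2) orthonormal genotype-class bases
    df_num: np.ndarray | None
    a_ok: np.ndarray | None  # testable for anova model
    n: int
    k: int


def _prepare(G: np.ndarray, C: np.ndarray, L: np.ndarray,
             anova: bool) -> _Prepared:
    n, k = C.shape
    Cw = solve_triangular(L, C, lower=True)
    if np.linalg.matrix_rank(Cw) < k:
        raise ValueError("design matrix is rank deficient after whitening")
    Q, _ = np.linalg.qr(Cw)

    Gw = solve_triangular(L, G, lower=True)
    Gr = Gw - Q @ (Q.T @ Gw)
    g_norm = np.linalg.norm(Gr, axis=0)
    scale = np.linalg.norm(Gw, axis=0)
    g_ok = g_norm > _COLLINEAR_TOL * np.maximum(scale, 1.0)

    Qd = df_num = a_ok = None
    if anova:
        S = G.shape[1]
        Qd = np.zeros((S, n, 2))
        df_num = np.zeros(S, dtype=int)
        a_ok = np.zeros(S, dtype=bool)
        for s in range(S):
            classes = np.unique(G[:, s])
            if classes.size < 2:
                continue
            D = np.column_stack([(G[:, s] == c).astype(float)
                                 for c in classes[1:]])
            Dw = solve_triangular(L, D, lower=True)
            Dr = Dw - Q @ (Q.T @ Dw)
            U, sv, _ = np.linalg.svd(Dr, full_matrices=False)
            rank = int(np.sum(sv > _COLLINEAR_TOL * max(sv[0], 1.0))) \
                if sv.size else 0
            if rank != classes.size - 1:
                continue  # genotype classes collinear with covariates
            Qd[s, :, :rank] = U[:, :rank]
            df_num[s] = rank
            a_ok[s] = True
    return _Prepared(Q=Q, Gr=Gr, g_norm=g_norm, g_ok=g_ok, Qd=Qd,
                     df_num=df_num, a_ok=a_ok, n=n, k=k)


def _chunk_stats(Y: np.ndarray, prep: _Prepared, L: np.ndarray,
                 models: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Statistics for a gene chunk Y (n x Gc) against all prepared SNPs."""
    n, k = prep.n, prep.k
    Yw = solve_triangular(L, Y, lower=True)
    Yr = Yw - prep.Q @ (prep.Q.T @ Yw)
    y_norm = np.linalg.norm(Yr, axis=0)
    y_ok = y_norm > _COLLINEAR_TOL * np.maximum(np.linalg.norm(Yw, axis=0), 1.0)
    out: dict[str, np.ndarray] = {"y_ok": y_ok}

    if "linear" in models:
        df = n - k - 1
        denom = np.outer(np.where(y_ok, y_norm, 1.0),
                         np.where(prep.g_ok, prep.g_norm, 1.0))
        R = (Yr.T @ prep.Gr) / denom
        R = np.clip(R, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = R * np.sqrt(df / np.maximum(1.0 - R * R, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        slope = (Yr.T @ prep.Gr) / np.where(prep.g_ok, prep.g_norm, 1.0)[None, :] ** 2
        ok = np.outer(y_ok, prep.g_ok)
        out.update(lin_t=np.where(ok, t, np.nan),
                   lin_p=np.where(ok, p, np.nan),
                   lin_slope=np.where(ok, slope, np.nan),
                   lin_df=df, lin_r=np.where(ok, R, np.nan))

    if "anova" in models:
        # explained SS per (SNP, gene): sum_k (Qd_k . Yr_g)^2
        T = np.einsum("snk,ng->skg", prep.Qd, Yr)
        ss_exp = np.sum(T * T, axis=1).T  # (Gc x S)
        rss0 = y_norm ** 2
        df_num = prep.df_num.astype(float)
        df_den = n - k - df_num
        rss1 = np.maximum(rss0[:, None] - ss_exp, 0.0)
        ok = np.outer(y_ok, prep.a_ok) & (df_den > 0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_exp / np.maximum(df_num, 1.0)[None, :]) / \
                np.maximum(rss1 / np.maximum(df_den, 1.0)[None, :], 1e-300)
        p = stats.f.sf(F, df_num[None, :], df_den[None, :])
        out.update(anova_F=np.where(ok, F, np.nan),
                   anova_p=np.where(ok, p, np.nan),
                   anova_df_num=prep.df_num, anova_df_den=df_den)
    return out


def scan_pvalues(expr_values: np.ndarray, dosages: np.ndarray,
                 C: np.ndarray, K: np.ndarray,
                 cfg: ScanConfig | None = None) -> dict[str, np.ndarray]:
    """Fast path: p-value (and statistic) matrices, shape (n_genes x n_snps),
    without building per-pair records. Used by the permutation null."""
    cfg = cfg or ScanConfig()
    Y = np.asarray(expr_values, float).T  # (n x G)
    G = np.asarray(dosages, float).T      # (n x S)
    L = whiten_factor(K, cfg.ridge)
    prep = _prepare(G, C, L, anova="anova" in cfg.models)
    res: dict[str, list[np.ndarray]] = {}
    for lo in range(0, Y.shape[1], cfg.chunk_size):
        st = _chunk_stats(Y[:, lo:lo + cfg.chunk_size], prep, L, cfg.models)
        for key in ("lin_t", "lin_p", "lin_slope", "lin_r",
                    "anova_F", "anova_p"):
            if key in st:
                res.setdefault(key, []).append(st[key])
    out = {k: np.vstack(v) for k, v in res.items()}
    if "anova" in cfg.models:
        out["anova_df_num"] = prep.df_num
        out["anova_df_den"] = prep.n - prep.k - prep.df_num
    if "linear" in cfg.models:
        out["lin_df"] = prep.n - prep.k - 1
    return out


# ------------------------------------------------------- per-pair surface

def linear_test(y: np.ndarray, g: np.ndarray, C: np.ndarray,
                K: np.ndarray | None = None,
                ridge: float = 1e-8) -> tuple[float, int, float, float]:
    """Single-pair additive test: returns (t, df, slope, p).

    With K = identity and C = intercept only this reduces exactly to the
    textbook Pearson-correlation t-test.
    """
    n = len(y)
    K = np.eye(n) if K is None else K
    out = scan_pvalues(np.asarray(y, float)[None, :],
                       np.asarray(g, float)[None, :], C, K,
                       ScanConfig(models=("linear",), ridge=ridge))
    t = float(out["lin_t"][0, 0])
    if not np.isfinite(t):
        raise ValueError("pair untestable: genotype or expression collinear "
                         "with covariates")
    return t, int(out["lin_df"]), float(out["lin_slope"][0, 0]), \
        float(out["lin_p"][0, 0])


def anova_test(y: np.ndarray, g: np.ndarray, C: np.ndarray,
               K: np.ndarray | None = None,
               ridge: float = 1e-8) -> tuple[float, int, int, float]:
    """Single-pair genotype-class F-test: returns (F, df_num, df_den, p)."""
    n = len(y)
    K = np.eye(n) if K is None else K
    if np.unique(g).size < 2:
        raise ValueError("pair untestable: single observed genotype class")
    out = scan_pvalues(np.asarray(y, float)[None, :],
                       np.asarray(g, float)[None, :], C, K,
                       ScanConfig(models=("anova",), ridge=ridge))
    F = float(out["anova_F"][0, 0])
    if not np.isfinite(F):
        raise ValueError("pair untestable: genotype classes collinear with "
                         "covariates")
    return F, int(out["anova_df_num"][0]), int(out["anova_df_den"][0]), \
        float(out["anova_p"][0, 0])


def orthonormalize_for_viz(y: np.ndarray, g: np.ndarray, C: np.ndarray,
                           K: np.ndarray | None = None,
                           ridge: float = 1e-8
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Centered, scaled, whitened, covariate-orthogonalized unit-norm
    coordinates (y*, g*) whose dot product equals the scan's partial
    correlation. These are the coordinates on which the linear model's
    relationship is actually fitted, hence the right scale for scatter
    plots of top pairs."""
    n = len(y)
    K = np.eye(n) if K is None else K
    L = whiten_factor(K, ridge)
    C = np.asarray(C, float)
    Cw = solve_triangular(L, C, lower=True)
    Q, _ = np.linalg.qr(Cw)

    def transform(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        v = (v - v.mean())
        sd = v.std(ddof=1)
        if sd > 0:
            v = v / sd
        vw = solve_triangular(L, v, lower=True)
        vr = vw - Q @ (Q.T @ vw)
        nrm = np.linalg.norm(vr)
        if nrm < _COLLINEAR_TOL:
            raise ValueError("vector collinear with covariates; no "
                             "orthonormal coordinates exist")
        return vr / nrm

    return transform(y), transform(g)


# ------------------------------------------------------------ full scan

def cis_trans_matrix(genes: pd.DataFrame, snps: pd.DataFrame,
                     cis_distance: int) -> np.ndarray:
    """Boolean (genes x snps) matrix, True where the pair is cis."""
    g_chrom = genes["chrom"].astype(str).to_numpy()
    s_chrom = snps["chrom"].astype(str).to_numpy()
    same = g_chrom[:, None] == s_chrom[None, :]
    pos = snps["pos"].to_numpy()
    lo = genes["start"].to_numpy()[:, None] - cis_distance
    hi = genes["end"].to_numpy()[:, None] + cis_distance
    return same & (pos[None, :] >= lo) & (pos[None, :] <= hi)


def run_scan(expr: NormalizedExpression, gt: GenotypeTable,
             design: StudyDesign, K: pd.DataFrame | np.ndarray,
             cfg: ScanConfig | None = None) -> pd.DataFrame:
    """All-pairs scan producing one record per gene-SNP pair per model.

    Columns: snp_id, gene_id, model, cis_trans, statistic, df_num, df_den,
    effect, p_value, fdr, reason. Untestable pairs keep their record with a
    reason code and NaN statistics, so the count contract (genes x SNPs per
    model) always holds. BH-FDR is applied within each (model x cis/trans)
    partition (or per model when cfg.fdr_partition == "model").
    """
    cfg = cfg or ScanConfig()
    if isinstance(K, pd.DataFrame):
        if list(K.index) != list(expr.sample_ids):
            K = K.loc[expr.sample_ids, expr.sample_ids]
        K = K.to_numpy()
    check_sample_alignment(expr, gt, design)

    out = scan_pvalues(expr.values, gt.dosages, design.matrix, K, cfg)
    nG, nS = expr.n_genes, gt.n_snps
    cis = cis_trans_matrix(expr.genes, gt.snps, cfg.cis_distance)

    gene_ids = np.repeat(expr.genes["gene_id"].to_numpy(), nS)
    snp_ids = np.tile(gt.snps["snp_id"].to_numpy(), nG)
    cls = np.where(cis.ravel(), "cis", "trans")

    frames = []
    for model in cfg.models:
        if model == "linear":
            stat = out["lin_t"].ravel()
            p = out["lin_p"].ravel()
            eff = out["lin_slope"].ravel()
            df_num = np.ones(nG * nS)
            df_den = np.full(nG * nS, float(out["lin_df"]))
        else:
            stat = out["anova_F"].ravel()
            p = out["anova_p"].ravel()
            eff = np.full(nG * nS, np.nan)
            df_num = np.tile(out["anova_df_num"].astype(float), nG)
            df_den = np.tile(out["anova_df_den"].astype(float), nG)
        reason = np.where(np.isfinite(p), "", "untestable_degenerate")
        df = pd.DataFrame({
            "snp_id": snp_ids, "gene_id": gene_ids, "model": model,
            "cis_trans": cls, "statistic": stat, "df_num": df_num,
            "df_den": df_den, "effect": eff, "p_value": p,
            "fdr": np.nan, "reason": reason})
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)

    part_cols = ["model"] if cfg.fdr_partition == "model" \
        else ["model", "cis_trans"]
    for _, idx in records.groupby(part_cols, sort=False).groups.items():
        records.loc[idx, "fdr"] = bh_fdr(records.loc[idx, "p_value"].to_numpy())
    return records


def scan_summary(records: pd.DataFrame, alpha: float = 0.01) -> dict:
    """Per-partition test counts, untestable counts and low-p counts."""
    out: dict[str, dict] = {}
    for (model, cls), sub in records.groupby(["model", "cis_trans"]):
        out[f"{model}:{cls}"] = {
            "n_tests": int(len(sub)),
            "n_untestable": int((sub["reason"] != "").sum()),
            f"n_p_below_{alpha}": int((sub["p_value"] < alpha).sum()),
        }
    return out
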