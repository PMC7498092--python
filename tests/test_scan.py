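from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_fixture, random_spd
from kineqtl.datatypes import (GenotypeTable, NormalizedExpression,
                               build_design)
from kineqtl.scan import (ScanConfig, anova_test, bh_fdr, classify_cis_trans,
                          linear_test, orthonormalize_for_viz, pair_count,
                          residualize, run_scan, scan_pvalues, whiten)
from oracles import bh_stepup_naive, gls_anova, gls_linear


class TestWhiten:
    def test_identity_covariance_is_noop(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        np.testing.assert_allclose(whiten(x, np.eye(10), ridge=0.0), x)

    def test_scaled_identity_divides(self):
        x = np.arange(6.0)
        np.testing.assert_allclose(whiten(x, 4 * np.eye(6), ridge=0.0), x / 2)

    def test_whitening_k_yields_identity(self):
        rng = np.random.default_rng(1)
        K = random_spd(8, rng)
        L = np.linalg.cholesky(K)
        W = whiten(K, K, ridge=0.0)
        # L^{-1} K = L^T, so whitening twice (both sides) gives identity
        np.testing.assert_allclose(
            np.linalg.solve(L, W.T), np.eye(8), atol=1e-10)

    def test_empirical_covariance_whitened_to_identity(self):
        rng = np.random.default_rng(2)
        n = 6
        K = random_spd(n, rng)
        L = np.linalg.cholesky(K)
        draws = rng.normal(size=(200_000, n)) @ L.T
        W = np.linalg.solve(L, draws.T)
        emp = np.cov(W)
        np.testing.assert_allclose(emp, np.eye(n), atol=0.02)

    def test_non_psd_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(Exception):
            whiten(np.ones(2), K)


class TestResidualize:
    def test_orthogonal_input_unchanged(self):
        C = np.ones((6, 1))
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        np.testing.assert_allclose(residualize(x, C), x, atol=1e-12)

    def test_column_annihilated(self):
        rng = np.random.default_rng(3)
        C = np.column_stack([np.ones(8), rng.normal(size=8)])
        np.testing.assert_allclose(residualize(C[:, 1], C), 0.0, atol=1e-12)

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        C = np.column_stack([np.ones(20), rng.normal(size=(20, 4))])
        r = residualize(rng.normal(size=20), C)
        assert np.abs(C.T @ r).max() < 1e-10

    def test_rank_deficient_rejected(self):
        C = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank"):
            residualize(np.arange(5.0), C)


class TestLinearTest:
    def test_perfect_fit(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2])
        t, df, slope, p = linear_test(g, g, np.ones((9, 1)))
        assert p < 1e-12 and slope == pytest.approx(1.0)

    def test_reduces_to_pearson_t_test(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        g = rng.integers(0, 3, 30).astype(float)
        t, df, _, p = linear_test(y, g, np.ones((30, 1)), np.eye(30))
        from scipy import stats
        r, p_ref = stats.pearsonr(y, g)
        assert df == 28
        assert t == pytest.approx(r * np.sqrt(28 / (1 - r * r)), abs=1e-8)
        assert p == pytest.approx(p_ref, rel=1e-8)

    def test_matches_gls_oracle_small(self):
        rng = np.random.default_rng(6)
        Y, G, C, K = random_fixture(rng, n=12, n_genes=1, n_snps=1)
        t, df, slope, p = linear_test(Y[0], G[0], C, K)
        t_o, df_o, slope_o, p_o = gls_linear(Y[0], G[0].astype(float), C, K)
        assert t == pytest.approx(t_o, abs=1e-8)
        assert df == df_o
        assert slope == pytest.approx(slope_o, abs=1e-8)
        assert p == pytest.approx(p_o, rel=1e-6)

    def test_null_pvalues_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        n = 38
        Y = rng.normal(size=(100, n))
        G = rng.integers(0, 3, size=(100, n))
        out = scan_pvalues(Y, G, np.ones((n, 1)), np.eye(n),
                           ScanConfig(models=("linear",)))
        p = out["lin_p"].ravel()
        assert stats.kstest(p[np.isfinite(p)], "uniform").pvalue > 0.01

    def test_collinear_genotype_untestable(self):
        n = 12
        C = np.column_stack([np.ones(n), np.r_[np.zeros(6), np.ones(6)]])
        g = C[:, 1] * 2  # dosage fully explained by the covariate
        with pytest.raises(ValueError, match="untestable"):
            linear_test(np.random.default_rng(0).normal(size=n), g, C)


class TestAnovaTest:
    def test_equal_class_means_give_zero_f(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # same mean per class
        F, df_num, df_den, p = anova_test(y, g, np.ones((6, 1)))
        assert F == pytest.approx(0.0, abs=1e-12)
        assert (df_num, df_den) == (2, 3)
        assert p == pytest.approx(1.0)

    def test_two_classes_equal_squared_t(self):
        rng = np.random.default_rng(8)
        n = 16
        y = rng.normal(size=n)
        g = np.repeat([0.0, 2.0], n // 2)
        F, df_num, df_den, p_f = anova_test(y, g, np.ones((n, 1)))
        t, df, _, p_t = linear_test(y, g, np.ones((n, 1)))
        assert df_num == 1
        assert F == pytest.approx(t * t, abs=1e-8)
        assert p_f == pytest.approx(p_t, rel=1e-8)

    def test_matches_gls_oracle_small(self):
        rng = np.random.default_rng(9)
        Y, G, C, K = random_fixture(rng, n=14, n_genes=1, n_snps=1)
        F, df_num, df_den, p = anova_test(Y[0], G[0], C, K)
        F_o, dn_o, dd_o, p_o = gls_anova(Y[0], G[0], C, K)
        assert F == pytest.approx(F_o, abs=1e-8)
        assert (df_num, df_den) == (dn_o, dd_o)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single observed"):
            anova_test(np.arange(6.0), np.ones(6), np.ones((6, 1)))

    def test_null_pvalues_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(10)
        n = 38
        Y = rng.normal(size=(100, n))
        G = rng.integers(0, 3, size=(100, n))
        out = scan_pvalues(Y, G, np.ones((n, 1)), np.eye(n),
                           ScanConfig(models=("anova",)))
        p = out["anova_p"].ravel()
        assert stats.kstest(p[np.isfinite(p)], "uniform").pvalue > 0.01


class TestClassifyCisTrans:
    @pytest.mark.parametrize("snp, gene, expected", [
        (("1", 4_000_000), ("1", 5_000_000, 5_002_000), "cis"),   # boundary
        (("1", 3_999_999), ("1", 5_000_000, 5_002_000), "trans"),  # 1bp out
        (("1", 6_002_000), ("1", 5_000_000, 5_002_000), "cis"),   # end side
        (("2", 5_000_000), ("1", 5_000_000, 5_002_000), "trans"),  # other chrom
        (("1", 5_001_000), ("1", 5_000_000, 5_002_000), "cis"),   # inside
    ])
    def test_window_rule(self, snp, gene, expected):
        assert classify_cis_trans(snp[0], snp[1], gene[0], gene[1], gene[2],
                                  cis_distance=1_000_000) == expected


class TestBhFdr:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_single(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)
        np.testing.assert_allclose(bh_fdr(np.array([0.123])), [0.123])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_naive_stepup_and_dominates_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_stepup_naive(p), atol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()


class TestRunScanBatched:
    def _study_pieces(self, study):
        from kineqtl.expression import prepare_expression
        from kineqtl.kinship import kinship_from_pedigree
        expr, _ = prepare_expression(study.counts)
        design = build_design(study.covariates, expr.sample_ids)
        K = kinship_from_pedigree(study.pedigree, expr.sample_ids)
        return expr, design, K

    def test_pair_count_contract(self):
        assert pair_count(1425, 19179) == 27_330_075

    def test_record_count_and_fdr_partitions(self, small_study):
        expr, design, K = self._study_pieces(small_study)
        gt = small_study.genotypes.subset(np.arange(40))
        rec = run_scan(expr, gt, design, K)
        assert len(rec) == 2 * expr.n_genes * gt.n_snps
        for _, sub in rec.groupby(["model", "cis_trans"]):
            ok = np.isfinite(sub["p_value"])
            assert (sub.loc[ok, "fdr"] >= sub.loc[ok, "p_value"] - 1e-12).all()
            np.testing.assert_allclose(
                sub.loc[ok, "fdr"],
                bh_fdr(sub.loc[ok, "p_value"].to_numpy()))

    def test_batched_equals_per_pair_oracle(self, small_study):
        expr, design, K = self._study_pieces(small_study)
        gt = small_study.genotypes.subset(np.arange(3))
        rec = run_scan(expr, gt, design, K,
                       ScanConfig(models=("linear", "anova")))
        Kn = K.to_numpy()
        for row in rec.head(40).itertuples():
            gi = expr.genes.index[expr.genes["gene_id"] == row.gene_id][0]
            si = gt.snps.index[gt.snps["snp_id"] == row.snp_id][0]
            y, g = expr.values[gi], gt.dosages[si].astype(float)
            if row.model == "linear":
                t_o, _, _, _ = gls_linear(y, g, design.matrix, Kn)
                assert row.statistic == pytest.approx(t_o, abs=1e-8)
            else:
                F_o, _, _, _ = gls_anova(y, g, design.matrix, Kn)
                assert row.statistic == pytest.approx(F_o, abs=1e-8)

    def test_chunking_invariance(self, small_study):
        expr, design, K = self._study_pieces(small_study)
        gt = small_study.genotypes.subset(np.arange(30))
        recs = [run_scan(expr, gt, design, K, ScanConfig(chunk_size=c))
                for c in (1, 7, 512)]
        for other in recs[1:]:
            pd.testing.assert_frame_equal(recs[0], other)

    def test_kinship_scale_invariance(self):
        rng = np.random.default_rng(11)
        Y, G, C, K = random_fixture(rng, n=20, n_genes=3, n_snps=5)
        a = scan_pvalues(Y, G, C, K)
        b = scan_pvalues(Y, G, C, 7.3 * K)
        np.testing.assert_allclose(a["lin_t"], b["lin_t"], atol=1e-9)
        np.testing.assert_allclose(a["anova_F"], b["anova_F"], atol=1e-9)

    def test_common_permutation_invariance(self):
        rng = np.random.default_rng(12)
        Y, G, C, K = random_fixture(rng, n=20, n_genes=3, n_snps=5)
        perm = rng.permutation(20)
        a = scan_pvalues(Y, G, C, K)
        b = scan_pvalues(Y[:, perm], G[:, perm], C[perm],
                         K[np.ix_(perm, perm)])
        np.testing.assert_allclose(a["lin_t"], b["lin_t"], atol=1e-8)
        np.testing.assert_allclose(a["anova_F"], b["anova_F"], atol=1e-8)

    def test_misaligned_samples_rejected(self, small_study):
        expr, design, K = self._study_pieces(small_study)
        gt = small_study.genotypes.subset(np.arange(5))
        gt.sample_ids[0] = "intruder"
        with pytest.raises(ValueError, match="misalignment"):
            run_scan(expr, gt, design, K)


class TestOrthonormalizeForViz:
    def test_reduces_to_standardized_correlation(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=25)
        g = rng.integers(0, 3, 25).astype(float)
        ys, gs = orthonormalize_for_viz(y, g, np.ones((25, 1)))
        from scipy import stats
        r, _ = stats.pearsonr(y, g)
        assert float(ys @ gs) == pytest.approx(r, abs=1e-10)

    def test_unit_norm_contract(self):
        rng = np.random.default_rng(14)
        Y, G, C, K = random_fixture(rng, n=22, n_genes=1, n_snps=1)
        ys, gs = orthonormalize_for_viz(Y[0], G[0].astype(float), C, K)
        assert np.linalg.norm(ys) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(gs) == pytest.approx(1.0, abs=1e-12)

    def test_dot_product_reproduces_scan_statistic(self):
        rng = np.random.default_rng(15)
        Y, G, C, K = random_fixture(rng, n=24, n_genes=1, n_snps=1)
        t, df, _, _ = linear_test(Y[0], G[0], C, K)
        ys, gs = orthonormalize_for_viz(Y[0], G[0].astype(float), C, K)
        r = float(ys @ gs)
        assert r * np.sqrt(df / (1 - r * r)) == pytest.approx(t, abs=1e-8)
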