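from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kineqtl.datatypes import build_design
from kineqtl.expression import prepare_expression
from kineqtl.kinship import a_matrix, kinship_from_pedigree
from kineqtl.scan import ScanConfig, cis_trans_matrix, scan_pvalues
from kineqtl.simulate import (SimulationConfig, simulate_covariates,
                              simulate_expression, simulate_genotypes,
                              simulate_pedigree, simulate_study)


class TestSimulatePedigree:
    def test_unrelated_option_gives_identity_a_matrix(self):
        cfg = SimulationConfig(unrelated=True, seed=1)
        ped = simulate_pedigree(cfg)
        assert (ped[["sire", "dam"]] == "0").all().all()
        K = kinship_from_pedigree(ped, ped["animal"].tolist())
        np.testing.assert_allclose(K.to_numpy(), np.eye(len(ped)))

    def test_determinism(self):
        cfg = SimulationConfig(seed=1)
        pd.testing.assert_frame_equal(simulate_pedigree(cfg),
                                      simulate_pedigree(cfg))

    def test_final_generation_is_study_and_has_full_sibs(self):
        cfg = SimulationConfig(seed=2)
        ped = simulate_pedigree(cfg)
        study = [a for a in ped["animal"] if a.startswith(("g1_s", "g2_s"))]
        assert len(study) == 38
        fams = ped[ped["animal"].isin(study)].groupby(["sire", "dam"]).size()
        assert (fams >= 2).any()  # at least one full-sib pair
        A = kinship_from_pedigree(ped, study)
        sib_pair = fams[fams >= 2].index[0]
        sibs = ped[(ped["sire"] == sib_pair[0]) &
                   (ped["dam"] == sib_pair[1])]["animal"].tolist()[:2]
        assert A.loc[sibs[0], sibs[1]] >= 0.5 - 1e-12

    def test_spans_four_generations(self):
        ped = simulate_pedigree(SimulationConfig(seed=3))
        gens = {a.split("_")[1][:2] for a in ped["animal"]
                if "_G" in a}
        assert {"G0", "G1", "G2", "G3"} <= gens


class TestSimulateGenotypes:
    def test_determinism(self):
        cfg = SimulationConfig(n_snps=50, n_genes=5, seed=4)
        ped = simulate_pedigree(cfg)
        gt1, b1 = simulate_genotypes(cfg, ped)
        gt2, b2 = simulate_genotypes(cfg, ped)
        np.testing.assert_array_equal(gt1.dosages, gt2.dosages)
        pd.testing.assert_frame_equal(b1, b2)

    def test_block_members_in_high_ld(self):
        cfg = SimulationConfig(n_snps=80, ld_block_size_mean=3.0, seed=5)
        ped = simulate_pedigree(cfg)
        gt, blocks = simulate_genotypes(cfg, ped)
        from oracles import pearson_r2
        for _, sub in blocks.groupby("block"):
            ids = sub["snp_id"].tolist()
            idx = {s: i for i, s in enumerate(gt.snps["snp_id"])}
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    da, db = gt.dosages[idx[a]], gt.dosages[idx[b]]
                    if np.ptp(da) == 0 or np.ptp(db) == 0:
                        assert np.array_equal(da, db)
                    else:
                        assert pearson_r2(da, db) >= 0.9 - 1e-12

    def test_mendelian_consistency_every_snp(self):
        """No (child, parents) dosage triple is incompatible: the child's
        dosage must lie in [#{parents hom-minor}, 2 - #{parents hom-major}]."""
        cfg = SimulationConfig(n_snps=80, ld_block_size_mean=2.5, seed=6)
        ped = simulate_pedigree(cfg)
        gt, _ = simulate_genotypes(cfg, ped, include_ancestors=True)
        idx = {s: j for j, s in enumerate(gt.sample_ids)}
        checked = 0
        for r in ped.itertuples():
            if r.sire == "0" or r.dam == "0":
                continue
            dc = gt.dosages[:, idx[r.animal]]
            ds = gt.dosages[:, idx[r.sire]]
            dd = gt.dosages[:, idx[r.dam]]
            lo = (ds == 2).astype(int) + (dd == 2).astype(int)
            hi = 2 - (ds == 0).astype(int) - (dd == 0).astype(int)
            assert ((dc >= lo) & (dc <= hi)).all()
            checked += 1
        assert checked >= 38  # every non-founder was audited

    def test_ancestor_view_consistent_with_study_view(self):
        cfg = SimulationConfig(n_snps=40, seed=6)
        ped = simulate_pedigree(cfg)
        gt_all, _ = simulate_genotypes(cfg, ped, include_ancestors=True)
        gt, _ = simulate_genotypes(cfg, ped)
        cols = [gt_all.sample_ids.index(s) for s in gt.sample_ids]
        np.testing.assert_array_equal(gt_all.dosages[:, cols], gt.dosages)

    def test_founder_frequency_recovered_at_large_n(self):
        # founders only, many samples: sample MAF within 3 binomial sd
        cfg = SimulationConfig(n_samples_group1=200, n_samples_group2=200,
                               n_snps=30, ld_block_size_mean=1.0,
                               unrelated=True, seed=7)
        ped = simulate_pedigree(cfg)
        gt, _ = simulate_genotypes(cfg, ped)
        n_alleles = 2 * gt.n_samples
        for i in range(gt.n_snps):
            f = gt.dosages[i].sum() / n_alleles
            # freq drawn in [0.35, 0.5]; binomial sd at the extreme
            sd = np.sqrt(0.5 * 0.5 / n_alleles)
            assert 0.35 - 3 * sd <= f <= 0.5 + 3 * sd


class TestSimulateCovariates:
    def test_group_sizes_and_batch_levels(self):
        cfg = SimulationConfig(seed=8)
        cov = simulate_covariates(cfg)
        assert (cov["breed"] == "duroc").sum() == 11
        assert (cov["breed"] == "landrace").sum() == 27
        assert cov["batch"].nunique() == 5

    def test_zero_covariate_effects_leave_expression_independent(self):
        cfg = SimulationConfig(
            n_snps=40, n_genes=60, seed=9,
            covariate_effect_sds={"breed": 0.0, "batch": 0.0, "rin": 0.0,
                                  "age_days": 0.0})
        study = simulate_study(cfg)
        assert (study.truth.covariate_effects.to_numpy() == 0).all()
        # regression of expression on breed: t-statistics ~ null
        expr, _ = prepare_expression(study.counts)
        breed = (study.covariates["breed"] == "duroc").to_numpy(float)
        out = scan_pvalues(expr.values, breed[None, :].astype(int) * 2,
                           np.ones((38, 1)), np.eye(38),
                           ScanConfig(models=("linear",)))
        frac = (out["lin_p"] < 0.05).mean()
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / expr.n_genes)


class TestSimulateExpression:
    def test_determinism_bitwise(self):
        cfg = SimulationConfig(n_snps=40, n_genes=20, n_cis_effects=2,
                               n_trans_effects=2, seed=10)
        s1, s2 = simulate_study(cfg), simulate_study(cfg)
        np.testing.assert_array_equal(s1.counts.counts, s2.counts.counts)
        pd.testing.assert_frame_equal(s1.truth.planted_pairs,
                                      s2.truth.planted_pairs)

    def test_planted_labels_respect_cis_window(self, small_study):
        truth = small_study.truth.planted_pairs
        genes = small_study.counts.genes
        snps = small_study.genotypes.snps
        cis = cis_trans_matrix(genes, snps, 1_000_000)
        gi = {g: i for i, g in enumerate(genes["gene_id"])}
        si = {s: i for i, s in enumerate(snps["snp_id"])}
        for r in truth.itertuples():
            expected = "cis" if cis[gi[r.gene_id], si[r.snp_id]] else "trans"
            assert r.cis_trans == expected

    def test_dimension_mismatch_named(self):
        cfg = SimulationConfig(n_snps=30, n_genes=10, seed=11)
        ped = simulate_pedigree(cfg)
        gt, _ = simulate_genotypes(cfg, ped)
        cov = simulate_covariates(cfg)
        cov = cov.iloc[:-1]  # drop one sample
        with pytest.raises(ValueError, match="sample axis"):
            simulate_expression(cfg, gt, cov)

    def test_polygenic_term_requires_kinship(self):
        cfg = SimulationConfig(n_snps=20, n_genes=5, polygenic_var=0.5,
                               seed=12)
        ped = simulate_pedigree(cfg)
        gt, _ = simulate_genotypes(cfg, ped)
        cov = simulate_covariates(cfg)
        with pytest.raises(ValueError, match="kinship"):
            simulate_expression(cfg, gt, cov)

    def test_planted_effect_detectable(self, small_study):
        """A planted pair with |effect| = 2 noise sd at n = 38 lands in the
        top 1% of its scan."""
        expr, _ = prepare_expression(small_study.counts)
        design = build_design(small_study.covariates, expr.sample_ids)
        out = scan_pvalues(expr.values, small_study.genotypes.dosages,
                           design.matrix, np.eye(38),
                           ScanConfig(models=("linear",)))
        p = out["lin_p"]
        gi = {g: i for i, g in enumerate(expr.genes["gene_id"])}
        si = {s: i for i, s in enumerate(small_study.genotypes.snps["snp_id"])}
        thresh = np.nanquantile(p, 0.01)
        additive = small_study.truth.planted_pairs.query(
            "effect_type == 'additive'")
        hits = sum(p[gi[r.gene_id], si[r.snp_id]] <= thresh
                   for r in additive.itertuples()
                   if r.gene_id in gi)
        n_present = sum(r.gene_id in gi for r in additive.itertuples())
        assert hits >= 0.8 * n_present


def test_null_scan_calibration(null_study):
    """No planted effects, no polygenic term: p < 0.01 fraction within 3
    binomial sd of 0.01 and KS-uniform."""
    from scipy import stats
    expr, _ = prepare_expression(null_study.counts)
    design = build_design(null_study.covariates, expr.sample_ids)
    out = scan_pvalues(expr.values, null_study.genotypes.dosages,
                       design.matrix, np.eye(38))
    p = out["lin_p"].ravel()
    p = p[np.isfinite(p)]
    assert p.size >= 5000
    frac = (p < 0.01).mean()
    assert abs(frac - 0.01) <= 3 * np.sqrt(0.01 * 0.99 / p.size) + 1e-12
    assert stats.kstest(p, "uniform").pvalue > 0.01
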