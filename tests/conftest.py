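from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kineqtl.datatypes import GenotypeTable, build_design
from kineqtl.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    A = rng.normal(size=(n, n))
    return A @ A.T / n + np.eye(n)


def random_fixture(rng: np.random.Generator, n: int = 38, n_genes: int = 5,
                   n_snps: int = 20):
    """Raw arrays for oracle-equivalence checks: expression, dosages with
    all three genotype classes, a full covariate design, SPD kinship."""
    Y = rng.normal(size=(n_genes, n))
    G = rng.integers(0, 3, size=(n_snps, n))
    for i in range(n_snps):  # guarantee >= 2 classes per SNP
        while np.unique(G[i]).size < 2:
            G[i] = rng.integers(0, 3, size=n)
    cov = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "breed": rng.choice(["duroc", "landrace"], n),
        "batch": rng.choice([f"b{i}" for i in range(5)], n),
        "rin": rng.normal(8, 0.5, n),
        "age_days": rng.normal(160, 10, n)})
    # re-draw factors until the design is full rank (tiny n edge case)
    while True:
        try:
            design = build_design(cov)
            break
        except ValueError:
            cov["batch"] = rng.choice([f"b{i}" for i in range(5)], n)
    K = random_spd(n, rng)
    return Y, G, design.matrix, K


@pytest.fixture(scope="session")
def small_study():
    """38-sample synthetic study with planted cis and trans effects."""
    cfg = SimulationConfig(n_snps=120, n_genes=30, n_cis_effects=3,
                           n_trans_effects=5, seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No planted effects, no polygenic signal: scan p-values uniform."""
    cfg = SimulationConfig(n_snps=150, n_genes=40, n_cis_effects=0,
                           n_trans_effects=0, seed=19)
    return simulate_study(cfg)


@pytest.fixture
def tiny_genotypes() -> GenotypeTable:
    snps = pd.DataFrame({
        "snp_id": ["a", "b", "c", "d"],
        "chrom": ["1", "1", "1", "2"],
        "pos": [100, 200, 300, 100]})
    dos = np.array([
        [0, 1, 2, 0, 1, 2],
        [0, 1, 2, 0, 1, 2],   # exact copy of a
        [0, 0, 1, 1, 2, 2],   # different pattern
        [2, 1, 0, 2, 1, 0]])  # allele-flipped copy of a
    return GenotypeTable(snps=snps, dosages=dos,
                         sample_ids=[f"s{i}" for i in range(6)])
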