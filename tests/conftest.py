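import numpy as np
import pandas as pd
import pytest

from snpcombo.io import GenotypeMatrix
from snpcombo.simulate import SimConfig, simulate_panel


def make_genotypes(dosages, chrom=None, pos=None, phenotype=None,
                   snp_ids=None):
    """Small-fixture constructor for a GenotypeMatrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else [(j + 1) * 1000 for j in range(m)]
    phenotype = phenotype if phenotype is not None else \
        [2] * (n // 2) + [1] * (n - n // 2)
    snp_ids = snp_ids if snp_ids is not None else [f"rs{j}" for j in range(m)]
    snp_map = pd.DataFrame(
        {"snp": snp_ids, "chrom": chrom, "pos": pos, "a1": "G", "a2": "A"}
    )
    samples = pd.DataFrame(
        {"sample": [f"S{i}" for i in range(n)], "phenotype": phenotype}
    )
    return GenotypeMatrix(dosages, snp_map, samples)


@pytest.fixture(scope="session")
def small_panel():
    """A small LD-structured panel with planted effects, shared by tests."""
    cfg = SimConfig(
        n_cases=150, n_controls=150, n_chromosomes=2, snps_per_chrom=100,
        block_size_snps=5, n_founder_haplotypes=6,
        n_main_causal=3, main_effect_or=2.0, n_epistatic_pairs=1,
        epistasis_or=2.0, prevalence_intercept=-0.5,
        missing_rate=0.0, bad_sample_fraction=0.0, bad_snp_fraction=0.0,
        snps_per_gene=2, set_size_range=(4, 12),
        seed=42,
    )
    g, y, truth = simulate_panel(cfg)
    return cfg, g, y, truth
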