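"""Shared fixtures: one small simulated breed reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from awmnet.deregress import deregress, filter_records
from awmnet.gwas import BayesBConfig, gwas_all_traits, qc_markers
from awmnet.mapping import map_snp_to_genes
from awmnet.simulate import GenotypeMatrix, SimConfig, simulate_breed


@pytest.fixture(scope="session")
def demo_config():
    return SimConfig(
        n_sires=12,
        progeny_per_sire=15,
        n_markers=500,
        n_genes=100,
        pi_qtl=0.9,
        missing_rate=0.02,
        fraction_near_gene=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def demo_breed(demo_config):
    return simulate_breed(demo_config)


@pytest.fixture(scope="session")
def qc_geno(demo_breed, deregressed):
    geno = qc_markers(demo_breed.genotypes)
    bulls = [b for b in geno.bulls if b in set(deregressed["bull"])]
    return geno.subset_bulls(bulls)


@pytest.fixture(scope="session")
def deregressed(demo_breed):
    return filter_records(deregress(demo_breed.evaluations), min_rel=0.2)


@pytest.fixture(scope="session")
def gwas_summaries(deregressed, qc_geno):
    cfg = BayesBConfig(chain_length=1500, burn_in=300, seed=7)
    return gwas_all_traits(deregressed, qc_geno, cfg)


@pytest.fixture(scope="session")
def snp_gene_map(demo_breed, qc_geno):
    return map_snp_to_genes(qc_geno.marker_map, demo_breed.genes)


def random_genotypes(rng, n, m, maf_low=0.1, maf_high=0.5) -> GenotypeMatrix:
    """Unstructured HWE genotypes for sampler-level tests."""
    maf = rng.uniform(maf_low, maf_high, m)
    codes = rng.binomial(2, maf, (n, m)).astype(float)
    df = pd.DataFrame(
        codes, index=[f"b{i:04d}" for i in range(n)], columns=[f"M{j:05d}" for j in range(m)]
    )
    mm = pd.DataFrame(
        {"chrom": "1", "marker": df.columns, "bp": np.arange(m) * 10_000 + 1}
    )
    return GenotypeMatrix(df, mm, df.mean() / 2)
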