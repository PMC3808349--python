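import numpy as np
import pytest

from mipway.genotype_core import GenotypeDataset, SnpRecord
from mipway.synthetic_fixtures import (
    SimulationConfig,
    figure4_fixture,
    simulate_annotation,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def fig4():
    """(structure, dataset) for the three-pathway overlap example."""
    return figure4_fixture()


@pytest.fixture()
def small_annotation():
    return simulate_annotation(
        n_genes=20,
        n_pathways=4,
        genes_per_pathway=5,
        overlap_fraction=0.2,
        snps_per_gene=(2, 3),
        seed=11,
    )


@pytest.fixture()
def small_dataset(small_annotation):
    cfg = SimulationConfig(n_cases=30, n_controls=30, seed=12)
    return simulate_dataset(cfg, small_annotation)


def make_dataset(genotypes, phenotype, snp_prefix="rs"):
    """Hand-rolled dataset from an explicit matrix (samples x SNPs)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_snps = genotypes.shape
    snps = [
        SnpRecord(f"{snp_prefix}{j + 1}", "1", (j + 1) * 100, "A", "B")
        for j in range(n_snps)
    ]
    return GenotypeDataset(
        snps=snps,
        sample_ids=[f"S{i + 1}" for i in range(n_samples)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        genotypes=genotypes,
    )
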