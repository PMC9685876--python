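import numpy as np
import pandas as pd
import pytest

from transqtl.simulate import (
    ExpressionMatrix,
    GenotypeMatrix,
    SimulationConfig,
    simulate_expression,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A 2-chromosome cohort small enough for per-test scans."""
    return SimulationConfig(
        n_samples=150,
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        n_variants_per_chrom=60,
        n_genes_per_chrom=20,
        ld_block_size=10,
        maf_range=(0.1, 0.5),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    genotypes = simulate_genotypes(tiny_config)
    expression, truth = simulate_expression(genotypes, tiny_config)
    return genotypes, expression, truth


def genotypes_from_dosage(dosage: np.ndarray, chrom="chr1", spacing=10_000) -> GenotypeMatrix:
    """Wrap a raw (samples x variants) dosage array for unit tests."""
    n, v = dosage.shape
    ids = [f"v{j}" for j in range(v)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": spacing * (np.arange(v) + 1),
            "ref": "A",
            "alt": "G",
            "maf": 0.3,
        },
        index=pd.Index(ids, name="variant_id"),
    )
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=samples, columns=ids), variants=variants
    )


def expression_from_values(values: np.ndarray, chrom="chr2", spacing=50_000) -> ExpressionMatrix:
    """Wrap a raw (genes x samples) matrix; genes live on ``chrom``."""
    g, n = values.shape
    ids = [f"g{j}" for j in range(g)]
    genes = pd.DataFrame(
        {"chrom": chrom, "tss": spacing * (np.arange(g) + 1), "strand": "+"},
        index=pd.Index(ids, name="gene_id"),
    )
    samples = [f"s{i}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples), genes=genes
    )
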