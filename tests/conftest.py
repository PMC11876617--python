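import numpy as np
import pandas as pd
import pytest

from pleionet import simulate


@pytest.fixture(scope="session")
def expression_panel():
    """Two-genotype developmental panel with a planted heterochronic shift."""
    cfg = simulate.ExpressionSimConfig(
        n_genes=300,
        n_dynamic=100,
        genotypes={"control": 0.0, "mutant": 0.5},
        noise_sd=0.1,
        seed=42,
    )
    return simulate.gen_expression_panel(cfg)


@pytest.fixture(scope="session")
def module_panel():
    """Panel with two planted co-expression blocks and enough sample groups
    for independent module factors to decorrelate."""
    cfg = simulate.ExpressionSimConfig(
        n_genes=110,
        n_dynamic=0,
        stages={f"s{i}": float(i) for i in range(1, 9)},
        genotypes={"a": 0.0, "b": 0.0, "c": 0.0},
        n_replicates=2,
        noise_sd=0.3,
        module_spec=[(50, 0.9), (50, 0.9)],
        seed=7,
    )
    return simulate.gen_expression_panel(cfg)


@pytest.fixture(scope="session")
def geno_pheno():
    """Structured panel with a causal window and h2 = 0.5 for both traits."""
    cfg = simulate.GenoPhenoSimConfig(
        n_individuals=300,
        n_snps=800,
        ld_rho=0.2,
        causal_windows=[(1, 20_000)],
        h2_targets=(0.5, 0.5),
        genetic_correlation=0.6,
        seed=11,
    )
    geno = simulate.gen_genotypes(cfg)
    pheno = simulate.gen_phenotypes(geno, cfg)
    return cfg, geno, pheno


@pytest.fixture
def gene_models():
    n = 60
    return pd.DataFrame(
        {
            "id": [f"g{i:03d}" for i in range(n)],
            "chrom": "1",
            "start": np.arange(n) * 1000 + 1,
            "end": np.arange(n) * 1000 + 400,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )
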