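import numpy as np
import pandas as pd
import pytest

import fullgen as fg


@pytest.fixture(scope="session")
def small_geno():
    """120 lines in 4 families, 10 SNPs, a little heterozygosity."""
    return fg.simulate_nam_genotypes(4, 30, 10, het_rate=0.05,
                                     missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def null_data():
    """500-line, 2-environment dataset with no genetic effects."""
    geno = fg.simulate_nam_genotypes(25, 20, 50, het_rate=0.03,
                                     missing_rate=0.0, seed=21)
    arch = fg.GeneticArchitecture(mu=0.0, residual_sd=1.0)
    pheno = fg.simulate_phenotypes(geno, arch, 2, seed=22)
    return geno, pheno


def make_pheno(values, env=None, trait="trait", line_prefix="L"):
    """Small helper: wrap a value vector into a PhenotypeTable."""
    values = np.asarray(values, dtype=float)
    env = np.ones(len(values), dtype=int) if env is None else np.asarray(env)
    return fg.PhenotypeTable(pd.DataFrame({
        "line": [f"{line_prefix}{i}" for i in range(len(values))],
        "family": "F0", "env": env, "trait": trait, "value": values}))
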