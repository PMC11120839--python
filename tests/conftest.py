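import numpy as np
import pandas as pd
import pytest

from epinet import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """80-family two-generation cohort, 120 unlinked SNPs, no planted effects."""
    spec = simdata.PedigreeSpec(n_families=80, generations=2, offspring_per_couple=3)
    G, ped = simdata.simulate_pedigree_genotypes(spec, 120, seed=11)
    K = simdata.expected_kinship(ped)
    return G, ped, K


@pytest.fixture(scope="session")
def small_trait(small_cohort):
    """Polygenic trait (h2 = 0.4) with age and sex effects on the small cohort."""
    G, ped, K = small_cohort
    cov = simdata.simulate_covariates(G.n_samples, seed=12)
    model = simdata.TraitModel(beta_age=-0.02, beta_sex=0.15,
                               sigma_g2=0.4, sigma_e2=0.6)
    pheno = simdata.simulate_phenotype(G, K, model, cov, seed=13)
    return pheno
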