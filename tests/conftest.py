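import numpy as np
import pytest

from assocpower import (
    CovariateTable,
    TraitModel,
    simulate_covariates,
    simulate_genotypes_independent,
)


@pytest.fixture(scope="session")
def small_panel():
    """30 independent common SNPs, 200 individuals."""
    rng = np.random.default_rng(11)
    mafs = rng.uniform(0.1, 0.5, size=30)
    return simulate_genotypes_independent(mafs, 200, seed=12)


@pytest.fixture(scope="session")
def small_covariates(small_panel):
    return simulate_covariates(small_panel.n_individuals, seed=13)


@pytest.fixture
def no_covariates():
    def make(n):
        return CovariateTable.empty(n)

    return make


@pytest.fixture
def null_model(small_covariates):
    return TraitModel(
        mu=1.0,
        covariate_effects=np.zeros(small_covariates.values.shape[1]),
        snp_effects={},
        error_sd=1.0,
    )
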