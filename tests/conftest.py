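import warnings

import numpy as np
import pytest

import corrbf
from corrbf.data_model import Dataset

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def bmi_pa_dataset():
    """The 44 x 6 synthetic example: exact sample r(bmi, pa) = -0.38."""
    return corrbf.make_fixture("bmi_pa", seed=3)


@pytest.fixture(scope="session")
def bivariate_dataset(bmi_pa_dataset):
    """Continuous (bmi, pa) columns only."""
    return Dataset(
        variables=bmi_pa_dataset.variables[:2],
        values=bmi_pa_dataset.values[:, :2],
    )


@pytest.fixture(scope="session")
def bivariate_params(bivariate_dataset):
    return corrbf.name_parameters(bivariate_dataset, ["bmi", "pa"])


@pytest.fixture(scope="session")
def bivariate_draws(bivariate_dataset):
    """A modest shared MCMC run on the continuous pair."""
    return corrbf.run_mcmc(bivariate_dataset, iterations=6000, chains=2, seed=11)


@pytest.fixture(scope="session")
def bivariate_posterior(bivariate_draws):
    return corrbf.fit_posterior_normal_approx(bivariate_draws)


@pytest.fixture(scope="session")
def bivariate_prior(bivariate_params):
    return corrbf.fit_prior_normal_approx(2, bivariate_params, m=50_000, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
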