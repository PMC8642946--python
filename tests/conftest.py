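import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pasekit.design import StrainDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> StrainDesign:
    return StrainDesign.default()


@pytest.fixture(scope="session")
def design2() -> StrainDesign:
    """Two animals per genotype-sex cell (16 samples)."""
    return StrainDesign.default(replicates=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_matrix(design) -> pd.DataFrame:
    """A 40-protein log2 matrix with known genotype structure, low noise."""
    from pasekit.synthetic import SimParams, simulate_proteome

    params = SimParams(n_proteins=40, sigma_additive=1.0, sigma_dominance=0.5,
                       sigma_sex=0.2, sigma_residual=0.1, fraction_null=0.25,
                       seed=7)
    _, matrix, _ = simulate_proteome(design, params)
    return matrix
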