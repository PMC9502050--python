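import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epomr.gwas import association_scan
from epomr.simulate import SimulationConfig, simulate_genotypes

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def region_config():
    """Small regional panel with a moderately strong causal variant."""
    return SimulationConfig(
        n_per_cohort=(2000,), n_variants=30, causal_index=15,
        beta_causal=0.2, skew=0.4, seed=11,
    )


@pytest.fixture(scope="session")
def region_genotypes(region_config):
    return simulate_genotypes(region_config)


@pytest.fixture(scope="session")
def region_scan(region_config, region_genotypes):
    """Association scan of a normal phenotype with the planted effect."""
    rng = np.random.default_rng(41)
    g = region_genotypes.dosages[:, region_config.causal_index].astype(float)
    y = region_config.beta_causal * g + rng.standard_normal(
        region_genotypes.n_samples
    )
    return association_scan(region_genotypes, y)
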