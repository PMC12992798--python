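import numpy as np
import pytest

from mertopo.synthetic import CohortConfig, FeatureParams, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that keeps the unit tests fast."""
    return CohortConfig(
        n_patients=8,
        frac_la=0.5,
        trajectories_per_hemisphere=2,
        feature_params={
            "LA": FeatureParams(28.47, 14.00, 5.59, 4.58, 2.32, 3.01, 3.0),
            "GA_low": FeatureParams(23.0, 14.37, 10.2, 9.0, 2.39, 2.94, 3.0),
            "GA_high": FeatureParams(18.0, 14.37, 14.7, 10.0, -0.07, 2.38, 2.5),
        },
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
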