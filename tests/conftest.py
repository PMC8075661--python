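import numpy as np
import pytest

from dynfc import ConnectomeDynamics, generate_cohort, make_cohort_config


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale planted-difference cohort: 40 ROIs, 20 subjects/group,
    5 latent states, state 0 occupancy 0.45 vs 0.05."""
    return generate_cohort(
        make_cohort_config(n_subjects_per_group=20, n_roi=40, seed=7)
    )


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """The small cohort fitted with DB selection over K=2..8."""
    return ConnectomeDynamics.from_cohort(small_cohort, k_range=(2, 8)).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
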