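import numpy as np
import pytest

from cartmorph import CohortConfig, generate_base_surface, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort configuration shared across tests."""
    return CohortConfig(n_models=6, n_grid_u=24, n_grid_v=18, seed=123)


@pytest.fixture(scope="session")
def base_surface(tiny_config):
    return generate_base_surface(tiny_config)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Cohort with no noise and no rigid scatter: pure planted modes."""
    cfg = CohortConfig(
        n_models=8, n_grid_u=24, n_grid_v=18, mode_amplitudes=(2.0, 1.0),
        vertex_noise_sd=0.0, rigid_rotation_sd_deg=0.0, rigid_translation_sd=0.0,
        side_mix=0.0, seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
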