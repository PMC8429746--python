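import numpy as np
import pytest

from petfcs import DiffusionComponent, default_lag_grid, synth_acf
from petfcs.datasets import DEFAULT_DIFFUSION, GLUA2_KINETICS


@pytest.fixture(scope="session")
def lag_grid():
    return default_lag_grid()


@pytest.fixture(scope="session")
def apo_curve(lag_grid):
    """Noisy synthetic curve from the GluA2 apo three-phase parameter set."""
    return synth_acf(DEFAULT_DIFFUSION, GLUA2_KINETICS["apo"], lag_grid,
                     noise_scale=0.01, duration=600.0, seed=42)


@pytest.fixture(scope="session")
def noise_free_apo_curve(lag_grid):
    return synth_acf(DEFAULT_DIFFUSION, GLUA2_KINETICS["apo"], lag_grid,
                     noise_scale=0.0, duration=600.0, seed=0)


@pytest.fixture(scope="session")
def diffusion_only_curve(lag_grid):
    return synth_acf(DiffusionComponent(1.0, 0.5e-3), [], lag_grid,
                     noise_scale=0.01, duration=600.0, seed=7)
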