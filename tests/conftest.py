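import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """A seeded 40-cell synthetic panel shared across tests."""
    from gscmorph.synth.cells import random_cell_panel

    return random_cell_panel(40, seed=7)


@pytest.fixture
def disk_mask():
    from skimage.draw import disk as draw_disk

    mask = np.zeros((64, 64), dtype=bool)
    rr, cc = draw_disk((32, 32), 15)
    mask[rr, cc] = True
    return mask


@pytest.fixture
def markov_matrices():
    trans = np.array(
        [
            [0.90, 0.04, 0.03, 0.03],
            [0.05, 0.85, 0.05, 0.05],
            [0.02, 0.08, 0.80, 0.10],
            [0.03, 0.03, 0.04, 0.90],
        ]
    )
    inherit = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return trans, inherit
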