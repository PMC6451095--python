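import numpy as np
import pytest

import smfoci as m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cell():
    """A 3 × 1 µm rod away from the frame border."""
    return m.generate_cell(3.0, 1.0, cell_id=0, centre=(4.8, 4.8))


@pytest.fixture(scope="session")
def small_config():
    """Single-cell 96 px frame configuration for rendering tests."""
    return m.TimelapseConfig(n_cells=1, frame_size=96)


@pytest.fixture(scope="session")
def short_timelapse():
    """A 60-cell, 3-time-point synthetic time-lapse shared across tests."""
    config = m.TimelapseConfig(n_cells=60, duration=20, interval=10, seed=2)
    return m.generate_timelapse(config)
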