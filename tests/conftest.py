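import numpy as np
import pytest

from wormmate import DualChannelStack, RoiTrack, StackSimConfig, generate_stack


@pytest.fixture
def small_stack():
    """Tiny noiseless stack with one cell, flat artifact, no transients."""
    config = StackSimConfig(
        n_frames=10,
        frame_rate=30.0,
        image_size=(32, 32),
        cell_positions=[(16, 16)],
        baseline_green=100.0,
        baseline_red=150.0,
        background_level=10.0,
        red_bleach=(150.0, 0.0, 0.0),
        artifact_series=np.ones(10),
        noise_sd=0.0,
        seed=0,
    )
    stack, truth = generate_stack(config)
    return stack, truth, config


@pytest.fixture
def uniform_stack():
    """Both channels uniformly 7.0 everywhere."""
    data = np.full((5, 16, 16, 2), 7.0)
    return DualChannelStack(data, frame_rate=30.0)
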