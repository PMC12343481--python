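import numpy as np
import pytest

from pocketcav.detection import DetectionParams
from pocketcav.phantoms import PhantomConfig


@pytest.fixture
def phantom_cfg():
    """Noise-free default-geometry phantom config (short sequence)."""
    return PhantomConfig(seed=1, noise_sigma=0.0, n_frames=30)


@pytest.fixture
def detect_params(phantom_cfg):
    return DetectionParams(
        ft_tip_row_px=phantom_cfg.ft_tip_row_px,
        ft_column_px=phantom_cfg.ft_column_px,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
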