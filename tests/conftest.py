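import numpy as np
import pytest

from tspnet.backbone import TSPNetConfig, desk_config
from tspnet.core import EpochSet
from tspnet.synthetic import SynthConfig, generate_epoch_set


@pytest.fixture(scope="session")
def tiny_config() -> TSPNetConfig:
    """Smallest config that exercises every stage (float64 for grad checks)."""
    return TSPNetConfig(n_input_channels=4, n_samples=16, tdfe_widths=(2, 3, 4),
                        sdfe_width=4, w_max=8, dtype="float64", seed=3)


@pytest.fixture(scope="session")
def small_epochs() -> EpochSet:
    """A small balanced synthetic set: 6 trials/class, 16 ch, 1 s at 128 Hz."""
    cfg = SynthConfig(n_subjects=1, trials_per_class=6, fs=128.0, n_samples=128,
                      effect_size=1.0, seed=7)
    return generate_epoch_set(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
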