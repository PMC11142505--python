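import numpy as np
import pytest

from swdeemd import (EEMDConfig, SynthConfig, WindowConfig,
                     build_feature_matrix)
from swdeemd.synthetic import gen_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced-duration copy of the study conditions for fast tests."""
    return SynthConfig(n_subjects=4, healthy_duration_s=3.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return gen_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """Feature matrix from the fast wavelet-only arm (~4.5:1 imbalance)."""
    return build_feature_matrix(small_dataset, arm="wd")


@pytest.fixture(scope="session")
def fast_eemd_cfg():
    return EEMDConfig(ensemble_size=5, noise_scale=0.2, max_imfs=3, seed=3)


@pytest.fixture(scope="session")
def win_cfg():
    return WindowConfig()
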