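import numpy as np
import pytest

from petpica.pica import PicaConfig, parallel_ica
from petpica.simulate import SimConfig, synthesize_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale cohort: 140 subjects, 8 components,
    coupled pair at r = 0.6, noise sd 0.1."""
    cfg = SimConfig(seed=1)
    tau, abeta, truth = synthesize_dataset(cfg)
    return cfg, tau, abeta, truth


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    _, tau, abeta, _ = default_dataset
    return parallel_ica(tau, abeta, PicaConfig(seed=1))


@pytest.fixture
def small_sim():
    """Desk-scale config for fast per-module tests."""
    return SimConfig(
        grid_dims=(14, 16, 14), n_subjects_per_group=(20, 20),
        n_components=4, coupled_pair=(0, 2),
        group_effect_components={"tau": (1,), "abeta": (3,)}, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
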