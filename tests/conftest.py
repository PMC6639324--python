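import numpy as np
import pytest

from perfradiomics.io import ClassLabel, MapKind, ParametricVolume, VOIMask
from perfradiomics.synthetic import SyntheticCohortConfig, generate_lesion


@pytest.fixture(scope="session")
def default_sim_config() -> SyntheticCohortConfig:
    return SyntheticCohortConfig()


@pytest.fixture(scope="session")
def pd_lesion(default_sim_config):
    """One PD-like phantom (rough texture), both maps."""
    return generate_lesion(default_sim_config, ClassLabel.PD, subject_seed=7)


@pytest.fixture(scope="session")
def ktrans_pair(pd_lesion):
    return pd_lesion[MapKind.KTRANS]


def random_masked_volume(rng, shape=(6, 6, 3), p_mask=0.7):
    """A small random volume plus a random (non-empty) mask."""
    vox = rng.normal(size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    vol = ParametricVolume(voxels=vox, spacing=(1.0, 1.0, 1.0), map_kind=MapKind.KTRANS)
    return vol, VOIMask(voxels=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
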