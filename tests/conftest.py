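from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from radstab.grid import ROIMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20160729)


def random_roi(rng, max_side=6, levels=None):
    """A random small volume + random nonempty mask (and optional labels)."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    values = rng.normal(0, 50, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    return VolumeGrid(values), ROIMask(mask)


@pytest.fixture
def tiny_nodule_config():
    from radstab.pipeline import StudyConfig

    return StudyConfig(
        mode="nodule", n_cases=4, n_repeat=2, seed=7, margin_voxels=6,
    )


@pytest.fixture
def tiny_phantom_config():
    from radstab.pipeline import StudyConfig

    return StudyConfig(
        mode="phantom", seed=7, phantom_shape=(16, 48, 48), n_rois=3,
    )
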