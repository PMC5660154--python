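import numpy as np
import pytest

from grainstack.stack import VoxelStack


def make_stack(values, dx=0.1, dy=0.1, dz=0.3, channel_name="test", exposure_ms=1.0):
    """VoxelStack helper with cubic-ish 0.003 um^3 voxels by default."""
    return VoxelStack(
        intensities=np.asarray(values, dtype=float),
        dx=dx, dy=dy, dz=dz, channel_name=channel_name, exposure_ms=exposure_ms,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
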