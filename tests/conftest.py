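import numpy as np
import pytest

import hippomorph as hm


@pytest.fixture(scope="session")
def default_phantom():
    """Zero-noise default phantom shared by read-only tests."""
    spec = hm.PhantomSpec()
    volume, landmarks, coverage, truth = hm.generate(spec)
    return spec, volume, landmarks, coverage, truth


@pytest.fixture()
def schema():
    return hm.SubfieldSchema()


def make_volume(voxels, hemisphere="right", spacing=(0.2, 0.2, 0.2)):
    return hm.LabelVolume.from_array(
        np.asarray(voxels, dtype=np.int16), spacing=spacing, hemisphere=hemisphere
    )


@pytest.fixture()
def volume_factory():
    return make_volume
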