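import numpy as np
import pytest

from rnflt.maps import DiscMask, RNFLTMap
from rnflt.synthetic import (
    ArtifactModelParams,
    MapModelParams,
    generate_rnflt_map,
    generate_segmentation_failure,
)

SMALL_RES = 32
SMALL_PITCH = 6.0 / SMALL_RES


@pytest.fixture(scope="session")
def small_params():
    """Map parameters for a fast 32x32 synthetic grid (6 mm field)."""
    return MapModelParams(shape=(SMALL_RES, SMALL_RES), pixel_pitch=SMALL_PITCH,
                          seed=11)


@pytest.fixture(scope="session")
def small_map(small_params):
    """One high-quality synthetic map with its disc mask."""
    return generate_rnflt_map(small_params, patient_id="P0", eye_id="P0-OD")


@pytest.fixture(scope="session")
def small_low_map(small_map):
    """A low-quality (artifact-donor) version of the small map."""
    m, disc = small_map
    low = generate_segmentation_failure(
        m, disc, ArtifactModelParams(target_ar=0.12, seed=7)
    )
    return low, disc


@pytest.fixture()
def flat_map():
    """A constant 100-um map on a 200x200 grid with default pitch."""
    return RNFLTMap(values=np.full((200, 200), 100.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
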