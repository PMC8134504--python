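import warnings

import numpy as np
import pytest

import mammoquant as mq

# scikit-image 0.26 deprecation chatter from optional code paths
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def wholemount_default():
    """Default-condition whole mount: seed 0, default noise."""
    params = mq.TreeGenParams(seed=0)
    img, truth = mq.generate_wholemount(params)
    return params, img, truth


@pytest.fixture(scope="session")
def segmented_default(wholemount_default):
    params, img, truth = wholemount_default
    seg = mq.segment_tree(img, params.nipple_px)
    return params, img, truth, seg


@pytest.fixture()
def single_protrusion_scene():
    """One cyst, one protrusion, study-like 5% noise."""
    params = mq.CystGenParams(
        protrusion_specs=[mq.ProtrusionSpec(30, 10, 0, 0)],
        compartment_ratio=1.8, noise_sd=5.0, seed=3)
    frames, truth = mq.generate_cyst_timelapse(params)
    return params, frames[0], truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    return 2 * inter / (np.count_nonzero(a) + np.count_nonzero(b))
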