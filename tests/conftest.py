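import numpy as np
import pytest

from icscore3d import phantom, segmentation


@pytest.fixture(scope="session")
def small_case():
    """One deterministic phantom case with a 2% designed marker fraction."""
    params = phantom.PhantomParams(
        image_shape=(4, 256, 256), pdl1_fraction_profile=0.02, seed=11
    )
    stack, truth = phantom.generate_case(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def classical_segmenters():
    return {
        "tumor": segmentation.classical_segmenter("tumor"),
        "immune": segmentation.classical_segmenter("immune"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
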