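import numpy as np
import pytest

from leukoscope import synthetic_smear as ss


@pytest.fixture(scope="session")
def small_dataset():
    """20 samples (5 per class) at 64 px, shared across tests."""
    return ss.generate_dataset(5, 64, seed=0)


@pytest.fixture(scope="session")
def feature_dataset():
    """50 samples per class at 64 px for separability checks."""
    return ss.generate_dataset(50, 64, seed=123)


def mean_color_features(sample) -> np.ndarray:
    """(mean hue, mean saturation, foreground area fraction) over the mask."""
    from leukoscope.hsv_segmentation import rgb_to_hsv

    hsv = rgb_to_hsv(sample.image)
    fg = sample.mask.astype(bool)
    return np.array([hsv[..., 0][fg].mean(), hsv[..., 1][fg].mean(), fg.mean()])
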