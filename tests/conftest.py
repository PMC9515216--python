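import numpy as np
import pytest

from ardaceph import phantom as ph
from ardaceph.model import CNNAgeRegressor


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject noise-free 64x64 phantom used by several unit tests."""
    spec = ph.study_config(n_subjects=300, image_size=(64, 64), noise_sd=0.0, seed=7)
    images, manifest = ph.generate_cohort(spec)
    X = np.stack([im.pixels for im in images])
    y = manifest["age"].to_numpy()
    return spec, images, manifest, X, y


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A briefly trained age regressor for saliency / retest unit tests."""
    _, _, _, X, y = small_cohort
    return CNNAgeRegressor(epochs=8, batch_size=64, seed=0).fit(X[:250], y[:250])
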