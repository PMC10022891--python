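import numpy as np
import pytest
from hypothesis import settings

import curvsense as cv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def surrogate_dataset():
    """2,500 noisy surrogate-labeled peptides plus a 500-sequence test set."""
    rng = np.random.default_rng(2024)
    data = cv.generate_dataset(3000, (7, 24), cv.SurrogateParams(noise_sd=0.5), rng=rng)
    return data[:2500], data[2500:]


@pytest.fixture(scope="session")
def trained_model(surrogate_dataset):
    """A moderately trained regressor shared across prediction tests."""
    train_data, _ = surrogate_dataset
    model, metrics = cv.train(
        train_data, cv.CNNSpec(), cv.TrainConfig(seed=7, max_epochs=40, patience=40)
    )
    return model, metrics
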