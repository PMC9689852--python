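import numpy as np
import pytest

import cstpbci as c
from cstpbci.preprocess import preprocess_recording

SESSION_SEED = 2026


@pytest.fixture(scope="session")
def default_recording():
    """One full synthetic session under the default protocol and templates."""
    return c.simulate_session(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def default_epochs(default_recording):
    """The default session preprocessed to labeled 1-s epochs at 250 Hz."""
    return preprocess_recording(default_recording)


@pytest.fixture(scope="session")
def cstp_model(default_epochs):
    """Full CSTP model (three pairs) fitted on the default session."""
    return c.fit_cstp(default_epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


def make_epochset(n_per_class=20, n_channels=8, n_samples=51, rate=250.0, seed=0,
                  signal=None):
    """Small synthetic EpochSet for unit tests.

    ``signal`` maps a class label to a channels x samples array added to
    that class's epochs on top of white noise.
    """
    from cstpbci.preprocess import EpochSet
    from cstpbci.simulate import CLASSES

    gen = np.random.default_rng(seed)
    data, labels = [], []
    for label in CLASSES:
        for _ in range(n_per_class):
            ep = gen.standard_normal((n_channels, n_samples))
            if signal and label in signal:
                ep = ep + signal[label]
            data.append(ep)
            labels.append(label)
    return EpochSet(
        data=np.asarray(data), labels=np.asarray(labels, dtype=object),
        sampling_rate=rate, channel_labels=[f"ch{i}" for i in range(n_channels)],
    )
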