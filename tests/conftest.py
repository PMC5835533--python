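import numpy as np
import pytest

import mttpipe as m


def small_config(**overrides):
    """A fast generator configuration for unit tests."""
    defaults = dict(
        n_ltc_left=2,
        n_hipp_left=2,
        n_ltc_right=1,
        n_hipp_right=1,
        trials_per_condition=20,
        artifact_rate=0.0,
        seed=7,
    )
    defaults.update(overrides)
    return m.GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-condition dataset: 6+6 left / 3+5 right electrodes,
    early LTC and late hippocampal effects, moderate noise."""
    return m.generate_dataset(m.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Features after the full preprocessing chain (filter, reject, average)."""
    epochs, meta = default_dataset
    epochs = m.reject_epochs(m.bandpass(epochs))
    return m.features_for_dataset(m.average_evoked(epochs), meta)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Deterministic dataset: no noise, no artifacts, no polarity flips."""
    cfg = m.GeneratorConfig(seed=0, noise_sd=0.0, artifact_rate=0.0, polarity_flip_prob=0.0)
    return m.generate_dataset(cfg)
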