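import numpy as np
import pytest

from midecode import MIEEGDataset, SynthConfig, generate_mi_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong planted ERD (depth 0.8), low noise, 100 trials/class."""
    config = SynthConfig(n_trials_per_class=100, erd_depth=0.8, noise_sd=0.05, seed=42)
    return generate_mi_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effect (erd_depth 0), 100 trials/class."""
    config = SynthConfig(n_trials_per_class=100, erd_depth=0.0, noise_sd=0.5, seed=42)
    return generate_mi_dataset(config)


@pytest.fixture()
def small_dataset():
    """Tiny random dataset for fast structural checks."""
    rng = np.random.default_rng(7)
    trials = rng.standard_normal((12, 4, 64))
    labels = np.tile([1, 2], 6)
    return MIEEGDataset(
        trials=trials,
        labels=labels,
        sampling_rate=128.0,
        channel_names=[f"CH{i}" for i in range(1, 5)],
        provenance="test",
    )
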