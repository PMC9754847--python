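import numpy as np
import pytest

from preictal import Epoch, EpochSet, Recording, SimulationConfig, simulate_epoch_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """3-channel, 10-s, 256 Hz recording with integer-valued samples."""
    signals = rng.integers(-500, 500, size=(3, 2560)).astype(float)
    return Recording(
        channel_labels=["FP1", "FP2", "CZ"],
        sampling_rate=256.0,
        signals=signals,
    )


@pytest.fixture
def tiny_epoch_set(rng):
    """Separable two-class epoch set: class 1 carries a strong coupling."""
    epochs = []
    for i in range(8):
        base = rng.standard_normal((4, 60))
        if i < 3:
            base[1] = base[0] + 0.1 * rng.standard_normal(60)
            label = 1
        else:
            label = 0
        epochs.append(Epoch(data=base, label=label, epoch_index=i))
    return EpochSet(epochs=epochs)


@pytest.fixture(scope="session")
def planted_epochs():
    """Default planted-network benchmark draw, shared across tests."""
    cfg = SimulationConfig(seed=2024)
    return simulate_epoch_set(cfg)
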