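import numpy as np
import pytest

from hfomorph import (
    Signal1D,
    SyntheticSpec,
    generate_recording,
    label_candidates,
    staba_detect,
)

FS = 5000.0


@pytest.fixture(scope="session")
def default_recording():
    """The canonical seeded fixture: 60 s, 10 spikes, 20 ripples, seed 42."""
    return generate_recording(SyntheticSpec())


@pytest.fixture(scope="session")
def default_candidates(default_recording):
    signal, _ = default_recording
    return staba_detect(signal)


@pytest.fixture(scope="session")
def labeled_candidates(default_recording, default_candidates):
    """Detected events carrying their ground-truth labels (unmatched dropped)."""
    _, truth = default_recording
    labeled = label_candidates(default_candidates, truth.events)
    return [e for e in labeled if e.label in ("spike", "ripple")]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def signal(values, fs=FS) -> Signal1D:
    return Signal1D(np.asarray(values, dtype=float), fs)
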