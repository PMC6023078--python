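import numpy as np
import pytest

from bpi.core import BreathEnvelope
from bpi.library import DEFAULT_VOCABULARY, build_library
from bpi.synth import generate_subject_dataset, make_class_specs, render_envelope


@pytest.fixture(scope="session")
def specs4():
    return make_class_specs(7, 4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but full-fidelity dataset: 2 classes, 2 train + 1 live reps."""
    return generate_subject_dataset(
        rng_seed=11, subject_id=0, n_classes=2, n_train=2, n_live=1
    )


@pytest.fixture(scope="session")
def small_library(specs4):
    """4-class library of jittered synthetic envelopes (3 templates each)."""
    train = {}
    for spec in specs4:
        rng = np.random.default_rng([5, spec.class_id])
        train[spec.class_id] = [render_envelope(spec, rng=rng) for _ in range(3)]
    return build_library(train, DEFAULT_VOCABULARY)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
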