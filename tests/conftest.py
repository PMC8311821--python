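import numpy as np
import pytest

from wristmic.classify import ModelSpec
from wristmic.corpus import build_training_corpus, prepare_annotated


@pytest.fixture(scope="session")
def tiny_corpus():
    """Four 30-second annotated sessions — enough for fast classifier tests."""
    return build_training_corpus(seed=123, n_sessions=4, session_s=30.0)


@pytest.fixture(scope="session")
def tiny_annotated(tiny_corpus):
    return prepare_annotated(tiny_corpus)


@pytest.fixture(scope="session")
def fast_spec():
    """Small, quick-to-train model spec for unit tests."""
    return ModelSpec(hidden_layer_sizes=(16,), max_iter=40, max_train_frames=4000)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
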