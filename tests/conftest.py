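"""Shared fixtures: small rendered corpora are expensive, so cache them."""

import numpy as np
import pytest

from sispin.corpus import build_corpus
from sispin.voice import VoiceSpec


@pytest.fixture(scope="session")
def dog_corpus():
    return build_corpus("dog", rng_seed=101)


@pytest.fixture(scope="session")
def cat_corpus():
    return build_corpus("cat", rng_seed=202)


@pytest.fixture(scope="session")
def reference_voice():
    return VoiceSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
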