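import numpy as np
import pytest

from neuroevent.bootstrap import DictionarySet, tokenize
from neuroevent.features import EmbeddingTable
from neuroevent.synthetic import SynthConfig, build_resources, generate_corpus

WORKED_SENTENCE = "High b-value fMRI was obtained through the central sulcus"


@pytest.fixture
def worked_dicts() -> DictionarySet:
    """Minimal dictionaries reproducing the worked annotation example."""
    return DictionarySet.from_strings(
        {
            "Acquisition": ["obtained"],
            "AOB": ["fMRI"],
            "BRI": ["central sulcus"],
            "ACQ_A": ["b-value"],
        }
    )


@pytest.fixture
def worked_tokens():
    return tokenize(WORKED_SENTENCE)


@pytest.fixture
def small_corpus():
    """A 60-mention synthetic corpus shared across model tests."""
    config = SynthConfig(
        seed=5,
        n_mentions=60,
        trigger_vocab=3,
        argument_vocab=4,
        attribute_vocab=2,
        multi_token_frac=0.2,
    )
    sentences, mentions, resources = generate_corpus(config)
    return sentences, mentions, resources


@pytest.fixture
def embeddings():
    return EmbeddingTable.seeded(25, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
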