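import numpy as np
import pytest

from metricvae.backbone import ModelConfig, init_params
from metricvae.data import TokenSequence, build_vocabulary


TINY_MODEL = ModelConfig(
    latent_dim=4, rnn_layers=1, hidden_size=16, embed_dim=8,
    bidirectional_encoder=True, learning_rate=1e-3,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_corpus():
    """Four short token sequences over a 3-letter alphabet, with vocab."""
    token_lists = [["a", "b", "a"], ["b", "c"], ["c", "a", "b", "c"], ["a"]]
    vocab = build_vocabulary(token_lists)
    seqs = [TokenSequence(indices=tuple(vocab.encode_tokens(t))) for t in token_lists]
    return token_lists, seqs, vocab


@pytest.fixture
def tiny_model(tiny_corpus, rng):
    _, _, vocab = tiny_corpus
    params = init_params(TINY_MODEL, vocab.size, rng)
    return params, TINY_MODEL, vocab
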