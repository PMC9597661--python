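"""Shared fixtures: one synthetic corpus, tokenizer and pre-trained desk
encoder are built per session and reused by every test that needs them."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chemlm import fixtures as fx
from chemlm import model as mdl
from chemlm.tokenizer import train_unigram

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

CORPUS_SEED = 11
PRETRAIN_SEED = 1
CORPUS_LINES = 5000
DESK_VOCAB = 500


@pytest.fixture(scope="session")
def pretrain_corpus() -> list[str]:
    """~5k synthetic SMILES with Zipf-duplicated molecules in canonical and
    randomized forms — the desk-scale pre-training stream."""
    corpus = fx.gen_corpus(fx.FixtureSpec(n_molecules=4935, seed=CORPUS_SEED))
    assert len(corpus.lines) >= CORPUS_LINES
    return corpus.lines[:CORPUS_LINES]


@pytest.fixture(scope="session")
def desk_tokenizer(pretrain_corpus):
    return train_unigram(pretrain_corpus, vocab_size=DESK_VOCAB, seed=0)


@pytest.fixture(scope="session")
def desk_encoder_random(desk_tokenizer):
    enc = mdl.TransformerEncoder(mdl.desk_config(desk_tokenizer.vocab_size),
                                 seed=0)
    enc.eval()
    return enc


@pytest.fixture(scope="session")
def desk_pretrained(pretrain_corpus, desk_tokenizer):
    """Desk encoder after 1 MLM epoch on the 5k corpus, plus its loss trace."""
    enc = mdl.TransformerEncoder(mdl.desk_config(desk_tokenizer.vocab_size),
                                 seed=0)
    enc, trace = mdl.pretrain(pretrain_corpus, desk_tokenizer, enc, epochs=1,
                              seed=PRETRAIN_SEED,
                              plan=mdl.BatchPlan(per_device=8, accum_steps=4))
    return enc, trace


@pytest.fixture(scope="session")
def desk_encoder_pretrained(desk_pretrained):
    return desk_pretrained[0]


@pytest.fixture(scope="session")
def screening_target():
    return fx.gen_screening_target(30, 300, seed=5)


@pytest.fixture(scope="session")
def nitro_dataset():
    return fx.gen_labeled_dataset(500, label_rule="nitro", noise_rate=0.0,
                                  seed=21)


@pytest.fixture(scope="session")
def tiny_corpus() -> list[str]:
    """A few hundred molecules for cheap unit tests."""
    return fx.gen_corpus(fx.FixtureSpec(n_molecules=300, seed=3)).lines


@pytest.fixture(scope="session")
def tiny_tokenizer(tiny_corpus):
    return train_unigram(tiny_corpus, vocab_size=120, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
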