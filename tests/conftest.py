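"""Shared fixtures: all corpora are generated programmatically at test time."""

import pytest

from radqc import (
    ContextTrainingConfig,
    calibrate_threshold,
    default_lexicon,
    default_rules,
    default_templates,
    generate_corpus,
    generate_paired_corpus,
    train,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def ruleset():
    return default_rules()


@pytest.fixture(scope="session")
def corpus(lexicon, templates):
    """300 clean synthetic reports, fixed seed."""
    return generate_corpus(300, rng_seed=42, templates=templates, lexicon=lexicon)


@pytest.fixture(scope="session")
def paired(corpus, lexicon):
    """Each report corrupted with probability 0.5 at the default type mix."""
    return generate_paired_corpus(corpus, 0.5, rng_seed=43, lexicon=lexicon)


@pytest.fixture(scope="session")
def model(corpus):
    return train(corpus, ContextTrainingConfig(rng_seed=1))


@pytest.fixture(scope="session")
def threshold(model, lexicon, templates):
    holdout = generate_corpus(150, rng_seed=777, templates=templates, lexicon=lexicon)
    return calibrate_threshold(model, [r.text for r in holdout])
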