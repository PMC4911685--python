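import pytest

from meshsuggest import (
    GeneratorConfig,
    build_index,
    generate,
    split,
)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 200-document planted corpus shared by retrieval/ranker tests."""
    config = GeneratorConfig(
        n_docs=200,
        n_labels=20,
        vocab_size=400,
        signal_terms_per_label=10,
        signal_strength=0.8,
        abstract_len=60,
        seed=7,
    )
    corpus, thesaurus, truth = generate(config)
    return corpus, thesaurus, truth


@pytest.fixture(scope="session")
def small_index(small_synthetic):
    corpus, _, _ = small_synthetic
    return build_index(corpus)


@pytest.fixture(scope="session")
def medium_split():
    """An 800-document corpus split 80/20, for end-to-end checks."""
    config = GeneratorConfig(
        n_docs=800,
        n_labels=30,
        vocab_size=1000,
        signal_strength=0.8,
        seed=11,
    )
    corpus, thesaurus, truth = generate(config)
    train, test = split(corpus, 0.8, seed=11)
    return train, test, thesaurus, truth
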