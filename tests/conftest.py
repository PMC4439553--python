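import pytest

from connectomine.synthetic import SynthConfig, generate_corpus, load_toy_lexicon


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_toy_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """30 gold-annotated synthetic abstracts (fixed seed)."""
    return generate_corpus(SynthConfig(n_documents=30, seed=42))


@pytest.fixture(scope="session")
def clean_corpus():
    """Corpus without surface corruption: mention strings are lexicon names."""
    return generate_corpus(
        SynthConfig(
            n_documents=30, seed=7, p_reorder=0.0, p_qualifier=0.0, p_bracket=0.0
        )
    )
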