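import pytest

from memrl.workbench import FixtureSpec, generate_corpus, toy_logp_setup


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small deterministic fixture corpus (5 molecules per family)."""
    return generate_corpus(FixtureSpec(n_per_family=5, seed=0))


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    """Untrained small language model over the tiny corpus vocabulary."""
    from memrl.generator import GeneratorModel, build_vocabulary

    vocab = build_vocabulary(tiny_corpus)
    return GeneratorModel(vocab, embedding_dim=16, hidden_size=24, n_layers=2, seed=0)


@pytest.fixture(scope="session")
def focused_prior():
    """Toy prior transfer-learned onto the high-AlogP slice (the LogP study)."""
    prior, corpus = toy_logp_setup(seed=1)
    return prior, corpus
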