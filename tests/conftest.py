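import pytest

from molforge import fixtures, generator, rafsf


@pytest.fixture(scope="session")
def corpus60() -> list[str]:
    """Small deterministic scaffold-enumeration corpus."""
    return fixtures.generate_corpus(fixtures.FixtureSpec(corpus_size=60, seed=2))


@pytest.fixture(scope="session")
def tiny_config() -> generator.GeneratorConfig:
    return generator.GeneratorConfig(n_layers=1, hidden_size=64, embedding_size=32)


@pytest.fixture(scope="session")
def tiny_model(corpus60, tiny_config) -> generator.SmilesGenerator:
    """A small LSTM trained briefly — shared by determinism/serialization tests."""
    return generator.pretrain(corpus60, 4, seed=0, config=tiny_config)


@pytest.fixture(scope="session")
def fragment_space(corpus60) -> rafsf.FragmentSpace:
    return rafsf.build_fragment_space(corpus60, corpus_id="fixture-60")
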