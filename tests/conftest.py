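import pytest

from avidalite import MicroConfig, enumerate_space, make_toy_map, standard_evaluator


@pytest.fixture(scope="session")
def std_evaluator():
    """Standard test-environment evaluator: 32-bit words, 26 letters,
    20xL budget, exact-copy fidelity, environment seed 42."""
    return standard_evaluator()


@pytest.fixture(scope="session")
def micro_config():
    """Enumerable micro space over {h-alloc, h-copy, h-divide} at L=4."""
    return MicroConfig(length=4, alphabet="wvx")


@pytest.fixture(scope="session")
def micro_evaluator(micro_config):
    return micro_config.evaluator()


@pytest.fixture(scope="session")
def micro_table(micro_config):
    return enumerate_space(micro_config)


@pytest.fixture(scope="session")
def toy_map():
    """Fully enumerated 4-label toy map over a 4-letter, length-8 space
    (65536 genomes) with skewed label frequencies and an inviable remainder."""
    return make_toy_map(8, 4, freqs=[0.4, 0.3, 0.2, 0.05], seed=7)
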