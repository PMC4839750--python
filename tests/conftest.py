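import numpy as np
import pytest

from tepinkit import ComplexCatalog, StaticPIN
from tepinkit.synthetic import SynthConfig, generate


@pytest.fixture
def triangle_pin() -> StaticPIN:
    return StaticPIN.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def small_catalog() -> ComplexCatalog:
    return ComplexCatalog([
        ("k1", frozenset({"A", "B", "C"})),
        ("k2", frozenset({"C", "D"})),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """Small strong-signal synthetic dataset shared across tests."""
    return generate(SynthConfig(n_proteins=80, n_complexes=6, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160421)
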