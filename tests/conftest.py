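import numpy as np
import pytest

from topothought import EmbeddingStore, RawDocument


@pytest.fixture
def tiny_store() -> EmbeddingStore:
    """Hand-written 3-d store with easy arithmetic."""
    return EmbeddingStore(
        {
            "a": np.array([0.0, 2.0, 0.0]),
            "b": np.array([2.0, 0.0, 0.0]),
            "c": np.array([0.0, 0.0, 2.0]),
            "d": np.array([1.0, 1.0, 1.0]),
        }
    )


@pytest.fixture
def small_corpus() -> list[RawDocument]:
    return [
        RawDocument("d1", "auth1", "a b c d " * 20),
        RawDocument("d2", "auth1", "a a b b " * 25),
        RawDocument("d3", "auth2", "c d a b " * 30),
        RawDocument("d4", "auth2", "b c " * 28),
    ]


def random_points(seed: int, T: int, d: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(size=(T, d))
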