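import numpy as np
import pytest

from scfsnn import CountMatrix, Labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_counts(values) -> CountMatrix:
    values = np.asarray(values)
    n, p = values.shape
    return CountMatrix(
        values,
        np.array([f"g{j}" for j in range(p)], dtype=object),
        np.array([f"c{i}" for i in range(n)], dtype=object),
    )


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    return toy_counts(rng.integers(0, 30, size=(40, 12)))


@pytest.fixture
def balanced_labels() -> Labels:
    return Labels(np.repeat([0, 1], 20), 2)
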