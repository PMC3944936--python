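import numpy as np
import pytest

from psodt.data import ExpressionDataset


def make_dataset(values, labels, gene_names=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionDataset(
        values=values,
        gene_names=np.array(
            gene_names if gene_names is not None else [f"g{j + 1}" for j in range(m)],
            dtype=object,
        ),
        sample_ids=np.array(
            sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(n)],
            dtype=object,
        ),
        labels=np.array(labels, dtype=object),
    )


@pytest.fixture
def xor_dataset():
    """Two genes jointly (but not marginally) informative."""
    return make_dataset(
        [[1, 1], [1, 2], [2, 1], [2, 2]], ["A", "B", "B", "A"]
    )


@pytest.fixture
def separable_dataset():
    """One gene cleanly separates two classes; the other is constant."""
    return make_dataset(
        [[1, 5], [2, 5], [3, 5], [4, 5]], ["A", "A", "B", "B"]
    )


class StubRng:
    """Uniform-generator stand-in returning a fixed value."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class SequenceRng:
    """Uniform-generator stand-in replaying a queue of draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size=None):
        if size is None:
            return self.draws.pop(0)
        out = np.array(self.draws[:size], dtype=float)
        del self.draws[:size]
        return out
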