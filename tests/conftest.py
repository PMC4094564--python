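import numpy as np
import pytest

from markov_memory import PathCorpus, StateVocabulary


@pytest.fixture
def tiny_corpus() -> PathCorpus:
    return PathCorpus.from_paths([("a", "b"), ("a", "c", "a")])


@pytest.fixture
def two_state_vocab() -> StateVocabulary:
    return StateVocabulary.from_labels(["a"])  # m = 2 with RESET


def random_paths(n_paths: int, n_labels: int, seed: int, max_len: int = 12):
    """Plain random label paths (no Markov structure) for oracle tests."""
    rng = np.random.default_rng(seed)
    labels = [f"x{i}" for i in range(n_labels)]
    paths = []
    for _ in range(n_paths):
        L = int(rng.integers(1, max_len + 1))
        paths.append(tuple(labels[int(j)] for j in rng.integers(0, n_labels, size=L)))
    return paths


@pytest.fixture
def random_corpus() -> PathCorpus:
    return PathCorpus.from_paths(random_paths(100, 5, seed=42))
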