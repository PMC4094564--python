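"""Synthetic path corpora with known statistical structure.

Two generators cover the validation needs of the whole toolkit:

* a *uniform random corpus*: every click picks uniformly among ``n_states``
  symbols, one of which is a terminal marker that ends the current path (the
  terminal draw is not emitted; RESET augmentation later re-adds
  termination).  Path lengths in draws are geometric with rate 1/n_states.
* an *order-k Markov corpus* drawn from an explicit transition tensor over
  data states, with geometric (or fixed) path lengths and uniform initial
  histories — the ground truth for order-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import PathCorpus

__all__ = [
    "GeneratorSpec",
    "random_stochastic_tensor",
    "generate_uniform_corpus",
    "generate_markov_corpus",
]


def _default_labels(n: int, prefix: str = "s") -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def random_stochastic_tensor(
    n_states: int,
    order: int,
    concentration: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Transition tensor with rows drawn from a symmetric Dirichlet.

    Shape ``(n_states**order, n_states)``; row ``r`` conditions on the history
    whose base-``n_states`` code is ``r`` (oldest symbol most significant).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if order < 0:
        raise ValueError("order must be >= 0")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_states, concentration), size=n_states**order)


def generate_uniform_corpus(
    n_states: int = 26,
    total_clicks: int = 100_000,
    seed: int = 0,
) -> PathCorpus:
    """Memoryless control corpus: uniform draws, one terminal symbol.

    Draws states uniformly from ``n_states`` symbols; drawing the designated
    terminal symbol ends the current path.  Generation stops once the
    accumulated emitted clicks reach ``total_clicks``.  Zero-length paths are
    dropped; single-click paths are retained for the filtering stage.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if total_clicks < 1:
        raise ValueError("total_clicks must be >= 1")
    rng = np.random.default_rng(seed)
    labels = _default_labels(n_states - 1)
    terminal = n_states - 1
    paths: list[tuple[str, ...]] = []
    clicks = 0
    current: list[str] = []
    while clicks < total_clicks:
        block = rng.integers(0, n_states, size=max(1024, int(1.2 * (total_clicks - clicks)) + 32))
        for draw in block:
            if draw == terminal:
                if current:
                    paths.append(tuple(current))
                    clicks += len(current)
                    current = []
                    if clicks >= total_clicks:
                        break
            else:
                current.append(labels[draw])
        # an unfinished path at block end carries over into the next block
    vocab_labels = labels
    corpus = PathCorpus.from_paths(
        paths,
        vocabulary=None,
        validate=False,
    )
    # fix the vocabulary to the full emitted alphabet in label order
    from .corpus import StateVocabulary

    vocab = StateVocabulary.from_labels(vocab_labels)
    corpus = PathCorpus(paths=corpus.paths, vocabulary=vocab, meta={"generator": "uniform", "seed": seed})
    return corpus


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for an order-k Markov corpus.

    ``tensor`` has shape ``(n_states**order, n_states)`` over data states
    (RESET is not part of the tensor; termination is a separate geometric
    stop with probability ``stop_prob`` per click, or a ``fixed_length``).
    The first ``order`` states of every path are drawn uniformly.
    """

    n_states: int
    order: int
    tensor: np.ndarray
    total_clicks: int
    seed: int = 0
    stop_prob: float = 0.125
    fixed_length: int | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        tensor = np.asarray(self.tensor, dtype=float)
        if tensor.shape != (self.n_states**self.order, self.n_states):
            raise ValueError(
                f"tensor shape {tensor.shape} != {(self.n_states**self.order, self.n_states)}"
            )
        if np.any(tensor < 0) or not np.allclose(tensor.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("tensor rows must be stochastic")
        if self.fixed_length is None and not 0.0 < self.stop_prob < 1.0:
            raise ValueError("stop_prob must be in (0, 1)")


def generate_markov_corpus(spec: GeneratorSpec) -> PathCorpus:
    """Sample a corpus from the order-k chain described by ``spec``.

    Path lengths are geometric with rate ``stop_prob`` (or all equal to
    ``fixed_length``); paths are added until the click total reaches
    ``spec.total_clicks``.  Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    k = spec.order
    tensor = np.asarray(spec.tensor, dtype=float)
    cumtensor = np.cumsum(tensor, axis=1)
    labels = spec.labels if spec.labels is not None else _default_labels(n)

    # path lengths first (number of emitted clicks per path)
    lengths: list[int] = []
    clicks = 0
    while clicks < spec.total_clicks:
        if spec.fixed_length is not None:
            block = np.full(256, spec.fixed_length, dtype=np.int64)
        else:
            block = rng.geometric(spec.stop_prob, size=256)
        for L in block:
            lengths.append(int(L))
            clicks += int(L)
            if clicks >= spec.total_clicks:
                break
    lens = np.array(lengths, dtype=np.int64)
    P = len(lens)
    max_len = int(lens.max())
    states = np.full((P, max_len), -1, dtype=np.int64)

    powers = n ** np.arange(k - 1, -1, -1) if k > 0 else np.zeros(0, dtype=np.int64)
    for t in range(max_len):
        active = np.nonzero(lens > t)[0]
        if len(active) == 0:
            break
        if t < k:
            states[active, t] = rng.integers(0, n, size=len(active))
        else:
            hist = states[active, t - k : t]
            codes = hist @ powers if k > 0 else np.zeros(len(active), dtype=np.int64)
            rows = cumtensor[codes]
            u = rng.random(len(active))
            states[active, t] = np.minimum((rows < u[:, None]).sum(axis=1), n - 1)

    paths = [tuple(labels[s] for s in states[i, : lens[i]]) for i in range(P)]
    from .corpus import StateVocabulary

    vocab = StateVocabulary.from_labels(labels)
    return PathCorpus(
        paths=tuple(paths),
        vocabulary=vocab,
        meta={"generator": "markov", "order": k, "seed": spec.seed},
    )
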