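"""Maximum-likelihood and Dirichlet-posterior estimation of transition tables.

Every row of an order-k transition matrix is a categorical distribution over
the ``m`` states (data states plus RESET).  The MLE is the row-wise count
ratio ``n_ij / n_i``; with a conjugate Dirichlet prior (hyperparameters act
as pseudo-counts, ``alpha = 1`` is Laplace smoothing) the posterior-mean row
is ``(alpha_ij + n_ij) / (A_i + n_i)``, a convex combination of the MLE and
the prior mean that guarantees strictly positive probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import Path, PathCorpus, StateVocabulary, TransitionCounts, augment_and_count

__all__ = [
    "MarkovModel",
    "mle_estimate",
    "log_likelihood",
    "posterior_mean_model",
    "posterior_variance",
    "MarkovChain",
]

ROW_SUM_TOL = 1e-9


def _alpha_vector(alpha: Union[float, Sequence[float], np.ndarray], m: int) -> np.ndarray:
    vec = np.broadcast_to(np.asarray(alpha, dtype=float), (m,)).copy()
    if np.any(vec <= 0):
        raise ValueError("Dirichlet hyperparameters must be strictly positive")
    return vec


@dataclass(frozen=True)
class MarkovModel:
    """Order-k stochastic transition table over observed histories.

    ``probs[r]`` is the probability row of the history with code
    ``history_codes[r]`` (same encoding as :class:`TransitionCounts`).
    ``default_row`` (the prior mean) covers histories never observed in
    training; it is ``None`` for the MLE, whose unobserved rows are undefined.
    """

    order: int
    vocabulary: StateVocabulary
    history_codes: np.ndarray
    probs: np.ndarray
    estimator_tag: str  # "mle" | "posterior_mean"
    alpha: np.ndarray | None = None
    default_row: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.probs) and not np.allclose(self.probs.sum(axis=1), 1.0, atol=ROW_SUM_TOL):
            raise ValueError("transition rows must sum to 1")

    @property
    def m(self) -> int:
        return self.vocabulary.m

    @property
    def n_histories(self) -> int:
        return len(self.history_codes)

    def _locate(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row indices into ``probs`` for history codes; boolean found mask."""
        pos = np.searchsorted(self.history_codes, codes)
        pos_c = np.minimum(pos, max(len(self.history_codes) - 1, 0))
        found = (
            (len(self.history_codes) > 0)
            & (pos < len(self.history_codes))
            & (self.history_codes[pos_c] == codes)
        )
        return pos_c, np.asarray(found)

    def encode_history(self, history: Sequence[str]) -> int:
        if len(history) != self.order:
            raise ValueError(f"history length {len(history)} != order {self.order}")
        code = 0
        for s in history:
            code = code * self.m + self.vocabulary.index(s)
        return code

    def has_history(self, history: Sequence[str]) -> bool:
        code = self.encode_history(history)
        pos = np.searchsorted(self.history_codes, code)
        return pos < len(self.history_codes) and self.history_codes[pos] == code

    def row(self, history: Sequence[str]) -> np.ndarray:
        code = self.encode_history(history)
        pos = np.searchsorted(self.history_codes, code)
        if pos < len(self.history_codes) and self.history_codes[pos] == code:
            return self.probs[pos]
        if self.default_row is not None:
            return self.default_row
        raise KeyError(
            f"history {tuple(history)!r} unobserved under MLE; "
            "use a posterior-mean (smoothed) model for unseen histories"
        )

    def to_frame(self):
        """Probability table as a pandas DataFrame (histories x state labels)."""
        import pandas as pd

        vocab = self.vocabulary
        index = ["|".join(self._decode(int(c))) for c in self.history_codes]
        return pd.DataFrame(self.probs, index=index, columns=list(vocab.all_labels))

    def _decode(self, code: int) -> Path:
        digits = []
        for _ in range(self.order):
            code, d = divmod(code, self.m)
            digits.append(d)
        return self.vocabulary.decode(reversed(digits))


def mle_estimate(counts: TransitionCounts) -> MarkovModel:
    """Row-wise maximum-likelihood estimate n_ij / n_i on observed histories."""
    if counts.total_transitions <= 0:
        raise ValueError("counts must contain at least one transition")
    totals = counts.row_totals().astype(float)
    probs = counts.matrix / totals[:, None]
    return MarkovModel(
        order=counts.order,
        vocabulary=counts.vocabulary,
        history_codes=counts.history_codes,
        probs=probs,
        estimator_tag="mle",
    )


def posterior_mean_model(
    counts: TransitionCounts,
    alpha: Union[float, Sequence[float], np.ndarray] = 1.0,
) -> MarkovModel:
    """Dirichlet posterior-mean table (alpha_ij + n_ij) / (A_i + n_i).

    ``alpha`` is a scalar or a length-m vector applied to every history row
    of the full nominal table; unobserved histories fall back to the prior
    mean row ``alpha / A``.
    """
    m = counts.m
    alpha_vec = _alpha_vector(alpha, m)
    A = alpha_vec.sum()
    totals = counts.row_totals().astype(float)
    probs = (counts.matrix + alpha_vec) / (totals + A)[:, None]
    return MarkovModel(
        order=counts.order,
        vocabulary=counts.vocabulary,
        history_codes=counts.history_codes,
        probs=probs,
        estimator_tag="posterior_mean",
        alpha=alpha_vec,
        default_row=alpha_vec / A,
    )


def posterior_variance(
    counts: TransitionCounts,
    alpha: Union[float, Sequence[float], np.ndarray],
    history: Sequence[str],
    state: str,
) -> float:
    """Posterior variance u(1-u) / (A + n_i + 1) of one transition probability."""
    m = counts.m
    alpha_vec = _alpha_vector(alpha, m)
    j = counts.vocabulary.index(state)
    code = counts.encode_history(history)  # unknown labels raise here
    pos = int(np.searchsorted(counts.history_codes, code))
    if pos < counts.n_histories and counts.history_codes[pos] == code:
        row = counts.matrix[pos].astype(float)
    else:
        row = np.zeros(m)  # unobserved history: pure prior
    A = alpha_vec.sum()
    n_i = row.sum()
    u = (alpha_vec[j] + row[j]) / (A + n_i)
    return float(u * (1.0 - u) / (A + n_i + 1.0))


def log_likelihood(model: MarkovModel, counts: TransitionCounts) -> float:
    """Sum of n_ij * log p_ij; 0*log 0 = 0 and unexplained transitions give -inf."""
    if model.order != counts.order:
        raise ValueError(f"order mismatch: model {model.order} vs counts {counts.order}")
    if model.vocabulary is not counts.vocabulary and model.vocabulary != counts.vocabulary:
        raise ValueError("model and counts use different vocabularies")
    pos, found = model._locate(counts.history_codes)
    total = 0.0
    if found.any():
        n = counts.matrix[found]
        p = model.probs[pos[found]]
        mask = n > 0
        if np.any(p[mask] <= 0.0):
            return float("-inf")
        total += float(np.sum(n[mask] * np.log(p[mask])))
    if not found.all():
        n = counts.matrix[~found]
        if model.default_row is None:
            if n.sum() > 0:
                return float("-inf")
        else:
            mask = n > 0
            p = np.broadcast_to(model.default_row, n.shape)
            if np.any(p[mask] <= 0.0):
                return float("-inf")
            total += float(np.sum(n[mask] * np.log(p[mask])))
    return total


class MarkovChain(BaseEstimator):
    """scikit-learn style estimator for an order-k Markov chain over paths.

    Parameters
    ----------
    order : history length k >= 0 (k = 0 is weighted random selection).
    alpha : Dirichlet hyperparameter (scalar or length-m vector); only used by
        the ``"posterior_mean"`` method.
    method : ``"posterior_mean"`` (smoothed, default) or ``"mle"``.

    After :meth:`fit`: ``vocabulary_``, ``counts_``, ``model_``,
    ``n_transitions_`` and the training ``log_likelihood_``.
    """

    def __init__(self, order: int = 1, alpha: float = 1.0, method: str = "posterior_mean"):
        self.order = order
        self.alpha = alpha
        self.method = method

    def _as_corpus(self, X) -> PathCorpus:
        if isinstance(X, PathCorpus):
            return X
        return PathCorpus.from_paths(X)

    def fit(self, X, y=None) -> "MarkovChain":
        if self.method not in ("mle", "posterior_mean"):
            raise ValueError(f"unknown method {self.method!r}")
        if not isinstance(self.order, (int, np.integer)) or self.order < 0:
            raise ValueError("order must be a non-negative integer")
        corpus = self._as_corpus(X)
        self.vocabulary_ = corpus.vocabulary
        self.counts_ = augment_and_count(corpus, self.order)
        if self.method == "mle":
            self.model_ = mle_estimate(self.counts_)
        else:
            self.model_ = posterior_mean_model(self.counts_, self.alpha)
        self.n_transitions_ = self.counts_.total_transitions
        self.log_likelihood_ = log_likelihood(self.model_, self.counts_)
        return self

    def score(self, X=None, y=None) -> float:
        """Total log-likelihood of a corpus (training corpus if X is None)."""
        if X is None:
            return log_likelihood(self.model_, self.counts_)
        corpus = self._as_corpus(X)
        counts = augment_and_count(
            PathCorpus(paths=corpus.paths, vocabulary=self.vocabulary_, meta=corpus.meta),
            self.order,
        )
        return log_likelihood(self.model_, counts)

    def predict_proba(self, histories: Iterable[Sequence[str]]) -> np.ndarray:
        """Next-state probability rows for each history (column order: labels, RESET last)."""
        return np.stack([self.model_.row(h) for h in histories])
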