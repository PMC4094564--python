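"""Structural transition analyses: global heatmap tables, local top
transitions, self-transition ("stickiness") profiles, endpoint splits.

The global table normalises every transition count by the grand total (not
row-wise), so all cells sum to one and the table reads as the joint
distribution of (history, next) pairs.  Self-transition profiles measure the
probability of staying in a category given a history of k consecutive
occurrences of it — rising stay probabilities with k are the signature of
topical stickiness.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import PathCorpus, TransitionCounts, augment_and_count
from .estimation import MarkovModel

__all__ = [
    "global_transition_table",
    "top_transitions",
    "top_transition_edges",
    "self_transition_profile",
    "split_by_endpoints",
]


def global_transition_table(counts: TransitionCounts) -> pd.DataFrame:
    """Counts normalised by the grand total N (cells sum to 1).

    For order 1 the result is the full labelled m x m matrix including RESET;
    for higher orders rows are the observed histories (labels joined by '|').
    """
    if counts.order < 1:
        raise ValueError("global transition table requires order >= 1")
    N = counts.total_transitions
    if N == 0:
        raise ValueError("no transitions to normalise")
    labels = list(counts.vocabulary.all_labels)
    weights = counts.matrix / N
    if counts.order == 1:
        full = pd.DataFrame(0.0, index=labels, columns=labels)
        row_labels = [counts.decode_history(int(c))[0] for c in counts.history_codes]
        for lab, w in zip(row_labels, weights):
            full.loc[lab] = w
        return full
    index = ["|".join(counts.decode_history(int(c))) for c in counts.history_codes]
    return pd.DataFrame(weights, index=index, columns=labels)


def top_transitions(
    model: MarkovModel,
    history: Sequence[str],
    top_n: int = 4,
) -> list[tuple[str, float]]:
    """The ``top_n`` most probable targets out of one history, with probabilities.

    Ties are broken by label order; ``top_n >= m`` returns the full row.
    Unknown histories raise under MLE (a smoothed model resolves them).
    """
    row = model.row(history)  # KeyError advice handled by MarkovModel.row
    labels = model.vocabulary.all_labels
    order = sorted(range(model.m), key=lambda j: (-row[j], labels[j]))
    return [(labels[j], float(row[j])) for j in order[: max(0, top_n)]]


def top_transition_edges(model: MarkovModel, top_n: int = 4) -> pd.DataFrame:
    """Edge list of the ``top_n`` strongest transitions out of every observed history.

    Columns: ``source`` (history labels joined by '|'), ``target``,
    ``probability`` — the graph-drawing-ready export of local structure.
    """
    rows = []
    for code in model.history_codes:
        history = model._decode(int(code))
        for target, prob in top_transitions(model, history, top_n=top_n):
            rows.append({"source": "|".join(history), "target": target, "probability": prob})
    return pd.DataFrame(rows, columns=["source", "target", "probability"])


def self_transition_profile(
    corpus: PathCorpus,
    categories: Iterable[str] | None = None,
    k_range: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Stay vs. switch behaviour per category and conditioning order.

    For category c and order k the history is k consecutive occurrences of c;
    ``stay_prob`` = n(c^k -> c) / n(c^k -> any).  RESET is excluded (its runs
    are structural).  Unobserved histories yield NaN probabilities.
    """
    vocab = corpus.vocabulary
    if categories is None:
        categories = vocab.labels
    else:
        categories = tuple(categories)
        unknown = [c for c in categories if c not in set(vocab.labels)]
        if unknown:
            raise ValueError(f"unknown categories: {unknown}")
    rows = []
    for k in k_range:
        counts = augment_and_count(corpus, k)
        for c in categories:
            history = (c,) * k
            try:
                row = counts.row(history)
            except KeyError:
                rows.append(
                    dict(category=c, order=k, stay_count=0, switch_count=0,
                         stay_prob=np.nan, switch_prob=np.nan)
                )
                continue
            total = int(row.sum())
            stay = int(row[vocab.index(c)])
            rows.append(
                dict(
                    category=c,
                    order=k,
                    stay_count=stay,
                    switch_count=total - stay,
                    stay_prob=stay / total,
                    switch_prob=(total - stay) / total,
                )
            )
    return pd.DataFrame(rows)


def split_by_endpoints(corpus: PathCorpus) -> tuple[PathCorpus, PathCorpus]:
    """Partition paths by whether the first and last state coincide.

    Returns ``(same, different)``; both sub-corpora keep the vocabulary.
    """
    same_idx = [i for i, p in enumerate(corpus.paths) if p and p[0] == p[-1]]
    diff_idx = [i for i, p in enumerate(corpus.paths) if p and p[0] != p[-1]]
    return (
        corpus.subset(same_idx, note="endpoints=same"),
        corpus.subset(diff_idx, note="endpoints=different"),
    )
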