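"""Stratified 10-fold evaluation of next-state prediction quality per order.

Whole paths are packed into folds that hold approximately equal click totals.
For each fold a posterior-mean (smoothed) model of every candidate order is
trained on the remaining folds and scored on the held-out transitions by the
average rank of the true next state under *modified competition ranking*
(ties all receive the worst rank of their tie group, "14445"), plus an
optional Top-K hit rate.  Sparse higher-order tables produce many smoothed
ties and unseen histories (scored at the maximum rank m), which is the
natural complexity penalty of this criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .corpus import PathCorpus, TransitionCounts, augment_and_count
from .estimation import MarkovModel, posterior_mean_model

__all__ = [
    "FoldAssignment",
    "make_stratified_folds",
    "ranks_with_ties",
    "average_rank",
    "topk_hit_rate",
    "CVResult",
    "cv_order_evaluation",
]


@dataclass(frozen=True)
class FoldAssignment:
    n_folds: int
    assignment: np.ndarray  # path index -> fold id
    fold_clicks: np.ndarray  # clicks per fold

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]


def make_stratified_folds(corpus: PathCorpus, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Greedy click-balanced packing of whole paths into folds.

    Paths are shuffled (seeded) and each is assigned to the currently lightest
    fold by click count, so fold totals differ by at most the longest path.
    """
    if corpus.n_paths < n_folds:
        raise ValueError(f"need at least {n_folds} paths, got {corpus.n_paths}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(corpus.n_paths)
    lengths = corpus.path_lengths()
    assignment = np.empty(corpus.n_paths, dtype=np.int64)
    loads = np.zeros(n_folds, dtype=np.int64)
    for i in order:
        f = int(np.argmin(loads))
        assignment[i] = f
        loads[f] += lengths[i]
    return FoldAssignment(n_folds=n_folds, assignment=assignment, fold_clicks=loads)


def ranks_with_ties(row: np.ndarray) -> np.ndarray:
    """Modified competition ranks of a probability row (descending, worst-of-tie).

    rank_i = #\\{j : p_j >= p_i\\}, e.g. (0.4, 0.2, 0.2, 0.2, 0.1) -> (1, 4, 4, 4, 5).
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise ValueError("expected a 1-D probability row")
    if not np.all(np.isfinite(row)) or np.any(row < 0):
        raise ValueError("row entries must be finite and non-negative")
    srt = np.sort(row)
    return (len(row) - np.searchsorted(srt, row, side="left")).astype(np.int64)


def _rank_matrix(probs: np.ndarray) -> np.ndarray:
    """Row-wise modified competition ranks for a stack of rows (m is small)."""
    return (probs[:, None, :] >= probs[:, :, None]).sum(axis=2)


def average_rank(
    model: MarkovModel,
    test_counts: TransitionCounts,
    allow_mle: bool = False,
) -> float:
    """Mean rank of the true next state over all held-out transitions.

    Histories never observed in training assign the maximum rank m to every
    state.  Requires a smoothed (posterior-mean) model unless ``allow_mle``.
    """
    if model.order != test_counts.order:
        raise ValueError("order mismatch between model and test counts")
    if model.estimator_tag != "posterior_mean" and not allow_mle:
        raise ValueError("average_rank requires a posterior-mean model (pass allow_mle=True to override)")
    m = model.m
    N = test_counts.total_transitions
    if N == 0:
        raise ValueError("empty test counts")
    pos, found = model._locate(test_counts.history_codes)
    total = 0.0
    if found.any():
        ranks = _rank_matrix(model.probs[pos[found]])
        total += float((ranks * test_counts.matrix[found]).sum())
    if not found.all():
        total += float(m * test_counts.matrix[~found].sum())
    return total / N


def topk_hit_rate(
    model: MarkovModel,
    test_counts: TransitionCounts,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Fraction of held-out transitions whose true next state is in the Top-K.

    Tie groups straddling the K boundary are resolved by seeded uniform draws
    among the tied states (one draw per test transition).
    """
    m = model.m
    if not 1 <= k <= m:
        raise ValueError(f"K must be in 1..{m}")
    if model.order != test_counts.order:
        raise ValueError("order mismatch between model and test counts")
    rng = np.random.default_rng(seed)
    N = test_counts.total_transitions
    if N == 0:
        raise ValueError("empty test counts")
    pos, found = model._locate(test_counts.history_codes)
    hits = 0.0
    for r in range(test_counts.n_histories):
        counts_row = test_counts.matrix[r]
        nz = np.nonzero(counts_row)[0]
        if len(nz) == 0:
            continue
        if found[r]:
            p = model.probs[pos[r]]
        elif model.default_row is not None:
            p = model.default_row
        else:
            raise KeyError("test history unobserved under MLE model")
        worst = ranks_with_ties(p)
        for j in nz:
            n = int(counts_row[j])
            w = int(worst[j])
            g = int(np.sum(p == p[j]))
            b = w - g + 1
            if w <= k:
                hits += n
            elif b <= k:
                hits += rng.binomial(n, (k - b + 1) / g)
    return hits / N


@dataclass
class CVResult:
    """Per-order, per-fold average ranks with fold means and optional Top-K rates."""

    ranks: pd.DataFrame  # index order, columns fold id
    mean_rank: pd.Series
    sd_rank: pd.Series
    topk: pd.DataFrame | None
    selected_order: int
    n_folds: int
    seed: int

    def to_tsv(self, file) -> None:
        out = self.ranks.copy()
        out["mean"] = self.mean_rank
        out["sd"] = self.sd_rank
        out.to_csv(file, sep="\t", index_label="order")


def cv_order_evaluation(
    corpus: PathCorpus,
    k_max: int = 5,
    alpha: Union[float, Sequence[float], np.ndarray] = 1.0,
    n_folds: int = 10,
    seed: int = 0,
    topk: int | None = None,
    score_reset: bool = True,
) -> CVResult:
    """Cross-validated average rank (and optional Top-K hit rate) per order.

    ``score_reset=False`` excludes transitions into RESET (path endings) from
    scoring.  One master seed derives the fold shuffle and the tie-break
    streams.
    """
    ss = np.random.SeedSequence(seed)
    fold_seed, tie_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    folds = make_stratified_folds(corpus, n_folds=n_folds, seed=fold_seed)
    orders = list(range(k_max + 1))
    ranks = np.zeros((len(orders), n_folds))
    hitrates = np.zeros((len(orders), n_folds)) if topk is not None else None
    for f in range(n_folds):
        test_idx = folds.fold_indices(f)
        train_idx = np.nonzero(folds.assignment != f)[0]
        train = corpus.subset(train_idx)
        test = corpus.subset(test_idx)
        for ki, k in enumerate(orders):
            train_counts = augment_and_count(train, k)
            model = posterior_mean_model(train_counts, alpha)
            test_counts = augment_and_count(test, k)
            if not score_reset:
                test_counts = test_counts.drop_target(corpus.vocabulary.reset_label)
            ranks[ki, f] = average_rank(model, test_counts)
            if topk is not None:
                hitrates[ki, f] = topk_hit_rate(model, test_counts, k=topk, seed=tie_seed + f)
    rank_df = pd.DataFrame(ranks, index=pd.Index(orders, name="order"), columns=range(n_folds))
    mean = rank_df.mean(axis=1)
    sd = rank_df.std(axis=1, ddof=1)
    topk_df = (
        pd.DataFrame(hitrates, index=pd.Index(orders, name="order"), columns=range(n_folds))
        if topk is not None
        else None
    )
    return CVResult(
        ranks=rank_df,
        mean_rank=mean,
        sd_rank=sd,
        topk=topk_df,
        selected_order=int(mean.idxmin()),
        n_folds=n_folds,
        seed=seed,
    )
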