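"""Path corpora over a finite categorical alphabet and order-k transition counts.

A *path* is an ordered tuple of opaque string labels (one user session, one
game, ...).  A :class:`PathCorpus` holds many paths over a shared
:class:`StateVocabulary` that reserves one artificial RESET label.  For a
Markov chain of order ``k`` every path is independently augmented with ``k``
leading RESET symbols and one trailing RESET symbol, so histories never leak
across paths and path termination is itself a predictable event.  Sliding
windows of (length-k history, next state) over the augmented paths are
tallied into a :class:`TransitionCounts` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path as FilePath
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "StateVocabulary",
    "PathCorpus",
    "TransitionCounts",
    "read_paths",
    "write_paths",
    "read_msnbc",
    "filter_min_length",
    "relabel",
    "augment_and_count",
    "counts_to_tsv",
    "counts_from_tsv",
]

#: A raw, un-augmented path.
Path = tuple[str, ...]

# Largest history code must fit into int64 with one extra base-m digit for the
# target state.
_CODE_LIMIT = 2**62


def _generate_reset_label(labels: Iterable[str]) -> str:
    seen = set(labels)
    candidate = "RESET"
    while candidate in seen:
        candidate += "*"
    return candidate


@dataclass(frozen=True)
class StateVocabulary:
    """Ordered state labels plus the reserved RESET symbol.

    ``m`` counts all states including RESET; internally states are indexed
    densely in first-seen order and RESET always takes index ``m - 1``.
    """

    labels: tuple[str, ...]
    reset_label: str = "RESET"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        if self.reset_label in self.labels:
            raise ValueError("reserved label in data: %r" % self.reset_label)

    @classmethod
    def from_labels(cls, labels: Iterable[str], reset_label: str | None = None) -> "StateVocabulary":
        labels = tuple(dict.fromkeys(labels))
        if reset_label is None:
            reset_label = _generate_reset_label(labels)
        elif reset_label in labels:
            raise ValueError("reserved label in data: %r" % reset_label)
        return cls(labels=labels, reset_label=reset_label)

    @property
    def m(self) -> int:
        """Total state count including RESET."""
        return len(self.labels) + 1

    @property
    def reset_index(self) -> int:
        return self.m - 1

    @cached_property
    def _index(self) -> dict[str, int]:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        idx[self.reset_label] = len(self.labels)
        return idx

    @cached_property
    def all_labels(self) -> tuple[str, ...]:
        """Labels in index order, RESET last."""
        return self.labels + (self.reset_label,)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown state label {label!r}") from None

    def label(self, index: int) -> str:
        return self.all_labels[index]

    def encode(self, path: Sequence[str]) -> np.ndarray:
        idx = self._index
        return np.fromiter((idx[s] for s in path), dtype=np.int64, count=len(path))

    def decode(self, indices: Iterable[int]) -> Path:
        labs = self.all_labels
        return tuple(labs[i] for i in indices)


@dataclass(frozen=True)
class PathCorpus:
    """A set of categorical paths over a shared vocabulary."""

    paths: tuple[Path, ...]
    vocabulary: StateVocabulary
    meta: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_paths(
        cls,
        paths: Iterable[Sequence[str]],
        vocabulary: StateVocabulary | None = None,
        reset_label: str | None = None,
        meta: dict | None = None,
        validate: bool = True,
    ) -> "PathCorpus":
        paths = tuple(tuple(p) for p in paths)
        if vocabulary is None:
            seen: dict[str, None] = {}
            for p in paths:
                for s in p:
                    seen.setdefault(s)
            vocabulary = StateVocabulary.from_labels(seen, reset_label=reset_label)
        if validate:
            known = set(vocabulary.labels)
            for p in paths:
                for s in p:
                    if s not in known:
                        if s == vocabulary.reset_label:
                            raise ValueError("reserved label in data: %r" % s)
                        raise ValueError(f"path symbol {s!r} not in vocabulary")
        return cls(paths=paths, vocabulary=vocabulary, meta=dict(meta or {}))

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def n_clicks(self) -> int:
        """Total number of visited states (tuple lengths summed)."""
        return sum(len(p) for p in self.paths)

    def path_lengths(self) -> np.ndarray:
        return np.fromiter((len(p) for p in self.paths), dtype=np.int64, count=len(self.paths))

    def subset(self, indices: Iterable[int], note: str | None = None) -> "PathCorpus":
        meta = dict(self.meta)
        if note:
            meta["filters"] = list(meta.get("filters", [])) + [note]
        return PathCorpus(
            paths=tuple(self.paths[i] for i in indices),
            vocabulary=self.vocabulary,
            meta=meta,
        )


def read_paths(
    file: Union[str, FilePath],
    delimiter: str = "\t",
    reset_label: str | None = None,
) -> PathCorpus:
    """Read a delimited-text corpus: one path per line, blank lines ignored."""
    text = FilePath(file).read_text(encoding="utf-8")
    paths: list[Path] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        paths.append(tuple(tok for tok in line.split(delimiter) if tok != ""))
    if not paths:
        raise ValueError("empty corpus")
    if reset_label is not None:
        if any(reset_label in p for p in paths):
            raise ValueError("reserved label in data: %r" % reset_label)
    corpus = PathCorpus.from_paths(paths, reset_label=reset_label, validate=False)
    corpus.meta["source"] = str(file)
    return corpus


def write_paths(corpus: PathCorpus, file: Union[str, FilePath], delimiter: str = "\t") -> None:
    with open(file, "w", encoding="utf-8") as fh:
        for p in corpus.paths:
            fh.write(delimiter.join(p) + "\n")


def read_msnbc(file: Union[str, FilePath], reset_label: str | None = None) -> PathCorpus:
    """Read the UCI-KDD anonymous web-data sequence dialect.

    Layout: ``%``-prefixed comment lines, one legend line naming the
    categories in order, then one space-separated sequence of 1-based
    category indices per line (one user session per line).
    """
    legend: list[str] | None = None
    paths: list[Path] = []
    with open(file, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("%"):
                continue
            if legend is None:
                legend = stripped.split()
                continue
            path = []
            for tok in stripped.split():
                try:
                    idx = int(tok)
                except ValueError:
                    raise ValueError(f"line {lineno}: non-integer token {tok!r}") from None
                if not 1 <= idx <= len(legend):
                    raise ValueError(
                        f"line {lineno}: category index {idx} outside legend range 1..{len(legend)}"
                    )
                path.append(legend[idx - 1])
            paths.append(tuple(path))
    if legend is None:
        raise ValueError("missing legend line")
    if not paths:
        raise ValueError("empty corpus")
    vocab = StateVocabulary.from_labels(legend, reset_label=reset_label)
    corpus = PathCorpus.from_paths(paths, vocabulary=vocab, validate=False)
    corpus.meta["source"] = str(file)
    corpus.meta["format"] = "msnbc"
    return corpus


def filter_min_length(corpus: PathCorpus, min_len: int = 2) -> PathCorpus:
    """Keep only paths with at least ``min_len`` visited states."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [i for i, p in enumerate(corpus.paths) if len(p) >= min_len]
    if not kept:
        raise ValueError("empty corpus after filtering")
    return corpus.subset(kept, note=f"min_length>={min_len}")


def relabel(
    corpus: PathCorpus,
    mapping: Mapping[str, Union[str, Sequence[str]]],
    seed: int = 0,
) -> PathCorpus:
    """Replace every state label by its category.

    Labels mapping to several equally ranked categories are resolved by one
    uniform draw *per label* (the same category replaces every occurrence),
    reproducible under ``seed``.
    """
    missing = [lab for lab in corpus.vocabulary.labels if lab not in mapping]
    if missing:
        raise ValueError(f"unmapped labels: {missing}")
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for lab in corpus.vocabulary.labels:  # first-seen order: deterministic
        val = mapping[lab]
        if isinstance(val, str):
            chosen[lab] = val
        else:
            options = sorted(val)
            if not options:
                raise ValueError(f"unmapped labels: [{lab!r}]")
            chosen[lab] = options[int(rng.integers(len(options)))] if len(options) > 1 else options[0]
    new_paths = [tuple(chosen[s] for s in p) for p in corpus.paths]
    out = PathCorpus.from_paths(new_paths, validate=False)
    out.meta.update(corpus.meta)
    out.meta["relabeled"] = True
    return out


@dataclass(frozen=True)
class TransitionCounts:
    """Sparse order-k transition counts n(history -> next).

    Histories are encoded as base-``m`` integers (first history symbol is the
    most significant digit); ``matrix[r, j]`` is the count of transitions from
    the history with code ``history_codes[r]`` into state index ``j``.
    ``history_codes`` is sorted ascending.
    """

    order: int
    vocabulary: StateVocabulary
    history_codes: np.ndarray  # (R,) int64, sorted
    matrix: np.ndarray  # (R, m) int64

    @property
    def m(self) -> int:
        return self.vocabulary.m

    @property
    def n_histories(self) -> int:
        return len(self.history_codes)

    @property
    def total_transitions(self) -> int:
        return int(self.matrix.sum())

    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def encode_history(self, history: Sequence[str]) -> int:
        if len(history) != self.order:
            raise ValueError(f"history length {len(history)} != order {self.order}")
        code = 0
        for s in history:
            code = code * self.m + self.vocabulary.index(s)
        return code

    def decode_history(self, code: int) -> Path:
        digits = []
        for _ in range(self.order):
            code, d = divmod(code, self.m)
            digits.append(d)
        return self.vocabulary.decode(reversed(digits))

    def row_index(self, history: Sequence[str]) -> int:
        code = self.encode_history(history)
        pos = int(np.searchsorted(self.history_codes, code))
        if pos == len(self.history_codes) or self.history_codes[pos] != code:
            raise KeyError(f"history {tuple(history)!r} not observed")
        return pos

    def row(self, history: Sequence[str]) -> np.ndarray:
        return self.matrix[self.row_index(history)]

    def histories(self) -> Iterable[Path]:
        for code in self.history_codes:
            yield self.decode_history(int(code))

    def items(self) -> Iterable[tuple[Path, np.ndarray]]:
        for r, code in enumerate(self.history_codes):
            yield self.decode_history(int(code)), self.matrix[r]

    def drop_target(self, label: str) -> "TransitionCounts":
        """Zero out one target column (e.g. exclude RESET-endings from scoring)."""
        j = self.vocabulary.index(label)
        matrix = self.matrix.copy()
        matrix[:, j] = 0
        keep = matrix.sum(axis=1) > 0
        return replace(self, matrix=matrix[keep], history_codes=self.history_codes[keep])


def augment_and_count(corpus: PathCorpus, order: int) -> TransitionCounts:
    """RESET-augment every path and tally all order-k transition windows.

    Each path of length L contributes exactly L+1 windows; windows never span
    two paths, so the total transition count is sum over paths of (L_p + 1).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if not corpus.paths:
        raise ValueError("empty corpus")
    vocab = corpus.vocabulary
    m = vocab.m
    k = order
    if m ** (k + 1) > _CODE_LIMIT:
        raise ValueError(f"order {k} too large for {m} states (history code overflow)")
    reset = vocab.reset_index

    encoded = [vocab.encode(p) for p in corpus.paths]
    lengths = np.fromiter((len(e) for e in encoded), dtype=np.int64, count=len(encoded))
    pad = np.full(k, reset, dtype=np.int64)
    tail = np.array([reset], dtype=np.int64)
    pieces: list[np.ndarray] = []
    for e in encoded:
        if k:
            pieces.append(pad)
        pieces.append(e)
        pieces.append(tail)
    arr = np.concatenate(pieces)

    aug_lengths = lengths + k + 1
    starts = np.concatenate(([0], np.cumsum(aug_lengths)[:-1]))
    n_windows = lengths + 1
    total = int(n_windows.sum())
    rep_starts = np.repeat(starts, n_windows)
    offsets = np.arange(total) - np.repeat(
        np.concatenate(([0], np.cumsum(n_windows)[:-1])), n_windows
    )
    ws = rep_starts + offsets

    codes = np.zeros(total, dtype=np.int64)
    for j in range(k + 1):
        codes = codes * m + arr[ws + j]

    uniq, cnt = np.unique(codes, return_counts=True)
    hist = uniq // m
    targ = uniq % m
    hcodes = np.unique(hist)
    rows = np.searchsorted(hcodes, hist)
    matrix = np.zeros((len(hcodes), m), dtype=np.int64)
    matrix[rows, targ] = cnt
    return TransitionCounts(order=k, vocabulary=vocab, history_codes=hcodes, matrix=matrix)


_HISTORY_SEP = "|"


def counts_to_tsv(counts: TransitionCounts, file: Union[str, FilePath], history_sep: str = _HISTORY_SEP) -> None:
    """Write integer counts as TSV (bit-exact round-trip via ``counts_from_tsv``)."""
    vocab = counts.vocabulary
    with open(file, "w", encoding="utf-8") as fh:
        fh.write(f"# order={counts.order}\n")
        fh.write(f"# reset={vocab.reset_label}\n")
        fh.write("# labels=" + history_sep.join(vocab.labels) + "\n")
        fh.write("history\ttarget\tcount\n")
        for history, row in counts.items():
            hstr = history_sep.join(history)
            for j in np.nonzero(row)[0]:
                fh.write(f"{hstr}\t{vocab.label(int(j))}\t{int(row[j])}\n")


def counts_from_tsv(file: Union[str, FilePath], history_sep: str = _HISTORY_SEP) -> TransitionCounts:
    order = None
    reset = None
    labels: tuple[str, ...] = ()
    cells: list[tuple[str, str, int]] = []
    with open(file, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# order="):
                order = int(line.split("=", 1)[1])
            elif line.startswith("# reset="):
                reset = line.split("=", 1)[1]
            elif line.startswith("# labels="):
                labels = tuple(line.split("=", 1)[1].split(history_sep))
            elif not line or line.startswith("history\t"):
                continue
            else:
                hstr, target, count = line.split("\t")
                cells.append((hstr, target, int(count)))
    if order is None or reset is None:
        raise ValueError("missing counts metadata header")
    vocab = StateVocabulary(labels=labels, reset_label=reset)
    m = vocab.m
    rows: dict[int, np.ndarray] = {}
    for hstr, target, count in cells:
        history = tuple(hstr.split(history_sep)) if order > 0 else ()
        code = 0
        for s in history:
            code = code * m + vocab.index(s)
        row = rows.setdefault(code, np.zeros(m, dtype=np.int64))
        row[vocab.index(target)] = count
    hcodes = np.array(sorted(rows), dtype=np.int64)
    matrix = np.stack([rows[int(c)] for c in hcodes]) if len(hcodes) else np.zeros((0, m), dtype=np.int64)
    return TransitionCounts(order=order, vocabulary=vocab, history_codes=hcodes, matrix=matrix)


def nominal_history_space(vocab: StateVocabulary, order: int) -> Iterable[Path]:
    """All m^k label histories (small m/k only; used by quadrature cross-checks)."""
    return itertools.product(vocab.all_labels, repeat=order)
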