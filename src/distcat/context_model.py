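"""Lexically specific distributional contexts and longitudinal co-occurrence.

For every token of an utterance, up to five local contexts are collected:
the preceding bigram (``w-1_X``), the following bigram (``X_w+1``), the
preceding trigram (``w-2_w-1_X``), the following trigram (``X_w+1_w+2``)
and the surrounding frame (``w-1_X_w+1``), where ``X`` marks the target
slot. A single boundary symbol (``#start`` / ``#end``) fills the slot
immediately outside the utterance on each side; a template that would
need a slot *beyond* a boundary symbol is simply omitted. Both targets
and context elements are homograph-disambiguated word keys.

Co-occurrence counting is longitudinal: each corpus is traversed in
chronological order and a word x context count matrix is accumulated on
growing prefixes of the utterance list (the first 40%, 50%, ... up to
100%), giving seven time slices per corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .corpus_io import END, START, TaggedCorpus, assign_word_keys

#: The seven prefix fractions of the longitudinal design.
SLICE_FRACTIONS = (0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00)

#: Context template names, in extraction order.
TEMPLATES = ("L1", "R1", "L2", "R2", "FRAME")


@dataclass(frozen=True)
class ContextKey:
    """One lexically specific context: a template plus its word-key slots."""

    template: str  # one of TEMPLATES
    elements: tuple[str, ...]  # word keys or boundary symbols

    def __post_init__(self) -> None:
        expected = 1 if self.template in ("L1", "R1") else 2
        if len(self.elements) != expected:
            raise ValueError(
                f"template {self.template} takes {expected} elements, "
                f"got {len(self.elements)}"
            )

    @property
    def label(self) -> str:
        e = self.elements
        if self.template == "L1":
            return f"{e[0]}_X"
        if self.template == "R1":
            return f"X_{e[0]}"
        if self.template == "L2":
            return f"{e[0]}_{e[1]}_X"
        if self.template == "R2":
            return f"X_{e[0]}_{e[1]}"
        return f"{e[0]}_X_{e[1]}"  # FRAME

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class TimeSlice:
    """One of the seven longitudinal measurement points."""

    time_index: int  # 0..6
    fraction: float  # 0.40 + 0.10 * time_index
    n_utterances: int

    def __post_init__(self) -> None:
        if not 0 <= self.time_index <= 6:
            raise ValueError("time_index must lie in 0..6")
        if abs(self.fraction - (0.40 + 0.10 * self.time_index)) > 1e-9:
            raise ValueError("fraction inconsistent with time_index")


def slice_schedule(total_utterances: int) -> list[TimeSlice]:
    """The seven growing prefixes over which co-occurrences are collected.

    Prefix size is ``max(1, floor(fraction * total))``; the last slice
    always covers the whole corpus.
    """
    if total_utterances < 1:
        raise ValueError("total_utterances must be positive")
    slices = []
    for t, frac in enumerate(SLICE_FRACTIONS):
        n = max(1, int(np.floor(frac * total_utterances + 1e-9)))
        slices.append(TimeSlice(t, frac, n))
    assert slices[-1].n_utterances == total_utterances
    return slices


def extract_contexts(
    utterance_keys: list[str] | tuple[str, ...], position: int
) -> list[ContextKey]:
    """The up-to-five contexts of the token at ``position``.

    ``utterance_keys`` holds the homograph-disambiguated word keys of the
    utterance's tokens (boundary symbols excluded; they are implied).
    """
    n = len(utterance_keys)
    if not 0 <= position < n:
        raise IndexError(f"position {position} out of range for length {n}")

    def slot(i: int) -> str | None:
        # exactly one boundary symbol exists per side; beyond it -> None
        if i == -1:
            return START
        if i == n:
            return END
        if 0 <= i < n:
            return utterance_keys[i]
        return None

    lm1, lm2 = slot(position - 1), slot(position - 2)
    rp1, rp2 = slot(position + 1), slot(position + 2)

    contexts: list[ContextKey] = []
    if lm1 is not None:
        contexts.append(ContextKey("L1", (lm1,)))
    if rp1 is not None:
        contexts.append(ContextKey("R1", (rp1,)))
    if lm2 is not None and lm1 is not None:
        contexts.append(ContextKey("L2", (lm2, lm1)))
    if rp1 is not None and rp2 is not None:
        contexts.append(ContextKey("R2", (rp1, rp2)))
    if lm1 is not None and rp1 is not None:
        contexts.append(ContextKey("FRAME", (lm1, rp1)))
    return contexts


@dataclass
class CooccurrenceMatrix:
    """Sparse word x context count matrix for one corpus at one slice.

    Rows and columns keep first-occurrence order, so repeated runs are
    reproducible. ``word_freq`` is the token frequency of each row word
    within the slice prefix; ``context_freq`` is the column total.
    """

    corpus_id: str
    slice: TimeSlice
    words: list[str]  # row word keys
    contexts: list[str]  # column context labels
    counts: sp.csr_matrix  # non-negative ints
    word_freq: np.ndarray  # per-row token frequency in the prefix

    @property
    def context_freq(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row(self, word: str) -> int:
        return self.words.index(word)

    def to_triplets(self, path: str | Path) -> None:
        """Export as a MatrixMarket sparse file plus row/column label TSVs."""
        import scipy.io as sio

        path = Path(path)
        sio.mmwrite(str(path), self.counts.tocoo(), field="integer")
        path.with_suffix(".rows.tsv").write_text(
            "\n".join(self.words) + "\n", encoding="utf-8"
        )
        path.with_suffix(".cols.tsv").write_text(
            "\n".join(self.contexts) + "\n", encoding="utf-8"
        )


@dataclass
class _CorpusEvents:
    """Flat event arrays for one fully traversed corpus (internal).

    Extraction runs once per corpus; each slice is then a prefix filter
    over these arrays.
    """

    corpus_id: str
    n_utterances: int
    words: list[str]  # word-key vocabulary, first-occurrence order
    contexts: list[str]  # context-label vocabulary, first-occurrence order
    token_utt: np.ndarray  # per token: utterance index
    token_word: np.ndarray  # per token: row index into words
    event_utt: np.ndarray  # per (token, context) event: utterance index
    event_word: np.ndarray  # per event: row index
    event_context: np.ndarray  # per event: column index


def _collect_events(corpus: TaggedCorpus) -> _CorpusEvents:
    keys = assign_word_keys(corpus)
    word_index: dict[str, int] = {}
    ctx_index: dict[str, int] = {}
    words: list[str] = []
    contexts: list[str] = []
    token_utt: list[int] = []
    token_word: list[int] = []
    event_utt: list[int] = []
    event_word: list[int] = []
    event_ctx: list[int] = []

    for u_idx, utt in enumerate(corpus.utterances):
        utt_keys = [keys[(t.wordform, t.fine_tag)] for t in utt.tokens]
        for pos, wkey in enumerate(utt_keys):
            w = word_index.get(wkey)
            if w is None:
                w = word_index[wkey] = len(words)
                words.append(wkey)
            token_utt.append(u_idx)
            token_word.append(w)
            for ctx in extract_contexts(utt_keys, pos):
                label = ctx.label
                c = ctx_index.get(label)
                if c is None:
                    c = ctx_index[label] = len(contexts)
                    contexts.append(label)
                event_utt.append(u_idx)
                event_word.append(w)
                event_ctx.append(c)

    return _CorpusEvents(
        corpus_id=corpus.corpus_id,
        n_utterances=len(corpus),
        words=words,
        contexts=contexts,
        token_utt=np.asarray(token_utt, dtype=np.int64),
        token_word=np.asarray(token_word, dtype=np.int64),
        event_utt=np.asarray(event_utt, dtype=np.int64),
        event_word=np.asarray(event_word, dtype=np.int64),
        event_context=np.asarray(event_ctx, dtype=np.int64),
    )


def _matrix_from_events(events: _CorpusEvents, slc: TimeSlice) -> CooccurrenceMatrix:
    emask = events.event_utt < slc.n_utterances
    tmask = events.token_utt < slc.n_utterances
    ew = events.event_word[emask]
    ec = events.event_context[emask]

    # restrict rows/cols to those actually seen in the prefix, keeping
    # global first-occurrence order
    seen_w = np.zeros(len(events.words), dtype=bool)
    seen_w[events.token_word[tmask]] = True
    seen_c = np.zeros(len(events.contexts), dtype=bool)
    seen_c[ec] = True
    w_ids = np.flatnonzero(seen_w)
    c_ids = np.flatnonzero(seen_c)
    w_map = np.full(len(events.words), -1, dtype=np.int64)
    w_map[w_ids] = np.arange(len(w_ids))
    c_map = np.full(len(events.contexts), -1, dtype=np.int64)
    c_map[c_ids] = np.arange(len(c_ids))

    counts = sp.coo_matrix(
        (np.ones(len(ew), dtype=np.int64), (w_map[ew], c_map[ec])),
        shape=(len(w_ids), len(c_ids)),
    ).tocsr()
    counts.sum_duplicates()

    freq = np.bincount(w_map[events.token_word[tmask]], minlength=len(w_ids))
    return CooccurrenceMatrix(
        corpus_id=events.corpus_id,
        slice=slc,
        words=[events.words[i] for i in w_ids],
        contexts=[events.contexts[i] for i in c_ids],
        counts=counts,
        word_freq=freq.astype(np.int64),
    )


def build_cooccurrence(corpus: TaggedCorpus, slc: TimeSlice) -> CooccurrenceMatrix:
    """Word x context counts over the first ``slc.n_utterances`` utterances.

    All words and all contexts are kept; no frequency floor is applied.
    """
    return _matrix_from_events(_collect_events(corpus), slc)


def build_all_slices(
    corpus: TaggedCorpus, slices: list[TimeSlice] | None = None
) -> list[CooccurrenceMatrix]:
    """All seven longitudinal matrices of one corpus in a single traversal."""
    events = _collect_events(corpus)
    if slices is None:
        slices = slice_schedule(events.n_utterances)
    return [_matrix_from_events(events, s) for s in slices]
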