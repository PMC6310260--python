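"""Unsupervised leave-one-out 1-nearest-neighbor categorization.

Every word is reduced to its row of the word x context co-occurrence
matrix. At each time slice, the distance between a target word and every
*other* word is computed (leave-one-out, so a word can never be its own
neighbor) and the closest word is selected. Gold coarse tags play no role
in learning: they are consulted only afterwards, to score the outcome as
a *hit* (neighbor shares the target's coarse tag) or a *miss*.

Two distance metrics are supported:

* ``cosine`` — one minus the normalized dot product; insensitive to
  absolute frequency (any positive rescaling of a vector leaves its
  cosine distances unchanged).
* ``numeric_overlap`` — the sum over columns of absolute element-wise
  differences, each scaled by that column's value range over all rows;
  sensitive to absolute frequency by construction.

Ties at the minimum distance are resolved by a two-step cascade: keep the
most frequent tied neighbors (token frequency in the current prefix),
then draw uniformly at random among those still tied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

from .corpus_io import CoarseTag
from .context_model import CooccurrenceMatrix

_EPS = 1e-300


class UndefinedDistanceError(ValueError):
    """A zero-norm vector has no direction, hence no cosine distance."""


class NotCategorizableError(ValueError):
    """Raised when a matrix has fewer than two rows."""


@dataclass(frozen=True)
class CategorizerConfig:
    metric: str = "cosine"  # "cosine" | "numeric_overlap"
    k: int = 1
    distance_tie_tol: float = 1e-9  # relative tolerance for "same distance"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k != 1:
            raise ValueError("only k = 1 neighborhoods are supported")
        if self.metric not in ("cosine", "numeric_overlap"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.distance_tie_tol <= 0:
            raise ValueError("distance_tie_tol must be positive")


@dataclass(frozen=True)
class ColumnRanges:
    """Per-column max and min over all word rows of a matrix."""

    maxs: np.ndarray
    mins: np.ndarray

    @classmethod
    def from_matrix(cls, counts: sp.spmatrix | np.ndarray) -> "ColumnRanges":
        if sp.issparse(counts):
            maxs = np.asarray(counts.max(axis=0).todense()).ravel().astype(float)
            mins = np.asarray(counts.min(axis=0).todense()).ravel().astype(float)
        else:
            arr = np.asarray(counts, dtype=float)
            maxs = arr.max(axis=0)
            mins = arr.min(axis=0)
        return cls(maxs=maxs, mins=mins)

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins


@dataclass(frozen=True)
class CategorizationOutcome:
    word: str
    corpus_id: str
    time_index: int
    neighbor: str
    predicted_coarse: CoarseTag
    hit: bool
    n_tied_at_min_distance: int
    tie_broken_randomly: bool


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - (a.b)/(|a||b|); zero for proportional non-negative vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedDistanceError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def numeric_overlap_terms(
    a: np.ndarray, b: np.ndarray, ranges: ColumnRanges
) -> np.ndarray:
    """Per-column scaled terms |a_i - b_i| / (max(i) - min(i)).

    A column with zero range contributes 0 (all rows agree there, so the
    difference is necessarily 0 as well).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    r = ranges.ranges
    if a.shape != b.shape or a.shape != r.shape:
        raise ValueError(
            f"dimension mismatch: vectors {a.shape}, {b.shape} vs ranges {r.shape}"
        )
    diff = np.abs(a - b)
    out = np.zeros_like(diff)
    nz = r > 0
    out[nz] = diff[nz] / r[nz]
    return out


def numeric_overlap_distance(
    a: np.ndarray, b: np.ndarray, ranges: ColumnRanges
) -> float:
    """Sum of range-scaled absolute column differences; 0 iff a = b."""
    return float(numeric_overlap_terms(a, b, ranges).sum())


def _pairwise_distances(
    counts: sp.csr_matrix, metric: str
) -> np.ndarray:
    """Dense all-pairs distance matrix under the requested metric."""
    X = counts.astype(np.float64)
    if metric == "cosine":
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        inv = 1.0 / np.maximum(norms, _EPS)
        Xn = sp.diags(inv) @ X
        sims = (Xn @ Xn.T).toarray()
        d = 1.0 - sims
        np.clip(d, 0.0, 2.0, out=d)
        return d
    # numeric overlap: scale columns by 1/range, then Manhattan distance.
    cr = ColumnRanges.from_matrix(X)
    r = cr.ranges
    scale = np.zeros_like(r)
    nz = r > 0
    scale[nz] = 1.0 / r[nz]
    Xs = (X @ sp.diags(scale)).tocsr()
    return pairwise_distances(Xs, metric="manhattan")


def _tie_set(dists: np.ndarray, tol: float) -> np.ndarray:
    """Indices whose distance ties the minimum under a relative tolerance.

    Two distances d1, d2 count as equal when
    |d1 - d2| <= tol * max(d1, d2, eps).
    """
    finite = np.isfinite(dists)
    dmin = dists[finite].min()
    thresh = tol * np.maximum(np.maximum(dists, dmin), 1e-30)
    return np.flatnonzero(finite & (np.abs(dists - dmin) <= thresh))


def _resolve_tie(
    tied: np.ndarray, freqs: np.ndarray, rng: np.random.Generator
) -> tuple[int, bool]:
    """Frequency-then-random cascade; returns (chosen index, used randomness)."""
    if len(tied) == 1:
        return int(tied[0]), False
    f = freqs[tied]
    most = tied[f == f.max()]
    if len(most) == 1:
        return int(most[0]), False
    return int(most[rng.integers(len(most))]), True


def tie_break(
    tied_indices: np.ndarray,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, bool, np.ndarray]:
    """Public tie-break cascade: keep most frequent, then sample uniformly.

    Returns (chosen index, whether randomness was used, retained candidate
    indices after the frequency heuristic).
    """
    tied = np.asarray(tied_indices)
    f = np.asarray(freqs)[tied]
    retained = tied[f == f.max()]
    if len(retained) == 1:
        return int(retained[0]), False, retained
    return int(retained[rng.integers(len(retained))]), True, retained


def categorize_word(
    target: str,
    matrix: CooccurrenceMatrix,
    coarse_tags: dict[str, CoarseTag],
    config: CategorizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CategorizationOutcome:
    """Categorize one word against all other rows of the matrix."""
    config = config or CategorizerConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if matrix.shape[0] < 2:
        raise NotCategorizableError("need at least two words to categorize")
    row = matrix.row(target)
    dists = _pairwise_distances(matrix.counts, config.metric)[row]
    dists[row] = np.inf  # leave-one-out
    tied = _tie_set(dists, config.distance_tie_tol)
    chosen, random_used = _resolve_tie(tied, matrix.word_freq, rng)
    neighbor = matrix.words[chosen]
    predicted = coarse_tags[neighbor]
    return CategorizationOutcome(
        word=target,
        corpus_id=matrix.corpus_id,
        time_index=matrix.slice.time_index,
        neighbor=neighbor,
        predicted_coarse=predicted,
        hit=predicted == coarse_tags[target],
        n_tied_at_min_distance=len(tied),
        tie_broken_randomly=random_used,
    )


def run_categorization(
    matrix: CooccurrenceMatrix,
    coarse_tags: dict[str, CoarseTag],
    config: CategorizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[CategorizationOutcome]:
    """Leave-one-out categorization of every row of the matrix.

    A single seeded generator is consumed in row order, so runs are
    bit-reproducible given ``config.rng_seed``.
    """
    config = config or CategorizerConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n = matrix.shape[0]
    if n < 2:
        raise NotCategorizableError("need at least two words to categorize")

    dmat = _pairwise_distances(matrix.counts, config.metric)
    np.fill_diagonal(dmat, np.inf)
    freqs = matrix.word_freq
    outcomes: list[CategorizationOutcome] = []
    for i in range(n):
        tied = _tie_set(dmat[i], config.distance_tie_tol)
        chosen, random_used = _resolve_tie(tied, freqs, rng)
        neighbor = matrix.words[chosen]
        predicted = coarse_tags[neighbor]
        word = matrix.words[i]
        outcomes.append(
            CategorizationOutcome(
                word=word,
                corpus_id=matrix.corpus_id,
                time_index=matrix.slice.time_index,
                neighbor=neighbor,
                predicted_coarse=predicted,
                hit=predicted == coarse_tags[word],
                n_tied_at_min_distance=len(tied),
                tie_broken_randomly=random_used,
            )
        )
    return outcomes
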