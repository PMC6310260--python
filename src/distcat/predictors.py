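"""Per-word distributional predictors at each longitudinal slice.

For every word (row of a co-occurrence matrix) four quantities are
computed:

* **log frequency** — natural log of the word's token count in the prefix;
* **log contextual diversity** — natural log of the number of distinct
  distributional contexts the word co-occurred with;
* **average conditional probability** of the word given its contexts —
  mean over the word's contexts of count(word, context) / freq(context);
  the operationalization of predictability (values in (0, 1]);
* **median information gain (IG)** of the word's co-occurring contexts —
  per context, IG is the entropy reduction in the coarse-tag distribution
  obtained by conditioning on the binary feature "co-occurs with this
  context"; a word's contexts are sorted by IG and the median taken
  (midpoint of the two central values for even counts).

IG uses natural-log entropies with a token-weighted class distribution by
default (each word type contributes its token frequency); a type-weighted
variant (each type counts once) is available via ``weighting="type"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus_io import CoarseTag
from .context_model import CooccurrenceMatrix

_COARSE_ORDER = [t.value for t in CoarseTag]


@dataclass(frozen=True)
class PredictorRecord:
    word: str
    corpus_id: str
    time_index: int
    frequency: int
    diversity: int
    log_frequency: float
    log_diversity: float
    avg_cond_prob: float
    median_ig: float


def avg_conditional_probability(
    target_counts: Mapping[str, float], unit_marginals: Mapping[str, float]
) -> float:
    """Mean over co-occurring units of count / marginal.

    Direction-agnostic: the pipeline applies it word-given-contexts
    (units are contexts), but the same averaging applies context-given-
    words (units are words).
    """
    if not target_counts:
        raise ValueError("no co-occurring units: average undefined")
    probs = []
    for unit, count in target_counts.items():
        marginal = unit_marginals[unit]
        if count <= 0 or count > marginal:
            raise ValueError(
                f"inconsistent counts for unit {unit!r}: {count} > marginal {marginal}"
            )
        probs.append(count / marginal)
    return float(np.mean(probs))


def _entropy_rows(mass: np.ndarray) -> np.ndarray:
    """Natural-log entropy of each row of a non-negative mass matrix."""
    totals = mass.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, mass / np.maximum(totals, 1e-300), 0.0)
        logp = np.where(p > 0, np.log(p), 0.0)
    return -(p * logp).sum(axis=1)


def ig_table(
    matrix: CooccurrenceMatrix,
    coarse_tags: Mapping[str, CoarseTag],
    weighting: str = "token",
) -> np.ndarray:
    """Information gain of every context column at this slice.

    With the binary feature "word co-occurs with context c", and Y the
    coarse tag of word tokens (token weighting) or word types (type
    weighting):

        IG(c) = H(Y) - [P(c) H(Y|c) + P(not c) H(Y|not c)]

    Values lie in [0, H(Y)].
    """
    if weighting not in ("token", "type"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n_words, n_ctx = matrix.shape
    tags = np.array(
        [_COARSE_ORDER.index(coarse_tags[w].value) for w in matrix.words]
    )
    weights = (
        matrix.word_freq.astype(float)
        if weighting == "token"
        else np.ones(n_words)
    )
    onehot = np.zeros((n_words, len(_COARSE_ORDER)))
    onehot[np.arange(n_words), tags] = weights

    presence = (matrix.counts > 0).astype(np.float64)  # words x contexts
    with_mass = presence.T @ onehot  # contexts x classes
    with_mass = np.asarray(with_mass)
    total_mass = onehot.sum(axis=0)  # per-class totals
    without_mass = total_mass[None, :] - with_mass

    h_prior = _entropy_rows(total_mass[None, :])[0]
    h_with = _entropy_rows(with_mass)
    h_without = _entropy_rows(without_mass)
    m_with = with_mass.sum(axis=1)
    m_without = without_mass.sum(axis=1)
    total = total_mass.sum()
    ig = h_prior - (m_with * h_with + m_without * h_without) / total
    return np.maximum(ig, 0.0)  # clip float round-off below zero


def information_gain(
    context: str,
    matrix: CooccurrenceMatrix,
    coarse_tags: Mapping[str, CoarseTag],
    weighting: str = "token",
) -> float:
    """IG of a single context column (see :func:`ig_table`)."""
    try:
        col = matrix.contexts.index(context)
    except ValueError:
        raise KeyError(f"context {context!r} not in matrix") from None
    return float(ig_table(matrix, coarse_tags, weighting)[col])


def median_ig(word: str, matrix: CooccurrenceMatrix, igs: np.ndarray) -> float:
    """Median IG over the word's distinct co-occurring contexts."""
    row = matrix.row(word)
    cols = matrix.counts[row].indices
    if len(cols) == 0:
        raise ValueError(f"word {word!r} has no contexts")
    return float(np.median(igs[cols]))


def compute_predictors(
    matrix: CooccurrenceMatrix,
    coarse_tags: Mapping[str, CoarseTag],
    ig_weighting: str = "token",
) -> pd.DataFrame:
    """One predictor record per word row of the matrix.

    Returns a DataFrame with columns word, corpus_id, time_index,
    frequency, diversity, log_frequency, log_diversity, avg_cond_prob,
    median_ig.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    counts = matrix.counts.tocsr()
    ctx_freq = matrix.context_freq.astype(float)
    igs = ig_table(matrix, coarse_tags, ig_weighting)

    n = matrix.shape[0]
    diversity = np.diff(counts.indptr)
    freq = matrix.word_freq.astype(int)
    avg_cp = np.empty(n)
    med_ig = np.empty(n)
    for i in range(n):
        cols = counts.indices[counts.indptr[i] : counts.indptr[i + 1]]
        vals = counts.data[counts.indptr[i] : counts.indptr[i + 1]]
        avg_cp[i] = float(np.mean(vals / ctx_freq[cols]))
        med_ig[i] = float(np.median(igs[cols]))

    return pd.DataFrame(
        {
            "word": matrix.words,
            "corpus_id": matrix.corpus_id,
            "time_index": matrix.slice.time_index,
            "frequency": freq,
            "diversity": diversity.astype(int),
            "log_frequency": np.log(freq),
            "log_diversity": np.log(diversity),
            "avg_cond_prob": avg_cp,
            "median_ig": med_ig,
        }
    )
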