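import numpy as np
import pytest
import scipy.sparse as sp

from distcat.corpus_io import CoarseTag, TaggedCorpus, TaggedToken, Utterance
from distcat.context_model import CooccurrenceMatrix, TimeSlice
from distcat.synthetic_data import SyntheticSpec, generate_study


def make_corpus(corpus_id: str, utterances: list[list[tuple[str, str]]]) -> TaggedCorpus:
    """Hand-build a corpus from [(wordform, fine_tag), ...] utterances."""
    from distcat.corpus_io import map_coarse_tag

    return TaggedCorpus(
        corpus_id,
        [
            Utterance(tuple(TaggedToken(w, t, map_coarse_tag(t)) for w, t in utt))
            for utt in utterances
        ],
    )


def make_matrix(
    words: list[str],
    contexts: list[str],
    counts: np.ndarray,
    word_freq: list[int] | None = None,
    time_index: int = 6,
    corpus_id: str = "toy",
) -> CooccurrenceMatrix:
    """Wrap a dense count array as a CooccurrenceMatrix for unit tests."""
    counts = np.asarray(counts)
    freq = (
        np.asarray(word_freq)
        if word_freq is not None
        else counts.sum(axis=1) // 5 + 1
    )
    return CooccurrenceMatrix(
        corpus_id=corpus_id,
        slice=TimeSlice(time_index, 0.40 + 0.10 * time_index, 100),
        words=list(words),
        contexts=list(contexts),
        counts=sp.csr_matrix(counts),
        word_freq=np.asarray(freq, dtype=np.int64),
    )


def simulate_glmm_table(
    seed: int,
    beta0: float = 0.3,
    beta_div: float = 0.6,
    beta_cp: float = -1.5,
    beta_time: float = 0.05,
    n_corpora: int = 10,
    n_words: int = 72,
    n_times: int = 7,
    sd_corpus: float = 0.3,
    sd_word: float = 0.8,
    sd_slope: float = 0.08,
):
    """Logistic mixed-model data with known coefficients and variances.

    One row per (corpus, word, time); by-corpus intercepts, by-word
    intercepts and time slopes; ~n_corpora * n_words * n_times rows.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    b_corpus = rng.normal(0, sd_corpus, n_corpora)
    b_word = rng.normal(0, sd_word, n_words)
    s_word = rng.normal(0, sd_slope, n_words)
    div_word = rng.normal(3.0, 1.0, n_words)  # word-level diversity baseline
    rows = []
    for c in range(n_corpora):
        for w in range(n_words):
            for t in range(n_times):
                div = div_word[w] + 0.15 * t + rng.normal(0, 0.2)
                cp = float(np.clip(rng.beta(2, 5) + 0.02 * rng.normal(), 0.01, 1.0))
                eta = (
                    beta0
                    + beta_time * t
                    + beta_div * div
                    + beta_cp * cp
                    + b_corpus[c]
                    + b_word[w]
                    + s_word[w] * t
                )
                hit = int(rng.random() < 1 / (1 + np.exp(-eta)))
                rows.append(
                    {
                        "hit": hit,
                        "corpus_id": f"c{c}",
                        "word": f"w{w}",
                        "time": t,
                        "log_diversity": div,
                        "avg_cond_prob": cp,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def lead_corpus():
    """'Lead is heavy' / 'They lead us': the classic homograph pair."""
    return make_corpus(
        "lead",
        [
            [("lead", "n"), ("is", "cop"), ("heavy", "adj")],
            [("they", "pro"), ("lead", "v"), ("us", "pro")],
        ],
    )


@pytest.fixture(scope="session")
def small_study():
    """A 3-corpus synthetic study small enough for per-test pipelines."""
    spec = SyntheticSpec(
        n_corpora=3,
        n_utterances_per_corpus=400,
        rng_seed=7,
    )
    corpora, truth = generate_study(spec)
    return spec, corpora, truth


@pytest.fixture(scope="session")
def small_tables(small_study):
    from distcat.cli_pipeline import study_tables

    _, corpora, truth = small_study
    outcomes, predictors = study_tables(corpora, truth, metrics=("cosine",), seed=7)
    return outcomes, predictors
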