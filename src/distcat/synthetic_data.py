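"""Synthetic child-directed-speech-like corpora with ground-truth categories.

The generator emits multiple chronologically ordered sub-corpora of short
tagged utterances that reproduce, in stylized form, the structural
features the pipeline depends on:

* a vocabulary per coarse tag with Zipf-distributed token frequencies;
* category-selective local contexts: utterances are concatenations of
  short templated chunks (function-word skeletons around one open slot);
  each template prefers one coarse tag and its slot is filled from that
  tag with probability ``selectivity``, else from a uniformly chosen
  other tag;
* per-word contextual stereotypy: each word carries its own preference
  distribution over its class's templates (Dirichlet with a word-specific
  concentration), so that at matched frequency some words occur in many
  different contexts while others keep recurring in one — the source of
  genuine variation in contextual diversity and predictability;
* homographs: a fraction of wordforms is shared between two classes under
  distinct fine tags;
* a core vocabulary shared by all sub-corpora (occupying the frequent
  Zipf ranks) plus rarer per-corpus idiosyncratic words, so the
  "occurs in all sub-corpora" analysis filter retains a known word set.

Everything is deterministic given (rng_seed, corpus_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus_io import (
    CoarseTag,
    TaggedCorpus,
    TaggedToken,
    Utterance,
    map_coarse_tag,
    write_tagged_corpus,
)

# fine tags used by the generator, per coarse class (all map onto the
# right coarse tag under the shipped default table)
FINE_TAGS = {
    "N": ("n", "pro"),
    "V": ("v", "aux"),
    "ADJ": ("adj",),
    "ADV": ("adv",),
    "FUNCT": ("det", "prep"),
}

_CLASSES = ("N", "V", "ADJ", "ADV", "FUNCT")

#: how often a chunk of each class is produced
CLASS_WEIGHTS = {"N": 0.32, "V": 0.27, "ADJ": 0.14, "ADV": 0.12, "FUNCT": 0.15}


@dataclass
class SyntheticSpec:
    """Study-level parameters of the generator.

    Defaults define the reference synthetic study: 13 longitudinal
    sub-corpora of 3,000 short utterances each.
    """

    n_corpora: int = 13
    n_utterances_per_corpus: int = 3000
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"N": 120, "V": 80, "ADJ": 36, "ADV": 28, "FUNCT": 36}
    )
    core_fraction: float = 0.70
    zipf_exponent: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in _CLASSES}
    )
    n_context_templates: dict[str, int] = field(
        default_factory=lambda: {"N": 8, "V": 8, "ADJ": 5, "ADV": 5, "FUNCT": 5}
    )
    selectivity: float = 0.75
    homograph_rate: float = 0.06
    mean_utterance_length: float = 5.0
    # per-word Dirichlet concentration over class templates, log-uniform
    stereotypy_range: tuple[float, float] = (0.15, 5.0)
    # per-word probability of occurring inside its private collocation
    # frame (fixed-phrase usage), drawn uniformly from this range
    collocation_range: tuple[float, float] = (0.0, 0.8)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.2 <= self.selectivity <= 1.0:
            raise ValueError("selectivity must lie in [0.2, 1]")
        if not 0.0 <= self.homograph_rate <= 0.3:
            raise ValueError("homograph_rate must lie in [0, 0.3]")
        if self.n_corpora < 1 or self.n_utterances_per_corpus < 1:
            raise ValueError("corpus counts must be positive")
        for c in _CLASSES:
            if self.vocab_sizes.get(c, 0) < 1:
                raise ValueError(f"vocabulary size for {c} must be >= 1")
            if self.n_context_templates.get(c, 0) < 1:
                raise ValueError(f"template count for {c} must be >= 1")
        if self.mean_utterance_length < 2:
            raise ValueError("mean utterance length must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("stereotypy_range", "collocation_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_corpora": self.n_corpora,
            "n_utterances_per_corpus": self.n_utterances_per_corpus,
            "vocab_sizes": dict(self.vocab_sizes),
            "core_fraction": self.core_fraction,
            "zipf_exponent": dict(self.zipf_exponent),
            "n_context_templates": dict(self.n_context_templates),
            "selectivity": self.selectivity,
            "homograph_rate": self.homograph_rate,
            "mean_utterance_length": self.mean_utterance_length,
            "stereotypy_range": list(self.stereotypy_range),
            "collocation_range": list(self.collocation_range),
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def reference_spec(rng_seed: int = 0) -> SyntheticSpec:
    """The shipped reference study (see ``reference_study.yaml``)."""
    spec = SyntheticSpec.from_yaml(Path(__file__).parent / "reference_study.yaml")
    spec.rng_seed = rng_seed
    return spec


@dataclass
class _Word:
    wordform: str
    fine_tag: str
    coarse: str
    core: bool


@dataclass
class _Vocabulary:
    """Per-class word lists, Zipf weights, template markers and preferences."""

    words: dict[str, list[_Word]]  # per class, rank order (core first)
    zipf: dict[str, np.ndarray]  # per class, normalized token probabilities
    templates: dict[str, list[tuple[str | None, str | None]]]  # (left, right)
    pref: dict[str, np.ndarray]  # per class: words x templates preference rows
    colloc_p: dict[str, np.ndarray]  # per class: per-word fixed-phrase prob
    colloc_partner: dict[str, list[str]]  # per class: per-word partner wordform


def _class_vocab(
    cls_name: str, n_core: int, n_idio: int, corpus_index: int, rng_core, rng_idio
) -> list[_Word]:
    fine = FINE_TAGS[cls_name]
    words = []
    for i in range(n_core):
        wf = f"{cls_name.lower()}{i:03d}"
        words.append(_Word(wf, fine[i % len(fine)], cls_name, True))
    for j in range(n_idio):
        wf = f"{cls_name.lower()}x{corpus_index:02d}{j:03d}"
        words.append(_Word(wf, fine[j % len(fine)], cls_name, False))
    return words


def _build_vocabulary(spec: SyntheticSpec, corpus_index: int) -> _Vocabulary:
    rng_core = np.random.default_rng([spec.rng_seed, 982_451_653])
    rng_idio = np.random.default_rng([spec.rng_seed, corpus_index, 15_485_863])

    words: dict[str, list[_Word]] = {}
    zipf: dict[str, np.ndarray] = {}
    pref: dict[str, np.ndarray] = {}
    for cls_name in _CLASSES:
        total = spec.vocab_sizes[cls_name]
        n_core = max(1, int(round(spec.core_fraction * total)))
        n_idio = total - n_core
        ws = _class_vocab(cls_name, n_core, n_idio, corpus_index, rng_core, rng_idio)
        words[cls_name] = ws
        ranks = np.arange(1, len(ws) + 1, dtype=float)
        p = ranks ** -spec.zipf_exponent[cls_name]
        zipf[cls_name] = p / p.sum()

        # word-specific stereotypy: Dirichlet preference over class templates;
        # core preferences from the shared stream, idiosyncratic per corpus
        k = spec.n_context_templates[cls_name]
        lo, hi = spec.stereotypy_range
        conc_core = np.exp(rng_core.uniform(np.log(lo), np.log(hi), size=n_core))
        rows_core = np.vstack(
            [rng_core.dirichlet(np.full(k, a)) for a in conc_core]
        )
        if n_idio:
            conc_idio = np.exp(rng_idio.uniform(np.log(lo), np.log(hi), size=n_idio))
            rows_idio = np.vstack(
                [rng_idio.dirichlet(np.full(k, a)) for a in conc_idio]
            )
            pref[cls_name] = np.vstack([rows_core, rows_idio])
        else:
            pref[cls_name] = rows_core

    # homographs: share wordforms across class pairs (distinct fine tags)
    total_vocab = sum(spec.vocab_sizes.values())
    n_pairs = int(round(spec.homograph_rate * total_vocab / 2))
    pairs = [("N", "V"), ("N", "ADJ"), ("V", "ADJ"), ("ADV", "ADJ"), ("N", "ADV")]
    for p_idx in range(n_pairs):
        a, b = pairs[p_idx % len(pairs)]
        core_a = [w for w in words[a] if w.core]
        core_b = [w for w in words[b] if w.core]
        wa = core_a[(3 + 2 * p_idx) % len(core_a)]
        wb = core_b[(5 + 2 * p_idx) % len(core_b)]
        if wa.fine_tag != wb.fine_tag:  # keep (wordform, fine_tag) unambiguous
            wb.wordform = wa.wordform

    # templates: marker words drawn from the core FUNCT vocabulary. Markers
    # are optional per template (fixed at construction): a slot without a
    # left marker sits directly after the previous chunk's content word, as
    # content words frequently do in real speech — this is what makes rare
    # words occur in rare, near-singleton contexts.
    funct_core = [w for w in words["FUNCT"] if w.core]
    templates: dict[str, list[tuple[str | None, str | None]]] = {}
    m = 0
    for cls_name in _CLASSES:
        tpls = []
        for t in range(spec.n_context_templates[cls_name]):
            has_left = rng_core.random() < 0.6
            has_right = rng_core.random() < 0.25
            left = funct_core[m % len(funct_core)].wordform if has_left else None
            right = (
                funct_core[(m + 7) % len(funct_core)].wordform if has_right else None
            )
            tpls.append((left, right))
            m += 3
        templates[cls_name] = tpls

    # private collocation frames: each word owns a dedicated partner word
    # (a fixed-phrase companion, realized as a function word) and a
    # word-specific probability of being produced right after it.
    # Fixed-phrase occurrences make the word dominate its contexts — the
    # partner rarely occurs without it, so the conditional probability of
    # the word given those contexts approaches 1 — while denying it the
    # shared class-template evidence that drives correct categorization.
    lo_c, hi_c = spec.collocation_range
    colloc_p: dict[str, np.ndarray] = {}
    colloc_partner: dict[str, list[str]] = {}
    for cls_name in _CLASSES:
        ws = words[cls_name]
        n_core = sum(1 for w in ws if w.core)
        p_core = rng_core.uniform(lo_c, hi_c, size=n_core)
        p_idio = rng_idio.uniform(lo_c, hi_c, size=len(ws) - n_core)
        colloc_p[cls_name] = np.concatenate([p_core, p_idio])
        colloc_partner[cls_name] = [
            f"k{cls_name.lower()}{i:03d}" for i in range(len(ws))
        ]
    return _Vocabulary(words, zipf, templates, pref, colloc_p, colloc_partner)


def _funct_token(vocab: _Vocabulary, wordform: str) -> TaggedToken:
    for w in vocab.words["FUNCT"]:
        if w.wordform == wordform:
            return TaggedToken(w.wordform, w.fine_tag, CoarseTag.FUNCT)
    raise KeyError(wordform)


def generate_corpus(spec: SyntheticSpec, corpus_index: int) -> TaggedCorpus:
    """One chronologically ordered synthetic sub-corpus."""
    if not 0 <= corpus_index < spec.n_corpora:
        raise ValueError(
            f"corpus_index {corpus_index} outside 0..{spec.n_corpora - 1}"
        )
    vocab = _build_vocabulary(spec, corpus_index)
    rng = np.random.default_rng([spec.rng_seed, corpus_index, 32_452_843])

    marker_tokens = {
        w.wordform: TaggedToken(w.wordform, w.fine_tag, CoarseTag.FUNCT)
        for w in vocab.words["FUNCT"]
    }
    class_names = list(CLASS_WEIGHTS)
    class_p = np.array([CLASS_WEIGHTS[c] for c in class_names])
    class_p = class_p / class_p.sum()

    # tokens per chunk average ~1.85 (slot + optional markers), so the
    # chunk count targets the requested mean utterance length
    mean_chunks = max(1.0, spec.mean_utterance_length / 1.85)

    utterances: list[Utterance] = []
    for _ in range(spec.n_utterances_per_corpus):
        n_chunks = 1 + rng.poisson(mean_chunks - 1.0)
        tokens: list[TaggedToken] = []
        for _ in range(n_chunks):
            cls_name = class_names[rng.choice(len(class_names), p=class_p)]
            t_idx = rng.integers(len(vocab.templates[cls_name]))
            left, right = vocab.templates[cls_name][t_idx]
            if rng.random() < spec.selectivity:
                filler_cls = cls_name
                # weight by Zipf x per-word preference for this template
                p = vocab.zipf[filler_cls] * vocab.pref[filler_cls][:, t_idx]
                p = p / p.sum()
            else:
                others = [c for c in _CLASSES if c != cls_name]
                filler_cls = others[rng.integers(len(others))]
                p = vocab.zipf[filler_cls]
            w_idx = rng.choice(len(p), p=p)
            w = vocab.words[filler_cls][w_idx]
            if (
                filler_cls == cls_name
                and rng.random() < vocab.colloc_p[filler_cls][w_idx]
            ):
                # fixed-phrase realization: dedicated partner, no markers
                partner = vocab.colloc_partner[filler_cls][w_idx]
                tokens.append(TaggedToken(partner, "co", CoarseTag.FUNCT))
                tokens.append(
                    TaggedToken(w.wordform, w.fine_tag, map_coarse_tag(w.fine_tag))
                )
                continue
            if left is not None:
                tokens.append(marker_tokens[left])
            tokens.append(
                TaggedToken(w.wordform, w.fine_tag, map_coarse_tag(w.fine_tag))
            )
            if right is not None:
                tokens.append(marker_tokens[right])
        utterances.append(Utterance(tuple(tokens)))
    return TaggedCorpus(f"synthetic-{corpus_index:02d}", utterances)


def ground_truth(spec: SyntheticSpec) -> dict[tuple[str, str], CoarseTag]:
    """(wordform, fine_tag) -> coarse tag for every word the study can emit."""
    truth: dict[tuple[str, str], CoarseTag] = {}
    for idx in range(spec.n_corpora):
        vocab = _build_vocabulary(spec, idx)
        for cls_name, ws in vocab.words.items():
            for w in ws:
                truth[(w.wordform, w.fine_tag)] = CoarseTag(cls_name)
            for partner in vocab.colloc_partner[cls_name]:
                truth[(partner, "co")] = CoarseTag.FUNCT
    return truth


def core_wordforms(spec: SyntheticSpec) -> set[tuple[str, str]]:
    """The (wordform, fine_tag) pairs shared by construction across corpora."""
    vocab = _build_vocabulary(spec, 0)
    return {
        (w.wordform, w.fine_tag)
        for ws in vocab.words.values()
        for w in ws
        if w.core
    }


def generate_study(
    spec: SyntheticSpec,
) -> tuple[list[TaggedCorpus], dict[tuple[str, str], CoarseTag]]:
    """All sub-corpora of the study plus the ground-truth tag map."""
    corpora = [generate_corpus(spec, i) for i in range(spec.n_corpora)]
    return corpora, ground_truth(spec)


def write_study(
    spec: SyntheticSpec, out_dir: str | Path
) -> list[Path]:
    """Emit the study as tagged-text files plus a ground-truth TSV and spec YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpora, truth = generate_study(spec)
    paths = []
    for corpus in corpora:
        p = out_dir / f"{corpus.corpus_id}.txt"
        write_tagged_corpus(corpus, p, dialect="tsv")
        paths.append(p)
    gt = out_dir / "ground_truth.tsv"
    with gt.open("w", encoding="utf-8") as fh:
        fh.write("wordform\tfine_tag\tcoarse_tag\n")
        for (wf, ft), tag in sorted(truth.items()):
            fh.write(f"{wf}\t{ft}\t{tag.value}\n")
    paths.append(gt)
    spec_path = out_dir / "spec.yaml"
    spec.to_yaml(spec_path)
    paths.append(spec_path)
    return paths
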