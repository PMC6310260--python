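"""Reading PoS-tagged utterance corpora of child-directed speech.

A corpus is an ordered sequence of utterances, each a sequence of
(wordform, fine PoS tag) tokens, as produced by transcription annotation
schemes such as the CHILDES MOR tier. Fine tags are mapped onto five
coarse lexical categories — nouns (including pronouns), verbs (including
auxiliaries and non-finite forms), adjectives, adverbs, and function
words, the residual bucket — which serve only to *evaluate* categorization,
never to drive it.

Homographs (one wordform carrying several fine tags, e.g. verb *lead* vs
noun *lead*) are kept distinct throughout: every token is identified by a
:class:`WordKey` that is the bare wordform when unambiguous and
``wordform-i`` (senses numbered by first occurrence) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping


class CoarseTag(str, Enum):
    """The five coarse lexical categories used for evaluation."""

    N = "N"
    V = "V"
    ADJ = "ADJ"
    ADV = "ADV"
    FUNCT = "FUNCT"


#: Utterance-boundary symbols. They are never stored as tokens but are
#: implied at both ends of every utterance and may appear inside context
#: keys.
START = "#start"
END = "#end"


# Fine (MOR-style) tag -> coarse category. Pronouns count as nouns;
# auxiliaries, copulas, modals and non-finite forms count as verbs;
# everything not otherwise listed collapses into FUNCT.
DEFAULT_TAG_MAPPING: dict[str, CoarseTag] = {
    # nouns, incl. pronouns
    "n": CoarseTag.N,
    "n:let": CoarseTag.N,
    "n:pt": CoarseTag.N,
    "n:prop": CoarseTag.N,
    "n:gerund": CoarseTag.N,
    "pro": CoarseTag.N,
    "pro:dem": CoarseTag.N,
    "pro:exist": CoarseTag.N,
    "pro:indef": CoarseTag.N,
    "pro:int": CoarseTag.N,
    "pro:obj": CoarseTag.N,
    "pro:per": CoarseTag.N,
    "pro:poss": CoarseTag.N,
    "pro:refl": CoarseTag.N,
    "pro:rel": CoarseTag.N,
    "pro:sub": CoarseTag.N,
    "pro:wh": CoarseTag.N,
    # verbs, incl. auxiliaries and non-finite forms
    "v": CoarseTag.V,
    "v:aux": CoarseTag.V,
    "aux": CoarseTag.V,
    "cop": CoarseTag.V,
    "mod": CoarseTag.V,
    "mod:aux": CoarseTag.V,
    "part": CoarseTag.V,
    "inf": CoarseTag.V,
    # adjectives
    "adj": CoarseTag.ADJ,
    "adj:pred": CoarseTag.ADJ,
    # adverbs
    "adv": CoarseTag.ADV,
    "adv:int": CoarseTag.ADV,
    "adv:loc": CoarseTag.ADV,
    "adv:tem": CoarseTag.ADV,
    "adv:wh": CoarseTag.ADV,
    # function words and all residual categories
    "det": CoarseTag.FUNCT,
    "det:art": CoarseTag.FUNCT,
    "det:dem": CoarseTag.FUNCT,
    "det:int": CoarseTag.FUNCT,
    "det:num": CoarseTag.FUNCT,
    "det:poss": CoarseTag.FUNCT,
    "prep": CoarseTag.FUNCT,
    "conj": CoarseTag.FUNCT,
    "coord": CoarseTag.FUNCT,
    "comp": CoarseTag.FUNCT,
    "qn": CoarseTag.FUNCT,
    "post": CoarseTag.FUNCT,
    "co": CoarseTag.FUNCT,
    "int": CoarseTag.FUNCT,
    "neg": CoarseTag.FUNCT,
    "on": CoarseTag.FUNCT,
    "fil": CoarseTag.FUNCT,
    "meta": CoarseTag.FUNCT,
}


class CorpusFormatError(ValueError):
    """Raised for malformed or empty corpus files."""


class TagMappingError(KeyError):
    """Raised in strict mode for a fine tag absent from the mapping."""


@dataclass(frozen=True)
class TaggedToken:
    wordform: str
    fine_tag: str
    coarse_tag: CoarseTag

    def __post_init__(self) -> None:
        if not self.wordform:
            raise ValueError("wordform must be non-empty")


@dataclass(frozen=True)
class Utterance:
    """One utterance; boundary symbols are implied, not stored."""

    tokens: tuple[TaggedToken, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("an utterance holds at least one token")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TaggedCorpus:
    """Chronologically ordered utterances of one longitudinal sub-corpus."""

    corpus_id: str
    utterances: list[Utterance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.utterances:
            raise CorpusFormatError(f"corpus {self.corpus_id!r} is empty")

    def __len__(self) -> int:
        return len(self.utterances)

    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)


def map_coarse_tag(
    fine_tag: str,
    mapping: Mapping[str, CoarseTag] | None = None,
    strict: bool = False,
) -> CoarseTag:
    """Map a fine PoS tag to one of the five coarse categories.

    Unknown tags fall into FUNCT (the residual bucket) unless ``strict``
    is set, in which case they raise :class:`TagMappingError`.
    """
    table = DEFAULT_TAG_MAPPING if mapping is None else mapping
    coarse = table.get(fine_tag)
    if coarse is None:
        base = fine_tag.split(":", 1)[0]
        coarse = table.get(base)
    if coarse is None:
        if strict:
            raise TagMappingError(f"no coarse mapping for fine tag {fine_tag!r}")
        coarse = CoarseTag.FUNCT
    return CoarseTag(coarse)


def _make_token(
    wordform: str,
    fine_tag: str,
    mapping: Mapping[str, CoarseTag] | None,
    strict: bool,
) -> TaggedToken:
    wf = wordform.strip().lower()
    tag = fine_tag.strip()
    return TaggedToken(wf, tag, map_coarse_tag(tag, mapping, strict))


def read_tagged_corpus(
    path: str | Path,
    dialect: str = "tsv",
    corpus_id: str | None = None,
    tag_mapping: Mapping[str, CoarseTag] | None = None,
    strict_tags: bool = False,
) -> TaggedCorpus:
    """Read a plain tagged-utterance text file.

    Dialects
    --------
    ``tsv``
        One utterance per line; tokens are whitespace-separated
        ``word/tag`` pairs (or ``word<TAB>tag<TAB>word<TAB>tag...``).
    ``vertical``
        One ``word<TAB>tag`` pair per line, utterances separated by blank
        lines.

    Utterance and token order follow file order. A token without a tag is
    a parse error naming the offending line.
    """
    path = Path(path)
    if dialect not in ("tsv", "vertical"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text(encoding="utf-8")
    cid = corpus_id if corpus_id is not None else path.stem

    utterances: list[Utterance] = []
    if dialect == "tsv":
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            tokens = []
            if "\t" in line and "/" not in line:
                fields = line.split("\t")
                if len(fields) % 2 != 0:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: odd number of tab fields (token missing its tag)"
                    )
                pairs = zip(fields[::2], fields[1::2])
            else:
                pairs = []
                for item in line.split():
                    word, sep, tag = item.rpartition("/")
                    if not sep or not word or not tag:
                        raise CorpusFormatError(
                            f"{path}:{lineno}: token {item!r} has no tag"
                        )
                    pairs.append((word, tag))
            for word, tag in pairs:
                if not word.strip() or not tag.strip():
                    raise CorpusFormatError(f"{path}:{lineno}: empty wordform or tag")
                tokens.append(_make_token(word, tag, tag_mapping, strict_tags))
            utterances.append(Utterance(tuple(tokens)))
    else:  # vertical
        current: list[TaggedToken] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped:
                if current:
                    utterances.append(Utterance(tuple(current)))
                    current = []
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'word<TAB>tag', got {stripped!r}"
                )
            current.append(_make_token(fields[0], fields[1], tag_mapping, strict_tags))
        if current:
            utterances.append(Utterance(tuple(current)))

    if not utterances:
        raise CorpusFormatError(f"{path}: no utterances found")
    return TaggedCorpus(cid, utterances)


def write_tagged_corpus(corpus: TaggedCorpus, path: str | Path, dialect: str = "tsv") -> None:
    """Write a corpus back out in one of the supported dialects (round-trips)."""
    path = Path(path)
    lines: list[str] = []
    if dialect == "tsv":
        for utt in corpus.utterances:
            lines.append(" ".join(f"{t.wordform}/{t.fine_tag}" for t in utt.tokens))
    elif dialect == "vertical":
        for utt in corpus.utterances:
            lines.extend(f"{t.wordform}\t{t.fine_tag}" for t in utt.tokens)
            lines.append("")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def assign_word_keys(corpus: TaggedCorpus) -> dict[tuple[str, str], str]:
    """Assign a homograph-disambiguated key to every (wordform, fine_tag).

    Two tokens share a key iff they share both wordform and fine tag. A
    wordform observed with m > 1 distinct fine tags in the corpus yields m
    keys ``wordform-1`` .. ``wordform-m``, numbered by the first occurrence
    of each sense; an unambiguous wordform keeps its bare form.
    """
    senses: dict[str, list[str]] = {}
    for utt in corpus.utterances:
        for tok in utt.tokens:
            tags = senses.setdefault(tok.wordform, [])
            if tok.fine_tag not in tags:
                tags.append(tok.fine_tag)
    keys: dict[tuple[str, str], str] = {}
    for wordform, tags in senses.items():
        if len(tags) == 1:
            keys[(wordform, tags[0])] = wordform
        else:
            for i, tag in enumerate(tags, start=1):
                keys[(wordform, tag)] = f"{wordform}-{i}"
    return keys


def coarse_tag_map(
    corpora: Iterable[TaggedCorpus],
) -> dict[tuple[str, str], CoarseTag]:
    """(wordform, fine_tag) -> coarse tag over one or more corpora."""
    out: dict[tuple[str, str], CoarseTag] = {}
    for corpus in corpora:
        for utt in corpus.utterances:
            for tok in utt.tokens:
                out[(tok.wordform, tok.fine_tag)] = tok.coarse_tag
    return out
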