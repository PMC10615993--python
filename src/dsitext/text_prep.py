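"""Deterministic story tokenization for the static and contextual embedding routes.

Two preparation routes exist because context-independent vector models score
content words only, while contextual encoders need the full sentence:

* :func:`prepare_static` lowercases, drops punctuation, numbers and stop
  words, and never stems or spell-corrects.
* :func:`prepare_contextual` keeps every word and punctuation mark and strips
  only non-printable/control/replacement characters.

Sentence splitting is rule-based on ``. ! ?`` with a small abbreviation
exception list, and is byte-deterministic.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .errors import InvalidInputError

__all__ = [
    "Story",
    "Token",
    "TokenizedStory",
    "load_stopwords",
    "default_stopwords",
    "split_sentences",
    "prepare_static",
    "prepare_contextual",
]

#: Abbreviations whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "sr", "jr", "st", "mt",
        "vs", "etc", "e.g", "i.e", "cf", "al", "inc", "ltd", "co",
        "jan", "feb", "mar", "apr", "jun", "jul", "aug", "sep", "sept",
        "oct", "nov", "dec", "no", "vol", "fig", "approx",
    }
)

# A word is letters optionally joined by internal apostrophes or hyphens
# ("don't", "mother-in-law" are single tokens); everything else that is not
# whitespace is a single punctuation/symbol token.
_WORD_RE = r"[^\W\d_]+(?:['’-][^\W\d_]+)*"
_NUMBER_RE = r"\d+(?:[.,]\d+)*"
_TOKEN_RE = re.compile(rf"{_WORD_RE}|{_NUMBER_RE}|\S", re.UNICODE)

_SENT_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+|$)")


@dataclass(frozen=True)
class Story:
    """A raw narrative with an identifier."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise InvalidInputError(f"story {self.id!r}: text is empty")


@dataclass(frozen=True)
class Token:
    """A surface token with its filter flags."""

    surface: str
    is_stopword: bool = False
    is_number: bool = False
    is_punctuation: bool = False

    def __post_init__(self) -> None:
        # flags are mutually exclusive by construction
        assert not (self.is_number and self.is_punctuation)

    @property
    def is_word(self) -> bool:
        return not (self.is_number or self.is_punctuation)


@dataclass
class TokenizedStory:
    """Ordered sentences of ordered tokens for one story."""

    story_id: str
    sentences: list[list[Token]] = field(default_factory=list)

    @property
    def tokens(self) -> list[Token]:
        return [t for sent in self.sentences for t in sent]

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def __len__(self) -> int:
        return sum(len(s) for s in self.sentences)


def load_stopwords(path) -> frozenset[str]:
    """Read a one-token-per-line UTF-8 stop-word list."""
    with open(path, encoding="utf-8") as fh:
        words = {line.strip().lower() for line in fh if line.strip()}
    if not words:
        raise InvalidInputError(f"stop-word list {path} is empty")
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The bundled 174-word English list (the ``tm`` R package dialect)."""
    ref = resources.files("dsitext.data").joinpath("stopwords_en.txt")
    words = {
        line.strip().lower()
        for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    return frozenset(words)


def _strip_control(text: str) -> str:
    """Remove non-printable/control and replacement characters, keeping newlines/tabs as spaces."""
    out = []
    for ch in text:
        if ch in ("�", "﻿"):
            continue
        cat = unicodedata.category(ch)
        if cat.startswith("C"):
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def _sentence_spans(text: str) -> list[str]:
    """Split on terminal ``. ! ?`` runs, honouring the abbreviation list."""
    sentences: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end(1)
        chunk = text[start:end]
        if m.group(1) == ".":
            # look back at the word carrying the period
            prev = re.search(r"(\S+)\.$", chunk)
            if prev is not None:
                word = prev.group(1).lower().rstrip(".")
                if word in ABBREVIATIONS:
                    continue  # "Dr. Smith" — not a boundary
        if chunk.strip():
            sentences.append(chunk.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences or ([text.strip()] if text.strip() else [])


def _classify(surface: str, stopwords: frozenset[str] | None = None) -> Token:
    lowered = surface.lower()
    if re.fullmatch(_NUMBER_RE, surface):
        return Token(lowered, is_number=True)
    if re.fullmatch(_WORD_RE, surface, re.UNICODE):
        is_stop = stopwords is not None and lowered in stopwords
        return Token(lowered, is_stopword=is_stop)
    return Token(lowered, is_punctuation=True)


def split_sentences(story: Story) -> TokenizedStory:
    """Tokenize into sentences without any filtering (flags still populated)."""
    text = _strip_control(story.text)
    if not text.strip():
        raise InvalidInputError(f"story {story.id!r}: text is empty after cleaning")
    out = TokenizedStory(story_id=story.id)
    for sent in _sentence_spans(text):
        toks = [_classify(m.group(0)) for m in _TOKEN_RE.finditer(sent)]
        if toks:
            out.sentences.append(toks)
    if not out.sentences:
        raise InvalidInputError(f"story {story.id!r}: no tokens found")
    return out


def prepare_static(story: Story, stopwords: Iterable[str] | None = None) -> TokenizedStory:
    """Lowercased word tokens with stop words, numbers and punctuation removed.

    No stemming and no spell correction are applied; out-of-vocabulary
    handling happens later at embedding lookup. An all-filtered story yields
    zero tokens (the score is undefined downstream, not an error here).
    """
    stopset = frozenset(w.lower() for w in stopwords) if stopwords is not None else default_stopwords()
    tokenized = split_sentences(story)
    out = TokenizedStory(story_id=story.id)
    for sent in tokenized.sentences:
        kept = [
            Token(t.surface, is_stopword=False)
            for t in sent
            if t.is_word and t.surface not in stopset
        ]
        if kept:
            out.sentences.append(kept)
    return out


def prepare_contextual(story: Story) -> TokenizedStory:
    """Full sentences with all words and punctuation retained.

    Only non-printable/control/replacement characters are stripped before
    tokenization; everything else is context for the encoder.
    """
    return split_sentences(story)


def detokenize(tokens: Sequence[Token] | TokenizedStory) -> str:
    """Join token surfaces with single spaces (used by idempotence checks)."""
    if isinstance(tokens, TokenizedStory):
        tokens = tokens.tokens
    return " ".join(t.surface for t in tokens)
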