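"""Lexical control variables: word count, readability, norm means, and MTLD.

These are the baseline predictors entered before the semantic-distance score
in the incremental-validity regression. Values are deterministic functions
of the text (plus user-supplied norm tables for frequency / prevalence /
age-of-acquisition).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, InvalidInputError, InvalidParameterError
from .text_prep import Story, TokenizedStory, split_sentences

__all__ = [
    "NormTable",
    "load_norm_table",
    "word_count",
    "count_syllables",
    "fk_grade",
    "readability_fk",
    "mean_norm",
    "mtld",
    "covariate_table",
]

NORM_FIELDS = ("frequency", "prevalence", "aoa")

#: MTLD factor threshold (the conventional value from the original algorithm).
MTLD_THRESHOLD = 0.72

# Words whose syllable count the vowel-group heuristic gets wrong.
_SYLLABLE_EXCEPTIONS = {
    "every": 2, "different": 3, "interesting": 4, "evening": 3,
    "beautiful": 3, "business": 2, "camera": 3, "chocolate": 2,
    "favorite": 3, "people": 2, "science": 2, "area": 3, "idea": 3,
    "quiet": 2, "being": 2, "doing": 2, "going": 2, "poem": 2,
}

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


@dataclass
class NormTable:
    """token -> {frequency, prevalence, aoa}; lowercased tokens, first occurrence wins."""

    values: dict[str, dict[str, float]]
    source: str = ""

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.values

    def get(self, token: str, field: str) -> float | None:
        row = self.values.get(token.lower())
        if row is None:
            return None
        return row.get(field)


def load_norm_table(path) -> NormTable:
    """Read a CSV with header ``token,frequency,prevalence,aoa``."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse norm CSV ({exc})") from exc
    if "token" not in frame.columns:
        raise FormatError(f"{path}: missing 'token' column")
    fields = [f for f in NORM_FIELDS if f in frame.columns]
    if not fields:
        raise FormatError(f"{path}: no norm columns among {NORM_FIELDS}")
    values: dict[str, dict[str, float]] = {}
    for _, row in frame.iterrows():
        token = str(row["token"]).lower()
        if token in values:
            continue
        entry = {}
        for f in fields:
            v = row[f]
            if pd.notna(v):
                if not math.isfinite(float(v)):
                    raise FormatError(f"{path}: non-finite {f} for token {token!r}")
                entry[f] = float(v)
        values[token] = entry
    if not values:
        raise FormatError(f"{path}: empty norm table")
    return NormTable(values=values, source=str(path))


def _word_surfaces(tokens: TokenizedStory | Sequence[str]) -> list[str]:
    if isinstance(tokens, TokenizedStory):
        return [t.surface for t in tokens.tokens if not t.is_punctuation]
    return [str(t).lower() for t in tokens]


def word_count(tokens: TokenizedStory | Sequence[str]) -> int:
    """Number of word tokens (punctuation excluded)."""
    return len(_word_surfaces(tokens))


def count_syllables(word: str) -> int:
    """Heuristic syllable count: vowel groups, silent-e correction, floor of 1."""
    w = word.lower().strip("'’-")
    if not w:
        return 0
    if w in _SYLLABLE_EXCEPTIONS:
        return _SYLLABLE_EXCEPTIONS[w]
    groups = _VOWEL_GROUP_RE.findall(w)
    count = len(groups)
    if w.endswith("e") and not w.endswith(("le", "ee", "ye")) and count > 1:
        count -= 1
    if w.endswith("ed") and count > 1 and not w.endswith(("ted", "ded")):
        count -= 1
    return max(count, 1)


def fk_grade(words: int, sentences: int, syllables: int) -> float:
    """Flesch–Kincaid grade level from raw counts."""
    if words <= 0 or sentences <= 0:
        raise InvalidInputError("FK grade needs at least one word and one sentence")
    return 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59


def readability_fk(story: Story | TokenizedStory) -> float:
    """Flesch–Kincaid grade level of a story using the heuristic syllable counter."""
    tokenized = split_sentences(story) if isinstance(story, Story) else story
    sentences = len(tokenized.sentences)
    words = [t.surface for t in tokenized.tokens if t.is_word]
    if not words or sentences == 0:
        raise InvalidInputError(f"story {tokenized.story_id!r}: no scoreable words")
    syllables = sum(count_syllables(w) for w in words)
    return fk_grade(len(words), sentences, syllables)


def mean_norm(
    tokens: TokenizedStory | Sequence[str], norms: NormTable, field: str
) -> tuple[float, float]:
    """Mean of ``field`` over tokens found in the norm table, plus coverage fraction.

    Duplicate tokens are weighted by occurrence. Returns ``(nan, 0.0)`` when
    no token is covered.
    """
    if field not in NORM_FIELDS:
        raise InvalidParameterError(f"unknown norm field {field!r}; expected one of {NORM_FIELDS}")
    surfaces = _word_surfaces(tokens)
    if not surfaces:
        return float("nan"), 0.0
    values = [v for s in surfaces if (v := norms.get(s, field)) is not None]
    coverage = len(values) / len(surfaces)
    if not values:
        return float("nan"), 0.0
    return sum(values) / len(values), coverage


def _mtld_pass(tokens: Sequence[str], threshold: float) -> float:
    """One directional MTLD pass: factor count including the partial remainder."""
    factors = 0.0
    types: set[str] = set()
    count = 0
    for tok in tokens:
        count += 1
        types.add(tok)
        if len(types) / count < threshold:
            factors += 1.0
            types.clear()
            count = 0
    if count > 0:
        ttr = len(types) / count
        factors += (1.0 - ttr) / (1.0 - threshold)
    return factors


def mtld(tokens: TokenizedStory | Sequence[str], threshold: float = MTLD_THRESHOLD) -> float:
    """Measure of Textual Lexical Diversity (forward/reverse mean).

    Each time the running type–token ratio drops below ``threshold`` a factor
    completes and the window resets; the remainder adds a partial factor
    ``(1 - TTR_end) / (1 - threshold)``. The pass value is token count over
    factor count, and the final score averages the forward and reverse
    passes. NaN (flagged undefined) when both passes have zero factors.
    """
    surfaces = _word_surfaces(tokens)
    if not surfaces:
        raise InvalidInputError("MTLD needs at least one token")
    values = []
    for seq in (surfaces, surfaces[::-1]):
        factors = _mtld_pass(seq, threshold)
        if factors > 0:
            values.append(len(seq) / factors)
    if not values:
        return float("nan")
    return sum(values) / len(values)


def covariate_table(
    stories: Iterable[Story], norms: NormTable | None = None
) -> pd.DataFrame:
    """Per-story covariate battery as a data frame.

    ``word_count``, ``readability`` and ``mtld`` are computed on the
    unfiltered word tokens; norm means are computed only over tokens present
    in the norm table, with per-field coverage columns.
    """
    rows = []
    for story in stories:
        tokenized = split_sentences(story)
        row: dict[str, object] = {
            "id": story.id,
            "word_count": word_count(tokenized),
            "readability": readability_fk(tokenized),
            "mtld": mtld(tokenized),
        }
        for field in NORM_FIELDS:
            key = {"frequency": "freq", "prevalence": "prev", "aoa": "aoa"}[field]
            if norms is None:
                row[key] = float("nan")
                row[f"{key}_coverage"] = 0.0
            else:
                value, coverage = mean_norm(tokenized, norms, field)
                row[key] = value
                row[f"{key}_coverage"] = coverage
        rows.append(row)
    return pd.DataFrame(rows)
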