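"""Text-length bias audit: random without-replacement subsectioning of stories.

For each subsection length ``w`` a story of ``L`` tokens is partitioned into
``k = floor(L / w)`` disjoint random samples of exactly ``w`` tokens (leftover
tokens unused), each sample is scored, and the per-story score at that length
is the mean over its samples. Comparing score distributions and cross-length
rank order reveals whether the metric is an artifact of text length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .text_prep import Token, TokenizedStory

__all__ = ["LengthDesign", "LengthCurve", "sample_subsections", "length_curve", "tokens_as_pseudo_sentence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LengthDesign:
    """Subsection design for one (L, w) combination."""

    subsection_length: int
    total_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.subsection_length < 2:
            raise InvalidParameterError("subsection length w must be >= 2")
        if self.subsection_length > self.total_length:
            raise InvalidParameterError(
                f"subsection length {self.subsection_length} exceeds story length {self.total_length}"
            )

    @property
    def count(self) -> int:
        return self.total_length // self.subsection_length


@dataclass
class LengthCurve:
    """Per-story scores by length plus distribution summaries and rank-order correlations."""

    scores: pd.DataFrame  # index: story id, columns: one per length
    summary: pd.DataFrame  # per length: mean, sd, quantiles
    correlations: pd.DataFrame  # Pearson matrix across lengths


def sample_subsections(
    tokens: Sequence[str], w: int, seed: int | np.random.Generator
) -> list[list[str]]:
    """``floor(L/w)`` disjoint uniform samples of exactly ``w`` tokens each.

    Token positions are drawn without replacement; positions within each
    sample keep their original text order. Leftover ``L mod w`` tokens are
    discarded. Deterministic given the seed.
    """
    L = len(tokens)
    design = LengthDesign(subsection_length=w, total_length=L, seed=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(L)
    out = []
    for i in range(design.count):
        positions = np.sort(perm[i * w : (i + 1) * w])
        out.append([tokens[p] for p in positions])
    return out


def tokens_as_pseudo_sentence(story_id: str, tokens: Sequence[str]) -> TokenizedStory:
    """Wrap a bag of sampled tokens as a single pseudo-sentence.

    Random subsections destroy sentence integrity, so contextual-style
    backends score a subsection as one sentence.
    """
    return TokenizedStory(story_id=story_id, sentences=[[Token(t) for t in tokens]])


def length_curve(
    corpus: dict[str, Sequence[str]],
    lengths: Sequence[int],
    scorer: Callable[[str, Sequence[str]], float],
    seed: int,
    truncate_to: int | None = None,
) -> LengthCurve:
    """Mean subsection score per story per length, with cross-length correlations.

    ``corpus`` maps story id to its (backend-appropriate, preprocessed) token
    sequence; stories are first truncated to ``truncate_to`` tokens (default:
    the minimum requested full length must be available). Stories shorter
    than the truncation length are excluded and logged. ``scorer(story_id,
    tokens)`` returns the score of one token subsection.
    """
    lengths = sorted(set(int(w) for w in lengths))
    if not lengths:
        raise InvalidParameterError("at least one subsection length required")
    L = truncate_to if truncate_to is not None else max(lengths)
    if max(lengths) > L:
        raise InvalidParameterError(f"requested length {max(lengths)} exceeds truncation {L}")

    ss = np.random.SeedSequence(seed)
    records: dict[str, dict[int, float]] = {}
    for story_idx, (story_id, tokens) in enumerate(sorted(corpus.items())):
        if len(tokens) < L:
            logger.warning("story %r: %d tokens < %d required; excluded", story_id, len(tokens), L)
            continue
        tokens = list(tokens[:L])
        row: dict[int, float] = {}
        for w in lengths:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(story_idx, w)))
            if w == L:
                # single subsection in original order: equals the full-story score exactly
                subs = [tokens]
            else:
                subs = sample_subsections(tokens, w, rng)
            row[w] = float(np.mean([scorer(story_id, sub) for sub in subs]))
        records[story_id] = row

    scores = pd.DataFrame.from_dict(records, orient="index")
    scores.index.name = "id"
    scores = scores[lengths]
    summary = pd.DataFrame(
        {
            "mean": scores.mean(),
            "sd": scores.std(ddof=1),
            "q25": scores.quantile(0.25),
            "median": scores.median(),
            "q75": scores.quantile(0.75),
        }
    )
    summary.index.name = "length"
    with np.errstate(invalid="ignore"):
        correlations = scores.corr(method="pearson")
    if scores.std(ddof=1).eq(0).any():
        logger.warning("zero variance at some lengths; correlations undefined there")
    return LengthCurve(scores=scores, summary=summary, correlations=correlations)
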