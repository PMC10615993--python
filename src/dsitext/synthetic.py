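"""Seeded fixture generators: cluster-structured corpora and simulated raters.

Stories are bags of symbolic tokens drawn from ``c`` topic clusters. A token
``alpha-bf`` belongs to the cluster anchored at ``alpha``; the synthetic
embedding backend places it near that anchor's direction (within-cluster
dispersion is a backend parameter), so ground-truth topical divergence is
known by construction: more clusters per story means more divergent token
vectors and a higher expected score.

Rater scores are a linear function of the (z-scored) true score plus
independent per-rater noise, rescaled to the 1–5 rating scale.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .text_prep import Story

__all__ = ["SyntheticCorpusSpec", "generate_stories", "generate_ratings", "CLUSTER_ANCHORS"]

#: Anchor names for topic clusters; the vocabulary ceiling for ``n_clusters``.
CLUSTER_ANCHORS = (
    "alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf",
    "hotel", "india", "juliett", "kilo", "lima", "mike", "november",
    "oscar", "papa", "quebec", "romeo", "sierra", "tango", "uniform",
    "victor", "whiskey", "xray", "yankee", "zulu",
)

_SUFFIXES = ["".join(p) for p in itertools.product(string.ascii_lowercase, repeat=2)]


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Reproducible recipe for one cluster-structured corpus."""

    n_stories: int
    words_per_story: int
    n_clusters: int
    seed: int
    variants_per_cluster: int = 40
    sentence_length: int = 10

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise InvalidParameterError("n_clusters must be >= 1")
        if self.n_clusters > len(CLUSTER_ANCHORS):
            raise InvalidParameterError(
                f"n_clusters {self.n_clusters} exceeds vocabulary of {len(CLUSTER_ANCHORS)} anchors"
            )
        if self.n_stories < 1 or self.words_per_story < 2:
            raise InvalidParameterError("need >= 1 story of >= 2 words")


def generate_stories(spec: SyntheticCorpusSpec) -> tuple[list[Story], pd.DataFrame]:
    """Corpus of symbolic stories plus per-story metadata (true cluster count).

    Each token is ``<anchor>-<suffix>`` with the anchor drawn uniformly from
    the story's clusters; text round-trips through the word tokenizer
    (hyphenated tokens stay whole). Bit-reproducible given (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    anchors = CLUSTER_ANCHORS[: spec.n_clusters]
    stories: list[Story] = []
    meta_rows = []
    for i in range(spec.n_stories):
        clusters = rng.integers(0, spec.n_clusters, size=spec.words_per_story)
        suffix_ids = rng.integers(0, spec.variants_per_cluster, size=spec.words_per_story)
        tokens = [f"{anchors[c]}-{_SUFFIXES[s]}" for c, s in zip(clusters, suffix_ids)]
        sentences = [
            " ".join(tokens[j : j + spec.sentence_length])
            for j in range(0, len(tokens), spec.sentence_length)
        ]
        story_id = f"s{spec.n_clusters:02d}_{i:04d}"
        stories.append(Story(id=story_id, text=". ".join(sentences) + "."))
        meta_rows.append(
            {"id": story_id, "n_clusters": spec.n_clusters, "words": spec.words_per_story}
        )
    return stories, pd.DataFrame(meta_rows)


def generate_ratings(
    scores: pd.Series,
    a: float,
    noise_sd: float,
    n_raters: int,
    seed: int,
    scale: tuple[float, float] = (1.0, 5.0),
) -> pd.DataFrame:
    """Simulated rater matrix: ``rater_j = a * z(score) + eps_j`` mapped onto the rating scale.

    ``eps_j`` is i.i.d. normal(0, noise_sd) per story and rater. The linear
    map centres the raw scores on the scale midpoint and scales them to fit
    the bounds, then clips (a no-op unless the scale is saturated), so rank
    order and the closed-form noise attenuation are preserved.
    """
    if n_raters < 1:
        raise InvalidParameterError("n_raters must be >= 1")
    if noise_sd < 0 or not np.isfinite(a):
        raise InvalidParameterError("need finite a and noise_sd >= 0")
    values = np.asarray(scores, dtype=np.float64)
    sd = values.std(ddof=0)
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    rng = np.random.default_rng(seed)
    raw = a * z[:, None] + rng.normal(0.0, noise_sd, size=(values.size, n_raters))
    lo, hi = scale
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    maxabs = np.max(np.abs(raw))
    scaled = mid + (half * raw / maxabs if maxabs > 0 else raw)
    scaled = np.clip(scaled, lo, hi)
    index = scores.index if isinstance(scores, pd.Series) else pd.RangeIndex(values.size)
    return pd.DataFrame(
        scaled, index=index, columns=[f"rater_{j + 1}" for j in range(n_raters)]
    )
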