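"""The DSI score: mean pairwise cosine distance over a story's embedding multiset.

The printed definition divides the summed pair distances by the number of
word pairs, so a story's score is the arithmetic mean of ``1 - cos(ω, κ)``
over all C(n, 2) unordered vector pairs and lives in [0, 2]. When a
contextual backend contributes several layers, the default is to pool the
union of both layers' vectors and take all pairs among them; per-layer and
cross-layer-only pairings are available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .embeddings import EmbeddingSet
from .errors import InvalidParameterError, UndefinedStatisticError
from .text_prep import Story

__all__ = ["DSIScore", "cosine_distance", "dsi", "dsi_batch", "composite_mean"]

logger = logging.getLogger(__name__)

PAIRINGS = ("pooled", "within_layer", "cross_layer")


@dataclass(frozen=True)
class DSIScore:
    """Scalar score plus diagnostics for one story under one model."""

    story_id: str
    model: str
    value: float  # NaN when undefined (n < 2)
    n: int
    pair_count: int
    dropped: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def cosine_distance(omega: np.ndarray, kappa: np.ndarray) -> float:
    """``1 - cos(ω, κ)``; symmetric, in [0, 2]."""
    omega = np.asarray(omega, dtype=np.float64)
    kappa = np.asarray(kappa, dtype=np.float64)
    no, nk = np.linalg.norm(omega), np.linalg.norm(kappa)
    if no == 0.0 or nk == 0.0:
        raise UndefinedStatisticError("cosine distance undefined for zero-norm vector")
    return float(1.0 - float(omega @ kappa) / (no * nk))


def _mean_pairwise(vectors: np.ndarray) -> tuple[float, int]:
    d = pdist(vectors, metric="cosine")
    return float(d.mean()), d.size


def dsi(embeddings: EmbeddingSet, pairing: str = "pooled", model: str | None = None) -> DSIScore:
    """Mean pairwise cosine distance of the story's embedding multiset.

    ``pairing='pooled'`` takes all pairs among the union of every layer's
    vectors; ``'within_layer'`` averages per-layer pooled scores;
    ``'cross_layer'`` keeps only pairs whose members come from different
    layers. A multiset with n < 2 yields a NaN score (logged), not an error,
    so batch runs can tolerate unmatched-word data loss.
    """
    if pairing not in PAIRINGS:
        raise InvalidParameterError(f"pairing must be one of {PAIRINGS}")
    label = model if model is not None else embeddings.backend
    n = embeddings.n
    if n < 2:
        logger.warning("story %r: n=%d < 2, DSI undefined", embeddings.story_id, n)
        return DSIScore(embeddings.story_id, label, float("nan"), n, 0, embeddings.dropped)

    X = embeddings.vectors
    if pairing == "pooled":
        value, pairs = _mean_pairwise(X)
    else:
        layer_ids = np.asarray([p[2] for p in embeddings.provenance])
        layers = np.unique(layer_ids)
        if pairing == "within_layer":
            scores = []
            pairs = 0
            for l in layers:
                Xl = X[layer_ids == l]
                if Xl.shape[0] >= 2:
                    v, c = _mean_pairwise(Xl)
                    scores.append(v)
                    pairs += c
            if not scores:
                return DSIScore(embeddings.story_id, label, float("nan"), n, 0, embeddings.dropped)
            value = float(np.mean(scores))
        else:  # cross_layer
            if layers.size < 2:
                return DSIScore(embeddings.story_id, label, float("nan"), n, 0, embeddings.dropped)
            total, pairs = 0.0, 0
            for i, li in enumerate(layers):
                Xi = X[layer_ids == li]
                for lj in layers[i + 1 :]:
                    Xj = X[layer_ids == lj]
                    # all cross pairs between the two layers
                    sim = Xi @ Xj.T
                    ni = np.linalg.norm(Xi, axis=1)[:, None]
                    nj = np.linalg.norm(Xj, axis=1)[None, :]
                    dmat = 1.0 - sim / (ni * nj)
                    total += float(dmat.sum())
                    pairs += dmat.size
            value = total / pairs
    return DSIScore(embeddings.story_id, label, value, n, pairs, embeddings.dropped)


def dsi_batch(
    stories: Iterable[Story],
    embedder: Callable[[Story], EmbeddingSet],
    model: str,
    pairing: str = "pooled",
) -> pd.DataFrame:
    """Score every story with one backend; missing scores are flagged rows, never dropped."""
    rows = []
    for story in stories:
        es = embedder(story)
        score = dsi(es, pairing=pairing, model=model)
        rows.append(
            {
                "id": score.story_id,
                "model": score.model,
                "dsi": score.value,
                "n": score.n,
                "pair_count": score.pair_count,
                "dropped": score.dropped,
            }
        )
    return pd.DataFrame(rows, columns=["id", "model", "dsi", "n", "pair_count", "dropped"])


def composite_mean(
    scores: pd.DataFrame, models: Sequence[str], label: str = "composite_ave"
) -> pd.DataFrame:
    """Per-story arithmetic mean of the listed models' scores (NaN-aware).

    Stories where every listed model is missing stay missing. Mirrors the
    averaged context-independent composite used alongside single-model scores.
    """
    if not models:
        raise InvalidParameterError("empty model set")
    sub = scores[scores["model"].isin(models)]
    missing = set(models) - set(sub["model"].unique())
    if missing:
        raise InvalidParameterError(f"models absent from score table: {sorted(missing)}")
    wide = sub.pivot_table(index="id", columns="model", values="dsi", dropna=False)
    out = wide.mean(axis=1, skipna=True).rename("dsi").reset_index()
    out["model"] = label
    out["n_models"] = wide.notna().sum(axis=1).to_numpy()
    return out[["id", "model", "dsi", "n_models"]]
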