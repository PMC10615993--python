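"""Embedding backends: static vector files, contextual encoders, and a seeded synthetic backend.

All three routes emit :class:`EmbeddingSet` objects — an ordered multiset of
finite, nonzero vectors per story — which is the only thing the scorer sees.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Protocol, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InvalidParameterError
from .text_prep import TokenizedStory

__all__ = [
    "VectorTable",
    "EmbeddingSet",
    "load_vector_file",
    "embed_static",
    "embed_contextual",
    "embed_synthetic",
    "SyntheticConfig",
    "SentenceEncoding",
    "SentenceEncoder",
    "HFBertEncoder",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# vector tables (word2vec-text / GloVe-text dialects)
# ---------------------------------------------------------------------------

@dataclass
class VectorTable:
    """token -> d-dimensional vector, case-normalized on lookup."""

    vocabulary: dict[str, np.ndarray]
    dimension: int
    source: str = ""

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise FormatError("empty vocabulary")

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.vocabulary

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vocabulary[token.lower()]

    def __len__(self) -> int:
        return len(self.vocabulary)


def load_vector_file(path, dialect: str = "auto") -> VectorTable:
    """Read a whitespace-delimited text vector file.

    ``dialect='auto'`` treats a first line of exactly two integers as a
    word2vec header; anything else is headerless GloVe-style. Duplicate
    tokens keep the first occurrence (warning logged).
    """
    if dialect not in ("auto", "word2vec", "glove"):
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    vocab: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        parts = first.split()
        is_header = False
        if dialect == "word2vec":
            is_header = True
        elif dialect == "auto":
            is_header = len(parts) == 2 and all(_is_int(p) for p in parts)
        lines: Iterable[tuple[int, str]]
        if is_header:
            lines = enumerate(fh, start=2)
        else:
            lines = _chain_first(first, fh)
        for lineno, line in lines:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split()
            token, values = fields[0].lower(), fields[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise FormatError(f"{path}:{lineno}: no vector values")
            elif len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values, found {len(values)}"
                )
            if token in vocab:
                logger.warning("%s:%d: duplicate token %r ignored", path, lineno, token)
                continue
            try:
                vocab[token] = np.asarray(values, dtype=np.float64)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if dim is None or not vocab:
        raise FormatError(f"{path}: no vector rows")
    return VectorTable(vocabulary=vocab, dimension=dim, source=str(path))


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _chain_first(first: str, fh):
    yield 1, first
    for lineno, line in enumerate(fh, start=2):
        yield lineno, line


# ---------------------------------------------------------------------------
# the scored unit container
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingSet:
    """The multiset of vectors scored for one story.

    ``provenance[i]`` is ``(token, sentence_index, layer_index)`` for
    ``vectors[i]``; static backends use layer 0.
    """

    story_id: str
    vectors: np.ndarray  # (n, d)
    provenance: list[tuple[str, int, int]] = field(default_factory=list)
    dropped: int = 0
    backend: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.size == 0:
            self.vectors = self.vectors.reshape(0, 0)
        else:
            if not np.all(np.isfinite(self.vectors)):
                raise InvalidParameterError(f"story {self.story_id!r}: non-finite vector")
            norms = np.linalg.norm(self.vectors, axis=1)
            if np.any(norms == 0):
                raise InvalidParameterError(f"story {self.story_id!r}: zero-norm vector")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def layers(self) -> list[int]:
        return sorted({p[2] for p in self.provenance})


def embed_static(tokens: TokenizedStory, table: VectorTable) -> EmbeddingSet:
    """One vector per token occurrence; out-of-vocabulary tokens are dropped and counted."""
    vecs: list[np.ndarray] = []
    prov: list[tuple[str, int, int]] = []
    dropped = 0
    for s_idx, sent in enumerate(tokens.sentences):
        for tok in sent:
            if tok.surface in table:
                vecs.append(table[tok.surface])
                prov.append((tok.surface, s_idx, 0))
            else:
                dropped += 1
    arr = np.vstack(vecs) if vecs else np.empty((0, table.dimension))
    es = EmbeddingSet(tokens.story_id, arr, prov, dropped, backend=f"static:{table.source}")
    if es.n < 2:
        warnings.warn(
            f"story {tokens.story_id!r}: only {es.n} embedded tokens; DSI undefined",
            stacklevel=2,
        )
    return es


# ---------------------------------------------------------------------------
# contextual encoders
# ---------------------------------------------------------------------------

@dataclass
class SentenceEncoding:
    """Per-sentence encoder output with special positions already removed.

    ``hidden[l]`` is the (n_pieces, d) hidden state of layer ``l`` where
    index 0 is the input-embedding output and 1..L are the transformer
    blocks (1-indexed, matching the layer-selection convention).
    """

    pieces: list[str]
    hidden: np.ndarray  # (L+1, n_pieces, d)


class SentenceEncoder(Protocol):
    def encode(self, sentence: str) -> SentenceEncoding: ...

    @property
    def num_layers(self) -> int: ...


def embed_contextual(
    tokens: TokenizedStory,
    encoder: SentenceEncoder,
    layers: Sequence[int] = (6, 7),
    include_punctuation: bool = True,
    pool_wordpieces: bool = False,
) -> EmbeddingSet:
    """Encode each sentence independently; each piece contributes one vector per requested layer.

    ``pool_wordpieces=True`` averages the pieces of each whole word instead
    (sensitivity-analysis mode); ``include_punctuation=False`` drops pieces
    that contain no letter or digit after encoding.
    """
    layers = sorted(set(int(l) for l in layers))
    if not layers:
        raise InvalidParameterError("at least one layer index required")
    for l in layers:
        if l < 0 or l > encoder.num_layers:
            raise InvalidParameterError(
                f"layer {l} outside encoder range 0..{encoder.num_layers}"
            )
    vecs: list[np.ndarray] = []
    prov: list[tuple[str, int, int]] = []
    dropped = 0
    for s_idx, sent in enumerate(tokens.sentences):
        text = " ".join(t.surface for t in sent)
        if not text.strip():
            warnings.warn(f"story {tokens.story_id!r}: empty sentence {s_idx} skipped")
            continue
        enc = encoder.encode(text)
        if len(enc.pieces) == 0:
            continue
        keep = np.ones(len(enc.pieces), dtype=bool)
        if not include_punctuation:
            keep = np.array(
                [any(ch.isalnum() for ch in p.lstrip("##")) for p in enc.pieces]
            )
            dropped += int((~keep).sum()) * len(layers)
        for layer in layers:
            H = enc.hidden[layer]
            if pool_wordpieces:
                pieces, H = _pool_pieces(enc.pieces, H, keep)
                for piece, vec in zip(pieces, H):
                    vecs.append(vec)
                    prov.append((piece, s_idx, layer))
            else:
                for piece, vec, k in zip(enc.pieces, H, keep):
                    if not k:
                        continue
                    vecs.append(vec)
                    prov.append((piece, s_idx, layer))
    if not vecs:
        arr = np.empty((0, 0))
    else:
        arr = np.vstack(vecs)
    return EmbeddingSet(tokens.story_id, arr, prov, dropped, backend="contextual")


def _pool_pieces(pieces: list[str], H: np.ndarray, keep: np.ndarray):
    """Mean-pool '##'-continuation pieces onto the word that starts them."""
    words: list[str] = []
    groups: list[list[int]] = []
    for i, p in enumerate(pieces):
        if not keep[i]:
            continue
        if p.startswith("##") and words:
            words[-1] += p[2:]
            groups[-1].append(i)
        else:
            words.append(p)
            groups.append([i])
    pooled = np.vstack([H[g].mean(axis=0) for g in groups]) if groups else H[:0]
    return words, pooled


class HFBertEncoder:
    """Adapter for a HuggingFace bidirectional transformer (requires torch + transformers).

    Hidden-state index 0 is the input-embedding output; 1..num_layers are the
    transformer blocks. Sentences longer than the model input budget are
    chunked at the budget boundary (rare for short narratives).
    """

    def __init__(self, model_name_or_path: str = "bert-large-uncased", device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ConfigurationError(
                "contextual backend requires the 'torch' and 'transformers' packages"
            ) from exc
        self._torch = __import__("torch")
        self.tokenizer = AutoTokenizer.from_pretrained(model_name_or_path)
        self.model = AutoModel.from_pretrained(
            model_name_or_path, output_hidden_states=True
        ).to(device)
        self.model.eval()
        self.device = device

    @property
    def num_layers(self) -> int:  # pragma: no cover - depends on extras
        return self.model.config.num_hidden_layers

    def encode(self, sentence: str) -> SentenceEncoding:  # pragma: no cover
        torch = self._torch
        pieces = self.tokenizer.tokenize(sentence)
        budget = self.tokenizer.model_max_length - 2
        chunks = [pieces[i : i + budget] for i in range(0, len(pieces), budget)] or [[]]
        if len(chunks) > 1:
            logger.warning("sentence of %d pieces chunked at budget %d", len(pieces), budget)
        hidden_chunks = []
        for chunk in chunks:
            ids = self.tokenizer.convert_tokens_to_ids(chunk)
            ids = self.tokenizer.build_inputs_with_special_tokens(ids)
            with torch.no_grad():
                out = self.model(torch.tensor([ids], device=self.device))
            # strip the [CLS]/[SEP] positions
            hs = torch.stack(out.hidden_states)[:, 0, 1:-1, :]
            hidden_chunks.append(hs.cpu().numpy())
        hidden = np.concatenate(hidden_chunks, axis=1)
        return SentenceEncoding(pieces=pieces, hidden=hidden)


# ---------------------------------------------------------------------------
# deterministic synthetic backend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the seeded synthetic backend.

    Tokens of the form ``anchor-variant`` share the anchor's base direction
    perturbed by ``dispersion`` — this is how cluster-structured fixtures
    control between-topic divergence. Plain tokens are their own anchor.
    """

    seed: int
    dimension: int = 50
    mode: str = "static"  # static | contextual
    context_mix: float = 0.0  # λ — weight of the sentence vector
    layers: tuple[int, ...] = (0,)
    dispersion: float = 0.25
    layer_jitter: float = 0.05
    anchor_sep: str = "-"  # survives word tokenization (hyphenated tokens stay whole)

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_mix <= 1.0:
            raise InvalidParameterError("context_mix λ must be in [0, 1]")
        if self.mode not in ("static", "contextual"):
            raise InvalidParameterError(f"unknown synthetic mode {self.mode!r}")
        if self.dimension < 2:
            raise InvalidParameterError("dimension must be >= 2")


@lru_cache(maxsize=262144)
def _hash_vector(key: str, seed: int, dim: int) -> np.ndarray:
    """Unit vector deterministically keyed by (key, seed); pure, so memoized."""
    digest = hashlib.blake2b(f"{seed}\x1f{key}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)
    v.setflags(write=False)
    return v


def _token_vector(surface: str, cfg: SyntheticConfig) -> np.ndarray:
    if cfg.anchor_sep in surface:
        anchor, _ = surface.split(cfg.anchor_sep, 1)
        base = _hash_vector(f"anchor::{anchor}", cfg.seed, cfg.dimension)
        noise = _hash_vector(f"variant::{surface}", cfg.seed, cfg.dimension)
        v = base + cfg.dispersion * noise
    else:
        v = _hash_vector(f"anchor::{surface}", cfg.seed, cfg.dimension)
    return v / np.linalg.norm(v)


def embed_synthetic(tokens: TokenizedStory, config: SyntheticConfig) -> EmbeddingSet:
    """Deterministic pseudo-random embeddings: identical (input, seed) -> identical vectors."""
    cfg = config
    vecs: list[np.ndarray] = []
    prov: list[tuple[str, int, int]] = []
    layers = cfg.layers if cfg.mode == "contextual" else (0,)
    for s_idx, sent in enumerate(tokens.sentences):
        surfaces = [t.surface for t in sent]
        if cfg.mode == "contextual":
            sent_vec = _hash_vector("sentence::" + "\x1f".join(surfaces), cfg.seed, cfg.dimension)
        for tok in sent:
            tv = _token_vector(tok.surface, cfg)
            for layer in layers:
                if cfg.mode == "contextual":
                    v = (1.0 - cfg.context_mix) * tv + cfg.context_mix * sent_vec
                else:
                    v = tv
                if layer != 0:
                    v = v + cfg.layer_jitter * layer * _hash_vector(
                        f"layer::{layer}::{tok.surface}", cfg.seed, cfg.dimension
                    )
                v = v / np.linalg.norm(v)
                vecs.append(v)
                prov.append((tok.surface, s_idx, layer))
    arr = np.vstack(vecs) if vecs else np.empty((0, cfg.dimension))
    return EmbeddingSet(tokens.story_id, arr, prov, 0, backend=f"synthetic:seed={cfg.seed}")
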