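import numpy as np
import pytest

from dsitext.embeddings import EmbeddingSet, SyntheticConfig
from dsitext.text_prep import Story


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def vector_file(tmp_path):
    """Tiny headerless GloVe-style vector file."""
    path = tmp_path / "vectors.txt"
    path.write_text(
        "cat 1.0 0.0 0.0\n"
        "sat 0.0 1.0 0.0\n"
        "dog 0.0 0.0 1.0\n"
        "mat 0.5 0.5 0.0\n"
    )
    return path


@pytest.fixture
def w2v_file(tmp_path):
    path = tmp_path / "w2v.txt"
    path.write_text("2 3\na 1 0 0\nb 0 1 0\n")
    return path


@pytest.fixture
def synthetic_config():
    return SyntheticConfig(seed=7, dimension=50)


@pytest.fixture
def stories():
    return [
        Story("s1", "The cat sat on the mat. The dog barked."),
        Story("s2", "A letter was sent with a stamp to the moon."),
        Story("s3", "Quiet rivers of light ran over the ancient stones."),
    ]


def embedding_set(vectors, story_id="x", layers=None):
    """Helper to build an EmbeddingSet from a raw array (layer 0 unless given)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if layers is None:
        layers = [0] * len(vectors)
    prov = [(f"t{i}", 0, l) for i, l in enumerate(layers)]
    return EmbeddingSet(story_id, vectors, prov, 0, backend="test")
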