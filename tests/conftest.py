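import numpy as np
import pytest

from cutcluster import (
    ClusterSet,
    KeyCorpus,
    MetadataKey,
    SimilarityMatrix,
    SynonymDictionary,
)


@pytest.fixture(scope="session")
def synonyms() -> SynonymDictionary:
    return SynonymDictionary.bundled()


@pytest.fixture
def age_keys_corpus() -> KeyCorpus:
    """Five heterogeneous spellings of an 'age' key, names only."""
    names = ["age (mouse)", "mouse age", "age (in month)", "age (month)", "age (date)"]
    return KeyCorpus(MetadataKey(name=n) for n in names)


@pytest.fixture
def small_partitions() -> tuple[ClusterSet, ClusterSet]:
    computed = ClusterSet.from_dict({"a": {"k1", "k2"}, "b": {"k3", "k4"}})
    reference = ClusterSet.from_dict({"x": {"k1", "k2", "k3"}, "y": {"k4"}})
    return computed, reference


def random_similarity_matrix(
    n: int, rng: np.random.Generator, keys: list[str] | None = None
) -> SimilarityMatrix:
    """Symmetric random similarity matrix with a unit diagonal."""
    a = rng.random((n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(
        keys=keys or [f"k{i}" for i in range(n)], entries=s
    )


def random_partition(keys: list[str], rng: np.random.Generator) -> ClusterSet:
    labels = {k: int(rng.integers(0, max(2, len(keys) // 2))) for k in keys}
    return ClusterSet.from_labels(labels)
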