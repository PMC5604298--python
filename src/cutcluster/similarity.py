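"""Pairwise key similarities and their weighted combination.

Two metadata keys are compared on three axes, each a Jaro-Winkler score
in [0, 1]:

* **name similarity** — the raw lexical distance of the key names;
* **core-concept similarity** — best match between the synonym-expanded
  core concepts of the names, which catches pairs like "disease" vs
  "illness" that share no surface form;
* **value similarity** — best match over the values observed under each
  key, which catches pairs like "gender" vs "sex" that share values
  ("Male", "Female").

The overall similarity is the convex combination

    sim(t_i, t_j) = alpha * sim_name + beta * sim_core + gamma * sim_value

with non-negative weights summing to one. The weights are a property of
the key category (age-like keys lean on values, strain-like keys on
names) and can be fitted from a labeled reference partition — see
:mod:`cutcluster.weights`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np

from ._strings import jaro_winkler_similarity
from .concepts import CoreConcept, SynonymDictionary, Tagger, extract_core_concept
from .io import KeyCorpus, MetadataKey, normalize_key

__all__ = [
    "SimilarityWeights",
    "SimilarityMatrix",
    "name_similarity",
    "core_similarity",
    "value_similarity",
    "combined_similarity",
    "similarity_matrix",
    "DEFAULT_VALUE_CAP",
]

DEFAULT_VALUE_CAP = 50
_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityWeights:
    """The (alpha, beta, gamma) weight triple, constrained to the simplex."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name, w in zip(("alpha", "beta", "gamma"), self):
            if not (-_SIMPLEX_TOL <= w <= 1 + _SIMPLEX_TOL):
                raise ValueError(f"{name}={w} outside [0, 1]")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"weights must sum to 1, got {self.alpha + self.beta + self.gamma}"
            )

    def __iter__(self):
        return iter((self.alpha, self.beta, self.gamma))

    @classmethod
    def name_only(cls) -> "SimilarityWeights":
        return cls(1.0, 0.0, 0.0)

    @classmethod
    def uniform(cls) -> "SimilarityWeights":
        return cls(1 / 3, 1 / 3, 1 / 3)

    def to_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}


def name_similarity(a: str, b: str) -> float:
    """Jaro-Winkler similarity of two normalized key names."""
    return jaro_winkler_similarity(normalize_key(a), normalize_key(b))


def core_similarity(a: CoreConcept, b: CoreConcept) -> float:
    """Best Jaro-Winkler match across the two synonym expansions.

    A shared synonym term gives exactly 1; disjoint single-term sets
    reduce to plain Jaro-Winkler of the heads; an empty set scores 0.
    """
    if not a.synonyms or not b.synonyms:
        return 0.0
    return max(
        jaro_winkler_similarity(x, y) for x in a.synonyms for y in b.synonyms
    )


def value_similarity(
    a: MetadataKey, b: MetadataKey, cap: int | None = DEFAULT_VALUE_CAP
) -> float:
    """Highest Jaro-Winkler score over pairs of observed values.

    Each key contributes at most ``cap`` distinct values (most frequent
    first; ``cap=None`` compares every value pair). A key with no
    observed values scores 0 against everything: absence of evidence is
    not similarity. Values are normalized like key names before
    comparison.
    """
    va = [normalize_key(v) for v in a.top_values(cap)]
    vb = [normalize_key(v) for v in b.top_values(cap)]
    if not va or not vb:
        return 0.0
    return max(jaro_winkler_similarity(x, y) for x in va for y in vb)


def combined_similarity(
    a: MetadataKey,
    b: MetadataKey,
    w: SimilarityWeights,
    *,
    tagger: Tagger | None = None,
    synonyms: SynonymDictionary | None = None,
    value_cap: int | None = DEFAULT_VALUE_CAP,
    cores: dict[str, CoreConcept] | None = None,
) -> float:
    """Overall similarity: the weighted combination of the three scores.

    Lazy by weight: a component with zero weight is never computed, so
    with ``beta = 0`` the tagger and synonym source are never invoked.
    ``cores`` optionally caches extracted concepts keyed by name.
    """
    total = 0.0
    if w.alpha > 0:
        total += w.alpha * name_similarity(a.name, b.name)
    if w.beta > 0:
        if cores is not None:
            ca = cores.get(a.name) or extract_core_concept(a.name, tagger, synonyms)
            cb = cores.get(b.name) or extract_core_concept(b.name, tagger, synonyms)
            cores.setdefault(a.name, ca)
            cores.setdefault(b.name, cb)
        else:
            ca = extract_core_concept(a.name, tagger, synonyms)
            cb = extract_core_concept(b.name, tagger, synonyms)
        total += w.beta * core_similarity(ca, cb)
    if w.gamma > 0:
        total += w.gamma * value_similarity(a, b, value_cap)
    # convex combination of [0,1] terms; clip guards float round-off only
    return min(1.0, max(0.0, total))


@dataclass
class SimilarityMatrix:
    """Symmetric overall-similarity matrix over an ordered key list."""

    keys: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.keys)
        if self.entries.shape != (n, n):
            raise ValueError(f"matrix shape {self.entries.shape} != ({n}, {n})")
        if not np.allclose(self.entries, self.entries.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.entries.size and (
            self.entries.min() < -1e-12 or self.entries.max() > 1 + 1e-12
        ):
            raise ValueError("similarities must lie in [0, 1]")
        self._index = {k: i for i, k in enumerate(self.keys)}
        if len(self._index) != n:
            raise ValueError("duplicate key names in similarity matrix")

    def index(self, name: str) -> int:
        return self._index[name]

    def sim(self, a: str, b: str) -> float:
        return float(self.entries[self._index[a], self._index[b]])

    def __len__(self) -> int:
        return len(self.keys)


def similarity_matrix(
    corpus: KeyCorpus,
    w: SimilarityWeights,
    *,
    tagger: Tagger | None = None,
    synonyms: SynonymDictionary | None = None,
    value_cap: int | None = DEFAULT_VALUE_CAP,
) -> SimilarityMatrix:
    """Materialize the overall similarity over all key pairs.

    Exactly n(n-1)/2 combined-similarity evaluations are performed (the
    diagonal is 1 by reflexivity, the lower triangle by symmetry).
    """
    names = corpus.names
    n = len(names)
    if n == 0:
        raise ValueError("corpus is empty")
    S = np.eye(n)
    cores: dict[str, CoreConcept] = {}
    for i in range(n):
        for j in range(i + 1, n):
            s = combined_similarity(
                corpus[names[i]], corpus[names[j]], w,
                tagger=tagger, synonyms=synonyms, value_cap=value_cap,
                cores=cores,
            )
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(keys=names, entries=S)


def export_components(
    corpus: KeyCorpus,
    stream: IO[str],
    *,
    tagger: Tagger | None = None,
    synonyms: SynonymDictionary | None = None,
    w: SimilarityWeights | None = None,
    value_cap: int | None = DEFAULT_VALUE_CAP,
) -> None:
    """Audit export: long-format TSV of per-pair component similarities."""
    w = w or SimilarityWeights.uniform()
    names = corpus.names
    cores = {
        name: extract_core_concept(name, tagger, synonyms) for name in names
    }
    stream.write("key_a\tkey_b\tsim_name\tsim_core\tsim_value\tsim_combined\n")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sn = name_similarity(a, b)
            sc = core_similarity(cores[a], cores[b])
            sv = value_similarity(corpus[a], corpus[b], value_cap)
            sim = w.alpha * sn + w.beta * sc + w.gamma * sv
            stream.write(f"{a}\t{b}\t{sn:.6f}\t{sc:.6f}\t{sv:.6f}\t{sim:.6f}\n")
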