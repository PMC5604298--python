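"""Fitting the similarity-combination weights from a reference partition.

Given a corpus whose keys carry a gold-standard cluster assignment,
every unordered key pair yields a training example: the three component
similarities (name, core concept, value) as features and a binary
label — 1 if the pair shares a reference cluster, 0 otherwise. A
linear regression of the label on the components, with the coefficients
projected onto the probability simplex (non-negative, summing to one,
no intercept), gives the (alpha, beta, gamma) weights. The fit is
deterministic: the minimum-norm least-squares solution is used before
projection, so refitting the same pairs is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .concepts import SynonymDictionary, Tagger, extract_core_concept
from .io import KeyCorpus
from .partition import ClusterSet
from .similarity import (
    DEFAULT_VALUE_CAP,
    SimilarityWeights,
    core_similarity,
    name_similarity,
    value_similarity,
)

__all__ = [
    "LabeledPair",
    "PairLabelSet",
    "build_pair_labels",
    "fit_weights",
    "project_to_simplex",
    "SimplexWeightRegressor",
]


@dataclass(frozen=True)
class LabeledPair:
    key_a: str
    key_b: str
    sim_name: float
    sim_core: float
    sim_value: float
    label: int


@dataclass
class PairLabelSet:
    """Unordered key pairs with component similarities and binary labels."""

    pairs: list[LabeledPair]

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for p in self.pairs:
            if p.key_a == p.key_b:
                raise ValueError(f"self-pair {p.key_a!r}")
            fs = frozenset((p.key_a, p.key_b))
            if fs in seen:
                raise ValueError(f"duplicate pair {sorted(fs)}")
            seen.add(fs)

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array(
            [[p.sim_name, p.sim_core, p.sim_value] for p in self.pairs], dtype=float
        )
        y = np.array([p.label for p in self.pairs], dtype=float)
        return X, y

    def __len__(self) -> int:
        return len(self.pairs)


def build_pair_labels(
    corpus: KeyCorpus,
    reference: ClusterSet,
    *,
    value_cap: int | None = DEFAULT_VALUE_CAP,
    tagger: Tagger | None = None,
    synonyms: SynonymDictionary | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> PairLabelSet:
    """Component similarities + co-cluster labels for all key pairs.

    Every corpus key must appear in the reference partition. With
    ``max_pairs`` set, a deterministic subsample of that size is drawn
    (all pairs are used by default).
    """
    names = corpus.names
    missing = [n for n in names if n not in reference.keys]
    if missing:
        raise KeyError(f"keys missing from the reference partition: {missing[:5]}")

    label_of = reference.key_to_cluster()
    cores = {n: extract_core_concept(n, tagger, synonyms) for n in names}

    index_pairs = [
        (i, j) for i in range(len(names)) for j in range(i + 1, len(names))
    ]
    if max_pairs is not None and max_pairs < len(index_pairs):
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(index_pairs), size=max_pairs, replace=False)
        index_pairs = [index_pairs[k] for k in sorted(picked)]

    pairs = []
    for i, j in index_pairs:
        a, b = names[i], names[j]
        pairs.append(
            LabeledPair(
                key_a=a,
                key_b=b,
                sim_name=name_similarity(a, b),
                sim_core=core_similarity(cores[a], cores[b]),
                sim_value=value_similarity(corpus[a], corpus[b], value_cap),
                label=int(label_of[a] == label_of[b]),
            )
        )
    return PairLabelSet(pairs)


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w : w >= 0, sum w = 1} (sort-based)."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


class SimplexWeightRegressor(RegressorMixin, BaseEstimator):
    """Least squares with coefficients constrained to the simplex.

    Fits ``y ~ X @ w`` without intercept; the minimum-norm
    unconstrained solution is projected onto the probability simplex.
    With three similarity components as columns of ``X`` and binary
    co-cluster labels as ``y`` this yields the (alpha, beta, gamma)
    combination weights.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Non-negative coefficients summing to 1.
    weights_ : SimilarityWeights
        The coefficient triple (only set for 3-column designs).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "labels are all identical; supply both co-clustered and "
                "separated pairs to fit weights"
            )
        raw, *_ = np.linalg.lstsq(X, y, rcond=None)  # minimum-norm solution
        self.coef_ = project_to_simplex(raw)
        self.n_features_in_ = X.shape[1]
        if X.shape[1] == 3:
            self.weights_ = SimilarityWeights(*self.coef_)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


def fit_weights(labels: PairLabelSet) -> SimilarityWeights:
    """Fit (alpha, beta, gamma) from labeled pairs; deterministic."""
    if not labels.pairs:
        raise ValueError("no training pairs")
    X, y = labels.design()
    return SimplexWeightRegressor().fit(X, y).weights_
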