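"""Agglomerative clustering of keys by the cut() criterion.

The criterion function is the size-normalized aggregated similarity
between two clusters,

    cut(C_i, C_j) = sum_{t_i in C_i} sum_{t_j in C_j} sim(t_i, t_j)
                    / (|C_i| * |C_j|),

used uniformly for both roles: cut(C, C) is the **cohesion** of a
cluster (the double sum runs over all ordered member pairs including
the diagonal, so a singleton has cohesion exactly 1) and cut(C_i, C_j)
for distinct clusters is their **coupling**. Agglomeration starts from
singletons, repeatedly merges the maximal-coupling pair, and stops once
no pair's coupling reaches the threshold epsilon — so epsilon controls
the granularity of the final partition instead of a preset cluster
count. Cached cohesions and couplings are updated in closed form after
each merge, giving O(n^2) total work.

:class:`CutClusterer` wraps the loop as a scikit-learn estimator over a
precomputed similarity matrix; :func:`run_cutcluster` is the
corpus-level convenience entry point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .partition import Cluster, ClusterSet, MergeNode, MergeTree
from .similarity import SimilarityMatrix

__all__ = [
    "cut",
    "cohesion",
    "coupling",
    "merge_update",
    "run_cutcluster",
    "CutClusterer",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.5


def cut(ci: Cluster, cj: Cluster, sim: SimilarityMatrix) -> float:
    """Mean pairwise similarity across the two member sets.

    When ``ci`` and ``cj`` are the same cluster the sum ranges over all
    ordered member pairs including the diagonal, which is what makes a
    singleton's cohesion exactly sim(t, t) = 1.
    """
    try:
        ii = [sim.index(m) for m in ci.members]
        jj = [sim.index(m) for m in cj.members]
    except KeyError as e:
        raise KeyError(f"cluster member {e.args[0]!r} not in similarity matrix") from e
    block = sim.entries[np.ix_(ii, jj)]
    return float(block.sum() / (len(ii) * len(jj)))


def cohesion(c: Cluster, sim: SimilarityMatrix) -> float:
    """cohesion(C) = cut(C, C)."""
    return cut(c, c, sim)


def coupling(ci: Cluster, cj: Cluster, sim: SimilarityMatrix) -> float:
    """coupling(C_i, C_j) = cut(C_i, C_j) for distinct clusters."""
    if ci.members == cj.members:
        raise ValueError("coupling requires two distinct clusters")
    return cut(ci, cj, sim)


@dataclass
class _State:
    """Active clusters with cached sizes, cohesions and couplings."""

    members: dict[int, frozenset[str]]
    sizes: dict[int, int]
    cohesions: dict[int, float]
    couplings: dict[frozenset[int], float]
    next_id: int


def merge_update(state: _State, s: int, t: int) -> int:
    """Merge clusters ``s`` and ``t``; update caches in closed form.

    With n_s = |C_s|, n_t = |C_t| and n_p = n_s + n_t, the exact
    updates are

        cohesion(C_p) = (n_s^2 coh_s + n_t^2 coh_t
                         + 2 n_s n_t coupling(s, t)) / n_p^2
        coupling(C_p, C_k) = (n_s coupling(s, k) + n_t coupling(t, k)) / n_p

    both algebraic consequences of the double-sum definition, so the
    cache always equals a from-scratch recomputation.
    """
    if s == t:
        raise ValueError("cannot merge a cluster with itself")
    ns, nt = state.sizes[s], state.sizes[t]
    np_ = ns + nt
    cst = state.couplings.pop(frozenset((s, t)))
    p = state.next_id
    state.next_id += 1

    state.members[p] = state.members.pop(s) | state.members.pop(t)
    state.sizes[p] = np_
    state.cohesions[p] = (
        ns * ns * state.cohesions.pop(s)
        + nt * nt * state.cohesions.pop(t)
        + 2.0 * ns * nt * cst
    ) / (np_ * np_)
    for k in list(state.members):
        if k == p:
            continue
        csk = state.couplings.pop(frozenset((s, k)))
        ctk = state.couplings.pop(frozenset((t, k)))
        state.couplings[frozenset((p, k))] = (ns * csk + nt * ctk) / np_
    return p


def _init_state(sim: SimilarityMatrix) -> tuple[_State, MergeTree]:
    n = len(sim)
    members = {i: frozenset({sim.keys[i]}) for i in range(n)}
    state = _State(
        members=members,
        sizes={i: 1 for i in range(n)},
        cohesions={i: 1.0 for i in range(n)},  # singleton cohesion is 1
        couplings={
            frozenset((i, j)): float(sim.entries[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        },
        next_id=n,
    )
    tree = MergeTree(leaves={i: sim.keys[i] for i in range(n)})
    return state, tree


def _argmax_pair(candidates) -> tuple[int, int, float] | None:
    """Max-coupling pair; ties break on the smallest (id, id) pair."""
    best: tuple[int, int] | None = None
    best_val = -1.0
    for pair, v in candidates:
        a, b = sorted(pair)
        if v > best_val + 1e-15 or (
            abs(v - best_val) <= 1e-15 and (best is None or (a, b) < best)
        ):
            best, best_val = (a, b), v
    if best is None:
        return None
    return best[0], best[1], best_val


def _run_global(state: _State, tree: MergeTree, epsilon: float) -> None:
    """Merge the globally maximal-coupling pair until none reaches epsilon."""
    while len(state.members) >= 2:
        picked = _argmax_pair(state.couplings.items())
        s, t, val = picked
        if val < epsilon:
            break
        p = merge_update(state, s, t)
        tree.nodes.append(MergeNode(left=s, right=t, merged=p, coupling=val))


def _run_cohesion_first(state: _State, tree: MergeTree, epsilon: float) -> None:
    """Tightest-cluster-first agglomeration.

    Each iteration restricts the pair search to pairs touching the
    maximal-cohesion cluster set and merges the best of them; the loop
    stops as soon as that best candidate falls below epsilon, i.e. once
    the currently tightest clusters cannot merge. Because clusters that
    would chain across loosely coupled groups are always looser than
    well-formed ones, this endpoint resists the over-merging that a
    purely global pair choice allows near the threshold.
    """
    while len(state.members) >= 2:
        best_coh = max(state.cohesions.values())
        star = {k for k, v in state.cohesions.items() if v >= best_coh - 1e-12}
        picked = _argmax_pair(
            (p, v) for p, v in state.couplings.items() if p & star
        )
        if picked is None or picked[2] < epsilon:
            break
        s, t, val = picked
        p = merge_update(state, s, t)
        tree.nodes.append(MergeNode(left=s, right=t, merged=p, coupling=val))


def run_cutcluster(
    sim: SimilarityMatrix,
    epsilon: float = DEFAULT_EPSILON,
    mode: Literal["global", "cohesion-first"] = "cohesion-first",
) -> tuple[ClusterSet, MergeTree]:
    """Run the agglomerative loop on a precomputed similarity matrix.

    Starts from singletons (cohesion 1, coupling = pairwise similarity)
    and merges until the selected pair's coupling drops below
    ``epsilon`` (checked before the merge) or one cluster remains.
    Deterministic given the matrix: ties break on cluster ids.
    ``epsilon > 1`` therefore yields all singletons (no coupling of
    non-identical keys can reach it) and ``epsilon = 0`` a single
    cluster.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(sim) == 0:
        return ClusterSet([]), MergeTree()

    state, tree = _init_state(sim)
    if mode == "global":
        _run_global(state, tree, epsilon)
    elif mode == "cohesion-first":
        _run_cohesion_first(state, tree, epsilon)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    tree.roots = sorted(state.members)
    clusters = [
        Cluster(id=cid, members=state.members[cid], cohesion=min(1.0, state.cohesions[cid]))
        for cid in tree.roots
    ]
    return ClusterSet(clusters), tree


class CutClusterer(ClusterMixin, BaseEstimator):
    """Threshold-terminated agglomerative clustering, scikit-learn style.

    Operates on a precomputed pairwise **similarity** matrix (not a
    distance), with entries in [0, 1] and a unit diagonal. Merging
    stops once no cluster pair's mean inter-similarity (coupling)
    reaches ``epsilon``, so the number of clusters is data-driven.

    Parameters
    ----------
    epsilon : float, default 0.5
        Coupling threshold terminating the agglomeration. 0 merges
        everything into one cluster; values above 1 keep all keys as
        singletons.
    mode : {"global", "cohesion-first"}, default "global"
        Pair-selection rule. "global" merges the globally
        maximal-coupling pair each iteration; "cohesion-first" first
        restricts candidates to pairs touching a maximal-cohesion
        cluster.

    Attributes
    ----------
    labels_ : ndarray of shape (n_keys,)
        Cluster index of every input key.
    n_clusters_ : int
        Number of clusters at termination.
    cluster_set_ : ClusterSet
        The partition with cached cohesions.
    merge_tree_ : MergeTree
        The dendrogram of merges with their coupling values.

    Examples
    --------
    >>> import numpy as np
    >>> S = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
    >>> CutClusterer(epsilon=0.5).fit_predict(S)
    array([0, 0, 1])
    """

    def __init__(
        self,
        epsilon: float = DEFAULT_EPSILON,
        mode: Literal["global", "cohesion-first"] = "cohesion-first",
    ):
        self.epsilon = epsilon
        self.mode = mode

    def fit(self, X, y=None, *, keys: list[str] | None = None):
        """Cluster from a precomputed (n, n) similarity matrix ``X``.

        ``keys`` optionally names the rows; defaults to "k0".."k{n-1}".
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError(f"expected a square similarity matrix, got {X.shape}")
        if keys is None:
            keys = [f"k{i}" for i in range(X.shape[0])]
        sim = SimilarityMatrix(keys=list(keys), entries=X)
        self.cluster_set_, self.merge_tree_ = run_cutcluster(
            sim, epsilon=self.epsilon, mode=self.mode
        )
        label_of = {}
        for idx, cluster in enumerate(self.cluster_set_):
            for m in cluster.members:
                label_of[m] = idx
        self.labels_ = np.array([label_of[k] for k in keys], dtype=int)
        self.n_clusters_ = len(self.cluster_set_)
        self.n_features_in_ = X.shape[1]
        return self
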