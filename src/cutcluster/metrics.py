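"""Partition-comparison metrics: F-Score, entropy, Rand index.

All three score a computed partition **C** (clusters C_1..C_N) against
a reference partition **R** (clusters R_1..R_M) of the same key set:

* clustering F-Score — for each computed cluster, the best harmonic
  mean of precision |C_i ∩ R_j|/|C_i| and recall |C_i ∩ R_j|/|R_j|
  over reference clusters, size-weighted over C (1 is best);
* normalized entropy — how each computed cluster's keys spread across
  reference clusters, -sum P log P / log M, size-weighted (0 is best,
  1 is worst);
* Rand index — the fraction of key pairs on which the two partitions
  agree (same-cluster in both, or split in both; 1 is best).

F-Score and entropy are deliberately asymmetric in (computed,
reference); the Rand index is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from .partition import Cluster, ClusterSet

__all__ = [
    "precision",
    "recall",
    "f_score",
    "entropy",
    "rand_index",
    "EvalReport",
    "evaluate",
]


def _check_nonempty(*clusters: Cluster | frozenset) -> list[frozenset]:
    out = []
    for c in clusters:
        members = c.members if isinstance(c, Cluster) else frozenset(c)
        if not members:
            raise ValueError("metrics are undefined for empty clusters")
        out.append(members)
    return out


def precision(ci: Cluster | frozenset, rj: Cluster | frozenset) -> float:
    """|C_i ∩ R_j| / |C_i| — purity of a computed cluster w.r.t. R_j."""
    a, b = _check_nonempty(ci, rj)
    return len(a & b) / len(a)


def recall(ci: Cluster | frozenset, rj: Cluster | frozenset) -> float:
    """|C_i ∩ R_j| / |R_j| — coverage of a reference cluster by C_i."""
    a, b = _check_nonempty(ci, rj)
    return len(a & b) / len(b)


def _check_cover(computed: ClusterSet, reference: ClusterSet) -> None:
    if computed.keys != reference.keys:
        diff = sorted(computed.keys ^ reference.keys)
        raise ValueError(
            f"partitions cover different key sets; symmetric difference: {diff}"
        )


def f_score(computed: ClusterSet, reference: ClusterSet) -> float:
    """Size-weighted best-match harmonic mean of precision and recall.

    Each computed cluster is matched to the reference cluster giving
    the largest harmonic mean 2PR/(P+R) (0 when P = R = 0), and the
    per-cluster scores are averaged weighted by cluster size.
    """
    _check_cover(computed, reference)
    total = sum(len(c) for c in computed)
    if total == 0:
        raise ValueError("cannot score empty partitions")
    acc = 0.0
    for ci in computed:
        best = 0.0
        for rj in reference:
            p = precision(ci, rj)
            r = recall(ci, rj)
            if p + r > 0:
                best = max(best, 2 * p * r / (p + r))
        acc += best * len(ci)
    return acc / total


def entropy(computed: ClusterSet, reference: ClusterSet) -> float:
    """Normalized distribution entropy of computed clusters over R.

    E(C_i, R) = -sum_j P(C_i, R_j) log P(C_i, R_j) / log M with the
    0 * log 0 := 0 convention, size-weighted over computed clusters.
    0 means every computed cluster sits inside one reference cluster;
    1 means keys are spread evenly over all M reference clusters.
    Requires M >= 2 (log M would vanish otherwise).
    """
    _check_cover(computed, reference)
    m = len(reference)
    if m < 2:
        raise ValueError(
            f"entropy normalization needs >= 2 reference clusters, got {m}"
        )
    log_m = math.log(m)
    total = sum(len(c) for c in computed)
    acc = 0.0
    for ci in computed:
        e = 0.0
        for rj in reference:
            p = precision(ci, rj)
            if p > 0:
                e -= p * math.log(p)
        acc += (e / log_m) * len(ci)
    return acc / total


def rand_index(computed: ClusterSet, reference: ClusterSet) -> float:
    """(TP + TN) / C(|T|, 2) over all unordered key pairs.

    TP counts pairs co-clustered in both partitions, TN pairs separated
    in both. Computed via the contingency table (sums of C(n_ij, 2))
    rather than an explicit pair loop.
    """
    _check_cover(computed, reference)
    n = len(computed.keys)
    if n < 2:
        raise ValueError(f"Rand index needs >= 2 keys, got {n}")

    def comb2(x: int | np.ndarray):
        return x * (x - 1) // 2

    contingency = np.array(
        [[len(ci.members & rj.members) for rj in reference] for ci in computed],
        dtype=np.int64,
    )
    tp = int(comb2(contingency).sum())
    same_c = int(comb2(contingency.sum(axis=1)).sum())
    same_r = int(comb2(contingency.sum(axis=0)).sum())
    total = comb2(n)
    tn = total - same_c - same_r + tp
    return (tp + tn) / total


@dataclass(frozen=True)
class EvalReport:
    """Scores of a computed partition against a reference partition."""

    f_score: float
    entropy: float
    rand_index: float
    n_computed: int
    n_reference: int
    n_keys: int

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"F-Score    {self.f_score:.4f}\n"
            f"Entropy    {self.entropy:.4f}\n"
            f"Rand index {self.rand_index:.4f}\n"
            f"({self.n_computed} computed / {self.n_reference} reference "
            f"clusters over {self.n_keys} keys)"
        )


def evaluate(computed: ClusterSet, reference: ClusterSet) -> EvalReport:
    """Compute all three metrics at once."""
    return EvalReport(
        f_score=f_score(computed, reference),
        entropy=entropy(computed, reference),
        rand_index=rand_index(computed, reference),
        n_computed=len(computed),
        n_reference=len(reference),
        n_keys=len(computed.keys),
    )
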