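"""Partitions of a key set: clusters, cluster sets, merge trees.

A :class:`ClusterSet` is a disjoint cover of a set of metadata keys —
every key belongs to exactly one cluster. This is the common currency
between the clusterer, the evaluation metrics, the weight-fitting stage
and the cluster files on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = ["Cluster", "ClusterSet", "MergeTree", "MergeNode"]


@dataclass
class Cluster:
    """A group of key names with an optional cached cohesion.

    Cohesion is the mean pairwise similarity over all ordered member
    pairs (including the diagonal), so a singleton always has cohesion
    exactly 1.
    """

    id: int
    members: frozenset[str]
    cohesion: float | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if self.cohesion is not None and not (-1e-12 <= self.cohesion <= 1 + 1e-12):
            raise ValueError(f"cohesion {self.cohesion} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, key: str) -> bool:
        return key in self.members


class ClusterSet:
    """A disjoint partition of a key set into clusters."""

    def __init__(self, clusters: Iterable[Cluster]):
        self.clusters: list[Cluster] = list(clusters)
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen & c.members
            if overlap:
                raise ValueError(
                    f"clusters are not disjoint; shared keys: {sorted(overlap)[:5]}"
                )
            seen |= c.members
        self._keys = frozenset(seen)

    @classmethod
    def from_dict(cls, mapping: Mapping[object, Iterable[str]]) -> "ClusterSet":
        """Build from a ``label -> keys`` mapping; labels order clusters."""
        clusters = [
            Cluster(id=i, members=frozenset(keys))
            for i, (_, keys) in enumerate(sorted(mapping.items(), key=lambda kv: str(kv[0])))
        ]
        return cls(clusters)

    @classmethod
    def from_labels(cls, labels: Mapping[str, object]) -> "ClusterSet":
        groups: dict[object, set[str]] = {}
        for key, lab in labels.items():
            groups.setdefault(lab, set()).add(key)
        return cls.from_dict(groups)

    @property
    def keys(self) -> frozenset[str]:
        return self._keys

    def key_to_cluster(self) -> dict[str, int]:
        return {k: c.id for c in self.clusters for k in c.members}

    def as_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    def same_cluster(self, a: str, b: str) -> bool:
        for c in self.clusters:
            if a in c.members:
                return b in c.members
        raise KeyError(a)

    def equivalent(self, other: "ClusterSet") -> bool:
        """Equality up to cluster relabeling/reordering."""
        return set(self.as_sets()) == set(other.as_sets())

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClusterSet({len(self.clusters)} clusters, {len(self._keys)} keys)"


@dataclass
class MergeNode:
    """One agglomeration step: two clusters joined at a coupling value."""

    left: int
    right: int
    merged: int
    coupling: float


@dataclass
class MergeTree:
    """Dendrogram of the agglomeration.

    ``leaves`` maps leaf cluster ids to key names; ``nodes`` records the
    merges in order; ``roots`` are the cluster ids alive at termination.
    The number of internal nodes always equals the number of merges.
    """

    leaves: dict[int, str] = field(default_factory=dict)
    nodes: list[MergeNode] = field(default_factory=list)
    roots: list[int] = field(default_factory=list)

    def n_merges(self) -> int:
        return len(self.nodes)

    def _subtree(self, node_id: int) -> dict | str:
        if node_id in self.leaves:
            return self.leaves[node_id]
        for n in self.nodes:
            if n.merged == node_id:
                return {
                    "left": self._subtree(n.left),
                    "right": self._subtree(n.right),
                    "coupling": n.coupling,
                }
        raise KeyError(node_id)

    def to_json(self) -> str:
        """Nested ``{left, right, coupling}`` forest, one tree per root."""
        return json.dumps([self._subtree(r) for r in self.roots], indent=2)

    def leaf_names(self, node_id: int) -> frozenset[str]:
        sub = self._subtree(node_id)

        def walk(x: dict | str) -> Iterator[str]:
            if isinstance(x, str):
                yield x
            else:
                yield from walk(x["left"])
                yield from walk(x["right"])

        return frozenset(walk(sub))
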