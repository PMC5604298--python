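"""Reading and aggregating key-value metadata tables and cluster files.

GEO-style sample metadata arrives as (record id, key, value) triples,
e.g. ``GSM549324  gender  Male``. Keys are free text and wildly
heterogeneous — "age (years)", "age(yrs)", "age_year" all name the same
attribute — so ingestion only merges spellings that differ by case or
whitespace; punctuation differences are kept, because they are exactly
the signal the similarity measures work on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .partition import ClusterSet

__all__ = [
    "KeyValueRecord",
    "MetadataKey",
    "KeyCorpus",
    "RejectedRow",
    "normalize_key",
    "parse_key_value_table",
    "aggregate",
    "select_category",
    "read_cluster_file",
    "write_cluster_file",
    "write_rejects_report",
]

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class KeyValueRecord:
    """One raw metadata pair attached to a record (e.g. a GEO Sample)."""

    record_id: str
    key: str
    value: str

    def __post_init__(self) -> None:
        if not self.key.strip():
            raise ValueError("key must be non-empty after trimming")


@dataclass(frozen=True)
class RejectedRow:
    line: int
    reason: str
    content: str


@dataclass
class MetadataKey:
    """A distinct (normalized) key with its observed values.

    ``values`` is a multiset (value -> count); ``frequency`` counts the
    key-value pairs that carried this key, so it can exceed the number
    of distinct values.
    """

    name: str
    raw_forms: set[str] = field(default_factory=set)
    values: dict[str, int] = field(default_factory=dict)
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if not self.raw_forms:
            self.raw_forms = {self.name}
        for raw in self.raw_forms:
            if normalize_key(raw) != self.name:
                raise ValueError(f"raw form {raw!r} does not normalize to {self.name!r}")

    def top_values(self, cap: int | None) -> list[str]:
        """Distinct values, most frequent first (ties lexicographic)."""
        ordered = sorted(self.values.items(), key=lambda kv: (-kv[1], kv[0]))
        vals = [v for v, _ in ordered]
        return vals if cap is None else vals[:cap]


class KeyCorpus:
    """A set of :class:`MetadataKey` with unique names."""

    def __init__(self, keys: Iterable[MetadataKey] = ()):
        self._keys: dict[str, MetadataKey] = {}
        for k in keys:
            if k.name in self._keys:
                raise ValueError(f"duplicate key name {k.name!r}")
            self._keys[k.name] = k

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self):
        return iter(self._keys.values())

    def __contains__(self, name: str) -> bool:
        return name in self._keys

    def __getitem__(self, name: str) -> MetadataKey:
        return self._keys[name]

    @property
    def names(self) -> list[str]:
        return sorted(self._keys)

    def n_raw_forms(self) -> int:
        """Count of distinct original spellings across all keys."""
        return len({raw for k in self for raw in k.raw_forms})

    def to_records(self) -> list[KeyValueRecord]:
        """Flatten back to records (synthetic ids); aggregate() inverts this."""
        recs = []
        for k in self:
            i = 0
            for v, n in sorted(k.values.items()):
                for _ in range(n):
                    recs.append(KeyValueRecord(f"r{i}", k.name, v))
                    i += 1
            for _ in range(max(0, k.frequency - i)):
                recs.append(KeyValueRecord(f"r{i}", k.name, ""))
                i += 1
        return recs

    def __repr__(self) -> str:  # pragma: no cover
        return f"KeyCorpus({len(self)} keys)"


def normalize_key(raw: str) -> str:
    """Lowercase, trim, collapse internal whitespace; keep punctuation.

    "disease_state" / "disease-state" / "disease state" stay distinct:
    the punctuation difference is what the name similarity scores.
    """
    return _WS.sub(" ", raw.strip()).lower()


def parse_key_value_table(
    stream: IO[str] | str | Path,
    *,
    sep: str | None = None,
    record_col: str = "record_id",
    key_col: str = "key",
    value_col: str = "value",
    header: bool = True,
) -> tuple[list[KeyValueRecord], list[RejectedRow]]:
    """Parse a delimited (record id, key, value) table.

    ``sep=None`` sniffs tab vs comma from the first line. Without a
    header the first three columns are taken positionally. Malformed
    rows (too few columns, empty key) are returned as rejects, never
    silently dropped.
    """
    if isinstance(stream, (str, Path)):
        with open(stream, encoding="utf-8") as fh:
            return parse_key_value_table(
                fh, sep=sep, record_col=record_col, key_col=key_col,
                value_col=value_col, header=header,
            )

    lines = stream.read().splitlines()
    if not lines:
        return [], []
    if sep is None:
        sep = "\t" if "\t" in lines[0] else ","

    start = 0
    idx = (0, 1, 2)
    if header:
        cols = [c.strip() for c in lines[0].split(sep)]
        try:
            idx = (cols.index(record_col), cols.index(key_col), cols.index(value_col))
        except ValueError as e:
            raise ValueError(
                f"header {cols!r} lacks required columns "
                f"({record_col!r}, {key_col!r}, {value_col!r})"
            ) from e
        start = 1

    records: list[KeyValueRecord] = []
    rejects: list[RejectedRow] = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(sep)
        if len(parts) <= max(idx[0], idx[1]):
            rejects.append(RejectedRow(ln, "too few columns", line))
            continue
        rid = parts[idx[0]].strip()
        key = parts[idx[1]].strip()
        value = parts[idx[2]].strip() if len(parts) > idx[2] else ""
        if not key:
            rejects.append(RejectedRow(ln, "empty key", line))
            continue
        records.append(KeyValueRecord(rid, key, value))
    return records, rejects


def write_rejects_report(rejects: Iterable[RejectedRow], stream: IO[str]) -> None:
    stream.write("line\treason\tcontent\n")
    for r in rejects:
        stream.write(f"{r.line}\t{r.reason}\t{r.content}\n")


def aggregate(records: Iterable[KeyValueRecord]) -> KeyCorpus:
    """Group records by normalized key into a :class:`KeyCorpus`.

    Case/whitespace variants of a key are merged (union of raw forms,
    pooled value multisets); duplicate (record, key) pairs contribute
    separate value observations.
    """
    table: dict[str, MetadataKey] = {}
    for rec in records:
        name = normalize_key(rec.key)
        mk = table.get(name)
        if mk is None:
            mk = MetadataKey(name=name, raw_forms={rec.key}, values={}, frequency=1)
            table[name] = mk
        else:
            mk.raw_forms.add(rec.key)
            mk.frequency += 1
        if rec.value != "":
            mk.values[rec.value] = mk.values.get(rec.value, 0) + 1
    return KeyCorpus(table.values())


def select_category(corpus: KeyCorpus, pattern: str) -> KeyCorpus:
    """Sub-corpus of keys whose name matches ``pattern``.

    Case-insensitive, unanchored search — mirrors pulling "all the
    variants of a key" out of a large corpus by regular expression
    before clustering a category.
    """
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as e:
        raise ValueError(f"invalid category pattern {pattern!r}: {e}") from e
    return KeyCorpus(k for k in corpus if rx.search(k.name))


def read_cluster_file(stream: IO[str] | str | Path, *, sep: str = "\t") -> ClusterSet:
    """Read a two-column (key, cluster label) file into a partition.

    ``#`` comment lines and blank lines are ignored. A key listed under
    two labels is a format error: partitions are disjoint by definition.
    """
    if isinstance(stream, (str, Path)):
        with open(stream, encoding="utf-8") as fh:
            return read_cluster_file(fh, sep=sep)
    assignment: dict[str, str] = {}
    for ln, line in enumerate(stream.read().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(sep)
        if len(parts) < 2:
            raise ValueError(f"line {ln}: expected 2 columns, got {len(parts)}")
        key, label = normalize_key(parts[0]), parts[1].strip()
        if key in assignment and assignment[key] != label:
            raise ValueError(
                f"line {ln}: key {key!r} assigned to both "
                f"{assignment[key]!r} and {label!r}"
            )
        assignment[key] = label
    return ClusterSet.from_labels(assignment)


def write_cluster_file(partition: ClusterSet, stream: IO[str] | str | Path, *, sep: str = "\t") -> None:
    """Write a partition as (key, cluster label) lines; inverse of read."""
    if isinstance(stream, (str, Path)):
        with open(stream, "w", encoding="utf-8") as fh:
            write_cluster_file(partition, fh, sep=sep)
            return
    for cluster in partition:
        for key in sorted(cluster.members):
            stream.write(f"{key}{sep}c{cluster.id}\n")
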