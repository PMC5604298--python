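"""Core-concept extraction and synonym expansion for key names.

Metadata key names are short noun phrases ("patient age", "tissue
isolated"). The core concept is the most informative part of such a
name: the first verb longer than four characters if one exists, else
the first noun together with an immediately preceding adjective. The
concept is then expanded with synonyms from an offline dictionary so
that, e.g., a key about "disease" and one about "illness" can still be
recognized as related.

Part-of-speech tagging is an injected interface — any callable mapping
a token to one of ``{"verb", "noun", "adjective", "other"}``. Two
deterministic, dependency-free taggers ship with the package: a
lexicon tagger covering the vocabulary common in sample-characteristics
keys, and a suffix-heuristic tagger for open vocabulary.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "CoreConcept",
    "Tagger",
    "LexiconTagger",
    "SuffixHeuristicTagger",
    "SynonymDictionary",
    "tokenize",
    "extract_core_concept",
]

Tagger = Callable[[str], str]

_TOKEN_RE = re.compile(r"[a-z0-9']+|[^\sa-z0-9']")

# Vocabulary seen in GEO characteristics keys. Past participles ("isolated",
# "derived") act as verbs in these phrases; unknown words default to noun,
# which is the right prior for attribute names.
_VERBS = {
    "isolated", "derived", "treated", "collected", "harvested", "infected",
    "induced", "injected", "exposed", "extracted", "dissected", "transfected",
    "stimulated", "cultured", "obtained", "measured", "sampled", "diagnosed",
    "separated", "processed", "grouped", "used",
}
_ADJECTIVES = {
    "primary", "parental", "clinical", "advanced", "pathological",
    "experimental", "original", "developmental", "gestational", "viral",
    "bacterial", "diseased", "normal", "healthy", "recipient", "insect",
    "human",
}
# Function words plus provenance/context tokens ("patient age", "donor
# strain", ...): the context word is never the informative concept of a
# characteristics key, so it is stoplisted from core-concept candidacy.
_OTHER = {
    "of", "at", "in", "the", "a", "an", "and", "or", "per", "to", "for",
    "with", "by", "on", "from",
    "patient", "sample", "donor", "subject", "host", "maternal", "paternal",
}


class LexiconTagger:
    """Deterministic lexicon lookup; unknown alphabetic tokens -> noun."""

    def __init__(
        self,
        verbs: Iterable[str] = _VERBS,
        adjectives: Iterable[str] = _ADJECTIVES,
        other: Iterable[str] = _OTHER,
    ):
        self._verbs = frozenset(verbs)
        self._adjectives = frozenset(adjectives)
        self._other = frozenset(other)

    def __call__(self, token: str) -> str:
        t = token.lower()
        if not t.isalpha():
            return "other"
        if t in self._verbs:
            return "verb"
        if t in self._adjectives:
            return "adjective"
        if t in self._other:
            return "other"
        return "noun"


class SuffixHeuristicTagger:
    """Open-vocabulary tagger using English suffix patterns.

    Coarser than the lexicon tagger but covers words it has never seen:
    -ed/-ing -> verb, -al/-ous/-ic/-ive -> adjective, else noun.
    """

    def __call__(self, token: str) -> str:
        t = token.lower()
        if not t.isalpha():
            return "other"
        if t in _OTHER:
            return "other"
        if len(t) > 4 and (t.endswith("ed") or t.endswith("ing")):
            return "verb"
        if len(t) > 3 and t.endswith(("al", "ous", "ive", "ish")):
            return "adjective"
        return "noun"


class SynonymDictionary:
    """Offline term -> synonyms table with symmetric closure.

    Loaded case-insensitively from a JSON object mapping each term to a
    list of synonyms; the closure makes lookup order-independent (if
    "month" lists "date", then "date" also yields "month").
    """

    def __init__(self, table: Mapping[str, Iterable[str]] | None = None):
        self._table: dict[str, set[str]] = {}
        if table:
            for term, syns in table.items():
                t = term.strip().lower()
                for s in syns:
                    self._add(t, s.strip().lower())

    def _add(self, a: str, b: str) -> None:
        if not a or not b or a == b:
            return
        self._table.setdefault(a, set()).add(b)
        self._table.setdefault(b, set()).add(a)

    @classmethod
    def from_json(cls, path: str | Path) -> "SynonymDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    @classmethod
    def bundled(cls) -> "SynonymDictionary":
        """The dictionary shipped with the package."""
        text = resources.files("cutcluster.data").joinpath("synonyms.json").read_text("utf-8")
        return cls(json.loads(text))

    @classmethod
    def empty(cls) -> "SynonymDictionary":
        return cls({})

    def lookup(self, term: str) -> frozenset[str]:
        return frozenset(self._table.get(term.strip().lower(), ()))

    def __len__(self) -> int:
        return len(self._table)


@dataclass(frozen=True)
class CoreConcept:
    """An extracted concept head with its synonym expansion (head included)."""

    head: str
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.head and self.head not in self.synonyms:
            object.__setattr__(self, "synonyms", self.synonyms | {self.head})


def tokenize(name: str) -> list[str]:
    """Split on whitespace and punctuation; punctuation kept as tokens."""
    return _TOKEN_RE.findall(name.lower())


def extract_core_concept(
    name: str,
    tagger: Tagger | None = None,
    synonyms: SynonymDictionary | None = None,
) -> CoreConcept:
    """Extract the core concept of a key name.

    Rule: first verb token longer than four characters; otherwise the
    first noun token, prefixed by an immediately preceding adjective.
    If neither exists (e.g. a purely numeric or punctuation name), the
    whole normalized name is used as the head so every key still has a
    usable concept.
    """
    tagger = tagger or LexiconTagger()
    synonyms = synonyms or SynonymDictionary.empty()
    tokens = tokenize(name)

    try:
        tags = [tagger(t) for t in tokens]
    except Exception:  # tagger failure -> fallback, logged
        logger.warning("tagger failed on %r; falling back to full name", name)
        tokens, tags = [], []

    head = ""
    for tok, tag in zip(tokens, tags):
        if tag == "verb" and len(tok) > 4:
            head = tok
            break
    if not head:
        for i, (tok, tag) in enumerate(zip(tokens, tags)):
            if tag == "noun":
                if i > 0 and tags[i - 1] == "adjective":
                    head = f"{tokens[i - 1]} {tok}"
                else:
                    head = tok
                break
    if not head:
        head = " ".join(tokens) if tokens else name.strip().lower()

    return CoreConcept(head=head, synonyms=frozenset({head}) | synonyms.lookup(head))
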