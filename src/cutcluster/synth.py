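"""Synthetic messy-metadata corpora with known reference clusters.

Real sample-characteristics keys drift apart through a handful of
mechanical processes: typos ("age at diagonosis"), unit parentheticals
("age (years)" / "age (yrs)"), separator changes ("age_year",
"age(years)"), prefixed context words ("patient age", "donor age"),
synonym swaps ("disease" / "illness") and compounding with a second
attribute ("age/sex"). The generator applies exactly these operators to
a set of seed concepts, each variant carrying values drawn from its
concept's sampler (numbers with units for age-like keys, term lists
for disease-like keys), and returns the corpus together with the
ground-truth partition grouping each concept's variants. Everything is
reproducible from a single seed, with per-concept substreams so adding
a concept does not reshuffle the output of existing ones.

Compound keys genuinely belong to more than one attribute; the
reference partition keeps them with their first concept (partitions
are disjoint) and a side annotation records the extra membership so
that this known failure mode can be measured.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io import KeyCorpus, MetadataKey, normalize_key
from .partition import ClusterSet

__all__ = [
    "ConceptSpec",
    "GeneratorConfig",
    "GeneratedData",
    "default_concepts",
    "perturb",
    "generate_corpus",
    "variant_contains_canonical",
    "load_reference_keys",
]

_UNIT_SUFFIXES = [" (years)", " (yrs)", " (months)", " (weeks)", " (days)", " (y)"]
_GENERIC_SUFFIXES = [" type", " name", " status", " group"]
_AFFIX_TOKENS = ["patient", "sample", "donor", "subject", "host"]
_COMPOUND_TAILS = ["sex", "gender", "cell type", "time", "genotype"]
_SEPARATORS = " _/"


@dataclass(frozen=True)
class ConceptSpec:
    """A seed concept: canonical key name, value sampler, synonym pool."""

    name: str
    value_kind: str = "terms"  # "numeric_unit" or "terms"
    synonyms: tuple[str, ...] = ()
    terms: tuple[str, ...] = ()
    units: tuple[str, ...] = ("years", "months", "weeks")
    suffixes: tuple[str, ...] = ()

    def suffix_pool(self) -> list[str]:
        if self.suffixes:
            return list(self.suffixes)
        return _UNIT_SUFFIXES if self.value_kind == "numeric_unit" else _GENERIC_SUFFIXES


def default_concepts() -> list[ConceptSpec]:
    """The six most frequent characteristics categories in GEO samples.

    Each concept mimics its category's real value style — ages are
    numbers with time units, cell lines and strains are nomenclature
    codes, diseases are diagnosis words, tissues anatomical terms,
    treatments drug doses — and its category-typical suffix vocabulary
    ("disease state", "tissue type", "strain background", ...). Distinct
    attributes drawing from distinct, lexically separable vocabularies
    is what gives the value similarity its discriminating power; value
    frequencies are heavy-tailed, so two keys of one concept usually
    share their most common values.
    """
    return [
        ConceptSpec(
            name="age",
            terms=("33 years", "21 years", "8 weeks", "6 months", "45 years",
                   "9 days", "3 months", "62 years"),
            units=("years", "months", "weeks", "days"),
            suffixes=(" (years)", " (yrs)", " (months)", " (weeks)", " (y)", " unit", " group"),
        ),
        ConceptSpec(
            name="cell line",
            terms=("u937", "ht-29", "hl-60", "k562", "jurkat", "hepg2", "u2os", "mcf-7"),
            suffixes=(" name", " id", " passage", " source", " background"),
        ),
        ConceptSpec(
            name="disease", synonyms=("illness",),
            terms=("asthma", "lupus", "gout", "influenza", "melanoma",
                   "malaria", "measles", "obesity"),
            suffixes=(" state", " status", " stage", " subtype", " severity"),
        ),
        ConceptSpec(
            name="strain",
            terms=("c57bl/6j", "cba/j", "nod/scid", "akr/j", "a/j",
                   "fvb/nj", "sjl/j", "b6129sf2/j"),
            suffixes=(" background", " number", " description", " [background]"),
        ),
        ConceptSpec(
            name="tissue", synonyms=("organ",),
            terms=("whole blood", "frontal cortex", "spinal cord", "left ventricle",
                   "optic nerve", "olfactory bulb", "dentate gyrus", "adipose tissue"),
            suffixes=(" type", " source", " site", " of origin"),
        ),
        ConceptSpec(
            name="treatment", synonyms=("therapy",),
            terms=("vehicle", "imatinib 10 nm", "rapamycin 5 um", "dmso 0.1%",
                   "doxorubicin 2 ug/ml", "lps 100 ng/ml", "metformin 50 mg/kg",
                   "cisplatin 40 mg/kg"),
            suffixes=(" agent", " dose", " dosage", " duration", " protocol"),
        ),
    ]


@dataclass
class GeneratorConfig:
    """Knobs of the corpus generator; all rates are probabilities."""

    concepts: list[ConceptSpec] = field(default_factory=default_concepts)
    variants_per_concept: int = 10
    typo_rate: float = 0.05
    unit_suffix_rate: float = 0.3
    separator_swap_rate: float = 0.3
    affix_rate: float = 0.2
    synonym_rate: float = 0.1
    compound_rate: float = 0.1
    values_per_key: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "typo_rate": self.typo_rate,
            "unit_suffix_rate": self.unit_suffix_rate,
            "separator_swap_rate": self.separator_swap_rate,
            "affix_rate": self.affix_rate,
            "synonym_rate": self.synonym_rate,
            "compound_rate": self.compound_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.variants_per_concept < 1 or self.values_per_key < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class GeneratedData:
    """Corpus + ground-truth partition (+ compound-key annotations)."""

    corpus: KeyCorpus
    reference: ClusterSet
    multi_membership: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self):  # allows `corpus, reference = generate_corpus(cfg)`
        return iter((self.corpus, self.reference))


def _concept_rng(seed: int, concept_name: str) -> np.random.Generator:
    digest = hashlib.sha256(concept_name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(seed), sub])


def perturb(
    name: str,
    op: str,
    rng: np.random.Generator,
    *,
    synonyms: tuple[str, ...] = (),
    suffixes: list[str] | None = None,
) -> str:
    """Apply a single named perturbation; the result is always non-empty.

    Operators: ``typo`` (adjacent swap / deletion / duplication),
    ``unit_suffix`` (append a parenthetical), ``separator_swap``
    (space <-> underscore <-> slash <-> fused), ``affix`` (context
    token), ``synonym`` (replace the leading concept term), and
    ``compound`` (append a second attribute after a slash).
    """
    if op == "typo":
        if len(name) < 2:
            return name + name
        kind = rng.choice(["swap", "delete", "insert"])
        # keep the first character: key typos rarely hit the initial letter
        i = int(rng.integers(1, len(name)))
        if kind == "swap" and i < len(name) - 1:
            return name[:i] + name[i + 1] + name[i] + name[i + 2:]
        if kind == "delete" and len(name) > 2:
            return name[:i] + name[i + 1:]
        return name[:i] + name[i] + name[i:]
    if op == "unit_suffix":
        pool = suffixes if suffixes is not None else _UNIT_SUFFIXES
        suf = str(rng.choice(pool))
        if rng.random() < 0.3:  # fused form, e.g. "age(yrs)"
            suf = suf.lstrip()
        return name + suf
    if op == "separator_swap":
        positions = [i for i, c in enumerate(name) if c in _SEPARATORS]
        if not positions:
            return name
        i = int(rng.choice(positions))
        repl = str(rng.choice([c for c in _SEPARATORS + "\0" if c != name[i]]))
        if repl == "\0":
            repl = ""  # fuse the two tokens
        return name[:i] + repl + name[i + 1:]
    if op == "affix":
        tok = str(rng.choice(_AFFIX_TOKENS))
        if rng.random() < 0.7:
            return f"{tok} {name}"
        return f"{tok}_{name}"
    if op == "synonym":
        if not synonyms:
            return name
        syn = str(rng.choice(list(synonyms)))
        head = name.split()[0] if " " in name else name
        return syn + name[len(head):]
    if op == "compound":
        tail = str(rng.choice(_COMPOUND_TAILS))
        return f"{name}/{tail}"
    raise ValueError(f"unknown perturbation {op!r}")


def _sample_values(
    concept: ConceptSpec, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw n values; term frequencies are heavy-tailed (Zipf-like),
    mirroring how a category's top values dominate real repositories."""
    vals = []
    if concept.value_kind == "numeric_unit":
        for _ in range(n):
            num = int(rng.integers(1, 90))
            vals.append(f"{num} {rng.choice(list(concept.units))}")
        return vals
    pool = list(concept.terms or ("unknown",))
    weights = np.array([1.0 / (r + 1) ** 1.5 for r in range(len(pool))])
    weights /= weights.sum()
    for _ in range(n):
        vals.append(str(rng.choice(pool, p=weights)))
    return vals


def _make_variant(
    concept: ConceptSpec, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, str | None]:
    """One perturbed variant of the concept's canonical name.

    Returns the variant plus the compound tail if one was attached.
    """
    name = concept.name
    tail = None
    if rng.random() < cfg.synonym_rate:
        name = perturb(name, "synonym", rng, synonyms=concept.synonyms)
    if rng.random() < cfg.affix_rate:
        name = perturb(name, "affix", rng)
    if rng.random() < cfg.unit_suffix_rate:
        name = perturb(name, "unit_suffix", rng, suffixes=concept.suffix_pool())
    if rng.random() < cfg.compound_rate:
        before = name
        name = perturb(name, "compound", rng)
        tail = name[len(before) + 1:]
    if rng.random() < cfg.separator_swap_rate:
        name = perturb(name, "separator_swap", rng)
    if rng.random() < cfg.typo_rate:
        name = perturb(name, "typo", rng)
    if name == concept.name:
        # force lexical variation so variant counts are meaningful
        op = "unit_suffix" if rng.random() < 0.5 else "affix"
        name = perturb(name, op, rng, suffixes=concept.suffix_pool())
    return normalize_key(name), tail


def generate_corpus(cfg: GeneratorConfig) -> GeneratedData:
    """Generate a messy corpus and its ground-truth partition.

    Each concept contributes its canonical key plus
    ``variants_per_concept`` perturbed variants (duplicates collapse,
    so the corpus holds at most ``n_concepts * (variants + 1)`` keys).
    Every key carries ``values_per_key`` values from its concept's
    sampler. The reference partition groups all variants of a concept;
    a variant colliding with an earlier concept's key stays with that
    earlier concept.
    """
    keys: dict[str, MetadataKey] = {}
    owner: dict[str, str] = {}
    multi: dict[str, list[str]] = {}

    for concept in cfg.concepts:
        rng = _concept_rng(cfg.seed, concept.name)
        names = [normalize_key(concept.name)]
        for _ in range(cfg.variants_per_concept):
            variant, tail = _make_variant(concept, cfg, rng)
            names.append(variant)
            if tail is not None:
                multi.setdefault(variant, [concept.name]).append(tail)
        for name in names:
            vals = _sample_values(concept, cfg.values_per_key, rng)
            if name not in owner:
                owner[name] = concept.name
                counts: dict[str, int] = {}
                for v in vals:
                    counts[v] = counts.get(v, 0) + 1
                keys[name] = MetadataKey(
                    name=name, raw_forms={name}, values=counts, frequency=len(vals)
                )
            elif owner[name] == concept.name:
                for v in vals:
                    keys[name].values[v] = keys[name].values.get(v, 0) + 1
                keys[name].frequency += len(vals)
            # collision with another concept: first owner keeps the key

    groups: dict[str, set[str]] = {}
    for name, concept_name in owner.items():
        groups.setdefault(concept_name, set()).add(name)
    reference = ClusterSet.from_dict(groups)
    return GeneratedData(
        corpus=KeyCorpus(keys.values()),
        reference=reference,
        multi_membership={k: v for k, v in multi.items() if k in owner},
    )


def variant_contains_canonical(variant: str, canonical: str) -> bool:
    """Substring check up to separator differences (space/underscore/slash)."""

    def squash(s: str) -> str:
        return "".join(c for c in s if c not in _SEPARATORS)

    return squash(canonical) in squash(variant)


def load_reference_keys() -> dict[str, tuple[KeyCorpus, ClusterSet]]:
    """The bundled curated GEO key sample, one (corpus, partition) per category.

    Keys only (no values) — suitable for name-similarity smoke tests
    and as a realistic category-selection fixture. Categories are kept
    separate because a handful of compound keys recur across categories
    and a single global partition would not be disjoint.
    """
    text = resources.files("cutcluster.data").joinpath("geo_keys.tsv").read_text("utf-8")
    per_cat: dict[str, dict[str, str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        category, cluster, key = line.split("\t")
        per_cat.setdefault(category, {})[normalize_key(key)] = cluster
    out = {}
    for category, assignment in per_cat.items():
        corpus = KeyCorpus(
            MetadataKey(name=k, raw_forms={k}, values={}, frequency=1)
            for k in assignment
        )
        out[category] = (corpus, ClusterSet.from_labels(assignment))
    return out
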