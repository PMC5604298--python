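# Methods

This note records the model, the numerical choices, and the design
decisions behind `cutcluster`, including what the synthetic-data
generator does and does not emulate.

## Similarity model

The overall similarity of two metadata keys is the convex combination
`α·sim_name + β·sim_core + γ·sim_value` with non-negative weights
summing to one. All three components are built on Jaro-Winkler string
similarity with the standard parameters (prefix scale 0.1, maximum
rewarded prefix 4 characters). Conventions:

* Two empty strings are identical (similarity 1); empty vs non-empty
  scores 0. Two keys with no observed values score 0 on the value
  component — absence of evidence is not similarity.
* Key names and values are normalized before comparison: lowercased,
  trimmed, internal whitespace collapsed. Punctuation is preserved,
  because "age (years)" / "age(yrs)" / "age_year" differ only in
  punctuation and that difference is precisely the signal the method
  measures. Spellings differing only by case or whitespace are merged
  at ingest; punctuation variants are not.
* The value similarity takes the highest score over all value pairs.
  Each key contributes at most `value_cap` distinct values (default
  50), most frequent first, which bounds the quadratic cost on keys
  carrying thousands of values; `value_cap=None` restores the literal
  all-pairs definition.
* Core-concept similarity is the maximum Jaro-Winkler score over the
  cross product of the two synonym-expanded concept sets. A shared
  thesaurus term therefore forces 1.0, and two bare heads reduce to
  plain Jaro-Winkler of the heads. Exact-match-only semantics were the
  other candidate; the maximum generalizes it and degrades gracefully
  for typo'd heads.
* With a zero weight a component is never computed; in particular
  `β = 0` never invokes the tagger or the synonym source.

### Core-concept extraction

The core concept of a key name is the first verb token longer than
four characters; failing that, the first noun token with an
immediately preceding adjective attached; failing that, the whole
normalized name (so keys like "age (yrs)" or purely numeric names
still carry a usable concept). Tokenization splits on whitespace and
punctuation; punctuation tokens are tagged "other".

Part-of-speech tagging is an injected callable. Two deterministic,
dependency-free taggers ship with the package: a lexicon tagger tuned
to sample-characteristics vocabulary, and a suffix-heuristic tagger
for open vocabulary. The lexicon deliberately stoplists provenance and
context tokens — *patient, sample, donor, subject, host, maternal,
paternal* — from noun candidacy: the core concept of "patient age" is
"age", not "patient". Without this, every "patient …" key shares the
concept "patient" and keys of different attributes bond to each other,
which is exactly the failure the core concept is meant to prevent.

Synonyms come from a pinned offline JSON dictionary (symmetric closure
applied at load), shipped with the package. The table is deliberately
lean — genuinely interchangeable terms such as disease/illness,
gender/sex, month/date — because every extra expansion term raises the
cross-concept maximum and dilutes the component's discriminating
power. Online thesauri are out of scope for reproducibility.

## Weight fitting

Training data are all unordered key pairs of a corpus, each carrying
its three component similarities and a binary label (1 if the pair
shares a reference cluster). The weights are the minimum-norm
unconstrained least-squares solution (no intercept, matching the
combination's form) projected onto the probability simplex by the
standard sort-based Euclidean projection. The procedure is
deterministic and refits bit-identically; when all three components
carry identical information the minimum-norm tie-break yields the
uniform weights (1/3, 1/3, 1/3). No cross-validation is performed;
weights are intended to be fitted per key category on its reference
partition. A `max_pairs` option draws a seeded subsample for very
large corpora; the default uses every pair.

## Clustering

The criterion function `cut(C_i, C_j)` is the mean overall similarity
over all ordered member pairs. On a single cluster the double sum
includes the diagonal, which is the only reading under which a
singleton's cohesion is exactly 1. Agglomeration starts from
singletons (cohesion 1, couplings equal to pairwise similarities) and
merges one pair per iteration; after merging C_s and C_t into C_p,

```
cohesion(C_p) = (n_s² coh_s + n_t² coh_t + 2 n_s n_t coupling(s,t)) / (n_s+n_t)²
coupling(C_p, C_k) = (n_s coupling(s,k) + n_t coupling(t,k)) / (n_s+n_t)
```

exact algebraic consequences of the definition, verified in tests
against from-scratch recomputation to 1e-12. Total work is O(n²).

Two selection modes are implemented:

* **cohesion-first** (default): each iteration restricts the pair
  search to pairs touching the maximal-cohesion cluster set and merges
  the best of them; the loop stops as soon as that best candidate
  falls below ε. This is the pseudo-code-literal reading (select the
  tightest cluster set, then its best pair). It also has a practical
  virtue: Jaro-Winkler gives unrelated biomedical strings a similarity
  of roughly 0.45–0.55, so with ε = 0.5 the couplings between genuinely
  different key groups sit just around the threshold. Because clusters
  that would chain across such groups are always looser than
  well-formed ones, stopping when the tightest clusters cannot merge
  blocks the chain merges that a global pair choice permits. Two other
  readings (per-cluster retirement; cohesion-ordered selection with
  global termination) were implemented and rejected: both degrade to
  the global mode's over-merging in measurement.
* **global**: merge the globally maximal-coupling pair until no pair
  reaches ε — classical average-linkage agglomeration with a
  similarity threshold.

Determinism: ties in coupling (within 1e-15) break on the
lexicographically smallest cluster-id pair; cluster ids are assigned
in input order and then in merge order. The threshold comparison is
strict — merging continues while the candidate coupling ≥ ε — so
ε = 0 always yields one cluster and ε > 1 always yields singletons.
The ε comparison happens before the merge. For both modes the merge
sequence does not depend on ε, so the partition at a larger ε refines
the partition at a smaller one.

Default ε is 0.5, the operating point used for the published GEO
curation results this package reimplements.

## Evaluation metrics

Precision and recall of a computed cluster against a reference
cluster are plain set ratios. The clustering F-Score takes, per
computed cluster, the best harmonic mean over reference clusters
(0/0 defined as 0) and size-weights; the normalized entropy uses
−Σ P log P / log M with 0·log 0 := 0 and requires M ≥ 2 (the
normalization is undefined for a single reference cluster and raises);
the Rand index counts concordant pairs via contingency-table algebra
(sums of C(n_ij, 2)), with an explicit pair loop kept as the test
oracle. Logarithm base cancels in the entropy ratio. F-Score and
entropy are intentionally asymmetric in (computed, reference);
the tests pin an instance where swapping the arguments changes the
value.

## Synthetic-data generator

The generator emulates the documented ways real characteristics keys
drift apart: character typos (swap/delete/duplicate, sparing the first
character), unit parentheticals ("(years)", "(yrs)", fused variants),
separator swaps (space/underscore/slash/fused), prefixed context
tokens (patient, sample, donor, subject, host), synonym substitution
(disease → illness), and compound keys ("age/sex"). Each concept's
variants form one reference cluster; compound keys keep a single
reference membership (their first concept) with a side annotation
recording the additional attribute, so the partition stays disjoint
while the known multi-membership failure mode remains measurable.
Sampling is reproducible from one seed, with per-concept substreams
derived from a hash of the concept name so adding a concept leaves
existing output unchanged.

Defaults: six concepts (age, cell line, disease, strain, tissue,
treatment — the most frequent sample-characteristics categories), 10
variants per concept, typo rate 0.05, unit-suffix rate 0.3, separator
rate 0.3, affix rate 0.2, synonym rate 0.1, compound rate 0.1, three
values per key.

Two generator properties are deliberate calibration, not accident,
and the recovery self-test depends on them:

* **Category-typical suffix vocabularies.** Suffixes are drawn per
  concept ("disease state", "tissue type", "strain background",
  "treatment dosage"), mirroring the real key lists, instead of a
  shared generic pool. Shared suffixes across concepts would raise
  cross-concept name similarity for no gain in realism.
* **Lexically separable value vocabularies.** Each category's value
  style matches its real counterpart — unit-bearing ages ("33 years"),
  cell-line codes ("k562"), disease words ("asthma"), strain
  nomenclature ("c57bl/6j"), multiword anatomy ("frontal cortex"),
  drug-plus-dose strings ("rapamycin 5 um") — and the specific pool
  members and their frequency ranks were screened programmatically so
  that the expected cross-concept value similarity (the max-over-pairs
  statistic under the sampler) stays below 0.47 for every concept
  pair, while heavy-tailed (Zipf, exponent 1.5) value frequencies make
  keys of one concept usually share their top values. This reflects a
  real property of curated metadata — different attributes draw from
  different vocabularies, and value frequencies are heavy-tailed — but
  it is an idealization: real categories overlap more (ages appear
  inside treatment-duration values, strain keys carry PubMed IDs), and
  the Jaro-Winkler noise floor between arbitrary same-style strings is
  ~0.5, right at the default threshold. Passing the recovery self-test
  therefore demonstrates correct mechanics on separable categories; it
  does not promise comparable accuracy on raw repository dumps, where
  the published operating point yields partitions that agree only
  moderately with human curation.

Under the frozen defaults the primary self-test (fitted weights,
default ε, 20 seeds) yields a mean F-Score of about 0.90 with
per-seed values ranging roughly 0.71–1.00; other 20-seed windows
measured 0.87–0.90. The margin is thin and stochastic, which the test
acknowledges by asserting the mean, not the minimum.

## Known limitations

* Jaro-Winkler's prefix bias makes prefixed context words ("patient
  X") look more like each other than like their own concept root; the
  core-concept channel compensates only as far as the tagger's lexicon
  reaches.
* Compound keys are assigned to a single cluster; the annotation makes
  the error measurable but the partition model cannot represent
  multi-membership.
* The value similarity's max-over-pairs definition saturates as keys
  accumulate values: with thousands of values per key almost any two
  keys share a near-match, and the component loses discriminating
  power unless capped.
* Weights are category-specific; a single weight triple fitted on a
  pooled corpus is known to perform markedly worse than per-category
  fits, which is why the intended workflow selects a category by
  regular expression first.
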