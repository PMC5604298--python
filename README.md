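# cutcluster

Harmonize heterogeneous biomedical metadata keys by clustering.

Public repositories of gene-expression data describe samples with
free-text key-value pairs ("gender: Male", "age (yrs): 62"). Because
submitters invent their own attribute names, the same concept appears
under dozens of spellings — "age (years)", "age(yrs)", "age_year",
"donor_age", "age at diagnosis (years)" — which silently breaks
keyword search and meta-analysis. `cutcluster` groups such
near-duplicate and closely related keys into clusters so that curators
can review one cluster instead of thousands of raw keys.

## Method

Two keys t_i, t_j are compared by a convex combination of three
Jaro-Winkler-based similarities:

```
sim(t_i, t_j) = α·sim_name + β·sim_core + γ·sim_value ,   α+β+γ = 1
```

* `sim_name` — Jaro-Winkler on the normalized key names;
* `sim_core` — best match between the synonym-expanded *core concepts*
  of the names (first verb longer than four characters, else first
  noun with its modifying adjective), so "disease" and "illness" can
  meet through an offline thesaurus;
* `sim_value` — highest Jaro-Winkler score over the values observed
  under the two keys, so "gender" and "sex" meet through "Male".

The weights (α, β, γ) are fitted per key category by linear
regression of the binary same-cluster label on the three components,
with the coefficients projected onto the probability simplex.

Clustering is agglomerative with a single criterion function, the
cutting cost

```
cut(C_i, C_j) = Σ_{t_i∈C_i} Σ_{t_j∈C_j} sim(t_i, t_j) / (|C_i|·|C_j|)
```

which read on one cluster is its **cohesion** (cut(C, C), exactly 1
for singletons) and on two clusters their **coupling**. Starting from
singletons, the algorithm repeatedly merges the maximal-coupling pair
(by default restricting candidates to the currently tightest clusters)
and stops once no candidate pair's coupling reaches the threshold
ε (default 0.5) — the number of clusters is driven by the data, not
preset. Cohesions and couplings are updated in closed form after every
merge, so a full run costs O(n²).

Partitions are scored against a reference with the clustering
F-Score (size-weighted best-match harmonic mean of precision and
recall), normalized entropy (0 best, 1 worst), and the Rand index.

## Worked example

Generate a messy synthetic corpus with known ground truth, fit
weights, cluster, and evaluate:

```python
from cutcluster import *

cfg = GeneratorConfig(seed=7, typo_rate=0.1)       # 6 concepts x 10 variants
data = generate_corpus(cfg)
syn = SynonymDictionary.bundled()

labels = build_pair_labels(data.corpus, data.reference, synonyms=syn)
w = fit_weights(labels)
print(f"fitted weights: alpha={w.alpha:.3f} beta={w.beta:.3f} gamma={w.gamma:.3f}")

S = similarity_matrix(data.corpus, w, synonyms=syn)
part, tree = run_cutcluster(S)                     # epsilon=0.5
print("clusters found:", len(part))
print(evaluate(part, data.reference))
```

prints

```
fitted weights: alpha=0.000 beta=0.323 gamma=0.677
clusters found: 5
F-Score    0.8906
Entropy    0.1352
Rand index 0.9379
(5 computed / 6 reference clusters over 60 keys)
```

The 60 generated keys (typos, unit parentheticals, separator variants,
prefixed context words, compound keys) are recovered into 5 clusters
against the 6 generating concepts: F-Score 0.89 means the clusters
almost coincide with the ground truth, entropy 0.14 means computed
clusters rarely straddle two concepts, and one cluster, e.g.

```
['age', 'age (months)', 'age (y)', 'age_genotype', 'agegroup',
 'host age', 'host_age', 'patient_age', 'subject age']
```

collects exactly the "age" spellings a curator would want reviewed
together.

The same pipeline is available from the shell:

```
cutcluster simulate --seed 7 --out-corpus corpus.tsv --out-reference ref.tsv
cutcluster fit-weights corpus.tsv ref.tsv --out weights.json
cutcluster cluster corpus.tsv --weights weights.json --out clusters.tsv --tree tree.json
cutcluster evaluate clusters.tsv ref.tsv
```

A curated sample of real GEO characteristics keys (six categories with
their manually assigned reference clusters) ships with the package for
smoke tests: `cutcluster.load_reference_keys()`.

Scikit-learn users can drive the core directly: `CutClusterer(epsilon=0.5)`
is a standard estimator over a precomputed similarity matrix
(`fit_predict`, `labels_`, `get_params`), and `SimplexWeightRegressor`
fits the combination weights.

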