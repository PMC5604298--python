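"""cut()/cohesion/coupling algebra and the agglomerative loop.

The key correctness tool is a brute-force reference implementation that
recomputes every cut() value from scratch each iteration; the
incremental engine must reproduce it exactly.
"""

import numpy as np
import pytest

from cutcluster import (
    Cluster,
    CutClusterer,
    SimilarityMatrix,
    SimilarityWeights,
    cohesion,
    coupling,
    cut,
    run_cutcluster,
    similarity_matrix,
)
from cutcluster.cluster import _init_state, merge_update

from conftest import random_similarity_matrix


def matrix_from(entries, keys=None):
    entries = np.asarray(entries, dtype=float)
    keys = keys or [f"k{i}" for i in range(len(entries))]
    return SimilarityMatrix(keys=keys, entries=entries)


def brute_force_cutcluster(sim, epsilon, mode):
    """From-scratch oracle: no caching, every cut() re-evaluated.

    Mirrors only the selection/termination RULES; all cohesion and
    coupling numbers are recomputed from the matrix each iteration.
    """
    clusters = {i: frozenset({k}) for i, k in enumerate(sim.keys)}
    next_id = len(sim.keys)

    def cut_raw(a, b):
        ii = [sim.index(m) for m in a]
        jj = [sim.index(m) for m in b]
        return sum(sim.entries[i, j] for i in ii for j in jj) / (len(ii) * len(jj))

    while len(clusters) >= 2:
        cohesions = {k: cut_raw(m, m) for k, m in clusters.items()}
        pairs = {
            (a, b): cut_raw(clusters[a], clusters[b])
            for a in clusters for b in clusters if a < b
        }
        if mode == "cohesion-first":
            best_coh = max(cohesions.values())
            star = {k for k, v in cohesions.items() if v >= best_coh - 1e-12}
            pairs = {p: v for p, v in pairs.items() if set(p) & star}
        if not pairs:
            break
        best_pair = None
        best_val = -1.0
        for p, v in sorted(pairs.items()):
            if v > best_val + 1e-15:
                best_pair, best_val = p, v
        if best_val < epsilon:
            break
        a, b = best_pair
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return sorted(frozenset(m) for m in clusters.values())


class TestCutAlgebra:
    def test_singleton_cohesion_is_one(self):
        sim = matrix_from([[1.0, 0.3], [0.3, 1.0]])
        c = Cluster(id=0, members={"k0"})
        assert cut(c, c, sim) == 1.0
        assert cohesion(c, sim) == 1.0

    def test_cut_direct_evaluation(self):
        # clusters {a,b}, {c} with sim(a,c)=0.2, sim(b,c)=0.6 -> (0.2+0.6)/2
        sim = matrix_from(
            [[1.0, 0.5, 0.2], [0.5, 1.0, 0.6], [0.2, 0.6, 1.0]],
            keys=["a", "b", "c"],
        )
        ab = Cluster(id=0, members={"a", "b"})
        c = Cluster(id=1, members={"c"})
        assert cut(ab, c, sim) == pytest.approx(0.4)
        assert cut(c, ab, sim) == pytest.approx(0.4)  # symmetry

    def test_pair_cohesion_closed_form(self):
        s = 0.7
        sim = matrix_from([[1.0, s], [s, 1.0]], keys=["a", "b"])
        ab = Cluster(id=0, members={"a", "b"})
        assert cohesion(ab, sim) == pytest.approx((1 + s) / 2)

    def test_coupling_of_singletons_is_similarity(self):
        sim = matrix_from([[1.0, 0.37], [0.37, 1.0]], keys=["a", "b"])
        a = Cluster(id=0, members={"a"})
        b = Cluster(id=1, members={"b"})
        assert coupling(a, b, sim) == pytest.approx(0.37)

    def test_coupling_same_cluster_is_error(self):
        sim = matrix_from([[1.0, 0.3], [0.3, 1.0]], keys=["a", "b"])
        a = Cluster(id=0, members={"a"})
        with pytest.raises(ValueError):
            coupling(a, Cluster(id=1, members={"a"}), sim)

    def test_unknown_member_is_error(self):
        sim = matrix_from([[1.0]])
        with pytest.raises(KeyError, match="ghost"):
            cut(Cluster(id=0, members={"ghost"}), Cluster(id=1, members={"k0"}), sim)


class TestMergeUpdate:
    def test_two_singletons_closed_form(self):
        sim = matrix_from([[1.0, 0.4, 0.1], [0.4, 1.0, 0.9], [0.1, 0.9, 1.0]])
        state, _ = _init_state(sim)
        p = merge_update(state, 0, 1)
        assert state.cohesions[p] == pytest.approx((1 + 0.4) / 2)
        # coupling of merged pair to third singleton: (0.1 + 0.9)/2
        assert state.couplings[frozenset((p, 2))] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_incremental_cache_matches_fresh_cut(self, seed):
        rng = np.random.default_rng(seed)
        sim = random_similarity_matrix(8, rng)
        state, _ = _init_state(sim)
        order = list(rng.permutation(8))
        ids = list(range(8))
        for _ in range(5):
            a, b = ids.pop(0), ids.pop(0)
            p = merge_update(state, a, b)
            ids.append(p)
            for k, members in state.members.items():
                c = Cluster(id=k, members=members)
                assert state.cohesions[k] == pytest.approx(
                    cut(c, c, sim), abs=1e-12
                )
            for pair, val in state.couplings.items():
                x, y = sorted(pair)
                cx = Cluster(id=x, members=state.members[x])
                cy = Cluster(id=y, members=state.members[y])
                assert val == pytest.approx(cut(cx, cy, sim), abs=1e-12)


class TestRunCutcluster:
    @pytest.mark.parametrize("mode", ["global", "cohesion-first"])
    def test_epsilon_above_one_keeps_singletons(self, mode):
        rng = np.random.default_rng(0)
        sim = random_similarity_matrix(6, rng)
        sim.entries[sim.entries < 1] *= 0.99  # all off-diagonal < 1
        part, tree = run_cutcluster(sim, epsilon=1.01, mode=mode)
        assert len(part) == 6
        assert tree.n_merges() == 0

    @pytest.mark.parametrize("mode", ["global", "cohesion-first"])
    def test_epsilon_zero_merges_everything(self, mode):
        rng = np.random.default_rng(1)
        sim = random_similarity_matrix(6, rng)
        part, tree = run_cutcluster(sim, epsilon=0.0, mode=mode)
        assert len(part) == 1
        assert tree.n_merges() == 5

    def test_empty_matrix(self):
        part, tree = run_cutcluster(
            SimilarityMatrix(keys=[], entries=np.zeros((0, 0))), epsilon=0.5
        )
        assert len(part) == 0

    def test_five_age_keys_first_merge(self, age_keys_corpus):
        sim = similarity_matrix(age_keys_corpus, SimilarityWeights.name_only())
        _, tree = run_cutcluster(sim, epsilon=0.5)
        assert tree.leaf_names(tree.nodes[0].merged) == frozenset(
            {"age (in month)", "age (month)"}
        )

    @pytest.mark.parametrize("mode", ["global", "cohesion-first"])
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        sim = random_similarity_matrix(n, rng)
        eps = float(rng.random())
        part, _ = run_cutcluster(sim, epsilon=eps, mode=mode)
        assert sorted(part.as_sets()) == brute_force_cutcluster(sim, eps, mode)

    @pytest.mark.parametrize("mode", ["global", "cohesion-first"])
    def test_partition_covers_keys_and_merge_count(self, mode):
        rng = np.random.default_rng(7)
        sim = random_similarity_matrix(12, rng)
        part, tree = run_cutcluster(sim, epsilon=0.5, mode=mode)
        assert part.keys == frozenset(sim.keys)
        assert tree.n_merges() == 12 - len(part)
        for node in tree.nodes:
            assert 0.5 <= node.coupling <= 1.0  # merges only at/above eps

    @pytest.mark.parametrize("mode", ["global", "cohesion-first"])
    def test_monotone_epsilon_refinement(self, mode):
        rng = np.random.default_rng(11)
        sim = random_similarity_matrix(10, rng)
        fine, _ = run_cutcluster(sim, epsilon=0.7, mode=mode)
        coarse, _ = run_cutcluster(sim, epsilon=0.3, mode=mode)
        # every fine cluster fits inside a single coarse cluster
        for c in fine.as_sets():
            assert any(c <= d for d in coarse.as_sets())

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        sim = random_similarity_matrix(9, rng)
        a, _ = run_cutcluster(sim, epsilon=0.5)
        b, _ = run_cutcluster(sim, epsilon=0.5)
        assert a.as_sets() == b.as_sets()


class TestMergeTree:
    def test_json_export_nested_structure(self):
        sim = matrix_from(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]],
            keys=["a", "b", "c"],
        )
        _, tree = run_cutcluster(sim, epsilon=0.5)
        import json

        forest = json.loads(tree.to_json())
        assert len(forest) == 2  # {a,b} merged, {c} alone
        merged = next(t for t in forest if isinstance(t, dict))
        assert merged["coupling"] == pytest.approx(0.9)


class TestEstimator:
    def test_fit_predict_labels(self):
        S = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        labels = CutClusterer(epsilon=0.5).fit_predict(S)
        assert labels[0] == labels[1] != labels[2]

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = CutClusterer(epsilon=0.7, mode="global")
        params = est.get_params()
        assert params == {"epsilon": 0.7, "mode": "global"}
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fitted_attributes(self):
        S = np.array([[1.0, 0.9], [0.9, 1.0]])
        est = CutClusterer(epsilon=0.5).fit(S, keys=["a", "b"])
        assert est.n_clusters_ == 1
        assert est.cluster_set_.keys == frozenset({"a", "b"})
        assert est.merge_tree_.n_merges() == 1

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            CutClusterer().fit(np.ones((2, 3)))
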