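"""Classifier, p-distances, neighbor joining and bootstrap supports."""

import itertools

import numpy as np
import pytest

from sipseek.simulate import ReferenceDB, make_reference_db, simulate_amplicon_reads
from sipseek.taxonomy import (
    UNCLASSIFIED,
    bootstrap_supports,
    classify_read,
    classify_reads,
    distance_matrix,
    nj_tree,
    p_distance,
    train_classifier,
)


class TestTrainClassifier:
    def test_single_reference_word_probabilities(self):
        db = ReferenceDB({"a": ["ACGTT"], "b": ["TTTTT"]}, 0.0, 0.5)
        model = train_classifier(db, k=3)
        # present: (1 + 0.5) / (1 + 1); absent: 0.5 / 2
        assert model.word_probability("ACG", "a") == pytest.approx(0.75)
        assert model.word_probability("CGT", "a") == pytest.approx(0.75)
        assert model.word_probability("AAA", "a") == pytest.approx(0.25)
        assert model.word_probability("TTT", "b") == pytest.approx(0.75)

    def test_duplicate_reference_follows_count_formula(self):
        db = ReferenceDB({"a": ["ACGTT", "ACGTT"], "b": ["TTTTT"]}, 0.0, 0.5)
        model = train_classifier(db, k=3)
        assert model.word_probability("ACG", "a") == pytest.approx((2 + 0.5) / 3)
        assert model.word_probability("AAA", "a") == pytest.approx(0.5 / 3)

    def test_training_is_deterministic(self, refdb):
        a = train_classifier(refdb)
        b = train_classifier(refdb)
        assert a.genotypes == b.genotypes
        assert np.array_equal(a.log_prob, b.log_prob)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(ReferenceDB({}, 0.0, 0.1))


class TestClassify:
    def test_noise_free_reference_read_classified_with_full_confidence(self, refdb, model):
        read = refdb.sequences["Methylosarcina"][0]
        a = classify_read(read, model, seed=1)
        assert a.genotype == "Methylosarcina"
        assert a.confidence == 100.0

    def test_exact_score_tie_goes_to_lexicographically_smallest(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        db = ReferenceDB({"beta": [seq], "alpha": [seq]}, 0.0, 0.5)
        model = train_classifier(db, k=8)
        a = classify_read(seq, model, confidence_cutoff=0.0, seed=2)
        assert a.genotype == "alpha"
        assert 30 <= a.confidence <= 70

    def test_random_reads_mostly_unclassified(self, refdb, model):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        reads = ["".join(rng.choice(bases, size=refdb.length)) for _ in range(100)]
        calls = classify_reads(reads, model, seed=4)
        assert (calls["genotype"] == UNCLASSIFIED).mean() >= 0.95

    def test_read_shorter_than_k_rejected(self, model):
        with pytest.raises(ValueError):
            classify_read("ACGT", model)

    def test_perfect_accuracy_on_noise_free_reads(self, refdb, model):
        comp = {g: 10.0 for g in refdb.genotypes}
        reads = simulate_amplicon_reads(comp, refdb, depth=2_000, error_rate=0.0, seed=5)
        calls = classify_reads(reads, model, seed=6)
        assert (calls["genotype"].to_numpy() == reads.true_genotypes).all()

    def test_accuracy_above_99_percent_at_one_percent_read_error(self, refdb, model):
        comp = {g: 10.0 for g in refdb.genotypes}
        reads = simulate_amplicon_reads(comp, refdb, depth=10_000, error_rate=0.01, seed=7)
        calls = classify_reads(reads, model, seed=8)
        acc = (calls["genotype"].to_numpy() == reads.true_genotypes).mean()
        assert acc >= 0.99

    def test_confidence_declines_as_genotypes_converge(self):
        means = []
        for d in (0.002, 0.005, 0.05):
            db = make_reference_db(genotypes=["a", "b"], n_refs_per_genotype=2,
                                   divergence=(0.0, d), seed=9)
            model = train_classifier(db)
            reads = [db.sequences["a"][0]] * 40
            calls = classify_reads(reads, model, confidence_cutoff=0.0, seed=10)
            means.append(calls["confidence"].mean())
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]


class TestPDistance:
    def test_known_values_and_symmetry(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("ACGT", "ACGA") == 0.25
        assert p_distance("ACGT", "TGCA") == p_distance("TGCA", "ACGT") == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")


# --------------------------------------------------------------------------
# exhaustive-topology oracle for neighbor joining
# --------------------------------------------------------------------------

def _all_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists."""
    base = [(0, n), (1, n), (2, n)]
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_id in trees:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1:]
                new += [(u, next_id), (v, next_id), (leaf, next_id)]
                nxt.append((new, next_id + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _paths(edges, n):
    """Leaf-pair -> set of edge indices on the connecting path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n):
        stack = [(a, None, frozenset())]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node < n and node != a:
                out[(a, node)] = used
            for nb, eidx in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node, used | {eidx}))
    return out


def _splits(edges, n):
    """Non-trivial bipartitions (frozensets not containing leaf 0)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        # leaves on v's side when the edge u-v is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def _ls_best_topology(d):
    """Least-squares oracle: the topology whose fitted branch lengths best
    reproduce the distance matrix."""
    n = d.shape[0]
    best, best_rss = None, np.inf
    for edges in _all_topologies(n):
        paths = _paths(edges, n)
        pairs = list(itertools.combinations(range(n), 2))
        a = np.zeros((len(pairs), len(edges)))
        y = np.array([d[i, j] for i, j in pairs])
        for row, (i, j) in enumerate(pairs):
            for eidx in paths[(i, j)]:
                a[row, eidx] = 1.0
        fit, rss, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = float(((a @ fit - y) ** 2).sum())
        if resid < best_rss - 1e-12:
            best_rss, best = resid, edges
    return best


def _random_additive(n, seed):
    rng = np.random.default_rng(seed)
    edges = _all_topologies(n)[rng.integers(0, len(_all_topologies(n)))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    paths = _paths(edges, n)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(lengths[e] for e in paths[(i, j)])
    return d, _splits(edges, n)


def _tree_splits_as_indices(tree, names):
    index = {nm: i for i, nm in enumerate(names)}
    return {frozenset(index[nm] for nm in side) for side in tree.bipartitions()}


class TestNeighborJoining:
    def test_three_taxa_branch_lengths_solve_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(d, names=["x", "y", "z"])
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["x"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["y"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["z"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2)])
    def test_matches_exhaustive_least_squares_oracle(self, n, seed):
        d, _ = _random_additive(n, seed)
        names = [str(i) for i in range(n)]
        got = _tree_splits_as_indices(nj_tree(d, names), names)
        oracle = _splits(_ls_best_topology(d), n)
        assert got == oracle

    @pytest.mark.parametrize("n,seed", [(7, 3), (8, 4), (8, 5)])
    def test_recovers_generating_topology_from_additive_distances(self, n, seed):
        d, true_splits = _random_additive(n, seed)
        names = [str(i) for i in range(n)]
        assert _tree_splits_as_indices(nj_tree(d, names), names) == true_splits

    def test_topology_invariant_under_taxon_permutation(self):
        d, _ = _random_additive(6, seed=6)
        names = [str(i) for i in range(6)]
        perm = [3, 0, 5, 1, 4, 2]
        d_perm = d[np.ix_(perm, perm)]
        names_perm = [names[i] for i in perm]
        full = frozenset(names)

        def canon(splits):
            return {s if "0" not in s else frozenset(full - s) for s in splits}

        a = canon(nj_tree(d, names).bipartitions())
        b = canon(nj_tree(d_perm, names_perm).bipartitions())
        assert a == b

    def test_agrees_with_scikit_bio_on_additive_distances(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        d, _ = _random_additive(7, seed=7)
        names = [str(i) for i in range(7)]
        ours = nj_tree(d, names).tree
        theirs = skbio_nj(DistanceMatrix(d, ids=names))
        assert ours.compare_rfd(theirs) == 0.0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [1.0, 0.0]]))
        bad = np.array([[0.0, 1.0, 2.0], [9.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(bad)
        neg = np.array([[0.0, -1.0, 2.0], [-1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(neg)


class TestBootstrapSupports:
    @staticmethod
    def _strong_alignment():
        db = make_reference_db(genotypes=["p", "q"], n_refs_per_genotype=2,
                               divergence=(0.02, 0.3), length=300, seed=11)
        return [(f"{g}{i}", s) for g in ("p", "q")
                for i, s in enumerate(db.sequences[g])]

    def test_strong_signal_yields_high_support(self):
        tree = bootstrap_supports(self._strong_alignment(), n_reps=100, seed=12)
        assert tree.supports
        assert all(v >= 90 for v in tree.supports.values())

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_supports(self._strong_alignment(), n_reps=1, seed=13)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproduces_supports(self):
        aln = self._strong_alignment()
        a = bootstrap_supports(aln, n_reps=50, seed=14)
        b = bootstrap_supports(aln, n_reps=50, seed=14)
        assert a.supports == b.supports

    def test_newick_includes_support_labels(self, tmp_path):
        tree = bootstrap_supports(self._strong_alignment(), n_reps=10, seed=15)
        path = tmp_path / "tree.nwk"
        newick = tree.to_newick(path)
        assert path.read_text().strip() == newick.strip()
        support = next(iter(tree.supports.values()))
        assert str(int(round(support))) in newick

    def test_distance_matrix_matches_pairwise_p_distance(self):
        aln = {"a": "ACGTACGT", "b": "ACGTACGA", "c": "TTTTACGT"}
        d, names = distance_matrix(aln)
        assert names == ["a", "b", "c"]
        assert d[0, 1] == pytest.approx(p_distance(aln["a"], aln["b"]))
        assert d[0, 2] == pytest.approx(p_distance(aln["a"], aln["c"]))
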