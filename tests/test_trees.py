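import itertools

import numpy as np
import pytest

from lemurmhc.seqcore import Sequence
from lemurmhc.molevol import (
    DistanceMatrix,
    bootstrap_consensus,
    majority_consensus,
    nj_tree,
)

from conftest import random_additive_tree, tree_distances


def canonical_splits(tree):
    leaves = tree.leaf_labels()
    ref = min(leaves)
    out = set()
    for split in tree.bipartitions():
        out.add(frozenset(leaves - split) if ref in split else split)
    return {s for s in out if 1 < len(s) < len(leaves) - 1}


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        assert canonical_splits(tree) == {frozenset({"C", "D"})}
        dists = tree_distances(tree)
        labels = ("A", "B", "C", "D")
        for i, j in itertools.combinations(range(4), 2):
            assert dists[frozenset({labels[i], labels[j]})] == pytest.approx(d[i, j])

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_matrices_recovered_exactly(self, n_taxa):
        for seed in range(5):
            rng = np.random.default_rng(100 * n_taxa + seed)
            labels, matrix, true_splits = random_additive_tree(rng, n_taxa)
            tree = nj_tree(DistanceMatrix(tuple(labels), matrix))
            assert canonical_splits(tree) == true_splits
            dists = tree_distances(tree)
            for i, j in itertools.combinations(range(n_taxa), 2):
                assert dists[frozenset({labels[i], labels[j]})] == pytest.approx(
                    matrix[i, j], abs=1e-9
                )

    def test_matches_exhaustive_least_squares_search_on_five_taxa(self):
        # all 15 unrooted 5-leaf topologies, branch lengths by least squares;
        # the minimum-error topology must be the NJ topology
        rng = np.random.default_rng(55)
        labels, matrix, true_splits = random_additive_tree(rng, 5)
        index = {lab: k for k, lab in enumerate(labels)}
        pairs = list(itertools.combinations(labels, 2))
        y = np.array([matrix[index[a], index[b]] for a, b in pairs])

        # a 5-leaf unrooted binary topology <=> two disjoint cherry pairs
        topologies = set()
        for pair_a in itertools.combinations(labels, 2):
            for pair_b in itertools.combinations(
                [l for l in labels if l not in pair_a], 2
            ):
                topologies.add(frozenset({frozenset(pair_a), frozenset(pair_b)}))
        assert len(topologies) == 15

        best = None
        for topology in topologies:
            splits = list(topology)
            rows = []
            for a, b in pairs:
                row = [0.0] * 7
                row[labels.index(a)] = 1.0
                row[labels.index(b)] = 1.0
                for k, s in enumerate(splits):
                    if (a in s) != (b in s):
                        row[5 + k] = 1.0
                rows.append(row)
            X = np.array(rows)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((X @ beta - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, topology)
        assert best[0] == pytest.approx(0.0, abs=1e-12)
        nj_splits = canonical_splits(nj_tree(DistanceMatrix(tuple(labels), matrix)))
        ref = min(labels)
        oracle_splits = set()
        for s in best[1]:
            oracle_splits.add(frozenset(set(labels) - s) if ref in s else s)
        oracle_splits = {s for s in oracle_splits if 1 < len(s) < 4}
        assert nj_splits == oracle_splits

    def test_agrees_with_dendropy_on_additive_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(8)
        labels, matrix, _ = random_additive_tree(rng, 8)
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(str(x) for x in matrix[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        ref_tree = pdm.nj_tree()
        ref_tree.encode_bipartitions()
        taxa = set(labels)
        ref = min(taxa)
        ref_splits = set()
        for edge in ref_tree.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node is ref_tree.seed_node:
                continue
            side = frozenset(
                leaf.taxon.label for leaf in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(taxa):
                side = frozenset(taxa - side) if ref in side else side
                if 1 < len(side) < len(taxa) - 1:
                    ref_splits.add(side)
        ours = canonical_splits(nj_tree(DistanceMatrix(tuple(labels), matrix)))
        assert ours == ref_splits

    def test_all_equal_distances_still_a_valid_tree(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        tree = nj_tree(DistanceMatrix(tuple("ABCDE"), d))
        assert tree.leaf_labels() == frozenset("ABCDE")
        lengths = []

        def walk(node):
            for c in node.children:
                lengths.append(c.length)
                walk(c)

        walk(tree.root)
        assert all(l >= 0 for l in lengths)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]], float))


class TestBootstrapConsensus:
    def make_two_clade_alignment(self):
        base_a = "A" * 60
        base_b = "G" * 12 + "A" * 48
        def variant(base, i):
            return base[:40] + "CT"[i % 2] * (2 + i) + base[42 + i:]
        return [
            Sequence("a1", base_a),
            Sequence("a2", variant(base_a, 0)),
            Sequence("a3", variant(base_a, 1)),
            Sequence("b1", base_b),
            Sequence("b2", variant(base_b, 0)),
            Sequence("b3", variant(base_b, 1)),
        ]

    def test_clear_clades_get_full_support(self):
        tree = bootstrap_consensus(
            self.make_two_clade_alignment(), gamma_a=None, n_reps=100, seed=1
        )
        supports = tree.support_values()
        # the a-clade and b-clade are two sides of one internal edge
        assert supports[frozenset({"b1", "b2", "b3"})] == 100.0

    def test_identical_sequences_collapse_to_star(self):
        seqs = [Sequence(f"s{i}", "ACGT" * 20) for i in range(5)]
        tree = bootstrap_consensus(seqs, n_reps=50, seed=2)
        assert len(tree.root.children) == 5
        assert tree.support_values() == {}

    def test_fixed_seed_is_reproducible(self):
        seqs = self.make_two_clade_alignment()
        first = bootstrap_consensus(seqs, gamma_a=None, n_reps=60, seed=9)
        second = bootstrap_consensus(seqs, gamma_a=None, n_reps=60, seed=9)
        assert first.newick() == second.newick()

    def test_invalid_replicate_count(self):
        with pytest.raises(ValueError):
            bootstrap_consensus(self.make_two_clade_alignment(), n_reps=0)

    def test_supports_are_percentages_below_100(self):
        tree = bootstrap_consensus(
            self.make_two_clade_alignment(), gamma_a=None, n_reps=100, seed=3
        )
        assert all(50.0 <= v <= 100.0 for v in tree.support_values().values())
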