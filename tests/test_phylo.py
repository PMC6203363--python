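import numpy as np
import pytest
from Bio import Phylo
from io import StringIO

from mircompare.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    align_and_distance,
    bootstrap,
    neighbor_joining,
    p_distance_matrix,
)
from mircompare.seqio import write_newick


def _mutate(rng, seq, k):
    s = list(seq)
    for p in rng.choice(len(s), size=k, replace=False):
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


class TestAlignAndDistance:
    def test_identical_sequences_zero_distance(self):
        aln, dm = align_and_distance([("a", "ACGTACGT" * 4)] * 3)
        assert np.all(dm.d == 0)

    def test_p_distance_definition(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAT"])
        dm = p_distance_matrix(aln)
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_distances_match_pairwise_oracle(self, rng):
        """Leaves derived from one ancestor: MSA p-distance equals the
        direct per-pair Hamming fraction."""
        ancestor = "".join(rng.choice(list("ACGT"), 30))
        leaves = [(f"t{i}", _mutate(rng, ancestor, k)) for i, k in enumerate((1, 2, 3, 4, 5))]
        aln, dm = align_and_distance(leaves)
        for i in range(5):
            for j in range(i + 1, 5):
                ham = sum(a != b for a, b in zip(leaves[i][1], leaves[j][1])) / 30
                assert dm.d[i, j] == pytest.approx(ham)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            align_and_distance([("a", "ACGT"), ("b", "ACGT")])

    def test_triangle_inequality_on_gap_free_inputs(self, rng):
        ancestor = "".join(rng.choice(list("ACGT"), 40))
        leaves = [(f"t{i}", _mutate(rng, ancestor, int(rng.integers(0, 10))))
                  for i in range(6)]
        _, dm = align_and_distance(leaves)
        n = len(dm.taxa)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-9


def _random_tree(rng, n_taxa):
    """A random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 0.6)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.uniform(0.05, 0.6)))
        nodes.append(parent)
    return PhyloTree(TreeNode(children=nodes))


def _path_distances(tree: PhyloTree):
    taxa = sorted(tree.leaf_names())
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))

    def walk(node, dist_to_leaves):
        if node.is_leaf():
            return {node.name: 0.0}
        below = {}
        for child in node.children:
            sub = walk(child, dist_to_leaves)
            sub = {k: v + child.length for k, v in sub.items()}
            for k1, v1 in below.items():
                for k2, v2 in sub.items():
                    d[idx[k1], idx[k2]] = d[idx[k2], idx[k1]] = v1 + v2
            below.update(sub)
        return below

    walk(tree.root, {})
    return DistanceMatrix(taxa, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]))
        tree = neighbor_joining(dm)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["a"] == pytest.approx(0.5 * (0.4 + 0.6 - 0.8))
        assert lengths["b"] == pytest.approx(0.5 * (0.4 + 0.8 - 0.6))
        assert lengths["c"] == pytest.approx(0.5 * (0.6 + 0.8 - 0.4))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrix_recovers_tree(self, n_taxa):
        """NJ is exact on additive distances: topology and branch lengths."""
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            true = _random_tree(rng, n_taxa)
            dm = _path_distances(true)
            est = neighbor_joining(dm)
            assert est.bipartitions() == true.bipartitions()
            assert np.allclose(_path_distances(est).d, dm.d, atol=1e-9)

    def test_equal_distances_tie_break_lowest_pair(self):
        n = 5
        d = np.full((n, n), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], d))
        # the first join must be the lowest-index pair (t0, t1)
        cherries = [
            frozenset(c.leaf_names())
            for c in tree.root.children if not c.is_leaf()
        ]
        assert frozenset({"t0", "t1"}) in set(cherries) | tree.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], d)

    def test_matches_scikit_bio_on_random_matrices(self):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(4, 8))
            x = rng.uniform(0.1, 1.0, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            taxa = [f"t{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(taxa, d))
            theirs = skbio_nj(SkDM(d, ids=taxa))
            their_bips = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    other = frozenset(taxa) - side
                    their_bips.add(min(side, other, key=lambda s: sorted(s)))
            assert ours.bipartitions() == their_bips


class TestBootstrap:
    def _clean_alignment(self):
        # two 4-taxon groups separated at many columns: one unambiguous split
        rows = [
            "AAAAAAAAAACCCCCCCCCC",
            "AAAAAAAAAACCCCCCCCGG",
            "TTTTTTTTTTCCCCCCCCCC",
            "TTTTTTTTTTCCCCCCCCGG",
        ]
        return Alignment(["a1", "a2", "b1", "b2"], rows)

    def test_unambiguous_split_gets_full_support(self):
        tree = bootstrap(self._clean_alignment(), n_replicates=200, seed=1)
        supports = [n.support for n in _internal_nodes(tree.root) if n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_zero_replicates_no_supports(self):
        tree = bootstrap(self._clean_alignment(), n_replicates=0, seed=1)
        assert all(n.support is None for n in _internal_nodes(tree.root))

    def test_deterministic_for_fixed_seed(self, rng):
        ancestor = "".join(rng.choice(list("ACGT"), 40))
        aln, _ = align_and_distance(
            [(f"t{i}", _mutate(rng, ancestor, int(rng.integers(1, 8))))
             for i in range(6)]
        )
        t1 = bootstrap(aln, 50, seed=9)
        t2 = bootstrap(aln, 50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_taxon_order(self):
        """On a tie-free alignment the supported splits do not depend on
        the order taxa are supplied in.  (With tied distances the NJ
        tie-break is index-based, so order can legitimately change the
        topology — the invariance claim applies to the generic case.)"""
        base = self._clean_alignment()
        def supports(names, rows):
            tree = bootstrap(Alignment(names, rows), 100, seed=4)
            out = {}
            def walk(node):
                for c in node.children:
                    if not c.is_leaf() and c.support is not None:
                        out[frozenset(c.leaf_names())] = c.support
                    walk(c)
            walk(tree.root)
            return out
        fwd = supports(base.names, base.rows)
        rev = supports(list(reversed(base.names)), list(reversed(base.rows)))
        # same splits (up to complement), same supports
        def canon(d, all_names):
            full = frozenset(all_names)
            return {min(k, full - k, key=lambda s: sorted(s)): v for k, v in d.items()}
        assert canon(fwd, base.names) == canon(rev, base.names)


def _internal_nodes(node):
    out = []
    for c in node.children:
        if not c.is_leaf():
            out.append(c)
        out.extend(_internal_nodes(c))
    return out


def test_newick_round_trip(tmp_path, rng):
    """Our writer emits newick that Bio.Phylo parses back to the same tree."""
    tree = _random_tree(np.random.default_rng(2), 6)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    parsed = Phylo.read(str(path), "newick")
    assert {t.name for t in parsed.get_terminals()} == set(tree.leaf_names())
    # total branch length survives the round trip
    ours = sum(n.length for n in tree.root.leaves()) + sum(
        n.length for n in _internal_nodes(tree.root)
    )
    assert parsed.total_branch_length() == pytest.approx(ours, abs=1e-4)


def test_negative_branch_clamped():
    # a decidedly non-additive matrix provokes negative NJ estimates
    d = np.array([
        [0.0, 0.1, 0.9, 0.9],
        [0.1, 0.0, 0.9, 0.1],
        [0.9, 0.9, 0.0, 0.1],
        [0.9, 0.1, 0.1, 0.0],
    ])
    tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
    def all_nodes(n):
        yield n
        for c in n.children:
            yield from all_nodes(c)
    assert all(n.length >= 0 for n in all_nodes(tree.root))
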