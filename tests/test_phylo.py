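import math

import dendropy
import numpy as np
import pytest

from cesakit import phylo
from cesakit.errors import AlignmentError, DistanceError
from cesakit.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    bootstrap,
    complete_deletion,
    nj_tree,
    poisson_distance,
    read_newick,
    write_newick,
)


def random_binary_tree(taxa_labels, rng):
    """A random binary unrooted tree with uniform branch lengths."""
    tns = dendropy.TaxonNamespace(list(taxa_labels))
    nodes = []
    for label in taxa_labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[j], nodes[i]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
        node.edge.length = float(rng.uniform(0.05, 1.0))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    labels, dist = phylo.tree_path_distances(tree)
    return DistanceMatrix(ids=labels, p=np.zeros_like(dist), d=dist, kind="p_distance")


def perturbed_alignment(rng, ids, length=60, k=6):
    """Rows a few substitutions away from a shared base (no saturated pairs)."""
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.choice(letters, length)
    rows = []
    for _ in ids:
        row = base.copy()
        for site in rng.choice(length, size=k, replace=False):
            row[site] = rng.choice(letters)
        rows.append("".join(row))
    return Alignment(ids=tuple(ids), rows=tuple(rows))


class TestCompleteDeletion:
    def test_gapped_column_removed_everywhere(self):
        aln = Alignment(ids=("a", "b"), rows=("AC-G", "AC-G"))
        assert complete_deletion(aln).rows == ("ACG", "ACG")

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDE", "ACDF"))
        assert complete_deletion(aln) == aln

    def test_single_gap_removes_whole_column(self):
        aln = Alignment(ids=("a", "b"), rows=("A-", "AA"))
        assert complete_deletion(aln).rows == ("A", "A")

    def test_ambiguity_counts_as_missing(self):
        aln = Alignment(ids=("a", "b"), rows=("AXC", "AAC"))
        assert complete_deletion(aln).rows == ("AC", "AC")

    def test_nothing_left_raises(self):
        aln = Alignment(ids=("a", "b"), rows=("-", "A"))
        with pytest.raises(AlignmentError):
            complete_deletion(aln)


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDE", "ACDE"))
        assert poisson_distance(aln).d[0, 1] == 0.0

    def test_half_different_gives_ln_two(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDE", "ACWY"))
        assert poisson_distance(aln).d[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_correction_dominates_p(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKL"))
        rows = tuple("".join(rng.choice(letters, 60)) for _ in range(4))
        dm = poisson_distance(Alignment(ids=("a", "b", "c", "d"), rows=rows))
        off_diag = ~np.eye(4, dtype=bool)
        assert (dm.d[off_diag] >= dm.p[off_diag]).all()
        assert ((dm.d > dm.p) == (dm.p > 0)).all()

    def test_saturated_pair_rejected(self):
        aln = Alignment(ids=("a", "b"), rows=("AAAA", "CCCC"))
        with pytest.raises(DistanceError, match="Poisson"):
            poisson_distance(aln)

    def test_monotone_increasing_in_p(self):
        p = np.linspace(0, 0.95, 50)
        d = -np.log(1 - p)
        assert (np.diff(d) > 0).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(ids=("a", "b", "c"), p=np.zeros_like(d), d=d, kind="p_distance")
        tree = nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            true_tree = random_binary_tree([f"t{i}" for i in range(n_taxa)], rng)
            estimated = nj_tree(additive_matrix(true_tree))
            assert estimated.bipartitions() == true_tree.bipartitions()
            _, d_true = phylo.tree_path_distances(true_tree)
            _, d_est = phylo.tree_path_distances(estimated)
            np.testing.assert_allclose(d_est, d_true, atol=1e-9)

    def test_equal_distances_tie_break_deterministic(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids=("a", "b", "c", "d"), p=np.zeros_like(d), d=d, kind="p_distance")
        first = nj_tree(dm).tree.as_string(schema="newick")
        second = nj_tree(dm).tree.as_string(schema="newick")
        assert first == second

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(DistanceError, match="symmetric"):
            DistanceMatrix(ids=("a", "b", "c"), p=np.zeros_like(d), d=d, kind="p_distance")

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(123)
        n = 7
        base = rng.uniform(0.1, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = tuple(f"t{i}" for i in range(n))
        mine = nj_tree(
            DistanceMatrix(ids=ids, p=np.zeros_like(d), d=d, kind="p_distance")
        )
        other = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        other_bips = set()
        all_ids = frozenset(ids)
        for node in other.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= n - 2:
                other_bips.add(frozenset({below, all_ids - below}))
        assert mine.bipartitions() == other_bips


class TestBootstrap:
    def test_clean_split_gets_full_support(self):
        # 30 columns all supporting a1|a2 vs b1|b2, plus 10 constant columns
        aln = Alignment(
            ids=("a1", "a2", "b1", "b2"),
            rows=(
                "A" * 30 + "G" * 10,
                "A" * 29 + "D" + "G" * 10,
                "C" * 30 + "G" * 10,
                "C" * 29 + "D" + "G" * 10,
            ),
        )
        result = bootstrap(aln, replicates=20, seed=0)
        split = frozenset({frozenset({"a1", "a2"}), frozenset({"b1", "b2"})})
        assert result.supports[split] == 100

    def test_single_replicate_supports_are_binary(self):
        aln = perturbed_alignment(np.random.default_rng(1), tuple("abcde"))
        result = bootstrap(aln, replicates=1, seed=0)
        assert set(result.supports.values()) <= {0, 100}

    def test_same_seed_reproducible(self):
        aln = perturbed_alignment(np.random.default_rng(2), tuple("abcde"))
        r1 = bootstrap(aln, replicates=30, seed=9)
        r2 = bootstrap(aln, replicates=30, seed=9)
        assert r1.supports == r2.supports

    def test_supports_invariant_under_leaf_relabeling(self):
        rng = np.random.default_rng(3)
        base = perturbed_alignment(rng, tuple("abcde"))
        rows = base.rows
        ids = tuple("abcde")
        permutation = {"a": "e", "b": "d", "c": "c", "d": "b", "e": "a"}
        r1 = bootstrap(Alignment(ids=ids, rows=rows), replicates=25, seed=4)
        permuted_ids = tuple(permutation[i] for i in ids)
        r2 = bootstrap(Alignment(ids=permuted_ids, rows=rows), replicates=25, seed=4)
        relabeled = {
            frozenset(frozenset(permutation[x] for x in side) for side in bip): s
            for bip, s in r1.supports.items()
        }
        assert relabeled == r2.supports


class TestNewick:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_random_trees(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree([f"t{i}" for i in range(6)], rng)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.bipartitions() == tree.bipartitions()
        _, d1 = phylo.tree_path_distances(tree)
        _, d2 = phylo.tree_path_distances(back)
        np.testing.assert_allclose(d1, d2, rtol=1e-4)

    def test_metacharacter_ids_quoted(self, tmp_path):
        d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
        ids = ("plain", "with space", "pa(ren")
        tree = nj_tree(DistanceMatrix(ids=ids, p=np.zeros_like(d), d=d, kind="p_distance"))
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        assert read_newick(path).leaf_labels == frozenset(ids)


def test_showcase_family_groups_orthologs(showcase):
    """Leaves of each ortholog group form a clade in the NJ tree."""
    aln = Alignment.from_records(showcase.records)
    tree = nj_tree(poisson_distance(complete_deletion(aln)))
    all_leaves = frozenset(aln.ids)
    bips = tree.bipartitions()
    for group in set(showcase.group_of.values()):
        members = frozenset(
            leaf for leaf, g in showcase.group_of.items() if g == group
        )
        assert frozenset({members, all_leaves - members}) in bips
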