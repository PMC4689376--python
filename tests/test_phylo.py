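"""p-distance, neighbor joining, bootstrap and Newick round-trips."""

import numpy as np
import pytest

from leasurvey.errors import LeaSurveyError, ParseError
from leasurvey.phylo import (
    Alignment,
    DistanceMatrix,
    bipartitions,
    bootstrap,
    nj_build,
    p_distance,
    patristic_distances,
    read_newick,
    write_newick,
)

from _oracles import random_additive_tree


def _aln(**rows):
    return Alignment(list(rows), list(rows.values()))


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAA", "AAAT", 0.25),
            ("A-AA", "AG-A", 0.0),  # pairwise deletion: 2 comparable, both match
        ],
    )
    def test_hand_counts(self, a, b, expected):
        dm = p_distance(_aln(x=a, y=b))
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(LeaSurveyError, match="comparable"):
            p_distance(_aln(x="A--", y="-GG"))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_build(DistanceMatrix(["A", "B", "C"], d))
        pd = patristic_distances(tree)
        assert pd[("A", "B")] == pytest.approx(5)
        assert pd[("A", "C")] == pytest.approx(9)
        assert pd[("B", "C")] == pytest.approx(10)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A,B),(C,D)) with every branch length 1
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = nj_build(DistanceMatrix(taxa, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        pd = patristic_distances(tree)
        for (x, y), val in pd.items():
            i, j = taxa.index(x), taxa.index(y)
            assert val == pytest.approx(d[i, j])

    def test_tied_matrix_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        taxa = list("EDCBA")
        t1 = nj_build(DistanceMatrix(taxa, d.copy()))
        t2 = nj_build(DistanceMatrix(taxa, d.copy()))
        assert write_newick(t1) == write_newick(t2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(LeaSurveyError):
            nj_build(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_additive_matrices_recover_generating_topology(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        taxa = [f"t{i}" for i in range(n_taxa)]
        for _ in range(10):
            _, _, dist, true_splits = random_additive_tree(taxa, rng)
            d = np.zeros((n_taxa, n_taxa))
            for (a, b), v in dist.items():
                i, j = taxa.index(a), taxa.index(b)
                d[i, j] = d[j, i] = v
            tree = nj_build(DistanceMatrix(taxa, d))
            assert bipartitions(tree) == true_splits


class TestBootstrap:
    def _two_clade_alignment(self):
        a, b = "AAAAAAAAAA", "TTTTTTTTTT"
        return Alignment(
            ["a1", "a2", "a3", "b1", "b2", "b3"], [a, a, a, b, b, b]
        )

    def test_clean_split_gets_full_support(self):
        tree = bootstrap(self._two_clade_alignment(), n_reps=100, seed=0)
        sups = [
            node.support
            for node in tree.preorder_node_iter()
            if getattr(node, "support", None) is not None
        ]
        assert sups and all(s == 1.0 for s in sups)

    def test_same_seed_reproduces_supports(self, bundle):
        from leasurvey.phylo import read_alignment

        aln = read_alignment(str(bundle.alignment_fasta))
        t1 = bootstrap(aln, n_reps=20, seed=11)
        t2 = bootstrap(aln, n_reps=20, seed=11)
        assert write_newick(t1) == write_newick(t2)

    def test_point_tree_independent_of_seed(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap(aln, n_reps=5, seed=1)
        t2 = bootstrap(aln, n_reps=5, seed=99)
        assert bipartitions(t1) == bipartitions(t2)

    def test_single_replicate_supports_are_binary(self):
        tree = bootstrap(self._two_clade_alignment(), n_reps=1, seed=4)
        for node in tree.preorder_node_iter():
            s = getattr(node, "support", None)
            if s is not None:
                assert s in (0.0, 1.0)

    def test_planted_groups_form_supported_clades(self, bundle):
        """Each synthetic group is strongly divergent from the others and
        must come back as a clade with bootstrap support >= 0.9."""
        from collections import defaultdict

        from leasurvey.phylo import read_alignment

        aln = read_alignment(str(bundle.alignment_fasta))
        tree = bootstrap(aln, n_reps=100, seed=0)
        splits = bipartitions(tree)
        support_of = {}
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        ref = min(leaves)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(leaves - side)
            if getattr(node, "support", None) is not None:
                support_of[side] = node.support
        groups = defaultdict(set)
        for g, grp in bundle.truth.group_of.items():
            groups[grp].add(g)
        for grp, members in groups.items():
            key = frozenset(members)
            if ref in key:
                key = frozenset(leaves - key)
            assert key in splits or key in support_of, f"{grp} not a clade"
            if key in support_of:
                assert support_of[key] >= 0.9, grp


class TestNewickIO:
    def test_roundtrip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(8)]
        _, _, dist, _ = random_additive_tree(taxa, rng)
        d = np.zeros((8, 8))
        for (a, b), v in dist.items():
            i, j = taxa.index(a), taxa.index(b)
            d[i, j] = d[j, i] = v
        tree = nj_build(DistanceMatrix(taxa, d))
        back = read_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        pd1, pd2 = patristic_distances(tree), patristic_distances(back)
        for k in pd1:
            assert pd2[k] == pytest.approx(pd1[k], abs=1e-9)

    def test_known_string_roundtrip(self):
        s = "(A:1,B:1,(C:1,D:1):0.5);"
        tree = read_newick(s)
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_unbalanced_parentheses_raise_parse_error(self):
        with pytest.raises(ParseError):
            read_newick("(A:1,B:1")
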