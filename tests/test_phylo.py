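import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from niltkit.phylo import (bipartitions, bootstrap_support, distance_matrix,
                           neighbor_joining, root_with_outgroup, unroot)
from niltkit.seqio import NamedSequence as NS

from _oracles import best_ls_topology, random_additive_matrix


class TestDistanceMatrix:
    def test_identical_rows_are_zero(self):
        dm = distance_matrix(["ACGT", "ACGT"])
        assert dm.data[0, 1] == 0.0

    def test_p_distance(self):
        dm = distance_matrix(["AAAA", "AAAT"])
        assert dm.data[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        dm = distance_matrix(["AA-A", "AATT"])  # 3 comparable, 1 mismatch
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_poisson_of_zero_is_zero(self):
        dm = distance_matrix(["ACGT", "ACGT"], model="poisson")
        assert dm.data[0, 1] == 0.0

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix(["A--A", "-AA-"])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)  # (4+6-8)/2
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_four_taxon_split_matches_ls_oracle(self):
        labels = list("ABCD")
        # additive matrix for ((A,B),(C,D))
        d = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
                     dtype=float)
        tree = neighbor_joining(DistanceMatrix(d, ids=labels))
        assert bipartitions(tree) == best_ls_topology(labels, d) == {("A", "B")}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrices_recover_ls_topology(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(8):
            dist, true_bips = random_additive_matrix(labels, rng)
            tree = neighbor_joining(DistanceMatrix(dist, ids=labels))
            assert bipartitions(tree) == true_bips
            assert best_ls_topology(labels, dist) == true_bips

    def test_agrees_with_skbio_on_additive_matrix(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(6)]
        dist, _ = random_additive_matrix(labels, rng)
        dm = DistanceMatrix(dist, ids=labels)
        assert bipartitions(neighbor_joining(dm)) == bipartitions(skbio_nj(dm))

    def test_branch_lengths_reproduce_additive_distances(self):
        rng = np.random.default_rng(13)
        labels = [f"t{i}" for i in range(5)]
        dist, _ = random_additive_matrix(labels, rng)
        tree = neighbor_joining(DistanceMatrix(dist, ids=labels))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    got = tree.find(a).distance(tree.find(b))
                    assert got == pytest.approx(dist[i, j], abs=1e-9)


def _signal_msa():
    blockA = "AAAAAAAAAA"
    blockB = "CCCCCCCCCC"
    return [
        NS("A", blockA + blockA + "ACGTAC", "nt"),
        NS("B", blockA + blockA + "ACGTAA", "nt"),
        NS("C", blockB + blockA + "GCTTAC", "nt"),
        NS("D", blockB + blockA + "GCTAAC", "nt"),
        NS("E", blockB + blockB + "TTTAAC", "nt"),
    ]


class TestBootstrap:
    def test_duplicated_block_msa_has_full_support(self):
        msa = [NS("A", "AACC" * 6, "nt"), NS("B", "AACA" * 6, "nt"),
               NS("C", "GGCC" * 6, "nt"), NS("D", "GGTC" * 6, "nt")]
        tree = bootstrap_support(msa, n_reps=50, seed=3)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproducible(self):
        msa = _signal_msa()
        t1 = bootstrap_support(msa, n_reps=80, seed=9)
        t2 = bootstrap_support(msa, n_reps=80, seed=9)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2

    def test_supports_bounded_and_true_split_maximal(self):
        msa = _signal_msa()
        tree = bootstrap_support(msa, n_reps=100, seed=4)
        by_bip = {}
        leaves = frozenset("ABCDE")
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                side = frozenset(t.name for t in n.tips())
                key = min(tuple(sorted(side)), tuple(sorted(leaves - side)))
                by_bip[key] = n.support
        assert all(0.0 <= s <= 100.0 for s in by_bip.values())
        assert by_bip[("A", "B")] == max(by_bip.values())

    def test_taxon_order_invariance(self):
        msa = _signal_msa()
        t1 = bootstrap_support(msa, n_reps=60, seed=2)
        t2 = bootstrap_support(msa[::-1], n_reps=60, seed=2)

        def by_bip(tree):
            leaves = frozenset("ABCDE")
            out = {}
            for n in tree.non_tips(include_self=False):
                if hasattr(n, "support"):
                    side = frozenset(t.name for t in n.tips())
                    out[min(tuple(sorted(side)), tuple(sorted(leaves - side)))] = n.support
            return out

        assert by_bip(t1) == by_bip(t2)


class TestRooting:
    def _tree(self):
        return bootstrap_support(_signal_msa(), n_reps=40, seed=1)

    def test_outgroup_becomes_child_of_root(self):
        rooted = root_with_outgroup(self._tree(), "E")
        assert "E" in [c.name for c in rooted.children]

    def test_supports_preserved(self):
        tree = self._tree()
        before = {b: None for b in bipartitions(tree)}
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                leaves = frozenset(t.name for t in tree.tips())
                side = frozenset(t.name for t in n.tips())
                before[min(tuple(sorted(side)), tuple(sorted(leaves - side)))] = n.support
        rooted = root_with_outgroup(tree, "E")
        leaves = frozenset(t.name for t in rooted.tips())
        for n in rooted.non_tips(include_self=False):
            side = frozenset(t.name for t in n.tips())
            key = min(tuple(sorted(side)), tuple(sorted(leaves - side)))
            if key in before and before[key] is not None:
                assert getattr(n, "support", None) == before[key]

    def test_root_then_unroot_preserves_topology(self):
        tree = self._tree()
        rooted = root_with_outgroup(tree, "C")
        assert bipartitions(unroot(rooted)) == bipartitions(tree)

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(self._tree(), "Z")
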