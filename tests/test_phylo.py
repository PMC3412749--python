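"""Distances, neighbour joining, bootstrap supports, parsimony score and
group assignment, with closed-form, brute-force and scikit-bio oracles."""

import math

import dendropy
import numpy as np
import pytest

from ugtfam import simkit
from ugtfam.formats import ProteinAlignment
from ugtfam.phylo import (DistanceMatrix, assign_groups, bootstrap, build_nj,
                          pairwise_distances, parsimony_score)

from _oracles import fitch_bruteforce


def _bipartitions(tree):
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.add(frozenset((side, taxa - side)))
    return out


class TestPairwiseDistances:
    def test_identical_and_simple_mismatch(self):
        aln = ProteinAlignment(["a", "b", "c"], ["AAAA", "AAAA", "AAAT"])
        dm = pairwise_distances(aln)
        assert dm.get("a", "b") == 0.0
        assert dm.get("a", "c") == 0.25

    def test_pairwise_deletion_recount_oracle(self):
        """Distances equal a per-pair recount on random gapped rows."""
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(20)]
        rows = ["".join(rng.choice(list("ACDE-"), size=60)) for _ in ids]
        rows = [r if r.strip("-") else "A" * 60 for r in rows]
        aln = ProteinAlignment(ids, rows)
        dm = pairwise_distances(aln)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ra, rb = aln.rows[a], aln.rows[b]
                pairs = [(x, y) for x, y in zip(ra, rb)
                         if x != "-" and y != "-"]
                if not pairs:
                    continue
                p = sum(1 for x, y in pairs if x != y) / len(pairs)
                assert dm.get(a, b) == pytest.approx(p)

    def test_dayhoff_correction_formula(self):
        aln = ProteinAlignment(["a", "b", "c"],
                               ["AAAAAAAAAA", "AAAAAAAATC", "AAAAAAAAAA"])
        dm = pairwise_distances(aln, model="dayhoff_corrected")
        p = 0.2
        assert dm.get("a", "b") == pytest.approx(-math.log(1 - p - 0.2 * p * p))

    def test_saturated_pair_falls_back_to_p(self):
        aln = ProteinAlignment(["a", "b", "c"],
                               ["AAAA", "TTTT", "AAAA"])
        dm = pairwise_distances(aln, model="dayhoff_corrected")
        assert dm.get("a", "b") == 1.0
        assert ("a", "b") in dm.saturated_pairs

    def test_zero_overlap_is_error(self):
        aln = ProteinAlignment(["a", "b", "c"], ["AA--", "--AA", "AAAA"])
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_distances(aln)


class TestBuildNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        tree = build_nj(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree: A,B on one side (pendants 1, 2), C,D on the other (3, 1),
        # internal edge 1
        ids = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0.0]])
        tree = build_nj(DistanceMatrix(ids, d))
        assert _bipartitions(tree) == {
            frozenset((frozenset("AB"), frozenset("CD")))}
        pend = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert pend == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1},
                                     abs=1e-9)
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.length and not e.head_node.is_leaf()]
        assert internal == pytest.approx([1.0], abs=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(8)
        n = 7
        coords = rng.uniform(0, 1, size=(n, 4))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ref = _bipartitions(build_nj(DistanceMatrix(ids, d)))
        perm = rng.permutation(n)
        d2 = d[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assert _bipartitions(build_nj(DistanceMatrix(ids2, d2))) == ref

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check against scikit-bio's NJ on a random
        (generic, tie-free) distance matrix."""
        import skbio
        rng = np.random.default_rng(9)
        n = 8
        coords = rng.uniform(0, 1, size=(n, 5))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ours = _bipartitions(build_nj(DistanceMatrix(ids, d)))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        taxa = frozenset(ids)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n - 1:
                theirs.add(frozenset((side, taxa - side)))
        assert ours == theirs

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_nj(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        aln = ProteinAlignment(["A", "B", "C", "D"],
                               ["AAAAAAAA", "AAAAAAAA",
                                "TTTTTTTT", "TTTTTTTT"])
        tree = bootstrap(aln, n_reps=50, seed=0)
        sups = [n.support for n in tree.preorder_node_iter()
                if not n.is_leaf() and n is not tree.seed_node]
        assert sups == [100.0]

    def test_same_seed_reproduces_supports(self, deep_clade_sim):
        aln = deep_clade_sim.truth.true_alignment
        t1 = bootstrap(aln, n_reps=20, seed=5)
        t2 = bootstrap(aln, n_reps=20, seed=5)
        s1 = sorted(n.support for n in t1.preorder_node_iter()
                    if not n.is_leaf() and n is not t1.seed_node)
        s2 = sorted(n.support for n in t2.preorder_node_iter()
                    if not n.is_leaf() and n is not t2.seed_node)
        assert s1 == s2

    def test_deep_clades_highly_supported(self, deep_clade_sim):
        """The planted deep split exceeds the 85% group-support criterion
        at 200 replicates."""
        aln = deep_clade_sim.truth.true_alignment
        tree = bootstrap(aln, n_reps=200, seed=5)
        a_side = frozenset(f"A{i}" for i in range(1, 7))
        b_side = frozenset(f"B{i}" for i in range(1, 7))
        support = None
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side in (a_side, b_side):
                support = node.support
        assert support is not None and support > 85

    def test_invalid_reps_rejected(self):
        aln = ProteinAlignment(["A", "B", "C"], ["AA", "AA", "AT"])
        with pytest.raises(ValueError):
            bootstrap(aln, n_reps=0)


class TestParsimony:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_invariant_columns_score_zero(self):
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1);")
        aln = ProteinAlignment(["A", "B", "C", "D"], ["MK"] * 4)
        assert parsimony_score(tree, aln) == 0

    def test_clean_split_costs_one(self):
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1);")
        aln = ProteinAlignment(["A", "B", "C", "D"], ["A", "A", "T", "T"])
        assert parsimony_score(tree, aln) == 1

    def test_leaf_mismatch_rejected(self):
        tree = self._tree("((A:1,B:1):1,C:1);")
        aln = ProteinAlignment(["A", "B"], ["MK", "MK"])
        with pytest.raises(ValueError):
            parsimony_score(tree, aln)

    def test_matches_exhaustive_minimisation(self):
        """Fitch count equals brute-force assignment minimisation on random
        6-leaf trees and random gapped columns."""
        rng = np.random.default_rng(10)
        newicks = [
            "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);",
            "((((A:1,B:1):1,C:1):1,D:1):1,(E:1,F:1):1);",
        ]
        ids = list("ABCDEF")
        for nwk in newicks:
            for _ in range(10):
                col = rng.choice(list("ACT-"), size=6)
                if all(c == "-" for c in col):
                    col[0] = "A"
                aln = ProteinAlignment(ids, [str(c) for c in col])
                tree = self._tree(nwk)
                observed = {c for c in col if c != "-"}
                leaf_states = {i: c for i, c in zip(ids, col) if c != "-"}
                expected = (0 if len(observed) <= 1 else
                            fitch_bruteforce(tree, leaf_states, observed))
                assert parsimony_score(tree, aln) == expected


class TestAssignGroups:
    def test_sister_to_reference_with_high_support(self):
        tree = dendropy.Tree.get(
            data="((gene:0.1,refA:0.1)100:0.3,(refB:0.1,other:0.4)100:0.3);",
            schema="newick")
        out = assign_groups(tree, {"refA": "A", "refB": "B"})
        assert out["gene"] == "A"
        assert out["other"] == "B"

    def test_leaf_outside_reference_clades_unassigned(self):
        tree = dendropy.Tree.get(
            data="((g1:0.1,refA:0.1)100:0.2,(refB:0.1,g2:0.1)40:0.2,far:0.9);",
            schema="newick")
        out = assign_groups(tree, {"refA": "A", "refB": "B"})
        assert out["far"] == "unassigned"
        assert out["g2"] == "unassigned"   # clade support below threshold

    def test_missing_reference_leaf_is_error(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        with pytest.raises(KeyError):
            assign_groups(tree, {"ghost": "A"})

    def test_simulated_groups_recovered(self, deep_clade_sim):
        """Leaves labelled by their generating clade are all recovered when
        the clades are well supported."""
        sim = deep_clade_sim
        aln = sim.truth.true_alignment
        tree = bootstrap(aln, n_reps=100, seed=5)
        refs = {"A1": "A", "B1": "B"}
        out = assign_groups(tree, refs)
        for leaf, grp in sim.truth.group_map.items():
            want = "A" if leaf.startswith("A") else "B"
            assert out[leaf] == want
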