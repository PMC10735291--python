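"""Alignment, Jukes-Cantor correction, neighbor-joining and clade tests."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    best_alignment_score,
    ls_best_splits,
    random_additive_matrix,
)
from malrkit.phylo import (
    AlignParams,
    clade_check,
    distance_matrix,
    global_align_free_end_gaps,
    jc_distance,
    jc_from_p,
    neighbor_joining,
    tree_splits,
)


class TestGlobalAlignFreeEndGaps:
    def test_identical_sequences_all_match(self):
        aln = global_align_free_end_gaps("ACGT", "ACGT")
        assert aln.columns == "MMMM"
        assert aln.p_distance == 0.0

    def test_contained_sequence_gets_free_end_gaps(self):
        aln = global_align_free_end_gaps("ACGT", "CG")
        assert aln.columns.count("M") == 2
        assert set(aln.columns) <= {"M", "E"}
        assert aln.score == 2.0

    def test_score_invariant_under_argument_swap(self):
        a, b = "ACGTTGCA", "ACTTGGA"
        assert (global_align_free_end_gaps(a, b).score
                == global_align_free_end_gaps(b, a).score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align_free_end_gaps("", "ACGT")

    def test_transition_transversion_classification(self):
        # interior A->G transition and G->T transversion, anchored by
        # matching ends so the free-end aligner cannot trim them away
        aln = global_align_free_end_gaps("CCATGCC", "CCGTTCC")
        assert aln.columns == "MMSMVMM"

    def test_score_matches_exhaustive_enumeration_on_short_seqs(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(12):
            a = "".join(rng.choice(bases, rng.integers(1, 7)))
            b = "".join(rng.choice(bases, rng.integers(1, 7)))
            got = global_align_free_end_gaps(a, b).score
            want = best_alignment_score(a, b)
            assert got == pytest.approx(want), (a, b)

    def test_transition_weighting_changes_score(self):
        params = AlignParams(transition=-0.5)
        plain = global_align_free_end_gaps("CCAACC", "CCGGCC")
        weighted = global_align_free_end_gaps("CCAACC", "CCGGCC", params)
        assert plain.score == 2.0
        assert weighted.score == 3.0


class TestJukesCantor:
    @pytest.mark.parametrize("p", [0.0, 0.1, 0.3])
    def test_closed_form(self, p):
        want = math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
        assert abs(jc_from_p(p) - want) <= 1e-12

    def test_distance_from_alignment_matches_closed_form(self):
        # 100 internal columns, 30 mismatches placed mid-sequence, matching
        # ends so the free-end-gap aligner keeps every column
        rng = np.random.default_rng(3)
        a = list("ACGT" * 25)
        b = a.copy()
        idx = rng.choice(np.arange(10, 90), size=30, replace=False)
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in idx:
            b[i] = rot[b[i]]
        d = jc_distance(global_align_free_end_gaps("".join(a), "".join(b)))
        assert d.p == pytest.approx(0.3)
        assert abs(d.distance - jc_from_p(0.3)) <= 1e-12

    def test_saturation_flagged_at_three_quarters(self):
        a = "A" * 40 + "CCGG" + "A" * 40
        b = "A" * 40 + "GGCC" + "A" * 40
        aln = global_align_free_end_gaps(a, b)
        assert not jc_distance(aln).saturated
        assert jc_from_p(0.75) == math.inf

    def test_monotone_in_p(self):
        ps = np.linspace(0, 0.74, 50)
        ds = [jc_from_p(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        dm = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]],
                          index=list("ABC"), columns=list("ABC"))
        nwk = neighbor_joining(dm)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances generated from ((A:1,B:2):1,C:3,D:4)
        dm = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0.0]],
            index=list("ABCD"), columns=list("ABCD"))
        nwk = neighbor_joining(dm)
        assert tree_splits(nwk) == {frozenset({"A", "B"})}
        assert "A:1" in nwk and "B:2" in nwk

    def test_recovers_random_additive_topologies_vs_ls_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            D, true_splits = random_additive_matrix(n, rng)
            names = [chr(65 + i) for i in range(n)]
            dm = pd.DataFrame(D, index=names, columns=names)
            nj_splits = tree_splits(neighbor_joining(dm))
            want = {frozenset(names[i] for i in s) for s in true_splits}
            oracle = {frozenset(names[i] for i in s)
                      for s in ls_best_splits(D)}
            assert nj_splits == want == oracle

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(8)
        D, _ = random_additive_matrix(6, rng)
        names = list("ABCDEF")
        dm = pd.DataFrame(D, index=names, columns=names)
        perm = ["D", "A", "F", "B", "C", "E"]
        assert (tree_splits(neighbor_joining(dm))
                == tree_splits(neighbor_joining(dm.loc[perm, perm])))

    def test_saturated_entries_rejected_by_default(self):
        dm = pd.DataFrame([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0.0]],
                          index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(dm)
        assert neighbor_joining(dm, allow_saturated=True)

    def test_fewer_than_three_taxa_rejected(self):
        dm = pd.DataFrame([[0, 1], [1, 0.0]], index=list("AB"),
                          columns=list("AB"))
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(dm)

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Independent cross-check against scikit-bio's NJ."""
        import skbio

        rng = np.random.default_rng(23)
        D, _ = random_additive_matrix(7, rng)
        names = list("ABCDEFG")
        nwk = neighbor_joining(pd.DataFrame(D, index=names, columns=names))
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        sk_splits = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                comp = frozenset(names) - side
                sk_splits.add(min(side, comp,
                                  key=lambda s: (len(s), sorted(s))))
        assert tree_splits(nwk) == sk_splits


class TestDistanceMatrixAndClades:
    def test_matrix_symmetric_zero_diagonal(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTTCGTAC", "c": "TTGTACGAAC"}
        dm = distance_matrix(seqs)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)

    def test_single_tip_is_trivial_split(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        assert clade_check(nwk, ["A"]).is_split

    def test_all_taxa_trivial_split(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        rep = clade_check(nwk, ["A", "B", "C", "D"])
        assert rep.is_split and rep.sister is None

    def test_constructed_clade_found_with_sister(self):
        # families a1..a5 coalesce before joining b (then outgroups)
        nwk = "(((((a1:1,a2:1):1,(a3:1,(a4:1,a5:1):1):1):2,b:1):1,c:4):1,d:5,e:6);"
        rep = clade_check(nwk, ["a1", "a2", "a3", "a4", "a5"])
        assert rep.is_split
        assert rep.sister == ("b",)
        assert not clade_check(nwk, ["a1", "a2", "b"]).is_split

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            clade_check("(A:1,B:1,C:1);", ["A", "Z"])

    def test_succession_consensus_chain_is_ladder(self):
        """NJ on the simulator's consensus chain keeps derived families
        together: the two youngest members form a clade."""
        from malrkit.simulate import make_succession_consensuses

        cons = make_succession_consensuses(5)
        names = list(cons)
        nwk = neighbor_joining(distance_matrix(cons))
        assert clade_check(nwk, names[-2:]).is_split
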