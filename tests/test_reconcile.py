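"""Distances, neighbor joining, bootstrap, and duplication-loss
reconciliation."""

import math

import numpy as np
import pytest

from wrkyevo.bruteforce import bruteforce_reconcile_cost, enumerate_rooted_topologies
from wrkyevo.io import SequenceRecord
from wrkyevo.reconcile import (
    ReconWeights,
    bootstrap_support,
    distance_matrix,
    duplication_screen,
    lca_reconcile,
    nj_tree,
    protein_distance,
    rearrange_weak_edges,
    root_by_reconciliation,
)
from wrkyevo.trees import parse_newick, to_newick_string


class TestProteinDistance:
    def test_identical_is_zero(self):
        assert protein_distance("MKTW", "MKTW") == 0.0

    def test_poisson_correction_closed_form(self):
        a = "A" * 9 + "C"
        b = "A" * 9 + "D"  # p = 0.1
        assert protein_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_all_gapped_is_error(self):
        with pytest.raises(ValueError, match="no shared"):
            protein_distance("--AA", "AA--")

    def test_saturated_is_error(self):
        with pytest.raises(ValueError, match="saturated"):
            protein_distance("AAAA", "CCCC")


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovers_tree(self):
        # generating tree ((A:2,B:3):1,(C:4,D:5))
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = nj_tree(labels, D)
        newick = to_newick_string(tree)
        assert newick == "((A:2,B:3):1,C:4,D:5);"

    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(["x", "y", "z"], D)
        lengths = {c.label: c.branch_length for c in tree.children}
        assert lengths == {"x": 1.0, "y": 2.0, "z": 3.0}

    def test_identical_rows_zero_length_cherry(self):
        D = np.array(
            [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        tree = nj_tree(["a", "b", "c", "d"], D)
        cherry = next(n for n in tree.postorder()
                      if not n.is_leaf() and n is not tree)
        assert all(c.branch_length == 0.0 for c in cherry.children)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            nj_tree(["a", "b", "c"], np.full((3, 3), np.nan))


class TestBootstrap:
    def _alignment(self):
        # ten columns perfectly supporting the (A,B) clade
        rows = {
            "A": "AAAAAAAAAA" + "W" * 10,
            "B": "AAAAAAAAAA" + "W" * 10,
            "C": "CCCCCCCCCC" + "W" * 10,
            "D": "DDDDDCCCCC" + "W" * 10,
        }
        return [SequenceRecord(k, "", v) for k, v in rows.items()]

    def test_conserved_clade_gets_full_support(self):
        tree = bootstrap_support(self._alignment(), n_reps=50, seed=1)
        supports = [
            n.support for n in tree.postorder()
            if not n.is_leaf() and n is not tree and n.support is not None
        ]
        assert supports and max(supports) == 100.0

    def test_seed_reproducibility(self):
        t1 = bootstrap_support(self._alignment(), n_reps=25, seed=9)
        t2 = bootstrap_support(self._alignment(), n_reps=25, seed=9)
        assert to_newick_string(t1) == to_newick_string(t2)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._alignment(), n_reps=0, seed=1)


SP_AB = parse_newick("(A,B)R;")


class TestLcaReconcile:
    def test_two_copies_in_both_species(self):
        rec = lca_reconcile(parse_newick("((A__1,B__1),(A__2,B__2));"), SP_AB)
        assert (rec.n_dup, rec.n_loss, rec.cost) == (1, 0, 1.5)

    def test_duplication_with_loss(self):
        rec = lca_reconcile(parse_newick("(A__1,(A__2,B__1));"), SP_AB)
        assert (rec.n_dup, rec.n_loss, rec.cost) == (1, 1, 2.5)

    def test_congruent_tree_costs_nothing(self):
        rec = lca_reconcile(parse_newick("(A__1,B__1);"), SP_AB)
        assert (rec.n_dup, rec.n_loss, rec.cost) == (0, 0, 0.0)

    def test_identity_weights_count_events(self):
        rec = lca_reconcile(
            parse_newick("(A__1,(A__2,B__1));"), SP_AB,
            weights=ReconWeights(c_dup=1.0, c_loss=1.0),
        )
        assert rec.cost == rec.n_dup + rec.n_loss

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            lca_reconcile(parse_newick("(A__1,Z__1);"), SP_AB)

    @pytest.mark.parametrize("seed", range(3))
    def test_cost_matches_bruteforce_on_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        sp = parse_newick("((A,B)N1,(C,D)N2)R;")
        species = sp.leaf_labels()
        shapes = enumerate_rooted_topologies([f"L{i}" for i in range(5)])
        for _ in range(10):
            gt = shapes[rng.integers(len(shapes))].copy()
            for k, leaf in enumerate(gt.leaves()):
                leaf.label = f"{species[rng.integers(4)]}__g{k}"
            rec = lca_reconcile(gt, sp)
            assert rec.cost == pytest.approx(bruteforce_reconcile_cost(gt, sp))


class TestRootingAndRearrangement:
    def test_rooting_minimizes_cost(self):
        sp = parse_newick("((A,B)N1,C)R;")
        gt = parse_newick("((A__1:1,C__1:1):1,B__1:2);")
        rooted, rec = root_by_reconciliation(gt, sp)
        assert rec.cost == 0.0

    def test_all_strong_supports_identity(self):
        sp = parse_newick("((A,B)N1,(C,D)N2)R;")
        gt = parse_newick("(((A__1:1,C__1:1)80:1,B__1:1)90:1,D__1:1);")
        out, c0, c1 = rearrange_weak_edges(gt, sp)
        assert to_newick_string(out) == to_newick_string(gt) and c0 == c1

    def test_weak_edge_nni_reduces_cost(self):
        sp = parse_newick("((A,B)N1,(C,D)N2)R;")
        gt = parse_newick("(((A__1:1,C__1:1)30:1,B__1:1)90:1,D__1:1);")
        out, c0, c1 = rearrange_weak_edges(gt, sp)
        assert c1 < c0
        # the chosen NNI is the best of the evaluated alternatives
        sides = {frozenset(c.leaf_labels()) for c in out.postorder()
                 if not c.is_leaf()}
        assert frozenset({"A__1", "B__1"}) in sides

    def test_rearrangement_never_increases_cost(self):
        sp = parse_newick("((A,B)N1,(C,D)N2)R;")
        gt = parse_newick("(((A__1:1,D__1:1)10:1,(B__1:1,C__1:1)20:1)90:1);")
        _, c0, c1 = rearrange_weak_edges(gt, sp)
        assert c1 <= c0


class TestDuplicationScreen:
    def test_rows_reference_existing_branches(self):
        sp = parse_newick("((A,B)N1,C)R;")
        rec = lca_reconcile(parse_newick("((A__1,B__1),(A__2,B__2));"), sp)
        rows = duplication_screen({"fam": rec})
        assert len(rows) == 1
        assert rows[0]["species_branch"] in {n.label for n in sp.postorder()}
        assert len(rows[0]["descendant_branches"]) == 2

    def test_no_duplications_empty(self):
        rec = lca_reconcile(parse_newick("(A__1,B__1);"), SP_AB)
        assert duplication_screen({"fam": rec}) == []
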