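"""Domain affinity, fusion detection, and parsimony event inference."""

import numpy as np
import pytest

from wrkyevo.arch_events import (
    ArchEventCall,
    ArchState,
    build_reference_sets,
    call_architecture_events,
    detect_fusion,
    domain_affinity,
)
from wrkyevo.templates import DOMAIN_FILLER_AA
from wrkyevo.trees import parse_newick

SP = parse_newick(
    "((A:1,B:1)N1:1,((C:1,D:1)N2:0.5,E:1.5)N3:0.5)R;"
)


def _domain(rng, length=45):
    return "WRKYGQK" + "".join(
        DOMAIN_FILLER_AA[i] for i in rng.integers(len(DOMAIN_FILLER_AA),
                                                  size=length - 7)
    )


@pytest.fixture(scope="module")
def refsets():
    rng = np.random.default_rng(0)
    g1, g2, g3 = _domain(rng), _domain(rng), _domain(rng)
    refs = {"f1.only": [g1], "f2.only": [g2], "f3.only": [g3]}
    return refs, (g1, g2, g3)


class TestAffinity:
    def test_exact_member_has_positive_margin(self, refsets):
        refs, (g1, _g2, _g3) = refsets
        label, margin = domain_affinity(g1, refs)
        assert label == "f1.only" and margin > 0

    def test_equidistant_query_is_ambiguous(self, refsets):
        refs, _ = refsets
        # a query made only of the shared heptapeptide scores equally
        label, _margin = domain_affinity("WRKYGQK", refs)
        assert label == "ambiguous"

    def test_empty_inputs_rejected(self, refsets):
        refs, _ = refsets
        with pytest.raises(ValueError):
            domain_affinity("", refs)
        with pytest.raises(ValueError):
            domain_affinity("WRKYGQK", {})


class TestDetectFusion:
    def test_two_distinct_donors_called(self):
        state = ArchState("A__f1n1", "A",
                          [("C2HC", "f1.only"), ("C2HC", "f2.only")])
        call = detect_fusion(state, {})
        assert call is not None
        assert (call.donor_N, call.donor_C) == ("f1", "f2")

    def test_same_group_both_domains_is_none(self):
        state = ArchState("A__f1n1", "A",
                          [("C2H2", "f1.N"), ("C2H2", "f1.C")])
        assert detect_fusion(state, {}) is None

    def test_ambiguous_affinity_is_conservative(self):
        state = ArchState("A__f1n1", "A",
                          [("C2HC", "f1.only"), ("C2HC", "ambiguous")])
        assert detect_fusion(state, {}) is None


class TestCallEvents:
    def test_identical_architectures_no_events(self):
        states = {
            sp: ArchState(f"{sp}__g1", sp, [("C2H2", "f1.N"), ("C2H2", "f1.C")])
            for sp in "ABCDE"
        }
        assert call_architecture_events(states, SP, group="f1") == []

    def test_loss_on_internal_branch_located(self):
        two = [("C2H2", "f1.N"), ("C2H2", "f1.C")]
        one = [("C2H2", "f1.N")]
        states = {
            "A": ArchState("A__g", "A", two),
            "B": ArchState("B__g", "B", two),
            "C": ArchState("C__g", "C", one),
            "D": ArchState("D__g", "D", one),
            "E": ArchState("E__g", "E", two),
        }
        calls = call_architecture_events(states, SP, group="f1")
        confident = [c for c in calls if not c.ambiguous]
        assert [(c.kind, c.branches) for c in confident] == [
            ("domain_loss_C", ["N2"])
        ]
        # branch age interval is the edge's bounds
        assert confident[0].age_interval == (1.0, 1.5)

    def test_single_species_loss_then_duplication(self):
        """Both events land on the same terminal branch (the single-species
        loss-plus-tandem-duplication case)."""
        two = [("C2H2", "f1.N"), ("C2H2", "f1.C")]
        derived = [("C2H2", "f1.N"), ("C2H2", "f1.N")]
        states = {sp: ArchState(f"{sp}__g", sp, two) for sp in "ABCE"}
        states["D"] = ArchState("D__g", "D", derived)
        calls = call_architecture_events(states, SP, group="f1")
        confident = sorted(
            (c.kind, tuple(c.branches)) for c in calls if not c.ambiguous
        )
        assert confident == [
            ("domain_loss_C", ("D",)),
            ("domain_tandem_dup", ("D",)),
        ]

    def test_species_input_order_irrelevant(self):
        two = [("C2H2", "f1.N"), ("C2H2", "f1.C")]
        one = [("C2H2", "f1.N")]
        items = [
            ("A", two), ("B", two), ("C", one), ("D", one), ("E", two),
        ]
        a = call_architecture_events(
            {sp: ArchState(f"{sp}__g", sp, st) for sp, st in items}, SP, "f1"
        )
        b = call_architecture_events(
            {sp: ArchState(f"{sp}__g", sp, st)
             for sp, st in reversed(items)}, SP, "f1"
        )
        assert [(c.kind, c.branches) for c in a] == [
            (c.kind, c.branches) for c in b
        ]

    def test_unknown_species_rejected(self):
        states = {"Z": ArchState("Z__g", "Z", [("C2H2", "f1.N")])}
        with pytest.raises(ValueError):
            call_architecture_events(states, SP)


class TestReferenceSets:
    def test_fusion_borrowed_domain_pruned(self):
        rng = np.random.default_rng(1)
        own, partner = _domain(rng), _domain(rng)
        domains_by_gene = {
            # partner family: plain single-domain group in two species
            "A__p1": [("only", "C2HC", partner)],
            "B__p2": [("only", "C2HC", partner)],
            # fused family: single-domain in A, fused (own + partner) in B
            "A__f1": [("only", "C2HC", own)],
            "B__f1": [("N", "C2HC", own), ("C", "C2HC", partner)],
        }
        family_of = {"A__p1": "p", "B__p2": "p", "A__f1": "f", "B__f1": "f"}
        refs, meta = build_reference_sets(domains_by_gene, family_of)
        fams = {label.split(".")[0] for label in refs}
        assert fams == {"p", "f"}
        # the borrowed partner copy must not create a second p-like label
        p_like = [l for l in refs if refs[l][0] == partner]
        assert len(p_like) == 1

    def test_incomplete_motifs_excluded(self):
        domains_by_gene = {"A__g": [("only", "none", "WRKYGQK")]}
        refs, _ = build_reference_sets(domains_by_gene, {"A__g": "f"})
        assert refs == {}
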