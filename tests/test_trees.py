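"""Newick parsing/writing and rooted-tree utilities."""

import pytest

from wrkyevo.trees import NewickError, parse_newick, to_newick_string


class TestParse:
    def test_minimal_two_leaf_tree(self):
        t = parse_newick("(A:1,B:2);")
        assert t.leaf_labels() == ["A", "B"]
        assert [c.branch_length for c in t.children] == [1.0, 2.0]

    def test_internal_numeric_label_is_support(self):
        t = parse_newick("((A,B)95,C);")
        inner = t.children[0]
        assert inner.support == 95.0 and inner.label == ""

    def test_internal_name_kept_when_not_in_support_range(self):
        t = parse_newick("((A,B)N1,C)R;")
        assert t.children[0].label == "N1"
        assert t.label == "R"

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "(A,B)", "", "(A,B));", "(A:x,B:1);", "(A,A);"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    @pytest.mark.parametrize(
        "newick",
        [
            "(A:1,B:2);",
            "((A:0.5,B:0.25)90:1.5,(C:1,D:1)75:0.5);",
            "((A,B)N1,(C,D)N2)R;",
            "(((a:0.1,b:0.2):0.05,c:0.3)88:0.01,d:1);",
        ],
    )
    def test_round_trip_preserves_content(self, newick):
        once = to_newick_string(parse_newick(newick))
        assert to_newick_string(parse_newick(once)) == once
        # topology/labels survive a second trip exactly
        assert parse_newick(once).leaf_labels() == parse_newick(newick).leaf_labels()

    def test_round_trip_matches_dendropy(self):
        import dendropy

        newick = "((A:0.5,B:0.25)90:1.5,(C:1,D:1)75:0.5);"
        mine = parse_newick(newick)
        dp = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(mine.leaf_labels()) == sorted(
            l.taxon.label for l in dp.leaf_node_iter()
        )
        assert mine.total_branch_length() == pytest.approx(dp.length())


class TestUtilities:
    def test_node_ages_ultrametric(self):
        t = parse_newick("((A:1,B:1)N1:2,C:3)R;")
        ages = t.node_ages()
        by_label = {n.label: ages[id(n)] for n in t.postorder()}
        assert by_label["R"] == pytest.approx(3.0)
        assert by_label["N1"] == pytest.approx(1.0)
        assert by_label["A"] == pytest.approx(0.0)

    def test_lca_queries(self):
        t = parse_newick("((A,B)N1,(C,D)N2)R;")
        table = t.lca_table()
        node = {n.label: n for n in t.postorder()}
        assert table.lca(node["A"], node["B"]) is node["N1"]
        assert table.lca(node["A"], node["D"]) is node["R"]
        assert table.is_ancestor_or_self(node["R"], node["C"])
        assert not table.is_ancestor_or_self(node["N1"], node["C"])
        assert table.edge_distance(node["R"], node["A"]) == 2
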