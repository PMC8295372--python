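"""Group classification rules and isoform selection."""

import pytest
from hypothesis import given, settings, strategies as st

from wrkyevo.classify import (
    GeneRecord,
    NotWrkyError,
    classification_table,
    classify_group,
    select_isoform,
)
from wrkyevo.scan import DomainCall


def call(start, zf_type, signature, hepta="WRKYGQK"):
    zf = 0 if zf_type == "none" else start + 20
    return DomainCall(
        protein_id="p", hepta_start=start, hepta_variant=hepta,
        zf_type=zf_type, signature=signature, zf_start=zf,
        zf_end=zf + 25 if zf else 0, score=40.0,
    )


CASES = [
    ([("C2H2", "CX4C"), ("C2H2", "CX4C")], "Ia", []),
    ([("C2HC", "CX5C"), ("C2HC", "CX5C")], "Ib", []),
    ([("C2H2", "IIa")], "IIa", []),
    ([("C2H2", "IIb")], "IIb", []),
    ([("C2H2", "CX4C")], "IIc", []),
    ([("C2H2", "IId")], "IId", []),
    ([("C2H2", "IIe")], "IIe", []),
    ([("C2HC", "CX5C")], "III", []),
    ([("none", "none")], "IV", []),
    # mixed finger types: labeled by the C-terminal (DNA-binding) domain
    ([("C2H2", "CX4C"), ("C2HC", "CX5C")], "Ib", ["mixed_zf"]),
    ([("C2HC", "CX5C"), ("C2H2", "CX4C")], "Ia", ["mixed_zf"]),
    # triple-domain: terminal pair rule with a flag
    (
        [("C2H2", "CX4C"), ("C2H2", "CX4C"), ("C2H2", "CX4C")],
        "Ia",
        ["multi_domain"],
    ),
]


class TestClassifyGroup:
    @pytest.mark.parametrize("doms,expected,flags", CASES)
    def test_rules(self, doms, expected, flags):
        calls = [call(10 + 60 * i, zf, sig) for i, (zf, sig) in enumerate(doms)]
        label, got_flags = classify_group(calls)
        assert label == expected
        assert got_flags == flags

    def test_no_calls_is_error(self):
        with pytest.raises(NotWrkyError):
            classify_group([])

    @given(st.permutations([0, 1, 2]))
    @settings(max_examples=12, deadline=None)
    def test_call_order_never_changes_label(self, perm):
        doms = [("C2H2", "CX4C"), ("C2HC", "CX5C"), ("none", "none")]
        calls = [call(10 + 60 * i, zf, sig) for i, (zf, sig) in enumerate(doms)]
        assert classify_group([calls[i] for i in perm]) == classify_group(calls)


class TestSelectIsoform:
    def test_longest_wins_when_both_complete(self):
        calls = {"a": [call(5, "C2H2", "CX4C")], "b": [call(5, "C2H2", "CX4C")]}
        assert select_isoform(calls, {"a": 300, "b": 250}) == "a"

    def test_shorter_complete_beats_longer_incomplete(self):
        calls = {"long": [call(5, "none", "none")], "short": [call(5, "C2H2", "CX4C")]}
        assert select_isoform(calls, {"long": 400, "short": 250}) == "short"

    def test_single_isoform(self):
        assert select_isoform({"only": []}, {"only": 100}) == "only"

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_isoform({}, {})


class TestClassificationTable:
    def _genes(self):
        out = []
        for i in range(6):
            out.append(
                GeneRecord(
                    gene_id=f"sp1__g{i}", species="sp1", group="III",
                    chromosome="chr1",
                )
            )
        out.append(GeneRecord(gene_id="sp2__g0", species="sp2", group="IIc",
                              chromosome="chr2"))
        return out

    def test_row_sums_and_density(self):
        df = classification_table(self._genes(), {"sp1": 300.0, "sp2": 400.0})
        row = df[df.species == "sp1"].iloc[0]
        assert row["total"] == 6 and row["III"] == 6
        assert row["wrky_per_mb"] == pytest.approx(0.02)
        assert df["total"].sum() == 7

    def test_missing_genome_size_omits_density(self):
        df = classification_table(self._genes(), {"sp1": 400.0})
        assert df[df.species == "sp2"]["wrky_per_mb"].isna().all()
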