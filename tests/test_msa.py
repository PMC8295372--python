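"""Progressive profile aligner."""

from wrkyevo.io import SequenceRecord
from wrkyevo.msa import progressive_align


def _recs(seqs):
    return [SequenceRecord(f"s{i}", "", s) for i, s in enumerate(seqs)]


def test_identical_sequences_align_without_gaps():
    out = progressive_align(_recs(["MKTWRKYGQK"] * 4))
    assert all(r.residues == "MKTWRKYGQK" for r in out)


def test_single_deletion_recovered():
    out = progressive_align(_recs(["MKTWAAAQK", "MKTWAAAQK", "MKTWAAQK"]))
    width = len(out[0].residues)
    assert all(len(r.residues) == width for r in out)
    assert out[2].residues.count("-") == 1
    assert out[2].residues.replace("-", "") == "MKTWAAQK"


def test_input_order_preserved():
    out = progressive_align(_recs(["ZZMKT"[1:], "MKT", "MKTAA"]))
    assert [r.id for r in out] == ["s0", "s1", "s2"]


def test_highly_similar_family_rows_equal_length():
    base = "MKTW" * 10
    variants = [base, base[:20] + "A" + base[21:], base[:5] + base[9:], base]
    out = progressive_align(_recs(variants))
    widths = {len(r.residues) for r in out}
    assert len(widths) == 1
    for rec, orig in zip(out, variants):
        assert rec.residues.replace("-", "") == orig
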