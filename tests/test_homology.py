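"""Alignment scoring, RBH orthology, and duplication-mode calls."""

import itertools

import pytest
from Bio.Align import substitution_matrices

from wrkyevo.homology import (
    GAP_EXTEND,
    GAP_OPEN,
    ParalogPair,
    classify_duplication,
    find_paralogs,
    normalize_positions,
    pairwise_align,
    rbh_orthologs,
    tip_fraction,
)

B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local(a: str, b: str) -> float:
    """Best local alignment score by enumerating all monotone pairings of
    subsequences (gap of length L costs GAP_OPEN + L*GAP_EXTEND)."""
    best = 0.0
    n, m = len(a), len(b)
    idx_a = [
        c for r in range(1, n + 1) for c in itertools.combinations(range(n), r)
    ]
    idx_b = [
        c for r in range(1, m + 1) for c in itertools.combinations(range(m), r)
    ]
    for ia in idx_a:
        for ib in idx_b:
            if len(ia) != len(ib):
                continue
            score = sum(B62[a[x]][b[y]] for x, y in zip(ia, ib))
            for seq in (ia, ib):
                pos = 0
                while pos < len(seq) - 1:
                    gap = seq[pos + 1] - seq[pos] - 1
                    if gap:
                        score -= GAP_OPEN + gap * GAP_EXTEND
                    pos += 1
            best = max(best, score)
    return best


class TestPairwiseAlign:
    def test_self_alignment(self):
        seq = "WRKYGQKMKT"
        hit = pairwise_align("a", seq, "b", seq)
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0
        assert hit.score == sum(B62[c][c] for c in seq)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("WRKYGQK", "WRKYGEK"),
            ("WRKYGQK", "GQKWRKY"),
            ("MKTWA", "MKWA"),
            ("ACDEFG", "ACEFG"),
        ],
    )
    def test_matches_exhaustive_enumeration(self, a, b):
        hit = pairwise_align("a", a, "b", b)
        assert hit.score == pytest.approx(brute_force_local(a, b))

    def test_dissimilar_low_score(self):
        hit = pairwise_align("a", "AAAAAAA", "b", "WWWWWWW")
        assert hit.score <= 0 or hit.identity == 0.0

    def test_illegal_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            pairwise_align("a", "MKB", "b", "MKT")


class TestRbh:
    def test_one_to_one_families(self):
        ref = {"r1": "WRKYGQK" * 6 + "AAAA", "r2": "MKTWVNPQ" * 6}
        prot = {"g1": "WRKYGQK" * 6 + "AATA", "g2": "MKTWVNPQ" * 5 + "MKTWVNPA"}
        mapping, unmapped = rbh_orthologs(prot, ref)
        assert mapping == {"g1": "r1", "g2": "r2"}
        assert unmapped == []

    def test_in_paralogs_one_copy_maps(self):
        ref = {"r1": "WRKYGQKMNPASTV" * 4}
        prot = {
            "g1": "WRKYGQKMNPASTV" * 4,
            "g2": "WRKYGQKMNPASTV" * 3 + "WRKYGQKMNPASTA",
        }
        mapping, unmapped = rbh_orthologs(prot, ref)
        assert mapping == {"g1": "r1"}  # exact copy wins; tie rule is id order
        assert unmapped == ["g2"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            rbh_orthologs({"g": "MKT"}, {})

    def test_reciprocal_definition_is_symmetric(self):
        ref = {"r1": "WRKYGQK" * 6, "r2": "MKTWVNPQ" * 6, "r3": "DDEEFFGGHH" * 5}
        prot = {"g1": "WRKYGEK" * 6, "g2": "MKTWVNPA" * 6, "g3": "DDEEFFGGHY" * 5}
        fwd, _ = rbh_orthologs(prot, ref)
        rev, _ = rbh_orthologs(ref, prot)
        assert fwd == {g: r for r, g in rev.items()}


class TestParalogs:
    def test_three_copies_three_pairs(self):
        fam = {"s__a": "f", "s__b": "f", "s__c": "f", "s__d": "other"}
        pairs = find_paralogs({"s": dict.fromkeys(fam)}, fam)
        assert len(pairs) == 3
        assert all(p.species == "s" for p in pairs)

    def test_low_coverage_pair_excluded(self):
        prot = {"s__a": "WRKYGQKMNPASTV" * 8, "s__b": "WRKYGQKMNP"}
        fam = {"s__a": "f", "s__b": "f"}
        pairs = find_paralogs({"s": dict.fromkeys(prot)}, fam, prot)
        assert pairs == []  # coverage of the long query is far below 40%

    def test_no_duplicates(self):
        assert find_paralogs({"s": {"s__a": None}}, {"s__a": "f"}) == []


class TestDuplicationMode:
    COORDS = {
        "a": ("chr9", 100_000, 102_000),
        "b": ("chr9", 119_000, 121_000),  # 19 kb apart, adjacent
        "c": ("chr2", 100_000, 102_000),
        "d": ("chr9", 10_100_000, 10_102_000),
    }
    ORDER = {"chr9": ["a", "b", "d"], "chr2": ["c"]}

    def _pair(self, x, y):
        return ParalogPair(species="s", gene_a=x, gene_b=y)

    def test_nearby_same_chromosome_is_tandem(self):
        assert classify_duplication(self._pair("a", "b"), self.COORDS, self.ORDER) == "tandem"

    def test_different_chromosome_is_segmental(self):
        assert classify_duplication(self._pair("a", "c"), self.COORDS, self.ORDER) == "segmental"

    def test_distant_same_chromosome_is_segmental(self):
        coords = dict(self.COORDS)
        order = {"chr9": ["a"] + [f"x{i}" for i in range(10)] + ["d"]}
        assert classify_duplication(self._pair("a", "d"), coords, order) == "segmental"

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError):
            classify_duplication(self._pair("a", "zz"), self.COORDS, self.ORDER)


class TestPositions:
    def test_midpoint_scaling(self):
        pos = normalize_positions(
            {"g": ("chr1", 4_999_001, 5_001_000 - 1)}, {"chr1": 20_000_000}
        )
        assert pos["g"] == pytest.approx(0.25, abs=1e-4)

    def test_bounds(self):
        pos = normalize_positions(
            {"lo": ("c", 1, 1), "hi": ("c", 100, 100)}, {"c": 100}
        )
        assert 0.0 <= pos["lo"] < 0.05 and pos["hi"] == pytest.approx(1.0)

    def test_midpoint_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_positions({"g": ("c", 90, 200)}, {"c": 100})

    def test_tip_fraction(self):
        coords = {"a": ("chr11", 1, 2), "b": ("chr12", 1, 2), "c": ("chr1", 1, 2)}
        positions = {"a": 0.05, "b": 0.02, "c": 0.5}
        pairs = [ParalogPair(species="s", gene_a="a", gene_b="b"),
                 ParalogPair(species="s", gene_a="a", gene_b="c")]
        assert tip_fraction(pairs, positions, coords) == pytest.approx(0.75)
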