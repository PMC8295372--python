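"""Heptapeptide/zinc-finger scanning and the calibrated profile screen."""

import numpy as np
import pytest

from wrkyevo import templates as T
from wrkyevo.scan import (
    CALIBRATION_SEED,
    ScanProfile,
    _decoy_pool,
    build_reference_alignment,
    calibrate_threshold,
    call_domains,
    motif_census,
    scan_heptapeptide,
    scan_zinc_finger,
)
from wrkyevo.io import read_fasta
import importlib.resources


class TestHeptapeptide:
    def test_single_exact_match(self):
        assert scan_heptapeptide("AAWRKYGQKAA") == [(3, "WRKYGQK")]

    def test_two_variants_reported_exactly(self):
        hits = scan_heptapeptide("WRKYGEK" + "A" * 4 + "WRKYGKK")
        assert [h[1] for h in hits] == ["WRKYGEK", "WRKYGKK"]

    def test_degenerate_cores_report_full_7mer(self):
        assert scan_heptapeptide("XWKKYABC") == [(2, "WKKYABC")]
        assert scan_heptapeptide("WRMCQQQ")[0][1] == "WRMCQQQ"

    def test_no_motif(self):
        assert scan_heptapeptide("MKTAAA") == []


class TestZincFinger:
    def test_iib_literal_with_hxh_pair(self):
        protein = "A" * 9 + "C" + "ABCDE" + "C" + "PVRKQVQ" + "A" * 14 + "HAH"
        zf_type, label, span = scan_zinc_finger(protein, 1)
        assert (zf_type, label) == ("C2H2", "IIb")
        assert span[0] == 10 and protein[span[1] - 1] == "H"

    def test_cx4c_with_hxc_pair_is_c2hc(self):
        protein = "A" * 5 + "C" + "AAAA" + "C" + "A" * 21 + "HAC"
        zf_type, label, _span = scan_zinc_finger(protein, 1)
        assert (zf_type, label) == ("C2HC", "CX4C")

    def test_no_cysteine_pair_downstream(self):
        assert scan_zinc_finger("A" * 80, 1) is None

    def test_spacer_outside_window_not_found(self):
        # H pair only 5 residues after the core: below the 18-residue floor
        protein = "C" + "AAAA" + "C" + "AAAAA" + "HAH" + "A" * 40
        assert scan_zinc_finger(protein, 1) is None


def _template_protein(rng, group):
    parts = ["".join(T.FREE_AA[j] for j in rng.integers(len(T.FREE_AA), size=25))]
    for tpl in T.GROUP_TEMPLATES[group]:
        parts.append(tpl.realize(rng)[0])
        parts.append("".join(T.FREE_AA[j] for j in rng.integers(len(T.FREE_AA), size=15)))
    return "".join(parts)


class TestCallDomains:
    @pytest.mark.parametrize("group", sorted(T.GROUP_TEMPLATES))
    def test_template_proteins_recover_domain_count(self, group, profile):
        rng = np.random.default_rng(5)
        protein = _template_protein(rng, group)
        calls = call_domains("p", protein, profile)
        assert len(calls) == len(T.GROUP_TEMPLATES[group])
        if len(calls) == 1:
            assert calls[0].terminal == "only"
        else:
            assert [c.terminal for c in calls] == ["N", "C"]

    def test_hepta_without_zinc_finger_emitted_as_partial(self, profile):
        calls = call_domains("p", "A" * 10 + "WRKYGQK" + "A" * 10, profile)
        assert len(calls) == 1 and calls[0].zf_type == "none"

    def test_shuffled_decoys_rarely_called(self, profile):
        """>= 99.9% of composition-matched shuffles yield zero calls."""
        rng = np.random.default_rng(CALIBRATION_SEED)
        decoys = _decoy_pool(rng, 10_000)
        n_called = sum(bool(call_domains("d", d, profile)) for d in decoys)
        assert n_called / len(decoys) <= 1e-3

    def test_calibration_reproducible_from_seed(self):
        records = build_reference_alignment()
        a = ScanProfile(records)
        b = ScanProfile(records)
        t1 = calibrate_threshold(a, seed=CALIBRATION_SEED, n=2000)
        t2 = calibrate_threshold(b, seed=CALIBRATION_SEED, n=2000)
        assert t1 == t2

    def test_packaged_reference_alignment_regenerates(self):
        packaged = importlib.resources.files("wrkyevo.data") / "reference_domains.afa"
        with importlib.resources.as_file(packaged) as p:
            on_disk = read_fasta(p)
        fresh = build_reference_alignment()
        assert [(r.id, r.residues) for r in on_disk] == [
            (r.id, r.residues) for r in fresh
        ]


class TestCensus:
    def test_counts_and_conservation(self, profile):
        rng = np.random.default_rng(17)
        calls = {}
        for k in range(10):
            calls[f"p{k}"] = call_domains(f"p{k}", _template_protein(rng, "IIc"), profile)
        for k in range(3):
            g = f"e{k}"
            tpl = T.DomainTemplate("IIc", hepta="WRKYGEK", zf_type="C2H2", core_len=4)
            calls[g] = call_domains(g, "A" * 20 + tpl.realize(rng)[0] + "A" * 10, profile)
        census = motif_census(calls)
        assert census == {"WRKYGEK": 3, "WRKYGQK": 10}
        assert sum(census.values()) == sum(len(v) for v in calls.values())

    def test_empty_set(self):
        assert motif_census({}) == {}

    def test_permutation_invariance(self, profile):
        rng = np.random.default_rng(3)
        calls = [
            c
            for k in range(6)
            for c in call_domains(f"p{k}", _template_protein(rng, "III"), profile)
        ]
        assert motif_census(calls) == motif_census(list(reversed(calls)))
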