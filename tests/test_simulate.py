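"""Synthetic-dataset simulator: birth-death process, architecture events,
sequence emission, annotation, and the truth log."""

import collections

import numpy as np
import pytest

from wrkyevo.selection.codon import translate_cds
from wrkyevo.simulate import (
    SimConfig,
    leaf_architecture,
    make_family,
    simulate_dataset,
    simulate_family,
    surviving_duplications,
)
from wrkyevo.trees import parse_newick


def _config(**kw):
    defaults = dict(n_families=5, seed=3)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBirthDeath:
    def test_null_rates_give_species_tree_congruence(self):
        cfg = _config(rate_dup=0.0, rate_loss=0.0)
        fam = make_family(cfg, 0)
        tree, events = simulate_family(cfg, fam)
        species = sorted(l.label.split("__")[0] for l in tree.leaves())
        assert species == sorted(cfg.tree().leaf_labels())
        kinds = {e.kind for e in events}
        assert kinds == {"speciation"}

    def test_same_seed_reproduces_tree_and_events(self):
        trees = []
        for _ in range(2):
            cfg = _config(rate_dup=0.05, rate_loss=0.02)
            fam = make_family(cfg, 1)
            tree, events = simulate_family(cfg, fam)
            trees.append(
                (
                    sorted(l.label for l in tree.leaves()),
                    [(e.kind, e.branch, e.time) for e in events],
                )
            )
        assert trees[0] == trees[1]

    def test_expected_leaf_count_matches_birth_process(self):
        """With no loss, E[leaves] = sum over species of exp(dup_rate *
        root-to-tip time); checked over 500 replicates within 3 SE."""
        sp = parse_newick("((A:2,B:2)N1:3,C:5)R;")
        rate = 0.08
        expected = 3 * np.exp(rate * 5.0)
        counts = []
        for seed in range(500):
            cfg = SimConfig(rate_dup=rate, rate_loss=0.0, seed=seed,
                            species_tree=sp.copy())
            fam = make_family(cfg, 0)
            tree, _ = simulate_family(cfg, fam)
            counts.append(len(tree.leaves()))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_extinct_family_flagged_not_error(self):
        cfg = _config(rate_dup=0.0, rate_loss=5.0)
        fam = make_family(cfg, 0)
        tree, events = simulate_family(cfg, fam)
        assert tree is None and fam.extinct
        assert any(e.kind == "gene_loss" for e in events)


class TestDataset:
    def test_architecture_constant_when_rates_zero(self, small_dataset):
        cfg = SimConfig(
            n_families=4, seed=5,
            rate_domain_loss=0.0, rate_domain_dup=0.0, rate_fusion=0.0,
        )
        res = simulate_dataset(cfg)
        for fid, fam in res.families.items():
            if fam.extinct:
                continue
            archs = {
                tuple((s.source_family, s.kind) for s in
                      leaf_architecture(fam, sp))
                for sp in {l.label.split("__")[0]
                           for l in fam.gene_tree.leaves()}
            }
            assert len(archs) == 1

    def test_translation_closed_loop(self, small_dataset):
        cds = {r.id: r.residues for r in small_dataset.cds}
        for rec in small_dataset.proteins:
            assert translate_cds(cds[rec.id]) == rec.residues

    def test_cds_length_divisible_by_three(self, small_dataset):
        assert all(len(r.residues) % 3 == 0 for r in small_dataset.cds)

    def test_tandem_pairs_within_window_segmental_apart(self, small_dataset):
        genes = small_dataset.truth["genes"]
        for pair in small_dataset.truth["paralog_pairs"]:
            a, b = genes[pair["gene_a"]], genes[pair["gene_b"]]
            if pair["mode"] == "tandem":
                assert a["chromosome"] == b["chromosome"]
                gap = max(a["start"], b["start"]) - min(a["end"], b["end"])
                assert gap <= 100_000
            else:
                far = a["chromosome"] != b["chromosome"] or (
                    max(a["start"], b["start"]) - min(a["end"], b["end"])
                    > 100_000
                )
                assert far

    def test_gene_intervals_non_overlapping(self, small_dataset):
        by_chrom_sp = collections.defaultdict(list)
        for g, info in small_dataset.truth["genes"].items():
            by_chrom_sp[(info["species"], info["chromosome"])].append(
                (info["start"], info["end"])
            )
        for intervals in by_chrom_sp.values():
            intervals.sort()
            for (s1, e1), (s2, _e2) in zip(intervals, intervals[1:]):
                assert e1 < s2

    def test_truth_motif_counts_match_architecture(self, small_dataset):
        counted = collections.Counter()
        for info in small_dataset.truth["genes"].values():
            for slot in info["architecture"]:
                counted[slot["hepta"]] += 1
        assert dict(counted) == small_dataset.truth["motif_expected"]

    def test_surviving_duplications_have_two_descendant_sets(self, small_dataset):
        for fam in small_dataset.families.values():
            for e in surviving_duplications(fam):
                assert len(e.gene_ids) >= 2


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, tmp_path):
        from wrkyevo.simulate import write_run

        for name in ("x", "y"):
            res = simulate_dataset(_config(n_families=6, seed=21))
            write_run(res, tmp_path / name)
        for fname in ("proteins.faa", "cds.fna", "annotation.gff3",
                      "truth.json", "config_echo.yml"):
            assert (tmp_path / "x" / fname).read_bytes() == (
                tmp_path / "y" / fname
            ).read_bytes()

    def test_validation_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            SimConfig(rate_dup=-1).validate()
        with pytest.raises(ValueError):
            SimConfig(p_tandem=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(omega_profile={"bad": (-1.0, 1.0)}).validate()
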