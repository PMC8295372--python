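"""Pipeline stages wiring the library modules together over a run directory.

Each stage reads the standard files written by earlier stages (FASTA,
GFF3, Newick, TSV) and writes tab-separated tables with a header line.
All floating-point output is formatted with %.6g so that identical
config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import arch_events as AE
from . import classify as CL
from . import homology as HO
from . import reconcile as RC
from .io import SequenceRecord, read_fasta, read_gff3, gene_features
from .msa import progressive_align
from .scan import DomainCall, ScanProfile, default_profile, motif_census, scan_proteome
from .selection import (
    CodonAlignment,
    fit_model,
    lrt,
    branch_test,
    classify_selection,
    occupancy_filter,
    site_posteriors,
    thread_codons,
)
from .simulate import SimConfig, simulate_dataset, write_run
from .trees import read_newick, write_newick

log = logging.getLogger("wrkyevo")

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


# ---------------------------------------------------------------------------


@_stage("simulate")
def stage_simulate(outdir: Path, config: SimConfig) -> None:
    result = simulate_dataset(config)
    write_run(result, outdir)
    log.info(
        "simulate: %d families, %d genes, %d events",
        config.n_families,
        len(result.truth["genes"]),
        len(result.truth["events"]),
    )


@_stage("scan")
def stage_scan(outdir: Path, profile: ScanProfile | None = None) -> None:
    records = read_fasta(outdir / "proteins.faa")
    profile = profile or default_profile()
    calls = scan_proteome(records, profile)
    rows = []
    for pid in sorted(calls):
        for c in calls[pid]:
            rows.append(
                {
                    "protein_id": c.protein_id,
                    "hepta_start": c.hepta_start,
                    "hepta_variant": c.hepta_variant,
                    "zf_type": c.zf_type,
                    "signature_label": c.signature,
                    "zf_start": c.zf_start,
                    "zf_end": c.zf_end,
                    "score": round(c.score, 3),
                    "terminal": c.terminal,
                }
            )
    _write(pd.DataFrame(rows), outdir / "domains.tsv")
    census = motif_census(calls)
    _write(
        pd.DataFrame(
            [{"hepta_variant": k, "count": v} for k, v in census.items()]
        ),
        outdir / "motif_census.tsv",
    )
    log.info("scan: %d proteins with calls, %d domains", len(calls), len(rows))


def _load_calls(outdir: Path) -> dict[str, list[DomainCall]]:
    df = pd.read_csv(outdir / "domains.tsv", sep="\t")
    out: dict[str, list[DomainCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append(
            DomainCall(
                protein_id=row.protein_id,
                hepta_start=int(row.hepta_start),
                hepta_variant="" if pd.isna(row.hepta_variant) else row.hepta_variant,
                zf_type=row.zf_type,
                signature=row.signature_label,
                zf_start=int(row.zf_start),
                zf_end=int(row.zf_end),
                score=float(row.score),
                terminal=row.terminal,
            )
        )
    return out


def _gene_isoform_map(outdir: Path):
    """gene id -> isoform protein records, from the GFF mRNA features."""
    feats = read_gff3(outdir / "annotation.gff3")
    proteins = {r.id: r for r in read_fasta(outdir / "proteins.faa")}
    genes: dict[str, dict] = {}
    for f in feats:
        if f.type == "gene":
            genes[f.id] = {
                "chromosome": f.seqid,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "isoforms": {},
            }
        elif f.type == "mRNA" and f.parent in genes:
            if f.id in proteins:
                genes[f.parent]["isoforms"][f.id] = proteins[f.id].residues
    return genes


@_stage("classify")
def stage_classify(outdir: Path) -> list[CL.GeneRecord]:
    calls = _load_calls(outdir)
    genes = _gene_isoform_map(outdir)
    records: list[CL.GeneRecord] = []
    rows = []
    for gid in sorted(genes):
        meta = genes[gid]
        gene = CL.GeneRecord(
            gene_id=gid,
            species=gid.split("__")[0],
            chromosome=meta["chromosome"],
            start=meta["start"],
            end=meta["end"],
            strand=meta["strand"],
            isoforms=meta["isoforms"],
            calls={iso: calls.get(iso, []) for iso in meta["isoforms"]},
        )
        if not any(gene.calls.values()):
            continue  # not a WRKY gene
        CL.classify_gene(gene)
        records.append(gene)
        rows.append(
            {
                "gene_id": gid,
                "species": gene.species,
                "chromosome": gene.chromosome,
                "start": gene.start,
                "end": gene.end,
                "group": gene.group,
                "representative_isoform": gene.representative_isoform,
                "flags": ";".join(gene.flags),
            }
        )
    _write(pd.DataFrame(rows), outdir / "classification.tsv")
    _write(CL.classification_table(records), outdir / "group_counts.tsv")
    _write(CL.chromosome_table(records), outdir / "chromosome_counts.tsv")
    log.info("classify: %d WRKY genes", len(records))
    return records


def _representative_proteomes(outdir: Path):
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t")
    proteins = {r.id: r.residues for r in read_fasta(outdir / "proteins.faa")}
    by_species: dict[str, dict[str, str]] = {}
    for row in cls.itertuples(index=False):
        by_species.setdefault(row.species, {})[row.gene_id] = proteins[
            row.representative_isoform
        ]
    return cls, by_species


@_stage("homology")
def stage_homology(outdir: Path, reference_species: str = "osaj") -> None:
    cls, by_species = _representative_proteomes(outdir)
    if reference_species not in by_species:
        reference_species = sorted(by_species)[0]
        log.warning("reference species missing; using %s", reference_species)
    reference = by_species[reference_species]
    ref_groups = HO.reference_self_groups(reference)
    ortho_rows, unassigned_rows = [], []
    family_of: dict[str, str] = {}
    for ref_gene, grp in ref_groups.items():
        family_of[ref_gene] = grp
    for species in sorted(by_species):
        if species == reference_species:
            continue
        proteome = by_species[species]
        mapping, unmapped = HO.rbh_orthologs(proteome, reference)
        for g in sorted(mapping):
            family_of[g] = ref_groups[mapping[g]]
            ortho_rows.append(
                {"gene_id": g, "species": species,
                 "reference_gene": mapping[g], "relation": "ortholog"}
            )
        for g in unmapped:
            co = HO.best_reference_hit(proteome[g], reference)
            if co is None:
                unassigned_rows.append({"gene_id": g, "species": species})
            else:
                family_of[g] = ref_groups[co]
                ortho_rows.append(
                    {"gene_id": g, "species": species,
                     "reference_gene": co, "relation": "co_ortholog"}
                )
    _write(pd.DataFrame(ortho_rows), outdir / "orthologs.tsv")
    _write(pd.DataFrame(unassigned_rows), outdir / "unassigned.tsv")

    coords = {
        row.gene_id: (row.chromosome, int(row.start), int(row.end))
        for row in cls.itertuples(index=False)
    }
    gene_order: dict[str, list[str]] = {}
    for g, (chrom, start, _end) in sorted(coords.items(), key=lambda kv: kv[1][1]):
        gene_order.setdefault(chrom, []).append(g)
    chrom_lengths = _chromosome_lengths(outdir)
    positions = HO.normalize_positions(coords, chrom_lengths)
    genes_by_species = {
        sp: dict.fromkeys(genes) for sp, genes in by_species.items()
    }
    proteins_flat = {g: s for d in by_species.values() for g, s in d.items()}
    pairs = HO.find_paralogs(genes_by_species, family_of, proteins_flat)
    pair_rows = []
    for p in pairs:
        p.mode = HO.classify_duplication(p, coords, gene_order)
        p.chrom_a, p.chrom_b = coords[p.gene_a][0], coords[p.gene_b][0]
        p.relative_pos_a = positions[p.gene_a]
        p.relative_pos_b = positions[p.gene_b]
        pair_rows.append(
            {
                "species": p.species, "gene_a": p.gene_a, "gene_b": p.gene_b,
                "family": family_of[p.gene_a], "mode": p.mode,
                "chrom_a": p.chrom_a, "chrom_b": p.chrom_b,
                "relative_pos_a": round(p.relative_pos_a, 4),
                "relative_pos_b": round(p.relative_pos_b, 4),
            }
        )
    _write(pd.DataFrame(pair_rows), outdir / "paralogs.tsv")
    _write(
        pd.DataFrame(
            [
                {"gene_id": g, "chromosome": coords[g][0],
                 "relative_pos": round(positions[g], 4)}
                for g in sorted(positions)
            ]
        ),
        outdir / "synteny_positions.tsv",
    )
    fam_rows = [
        {"gene_id": g, "family": family_of[g]} for g in sorted(family_of)
    ]
    _write(pd.DataFrame(fam_rows), outdir / "families.tsv")
    log.info("homology: %d orthologs, %d paralog pairs", len(ortho_rows), len(pairs))


def _chromosome_lengths(outdir: Path) -> dict[str, int]:
    import json

    truth = outdir / "truth.json"
    if truth.exists():
        with open(truth) as fh:
            return {
                k: int(v)
                for k, v in json.load(fh)["chromosome_lengths"].items()
            }
    feats = gene_features(read_gff3(outdir / "annotation.gff3"))
    out: dict[str, int] = {}
    for f in feats:
        out[f.seqid] = max(out.get(f.seqid, 0), f.end + 100_000)
    return out


def _family_members(outdir: Path, min_size: int = 3) -> dict[str, list[str]]:
    fam = pd.read_csv(outdir / "families.tsv", sep="\t")
    groups: dict[str, list[str]] = {}
    for row in fam.itertuples(index=False):
        groups.setdefault(row.family, []).append(row.gene_id)
    return {
        f: sorted(genes) for f, genes in sorted(groups.items())
        if len(genes) >= min_size
    }


@_stage("reconcile")
def stage_reconcile(
    outdir: Path, seed: int = 0, n_bootstrap: int = 100, max_families: int = 0
) -> None:
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t")
    rep_of = dict(zip(cls.gene_id, cls.representative_isoform))
    proteins = {r.id: r.residues for r in read_fasta(outdir / "proteins.faa")}
    species_tree = read_newick(outdir / "species_tree.nwk")
    groups = _family_members(outdir)
    if max_families:
        groups = dict(list(groups.items())[:max_families])
    recs: dict[str, RC.ReconciledTree] = {}
    rows = []
    tree_dir = outdir / "reconciled_trees"
    tree_dir.mkdir(exist_ok=True)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for k, (fid, genes) in enumerate(sorted(groups.items())):
        records = [SequenceRecord(g, "", proteins[rep_of[g]]) for g in genes]
        aligned = progressive_align(records)
        from .io import write_fasta

        write_fasta(aligned, aln_dir / f"{fid}.afa")
        tree = RC.bootstrap_support(aligned, n_bootstrap, seed=seed + 31 * k)
        rooted, _ = RC.root_by_reconciliation(tree, species_tree)
        rearranged, cost0, cost1 = RC.rearrange_weak_edges(rooted, species_tree)
        rec = RC.lca_reconcile(rearranged, species_tree)
        recs[fid] = rec
        rows.append(
            {
                "family": fid, "n_genes": len(genes), "n_dup": rec.n_dup,
                "n_loss": rec.n_loss, "cost": rec.cost,
                "cost_before_rearrangement": cost0,
                "cost_after_rearrangement": cost1,
            }
        )
        write_newick(rearranged, tree_dir / f"{fid}.nwk")
        with open(tree_dir / f"{fid}.events.nwk", "w") as fh:
            fh.write(_annotated_newick(rearranged, rec) + "\n")
    _write(pd.DataFrame(rows), outdir / "reconciliation.tsv")
    screen = RC.duplication_screen(recs)
    _write(
        pd.DataFrame(
            [
                {
                    "family": r["family"],
                    "dup_node": r["dup_node"],
                    "species_branch": r["species_branch"],
                    "descendant_branches": "|".join(
                        ",".join(sorted(s)) for s in r["descendant_branches"]
                    ),
                }
                for r in screen
            ]
        ),
        outdir / "duplication_screen.tsv",
    )
    log.info(
        "reconcile: %d families, %d duplication nodes",
        len(groups), len(screen),
    )


def _annotated_newick(tree, rec: RC.ReconciledTree) -> str:
    """Newick with [&&event=D/S] comments on internal nodes."""

    def emit(n) -> str:
        if n.is_leaf():
            core = n.label
        else:
            core = "(" + ",".join(emit(c) for c in n.children) + ")"
            ev = rec.events.get(id(n), "")
            if ev in ("duplication", "speciation"):
                core += f"[&&event={'D' if ev == 'duplication' else 'S'}]"
        if n.branch_length is not None:
            core += f":{n.branch_length:.6g}"
        return core

    return emit(tree) + ";"


@_stage("events")
def stage_events(outdir: Path) -> None:
    calls = _load_calls(outdir)
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t")
    rep_of = dict(zip(cls.gene_id, cls.representative_isoform))
    proteins = {r.id: r.residues for r in read_fasta(outdir / "proteins.faa")}
    fam = pd.read_csv(outdir / "families.tsv", sep="\t")
    family_of = dict(zip(fam.gene_id, fam.family))
    species_tree = read_newick(outdir / "species_tree.nwk")
    domains_by_gene: dict[str, list[tuple[str, str, str]]] = {}
    for gid, rep in rep_of.items():
        if gid not in family_of:
            continue
        seqs = []
        for c in calls.get(rep, []):
            end = c.zf_end if c.zf_end else c.hepta_start + 6
            seqs.append(
                (c.terminal, c.zf_type, proteins[rep][c.hepta_start - 1 : end])
            )
        domains_by_gene[gid] = seqs
    refs, meta = AE.build_reference_sets(domains_by_gene, family_of)
    aff_rows = []
    states_by_family: dict[str, dict[str, AE.ArchState]] = {}
    for gid in sorted(domains_by_gene):
        fid = family_of[gid]
        species = gid.split("__")[0]
        doms = []
        for terminal, zf, seq in domains_by_gene[gid]:
            label, margin = AE.domain_affinity(seq, refs)
            doms.append((zf, label))
            aff_rows.append(
                {
                    "gene_id": gid, "terminal": terminal, "zf_type": zf,
                    "affinity": label, "margin": round(margin, 2),
                }
            )
        states_by_family.setdefault(fid, {}).setdefault(
            species, AE.ArchState(gid, species, doms)
        )
    _write(pd.DataFrame(aff_rows), outdir / "affinities.tsv")
    event_rows = []
    for fid in sorted(states_by_family):
        for call in AE.call_architecture_events(
            states_by_family[fid], species_tree, group=fid
        ):
            event_rows.append(
                {
                    "kind": call.kind, "family": call.group,
                    "branches": ",".join(call.branches),
                    "age_min": call.age_interval[0],
                    "age_max": call.age_interval[1],
                    "donor_N": call.donor_N, "donor_C": call.donor_C,
                    "supporting_genes": ",".join(call.supporting_genes),
                    "ambiguous": call.ambiguous,
                }
            )
    _write(pd.DataFrame(event_rows), outdir / "arch_events.tsv")
    log.info("events: %d architecture event calls", len(event_rows))


def _filter_codon_columns(aln: CodonAlignment, kept: list[int]) -> CodonAlignment:
    """Keep only the codon columns surviving the protein occupancy filter."""
    return CodonAlignment(
        taxa=aln.taxa,
        codons=[[row[c] for c in kept] for row in aln.codons],
        column_map=kept,
    )


@_stage("selection")
def stage_selection(
    outdir: Path, seed: int = 0, max_groups: int = 2, max_branch_tests: int = 2,
    n_restarts: int = 2,
) -> None:
    cls = pd.read_csv(outdir / "classification.tsv", sep="\t")
    rep_of = dict(zip(cls.gene_id, cls.representative_isoform))
    proteins = {r.id: r.residues for r in read_fasta(outdir / "proteins.faa")}
    cds = {r.id: r.residues for r in read_fasta(outdir / "cds.fna",
                                                alphabet="nucleotide")}
    species_tree = read_newick(outdir / "species_tree.nwk")
    n_species = len(species_tree.leaf_labels())
    groups = _family_members(outdir, min_size=4)
    single_copy = []
    for fid, genes in groups.items():
        species = [g.split("__")[0] for g in genes]
        if len(set(species)) == len(species) and len(species) >= max(
            4, n_species // 2
        ):
            single_copy.append(fid)
    fit_rows, lrt_rows, site_rows, call_rows = [], [], [], []
    for fid in single_copy[:max_groups]:
        genes = groups[fid]
        records = [SequenceRecord(g, "", proteins[rep_of[g]]) for g in genes]
        aligned = progressive_align(records)
        _filtered, colmap = occupancy_filter(aligned, min_fraction=0.93)
        cds_by_gene = {g: cds[rep_of[g]] for g in genes}
        codon_aln = _filter_codon_columns(thread_codons(aligned, cds_by_gene), colmap)
        ids, D = RC.distance_matrix(_filtered)
        tree = RC.nj_tree(ids, D)
        fits = {}
        m0 = fit_model(
            codon_aln, tree, "M0", optimize_branch_lengths=True,
            n_restarts=n_restarts, seed=seed,
        )
        fits["M0"] = m0
        for model in ("M1a", "M2a", "M7", "M8"):
            fits[model] = fit_model(
                codon_aln, tree, model, branch_lengths=m0.branch_lengths,
                n_restarts=n_restarts, seed=seed,
            )
        for model, fit in fits.items():
            fit_rows.append(
                {
                    "family": fid, "model": model, "lnL": round(fit.lnL, 4),
                    "converged": fit.converged,
                    **{f"param_{k}": round(v, 4) for k, v in fit.params.items()},
                }
            )
        for null, alt, df in (("M1a", "M2a", 2), ("M7", "M8", 2)):
            stat, p = lrt(fits[null].lnL, fits[alt].lnL, df)
            lrt_rows.append(
                {
                    "family": fid, "comparison": f"{null}_vs_{alt}",
                    "stat": round(stat, 4), "df": df, "p": round(p, 6),
                }
            )
        call = classify_selection(fits)
        call_rows.append(
            {
                "family": fid, "call": call["call"],
                "p_m1a_m2a": round(call["m1a_m2a"]["p"], 6),
                "p_m7_m8": round(call["m7_m8"]["p"], 6),
            }
        )
        post = site_posteriors(fits["M8"])
        for site, pp in enumerate(post["positive_posterior"]):
            tier = (
                "p99" if pp >= 0.99 else "p95" if pp >= 0.95 else ""
            )
            if tier:
                site_rows.append(
                    {
                        "family": fid, "site": site + 1,
                        "posterior": round(float(pp), 4), "tier": tier,
                    }
                )
    # branch tests on families with duplication nodes
    screen_path = outdir / "duplication_screen.tsv"
    branch_rows = []
    if screen_path.exists():
        screen = pd.read_csv(screen_path, sep="\t")
        tested = 0
        for row in screen.itertuples(index=False):
            if tested >= max_branch_tests:
                break
            fid = row.family
            genes = groups.get(fid)
            if not genes:
                continue
            records = [SequenceRecord(g, "", proteins[rep_of[g]]) for g in genes]
            aligned = progressive_align(records)
            _filtered, colmap = occupancy_filter(aligned, min_fraction=0.93)
            codon_aln = _filter_codon_columns(
                thread_codons(aligned, {g: cds[rep_of[g]] for g in genes}), colmap
            )
            gene_tree = read_newick(outdir / "reconciled_trees" / f"{fid}.nwk")
            for node in gene_tree.postorder():  # subs/site scale for codons
                if node.branch_length is not None:
                    node.branch_length = max(node.branch_length, 1e-4)
            fg = [
                frozenset(part.split(","))
                for part in str(row.descendant_branches).split("|")
            ]
            try:
                bt = branch_test(
                    codon_aln, gene_tree, fg, n_restarts=n_restarts, seed=seed
                )
            except ValueError as exc:
                log.warning("branch test skipped for %s: %s", fid, exc)
                continue
            branch_rows.append(
                {
                    "family": fid, "dup_node": row.dup_node,
                    "omega0": round(bt["omega0"], 4),
                    "omega1": round(bt["omega1"], 4),
                    "stat": round(bt["stat"], 4), "p": round(bt["p"], 6),
                    "relaxed": bt["relaxed"],
                }
            )
            tested += 1
    _write(pd.DataFrame(fit_rows), outdir / "selection_fits.tsv")
    _write(pd.DataFrame(lrt_rows), outdir / "lrt.tsv")
    _write(pd.DataFrame(site_rows), outdir / "sites.tsv")
    _write(pd.DataFrame(call_rows), outdir / "gene_calls.tsv")
    _write(pd.DataFrame(branch_rows), outdir / "branch_tests.tsv")
    log.info(
        "selection: %d single-copy groups fitted, %d branch tests",
        len(call_rows), len(branch_rows),
    )


def run_pipeline(outdir: Path, config: SimConfig, seed: int,
                 n_bootstrap: int = 50, max_selection_groups: int = 2) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.seed = seed
    stage_simulate(outdir, config)
    stage_scan(outdir)
    stage_classify(outdir)
    stage_homology(outdir)
    stage_reconcile(outdir, seed=seed, n_bootstrap=n_bootstrap)
    stage_events(outdir)
    stage_selection(outdir, seed=seed, max_groups=max_selection_groups)
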