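"""Reproducible validation experiments over the whole pipeline.

Each function regenerates its inputs from a seed, runs the relevant
module(s), and returns summary numbers.  The same functions back the
acceptance test suite and ``scripts/acceptance.py``; problem sizes are
chosen so the full set runs on one CPU in minutes (the methods note
records the sizes used).
"""

from __future__ import annotations

import filecmp
import itertools
import math
import tempfile
from pathlib import Path

import numpy as np

from . import arch_events as AE
from .bruteforce import (
    bruteforce_reconcile_cost,
    bruteforce_site_likelihood,
    enumerate_rooted_topologies,
    oracle_ng86_counts,
)
from .classify import classify_group, select_isoform
from .homology import classify_duplication, ParalogPair
from .reconcile import ReconWeights, lca_reconcile
from .scan import default_profile, scan_proteome
from .selection.codon import CODONS, ng86
from .selection.likelihood import CodonMatrix, PruningEngine, uniform_frequencies
from .selection.models import branch_test, fit_model, lrt
from .simulate import (
    Family,
    SimConfig,
    inject_architecture_events,
    make_family,
    simulate_dataset,
    simulate_family,
)
from .trees import TreeNode, parse_newick


# ---------------------------------------------------------------------------
# 1. reconciliation vs exhaustive mapping enumeration
# ---------------------------------------------------------------------------

SPECIES_TREES = [
    "(A,B)R;",
    "((A,B)N1,C)R;",
    "((A,B)N1,(C,D)N2)R;",
]


def _gene_trees_for(species: list[str], n_leaves: int, sample: int, rng):
    """Topology x species-assignment gene trees; exhaustive when sample=0."""
    shapes = enumerate_rooted_topologies([f"L{i}" for i in range(n_leaves)])
    assignments = list(itertools.product(species, repeat=n_leaves))
    combos = [(s, a) for s in range(len(shapes)) for a in range(len(assignments))]
    if sample:
        idx = rng.choice(len(combos), size=min(sample, len(combos)), replace=False)
        combos = [combos[i] for i in idx]
    for si, ai in combos:
        tree = shapes[si].copy()
        for k, leaf in enumerate(tree.leaves()):
            leaf.label = f"{assignments[ai][k]}__g{k}"
        yield tree


def reconciliation_oracle_check(seed: int = 0) -> dict:
    """LCA reconciliation cost vs brute-force minimum over valid mappings.

    Exhaustive over gene trees with <= 4 leaves on 2-, 3- and 4-species
    trees, plus seeded samples of 5- and 6-leaf gene trees.
    """
    rng = np.random.default_rng(seed)
    weights = ReconWeights()
    n_cases = n_agree = 0
    for sp_newick in SPECIES_TREES:
        sp = parse_newick(sp_newick)
        species = sp.leaf_labels()
        plans = [(2, 0), (3, 0), (4, 0), (5, 60), (6, 40)]
        for n_leaves, sample in plans:
            if n_leaves == 4 and len(species) == 4:
                sample = 400  # keep the 4x4 block tractable
            for gt in _gene_trees_for(species, n_leaves, sample, rng):
                rec = lca_reconcile(gt, sp, weights=weights)
                brute = bruteforce_reconcile_cost(gt, sp, weights=weights)
                n_cases += 1
                n_agree += math.isclose(rec.cost, brute)
    worked1 = lca_reconcile(
        parse_newick("((A__1,B__1),(A__2,B__2));"), parse_newick("(A,B)R;")
    )
    worked2 = lca_reconcile(
        parse_newick("(A__1,(A__2,B__1));"), parse_newick("(A,B)R;")
    )
    return {
        "n_cases": n_cases,
        "n_agree": n_agree,
        "agreement_pct": 100.0 * n_agree / n_cases,
        "worked_case_1": (worked1.n_dup, worked1.n_loss, worked1.cost),
        "worked_case_2": (worked2.n_dup, worked2.n_loss, worked2.cost),
    }


# ---------------------------------------------------------------------------
# 2. pruning likelihood vs exhaustive state summation
# ---------------------------------------------------------------------------


def _random_tree(rng, n_leaves: int) -> TreeNode:
    shapes = enumerate_rooted_topologies([f"t{i}" for i in range(n_leaves)])
    tree = shapes[rng.integers(len(shapes))].copy()
    for node in tree.postorder():
        if node is not tree:
            node.branch_length = float(rng.uniform(0.02, 0.6))
    return tree


def pruning_oracle_check(seed: int = 0, n_instances: int = 50) -> dict:
    """Max relative error between pruning and exhaustive summation."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_leaves = int(rng.integers(3, 5))
        tree = _random_tree(rng, n_leaves)
        taxa = tree.leaf_labels()
        kappa = float(rng.uniform(1.0, 5.0))
        omega = float(np.exp(rng.uniform(-2.0, 1.0)))
        pi = rng.dirichlet(np.ones(61) * 5.0)
        mat = CodonMatrix(kappa, omega, pi)
        engine = PruningEngine(tree, taxa)
        n_sites = int(rng.integers(1, 4))
        X = rng.integers(0, 61, size=(n_leaves, n_sites))
        lnl, site_lnl, _ = engine.log_likelihood_mixture(
            X, np.array([1.0]), [mat]
        )
        for s in range(n_sites):
            leaf_states = {taxa[i]: int(X[i, s]) for i in range(n_leaves)}
            brute = bruteforce_site_likelihood(
                tree, leaf_states, pi, mat.transition
            )
            rel = abs(math.exp(site_lnl[s]) - brute) / brute
            worst = max(worst, rel)
    return {"n_instances": n_instances, "max_relative_error": worst}


# ---------------------------------------------------------------------------
# 3. NG86 vs pathway enumeration
# ---------------------------------------------------------------------------


def ng86_oracle_check(seed: int = 0, n_pairs: int = 100, n_codons: int = 100) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        a = [CODONS[i] for i in rng.integers(0, 61, size=n_codons)]
        b = [CODONS[i] for i in rng.integers(0, 61, size=n_codons)]
        # mutate a copy of `a` lightly half the time, for realistic divergence
        if rng.random() < 0.5:
            b = list(a)
            for k in rng.choice(n_codons, size=n_codons // 5, replace=False):
                b[k] = CODONS[rng.integers(0, 61)]
        S, N, Sd, Nd = oracle_ng86_counts(a, b)
        try:
            res = ng86(a, b)
        except ValueError:
            continue
        worst = max(
            worst,
            abs(res.syn_sites - S),
            abs(res.nonsyn_sites - N),
            abs(res.syn_diffs - Sd),
            abs(res.nonsyn_diffs - Nd),
        )
    return {"n_pairs": n_pairs, "max_count_error": worst}


# ---------------------------------------------------------------------------
# 4. selection model recovery
# ---------------------------------------------------------------------------

_TREE8 = (
    "(((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.1,"
    "((E:0.15,F:0.15):0.08,(G:0.15,H:0.15):0.08):0.1);"
)
_TREE6 = "((A:0.2,B:0.2):0.1,((C:0.2,D:0.2):0.1,(E:0.2,F:0.2):0.1):0.05);"


def m0_recovery(seed: int = 0, n_reps: int = 20, n_codons: int = 500) -> dict:
    """Median M0 omega-hat at true omega in {0.2, 0.5, 1, 2}; 8 taxa."""
    tree = parse_newick(_TREE8)
    engine = PruningEngine(tree, tree.leaf_labels())
    pi = uniform_frequencies()
    out = {}
    rng = np.random.default_rng(seed)
    for true_omega in (0.2, 0.5, 1.0, 2.0):
        mat = CodonMatrix(2.0, true_omega, pi)
        estimates = []
        for _ in range(n_reps):
            X = engine.evolve(rng, [mat], np.zeros(n_codons, dtype=np.int64))
            fit = fit_model(
                X, tree, "M0", pi="uniform", n_restarts=2,
                seed=int(rng.integers(2**31)),
            )
            estimates.append(fit.params["omega"])
        out[true_omega] = float(np.median(estimates))
    return out


def m1a_m2a_type1(seed: int = 0, n_reps: int = 200, n_codons: int = 200) -> dict:
    """Rejection rate of the M1a-vs-M2a LRT at alpha=0.05 on M1a data."""
    tree = parse_newick(_TREE6)
    engine = PruningEngine(tree, tree.leaf_labels())
    pi = uniform_frequencies()
    p0, omega0 = 0.8, 0.2
    mats = [CodonMatrix(2.0, omega0, pi), CodonMatrix(2.0, 1.0, pi)]
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_reps):
        site_class = (rng.random(n_codons) > p0).astype(np.int64)
        X = engine.evolve(rng, mats, site_class)
        fit_seed = int(rng.integers(2**31))
        f1 = fit_model(X, tree, "M1a", pi="uniform", n_restarts=1, seed=fit_seed)
        f2 = fit_model(X, tree, "M2a", pi="uniform", n_restarts=2, seed=fit_seed)
        # M2a nests M1a, so the true alternative optimum is never below the
        # null; an optimizer shortfall just yields p = 1 (no rejection)
        _, p = lrt(f1.lnL, max(f2.lnL, f1.lnL), 2)
        rejections += p < 0.05
    rate = rejections / n_reps
    half = 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
    return {
        "n_reps": n_reps,
        "rejections": rejections,
        "rate": rate,
        "ci_low": 0.05 - half,
        "ci_high": 0.05 + half,
    }


def branch_recovery(seed: int = 0, n_reps: int = 20, n_codons: int = 500) -> dict:
    """Fraction of replicates with omega1 > omega0 when the foreground
    evolves at omega 1.0 over a 0.4 background."""
    tree = parse_newick(_TREE8)
    engine = PruningEngine(tree, tree.leaf_labels())
    pi = uniform_frequencies()
    fg_sets = [frozenset({"A", "B"}), frozenset({"A"}), frozenset({"B"})]
    from .selection.models import _clade_sets

    clades = _clade_sets(engine)
    branch_class = np.array([1 if clades[k] in fg_sets else 0
                             for k in range(engine.n_nodes)])
    mats = [CodonMatrix(2.0, 0.4, pi), CodonMatrix(2.0, 1.0, pi)]
    rng = np.random.default_rng(seed + 2)
    correct = 0
    for _ in range(n_reps):
        X = engine.evolve(
            rng, mats, np.zeros(n_codons, dtype=np.int64),
            branch_class=branch_class,
        )
        bt = branch_test(
            X, tree, fg_sets, pi="uniform", n_restarts=2,
            seed=int(rng.integers(2**31)),
        )
        correct += bt["omega1"] > bt["omega0"]
    return {"n_reps": n_reps, "correct": correct, "fraction": correct / n_reps}


# ---------------------------------------------------------------------------
# 5. classifier closed loop
# ---------------------------------------------------------------------------


def classifier_closed_loop(seed: int = 0, n_families: int = 50) -> dict:
    cfg = SimConfig(n_families=n_families, seed=seed)
    res = simulate_dataset(cfg)
    profile = default_profile()
    calls_by_iso = scan_proteome(res.proteins, profile)
    prot = {r.id: len(r.residues) for r in res.proteins}
    n = correct = 0
    fusion_ok = fusion_total = 0
    loss_ok = loss_total = 0
    for gid, info in res.truth["genes"].items():
        lengths = {i: prot[i] for i in info["isoforms"]}
        calls = {i: calls_by_iso.get(i, []) for i in info["isoforms"]}
        rep = select_isoform(calls, lengths)
        try:
            label, _flags = classify_group(calls[rep])
        except ValueError:
            label = "<none>"
        n += 1
        good = label == info["group"] and rep == info["representative_isoform"]
        correct += good
        kinds = {s["kind"] for s in info["architecture"]}
        if "partner" in kinds:
            fusion_total += 1
            fusion_ok += good
        if any(
            e["kind"].startswith("domain_loss") and gid in e["gene_ids"]
            for e in res.truth["events"]
        ):
            loss_total += 1
            loss_ok += good
    return {
        "n_genes": n,
        "accuracy_pct": 100.0 * correct / n,
        "fusion_products": fusion_total,
        "fusion_correct": fusion_ok,
        "domain_loss_products": loss_total,
        "domain_loss_correct": loss_ok,
    }


# ---------------------------------------------------------------------------
# 6. architecture event recovery
# ---------------------------------------------------------------------------


def _forced_spec(family: Family, sp_tree: TreeNode, rng) -> dict[str, list[str]]:
    """One randomly placed applicable event for the family."""
    if family.group == "IV" or family.extinct:
        return {}
    if len(family.templates) == 2:
        kinds = ["domain_loss_N", "domain_loss_C"]
    elif family.group == "III":
        kinds = ["domain_tandem_dup", "fusion", "fusion"]
    else:
        kinds = ["domain_tandem_dup"]
    edges = [n for n in sp_tree.postorder() if n is not sp_tree]
    lengths = np.array([e.branch_length or 0.0 for e in edges])
    branch = edges[rng.choice(len(edges), p=lengths / lengths.sum())].label
    return {branch: [kinds[rng.integers(len(kinds))]]}


def _infer_family_events(
    families: dict[str, Family], res_proteins, truth, sp_tree
) -> dict[str, list[AE.ArchEventCall]]:
    profile = default_profile()
    calls_by_iso = scan_proteome(res_proteins, profile)
    prot = {r.id: r.residues for r in res_proteins}
    domains_by_gene: dict[str, list] = {}
    family_of: dict[str, str] = {}
    for gid, info in truth["genes"].items():
        rep = info["representative_isoform"]
        seqs = []
        for c in calls_by_iso.get(rep, []):
            end = c.zf_end if c.zf_end else c.hepta_start + 6
            seqs.append((c.terminal, c.zf_type, prot[rep][c.hepta_start - 1 : end]))
        domains_by_gene[gid] = seqs
        family_of[gid] = info["family"]
    refs, _meta = AE.build_reference_sets(domains_by_gene, family_of)
    out: dict[str, list[AE.ArchEventCall]] = {}
    for fid in sorted(families):
        if families[fid].extinct:
            continue
        states: dict[str, AE.ArchState] = {}
        for gid, info in truth["genes"].items():
            if info["family"] != fid or info["species"] in states:
                continue
            doms = []
            for terminal, zf, seq in domains_by_gene[gid]:
                label, _margin = AE.domain_affinity(seq, refs)
                doms.append((zf, label))
            states[info["species"]] = AE.ArchState(gid, info["species"], doms)
        out[fid] = AE.call_architecture_events(states, sp_tree, group=fid)
    return out


ARCH_KINDS = ("domain_loss_N", "domain_loss_C", "domain_tandem_dup", "fusion")


def score_arch_events(calls_by_family, truth_events) -> dict:
    """Precision over confident calls; recall over truth events that are
    detectable in principle and not solely covered by multi-solution
    (ambiguous) alternatives.

    An event is detectable only when the family retains surviving genes
    both inside and outside the affected clade: with every observed gene
    affected (or none), the derived state is indistinguishable from the
    ancestral one.
    """
    tp = fp = 0
    truth_total = truth_ambiguous = truth_matched = 0
    n_undetectable = 0
    for fid, calls in calls_by_family.items():
        truth = []
        for e in truth_events:
            if e["family"] != fid or e["kind"] not in ARCH_KINDS:
                continue
            if e.get("detectable", True):
                truth.append(e)
            else:
                n_undetectable += 1
        confident = [c for c in calls if not c.ambiguous]
        ambiguous = [c for c in calls if c.ambiguous]
        matched: set[int] = set()
        for call in confident:
            hit = False
            for i, e in enumerate(truth):
                if i in matched:
                    continue
                if e["kind"] == call.kind and e["branch"] in call.branches:
                    matched.add(i)
                    hit = True
                    break
            if hit:
                tp += 1
            else:
                fp += 1
        for i, e in enumerate(truth):
            truth_total += 1
            if i in matched:
                truth_matched += 1
            elif any(
                a.kind == e["kind"] and e["branch"] in a.branches
                for a in ambiguous
            ):
                truth_ambiguous += 1
    denom = truth_total - truth_ambiguous
    return {
        "tp": tp,
        "fp": fp,
        "truth_events": truth_total,
        "ambiguous_covered": truth_ambiguous,
        "undetectable": n_undetectable,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": truth_matched / denom if denom else 1.0,
    }


def arch_event_recovery(seed: int = 0, n_families: int = 50) -> dict:
    """Recovery of one injected architecture event per family."""
    cfg = SimConfig(
        n_families=n_families, seed=seed,
        rate_domain_loss=0.0, rate_domain_dup=0.0, rate_fusion=0.0,
    )
    sp_tree = cfg.tree()
    families: dict[str, Family] = {}
    for i in range(cfg.n_families):
        fam = make_family(cfg, i)
        simulate_family(cfg, fam)
        families[fam.family_id] = fam
    pool = list(families.values())
    rng = np.random.default_rng([seed, 99])
    for fam in pool:
        forced = _forced_spec(fam, sp_tree, rng)
        inject_architecture_events(cfg, fam, pool, forced=forced)
    from .simulate import emit_sequences

    for fam in pool:
        emit_sequences(cfg, fam)
    # assemble the dataset pieces needed for inference
    from .io import SequenceRecord
    from .simulate import assemble_gene, leaf_architecture

    proteins = []
    truth_genes: dict[str, dict] = {}
    truth_events = []
    for fid in sorted(families):
        fam = families[fid]
        if fam.extinct:
            continue
        for leaf in sorted(fam.gene_tree.leaves(), key=lambda l: l.label):
            gid = leaf.label
            species = gid.split("__")[0]
            protein, _cds = assemble_gene(fam, gid, families)
            proteins.append(SequenceRecord(f"{gid}.t1", "", protein))
            truth_genes[gid] = {
                "species": species,
                "family": fid,
                "representative_isoform": f"{gid}.t1",
                "architecture": [
                    {"kind": s.kind} for s in leaf_architecture(fam, species)
                ],
            }
        present = {l.label.split("__")[0] for l in fam.gene_tree.leaves()}
        clade_of = {n.label: set(n.leaf_labels()) for n in sp_tree.postorder()}
        for e in fam.events:
            if e.kind in ARCH_KINDS:
                affected = {g.split("__")[0] for g in e.gene_ids}
                outside = present - clade_of.get(e.branch, set())
                truth_events.append(
                    {"kind": e.kind, "branch": e.branch, "family": fid,
                     "details": e.details,
                     "detectable": bool(affected) and bool(outside)}
                )
    calls_by_family = _infer_family_events(
        families, proteins, {"genes": truth_genes}, sp_tree
    )
    result = score_arch_events(calls_by_family, truth_events)
    result["wrky98_scenario"] = wrky98_scenario(seed)
    return result


def wrky98_scenario(seed: int = 0) -> dict:
    """Two-domain family loses its C-terminal domain on an internal
    branch, then regains a second domain by tandem duplication in one
    descendant lineage: exactly those two events must be called on the
    correct branches."""
    cfg = SimConfig(
        n_families=4, seed=seed,
        rate_dup=0.0, rate_loss=0.0,
        rate_domain_loss=0.0, rate_domain_dup=0.0, rate_fusion=0.0,
    )
    sp_tree = cfg.tree()
    families: dict[str, Family] = {}
    groups = ["Ib", "III", "III", "IIc"]
    for i, grp in enumerate(groups):
        fam = make_family(cfg, i, group=grp)
        simulate_family(cfg, fam)
        families[fam.family_id] = fam
    pool = list(families.values())
    target = families["f00"]
    forced = {"N6": ["domain_loss_C"], "oruf": ["domain_tandem_dup"]}
    for fam in pool:
        inject_architecture_events(
            cfg, fam, pool, forced=forced if fam is target else {}
        )
    from .io import SequenceRecord
    from .simulate import assemble_gene, emit_sequences, leaf_architecture

    for fam in pool:
        emit_sequences(cfg, fam)
    proteins = []
    truth_genes = {}
    for fid in sorted(families):
        fam = families[fid]
        for leaf in sorted(fam.gene_tree.leaves(), key=lambda l: l.label):
            gid = leaf.label
            protein, _ = assemble_gene(fam, gid, families)
            proteins.append(SequenceRecord(f"{gid}.t1", "", protein))
            truth_genes[gid] = {
                "species": gid.split("__")[0],
                "family": fid,
                "representative_isoform": f"{gid}.t1",
            }
    calls = _infer_family_events(
        families, proteins, {"genes": truth_genes}, sp_tree
    )["f00"]
    confident = sorted(
        (c.kind, tuple(c.branches)) for c in calls if not c.ambiguous
    )
    expected = [("domain_loss_C", ("N6",)), ("domain_tandem_dup", ("oruf",))]
    return {
        "calls": confident,
        "exact_match": confident == expected
        and not any(c.ambiguous for c in calls),
    }


# ---------------------------------------------------------------------------
# 7. duplication-mode recovery
# ---------------------------------------------------------------------------


def duplication_mode_recovery(seed: int = 0, n_families: int = 40) -> dict:
    cfg = SimConfig(n_families=n_families, seed=seed)
    res = simulate_dataset(cfg)
    coords = {
        g: (info["chromosome"], info["start"], info["end"])
        for g, info in res.truth["genes"].items()
    }
    by_chrom: dict[str, list[str]] = {}
    for g, (chrom, start, _e) in sorted(coords.items(), key=lambda kv: kv[1][1]):
        by_chrom.setdefault(chrom, []).append(g)
    n = correct = tandem = segmental = 0
    for pair in res.truth["paralog_pairs"]:
        p = ParalogPair(
            species=pair["species"], gene_a=pair["gene_a"], gene_b=pair["gene_b"]
        )
        mode = classify_duplication(p, coords, by_chrom)
        n += 1
        correct += mode == pair["mode"]
        tandem += mode == "tandem"
        segmental += mode == "segmental"
    return {
        "n_pairs": n,
        "accuracy_pct": 100.0 * correct / n if n else 100.0,
        "tandem": tandem,
        "segmental": segmental,
        "partition_ok": tandem + segmental == n,
    }


# ---------------------------------------------------------------------------
# 8. pipeline determinism
# ---------------------------------------------------------------------------


def pipeline_determinism(seed: int = 0, n_families: int = 12) -> dict:
    from .pipeline import run_pipeline

    with tempfile.TemporaryDirectory() as tmp:
        run_a, run_b = Path(tmp) / "a", Path(tmp) / "b"
        for out in (run_a, run_b):
            run_pipeline(
                out, SimConfig(n_families=n_families), seed=seed,
                n_bootstrap=30, max_selection_groups=1,
            )
        tables = sorted(p.name for p in run_a.glob("*.tsv"))
        identical = all(
            filecmp.cmp(run_a / t, run_b / t, shallow=False) for t in tables
        )
        return {"n_tables": len(tables), "byte_identical": identical}
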