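"""Synthetic Oryza-like WRKY dataset simulator with ground-truth event logs.

Gene families evolve along a dated, ultrametric species tree (default: a
packaged 10-species tree with a 15-Myr root and an AA/BB-type split at
6.76 Myr) under a birth-death process (duplication/loss per gene lineage
per Myr).  Domain-architecture events (N/C-terminal domain loss, domain
tandem duplication, two-gene fusion) are injected on species-tree
branches; codon sequences evolve along the gene trees under a GY94-style
process with per-site omega classes, frozen signature sites, and a
restricted amino-acid alphabet at intra-domain spacer sites.  Every
event is recorded in a truth log so downstream stages can be scored
without re-reading sequences.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import templates as T
from .io import GffFeature, SequenceRecord, write_fasta, write_gff3
from .trees import TreeNode, read_newick, to_newick_string, write_newick
from .selection.codon import CODONS, GENETIC_CODE
from .selection.likelihood import CodonMatrix, uniform_frequencies

LEAD_LEN = 25  # residues before the first domain
LINKER_LEN = 15  # residues after each domain
TAIL_LEN = 20

#: codons encoding residues banned at restricted (intra-domain spacer) sites
_RESTRICTED_ALLOWED = np.array(
    [GENETIC_CODE[c] not in "CHW" for c in CODONS]
)

_AA_TO_CODONS: dict[str, list[int]] = {}
for _i, _c in enumerate(CODONS):
    _AA_TO_CODONS.setdefault(GENETIC_CODE[_c], []).append(_i)


def default_species_tree() -> TreeNode:
    path = importlib.resources.files("wrkyevo.data") / "oryza_like_species_tree.nwk"
    with importlib.resources.as_file(path) as p:
        return read_newick(p)


DEFAULT_GROUP_WEIGHTS = {
    "Ia": 0.09,
    "Ib": 0.02,
    "IIa": 0.02,
    "IIb": 0.06,
    "IIc": 0.20,
    "IId": 0.09,
    "IIe": 0.10,
    "III": 0.31,
    "IV": 0.11,
}

DEFAULT_HEPTA_FREQS = {
    "WRKYGQK": 0.845,
    "WRKYGEK": 0.070,
    "WRKYGKK": 0.050,
    "WKKYGQK": 0.011,
    "WRMCGQK": 0.010,
    "WSKYGQK": 0.007,
    "WVKYGQK": 0.007,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_families: int = 30
    n_chromosomes: int = 12
    chromosome_length: int = 30_000_000
    rate_dup: float = 0.02  # gene duplications / lineage / Myr
    rate_loss: float = 0.01
    p_tandem: float = 1 / 3  # tandem fraction among gene duplications
    rate_domain_loss: float = 0.004  # architecture events / family lineage / Myr
    rate_domain_dup: float = 0.003
    rate_fusion: float = 0.004
    kappa: float = 2.0
    subst_rate: float = 0.02  # expected substitutions / codon / Myr
    #: per-family site-class omegas and proportions
    omega_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"purifying": (0.2, 0.85), "neutral": (1.0, 0.15)}
    )
    freeze_signatures: bool = True
    group_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    hepta_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEPTA_FREQS)
    )
    isoform_fraction: float = 0.15
    hotspot_fraction: float = 0.25  # families seeded on the chr11/12 distal tips
    tandem_gap: int = 6_000  # bp between tandem cluster members
    seed: int = 0
    species_tree: Optional[TreeNode] = None

    def tree(self) -> TreeNode:
        if self.species_tree is None:
            self.species_tree = default_species_tree()
        return self.species_tree

    def validate(self) -> None:
        rates = [self.rate_dup, self.rate_loss, self.rate_domain_loss,
                 self.rate_domain_dup, self.rate_fusion]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if not 0 <= self.p_tandem <= 1:
            raise ValueError("p_tandem must be in [0, 1]")
        for name, (omega, prop) in self.omega_profile.items():
            if omega <= 0:
                raise ValueError(f"omega for class {name!r} must be > 0")
            if prop < 0:
                raise ValueError(f"proportion for class {name!r} must be >= 0")


@dataclass
class TrueEvent:
    kind: str  # speciation | gene_dup_tandem | gene_dup_segmental | gene_loss
    #        | domain_loss_N | domain_loss_C | domain_tandem_dup | fusion
    branch: str  # species-tree edge id (= child node label)
    gene_ids: list[str]
    time: float  # Myr before present
    family: str = ""
    details: dict = field(default_factory=dict)


@dataclass
class DomainSlot:
    """One domain position in a gene's architecture (ordered N->C)."""

    source_family: str  # clade affinity
    template_index: int  # which template domain of the source family
    kind: str  # own | copy | partner

    def descriptor(self, families: dict[str, "Family"]):
        tpl = families[self.source_family].templates[self.template_index]
        sig = tpl.literal_label or (f"CX{tpl.core_len}C" if tpl.has_zf else "none")
        return _Descriptor(zf_type=tpl.zf_type, signature=sig)


@dataclass
class _Descriptor:
    zf_type: str
    signature: str


@dataclass
class FamilyTemplateDomain:
    hepta: str
    zf_type: str
    core_len: int
    literal_label: str  # subgroup name or ""
    residues: str  # realized domain string
    frozen: list[bool]

    @property
    def has_zf(self) -> bool:
        return self.zf_type != "none"


@dataclass
class Family:
    family_id: str
    group: str
    templates: list[FamilyTemplateDomain]
    gene_tree: Optional[TreeNode] = None
    extinct: bool = False
    events: list[TrueEvent] = field(default_factory=list)
    #: species-tree node label -> architecture (list of DomainSlot)
    arch_by_node: dict[str, list[DomainSlot]] = field(default_factory=dict)
    #: leaf gene id -> cluster serial (tandem co-cluster membership)
    cluster_of: dict[str, int] = field(default_factory=dict)
    n_clusters: int = 1
    layout: dict = field(default_factory=dict)
    site_class: Optional[np.ndarray] = None
    leaf_codons: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# family creation and birth-death simulation
# ---------------------------------------------------------------------------


def _draw(rng, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def make_family(config: SimConfig, index: int, group: Optional[str] = None) -> Family:
    rng = np.random.default_rng([config.seed, 1, index])
    if group is None:
        group = _draw(rng, config.group_weights)
    fam_id = f"f{index:02d}"
    tdoms = []
    for tpl in T.GROUP_TEMPLATES[group]:
        hepta_freqs = config.hepta_freqs
        if group == "IV":
            # degenerate-core variants are observed only in complete-domain
            # groups; a partial-motif gene must keep a canonical
            # heptapeptide to remain recognizable at all
            hepta_freqs = {
                k: v for k, v in config.hepta_freqs.items()
                if k in T.HEPTA_CANONICAL
            }
        hepta = _draw(rng, hepta_freqs)
        tpl = T.DomainTemplate(
            group=tpl.group, hepta=hepta, zf_type=tpl.zf_type,
            core_len=tpl.core_len, literal=tpl.literal,
        )
        residues, frozen = tpl.realize(rng)
        label = tpl.group if tpl.literal else ""
        tdoms.append(
            FamilyTemplateDomain(
                hepta=hepta, zf_type=tpl.zf_type, core_len=tpl.core_len,
                literal_label=label, residues=residues, frozen=frozen,
            )
        )
    return Family(family_id=fam_id, group=group, templates=tdoms)


def simulate_family(config: SimConfig, family: Family) -> tuple[Optional[TreeNode], list[TrueEvent]]:
    """Birth-death gene tree along the species tree; leaves named
    species__familyNk.  Returns (pruned gene tree or None if extinct,
    event list)."""
    config.validate()
    sp_tree = config.tree()
    ages = sp_tree.node_ages()
    rng = np.random.default_rng([config.seed, 2, int(family.family_id[1:])])
    events: list[TrueEvent] = []
    counters = {"leaf": 0, "node": 0}
    total = config.rate_dup + config.rate_loss

    def evolve(sp_node: TreeNode, age_top: float, cluster: int) -> Optional[TreeNode]:
        """One gene lineage entering the species branch above ``sp_node``
        at time ``age_top``; returns the subtree it generates."""
        age_bottom = ages[id(sp_node)]
        t = age_top
        while True:
            dt = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t - dt <= age_bottom:
                break
            t -= dt
            if rng.random() < (config.rate_dup / total if total else 0.0):
                tandem = rng.random() < config.p_tandem
                if tandem:
                    cl_a, cl_b = cluster, cluster
                else:
                    family.n_clusters += 1
                    cl_a, cl_b = cluster, family.n_clusters - 1
                counters["node"] += 1
                label = f"D{counters['node']}"
                left = evolve(sp_node, t, cl_a)
                right = evolve(sp_node, t, cl_b)
                kind = "gene_dup_tandem" if tandem else "gene_dup_segmental"
                kids = [c for c in (left, right) if c is not None]
                node = None
                if len(kids) == 2:
                    node = TreeNode(label=label, children=kids,
                                    branch_length=age_top - t)
                elif len(kids) == 1:
                    node = kids[0]
                    node.branch_length = (node.branch_length or 0.0) + (age_top - t)
                events.append(
                    TrueEvent(
                        kind=kind, branch=sp_node.label, time=round(t, 6),
                        gene_ids=sorted(l.label for k in kids for l in k.leaves()),
                        family=family.family_id,
                        details={"survived": len(kids) == 2, "node": label},
                    )
                )
                return node
            else:
                events.append(
                    TrueEvent(
                        kind="gene_loss", branch=sp_node.label, time=round(t, 6),
                        gene_ids=[], family=family.family_id,
                    )
                )
                return None
        # reached the bottom of the species branch
        if sp_node.is_leaf():
            counters["leaf"] += 1
            gene_id = f"{sp_node.label}__{family.family_id}n{counters['leaf']}"
            family.cluster_of[gene_id] = cluster
            return TreeNode(label=gene_id, branch_length=age_top - age_bottom)
        counters["node"] += 1
        label = f"S{counters['node']}"
        kids = [evolve(c, age_bottom, cluster) for c in sp_node.children]
        kids = [k for k in kids if k is not None]
        events.append(
            TrueEvent(
                kind="speciation", branch=sp_node.label, time=round(age_bottom, 6),
                gene_ids=sorted(l.label for k in kids for l in k.leaves()),
                family=family.family_id,
                details={"survived": len(kids) >= 2, "node": label},
            )
        )
        if not kids:
            return None
        if len(kids) == 1:
            node = kids[0]
            node.branch_length = (node.branch_length or 0.0) + (age_top - age_bottom)
            return node
        return TreeNode(label=label, children=kids,
                        branch_length=age_top - age_bottom)

    root_age = ages[id(sp_tree)]
    tree = evolve(sp_tree, root_age, cluster=0)
    family.gene_tree = tree
    family.extinct = tree is None
    family.events = events
    return tree, events


def surviving_duplications(family: Family) -> list[TrueEvent]:
    return [
        e for e in family.events
        if e.kind.startswith("gene_dup") and e.details.get("survived")
    ]


# ---------------------------------------------------------------------------
# architecture events
# ---------------------------------------------------------------------------


def _species_presence(family: Family) -> set[str]:
    if family.extinct:
        return set()
    return {leaf.label.split("__")[0] for leaf in family.gene_tree.leaves()}


def inject_architecture_events(
    config: SimConfig,
    family: Family,
    partner_pool: list[Family],
    log: Optional[list[str]] = None,
    forced: Optional[dict[str, list[str]]] = None,
) -> list[TrueEvent]:
    """Place domain loss / tandem duplication / fusion events on species-tree
    branches, propagating the family architecture down the tree.

    Fusion requires this family to be a single-domain Group III state and
    a distinct Group III partner family with genes in every species of
    the affected clade (the partner donates the C-terminal domain; the
    product replaces this family's locus, mirroring a fusion that places
    one gene's DNA-binding domain under the other's promoter).
    """
    sp_tree = config.tree()
    ages = sp_tree.node_ages()
    rng = np.random.default_rng([config.seed, 3, int(family.family_id[1:])])
    own = [
        DomainSlot(family.family_id, i, "own")
        for i in range(len(family.templates))
    ]
    family.arch_by_node = {sp_tree.label: list(own)}
    new_events: list[TrueEvent] = []
    presence = {f.family_id: _species_presence(f) for f in partner_pool}
    my_species = _species_presence(family)

    def clade_species(node: TreeNode) -> set[str]:
        return set(node.leaf_labels())

    def genes_in(species: set[str]) -> list[str]:
        if family.extinct:
            return []
        return sorted(
            l.label for l in family.gene_tree.leaves()
            if l.label.split("__")[0] in species
        )

    for node in sp_tree.preorder():
        if node is sp_tree:
            continue
        parent_label = _parent_label(sp_tree, node)
        arch = list(family.arch_by_node[parent_label])
        duration = node.branch_length or 0.0
        affected = clade_species(node) & my_species
        if forced is not None:
            requested = list(forced.get(node.label, []))
        else:
            requested = []
            for kind, rate in (
                ("domain_loss", config.rate_domain_loss),
                ("domain_tandem_dup", config.rate_domain_dup),
                ("fusion", config.rate_fusion),
            ):
                requested.extend([kind] * rng.poisson(rate * duration))
        for kind in requested:
            if True:
                t = round(ages[id(node)] + rng.random() * duration, 6)
                if not affected:
                    if log is not None:
                        log.append(
                            f"{family.family_id}: {kind} on empty branch "
                            f"{node.label} skipped"
                        )
                    continue
                if kind.startswith("domain_loss"):
                    complete = [s for s in arch if s.descriptor(
                        {f.family_id: f for f in partner_pool + [family]}
                    ).zf_type != "none"]
                    if len(arch) < 2 or len(complete) < 2:
                        if log is not None:
                            log.append(
                                f"{family.family_id}: domain_loss on "
                                f"single-domain state skipped ({node.label})"
                            )
                        continue
                    if kind in ("domain_loss_N", "domain_loss_C"):
                        terminal = kind[-1]
                    else:
                        terminal = "N" if rng.random() < 0.5 else "C"
                    idx = 0 if terminal == "N" else len(arch) - 1
                    arch.pop(idx)
                    new_events.append(
                        TrueEvent(
                            kind=f"domain_loss_{terminal}", branch=node.label,
                            gene_ids=genes_in(affected), time=t,
                            family=family.family_id,
                        )
                    )
                elif kind == "domain_tandem_dup":
                    if len(arch) != 1:
                        if log is not None:
                            log.append(
                                f"{family.family_id}: domain_tandem_dup on "
                                f"multi-domain state skipped ({node.label})"
                            )
                        continue
                    src = arch[0]
                    arch = [src, DomainSlot(src.source_family,
                                            src.template_index, "copy")]
                    new_events.append(
                        TrueEvent(
                            kind="domain_tandem_dup", branch=node.label,
                            gene_ids=genes_in(affected), time=t,
                            family=family.family_id,
                        )
                    )
                else:  # fusion
                    if family.group != "III" or len(arch) != 1 or arch[0].kind != "own":
                        continue
                    partners = [
                        f for f in partner_pool
                        if f.group == "III"
                        and f.family_id != family.family_id
                        and affected <= presence[f.family_id]
                    ]
                    if not partners:
                        if log is not None:
                            log.append(
                                f"{family.family_id}: fusion on {node.label} "
                                "skipped (<2 co-resident Group III families)"
                            )
                        continue
                    partner = partners[rng.integers(len(partners))]
                    arch = [arch[0], DomainSlot(partner.family_id, 0, "partner")]
                    new_events.append(
                        TrueEvent(
                            kind="fusion", branch=node.label,
                            gene_ids=genes_in(affected), time=t,
                            family=family.family_id,
                            details={
                                "donor_N": family.family_id,
                                "donor_C": partner.family_id,
                                "promoter_from": partner.family_id,
                            },
                        )
                    )
        family.arch_by_node[node.label] = arch
    family.events.extend(new_events)
    return new_events


def _parent_label(tree: TreeNode, node: TreeNode) -> str:
    parents = tree.parent_map()
    return parents[id(node)].label


def leaf_architecture(family: Family, species: str) -> list[DomainSlot]:
    return family.arch_by_node.get(species, [])


def expected_gene_group(family: Family, species: str,
                        families: dict[str, Family]) -> tuple[str, list[str]]:
    arch = leaf_architecture(family, species)
    return T.expected_group([slot.descriptor(families) for slot in arch])


# ---------------------------------------------------------------------------
# sequence emission
# ---------------------------------------------------------------------------


def _family_layout(family: Family, rng) -> dict:
    """Codon layout of the family's base (template) sequence."""
    segments = []  # (name, start, length)
    pos = 0

    def add(name: str, length: int):
        nonlocal pos
        segments.append({"name": name, "start": pos, "length": length})
        pos += length

    add("lead", LEAD_LEN)
    for i, dom in enumerate(family.templates):
        add(f"dom{i}", len(dom.residues))
        add(f"linker{i}", LINKER_LEN)
    add("tail", TAIL_LEN)
    return {"segments": segments, "length": pos}


def _root_residues(family: Family, layout, rng) -> tuple[list[str], np.ndarray]:
    """Root amino acids plus per-site category (0 frozen, 1 restricted, 2 free)."""
    residues = [""] * layout["length"]
    category = np.full(layout["length"], 2, dtype=np.int64)
    for seg in layout["segments"]:
        start, length = seg["start"], seg["length"]
        if seg["name"].startswith("dom"):
            i = int(seg["name"][3:])
            dom = family.templates[i]
            for k in range(length):
                residues[start + k] = dom.residues[k]
                category[start + k] = 0 if dom.frozen[k] else 1
        else:
            for k in range(length):
                residues[start + k] = T.FREE_AA[rng.integers(len(T.FREE_AA))]
    return residues, category


class _IdentityMatrix:
    def __init__(self, pi):
        self.pi = pi

    def transition(self, t):
        return np.eye(len(self.pi))


def emit_sequences(config: SimConfig, family: Family) -> None:
    """Evolve codon sequences along the family gene tree.

    Frozen signature sites never substitute (unless
    ``config.freeze_signatures`` is off); restricted intra-domain spacer
    sites exclude C/H/W targets; free sites follow the family omega
    profile.  Stores per-leaf codon index arrays on the family.
    """
    if family.extinct:
        return
    rng = np.random.default_rng([config.seed, 4, int(family.family_id[1:])])
    layout = _family_layout(family, rng)
    residues, category = _root_residues(family, layout, rng)
    n_sites = layout["length"]
    class_names = sorted(config.omega_profile)
    props = np.array([config.omega_profile[c][1] for c in class_names], dtype=float)
    props = props / props.sum()
    omega_class = rng.choice(len(class_names), size=n_sites, p=props)
    pi = uniform_frequencies()
    mats = {}
    for ci, cname in enumerate(class_names):
        omega = config.omega_profile[cname][0]
        mats[("free", ci)] = CodonMatrix(config.kappa, omega, pi)
        mats[("restricted", ci)] = CodonMatrix(
            config.kappa, omega, pi, allowed=_RESTRICTED_ALLOWED
        )
    identity = _IdentityMatrix(pi)

    def site_matrix(s: int):
        if category[s] == 0 and config.freeze_signatures:
            return identity
        if category[s] <= 1:
            return mats[("restricted", int(omega_class[s]))]
        return mats[("free", int(omega_class[s]))]

    matrix_id = np.array(
        [
            0 if (category[s] == 0 and config.freeze_signatures)
            else (1 + int(omega_class[s]) if category[s] <= 1
                  else 1 + len(class_names) + int(omega_class[s]))
            for s in range(n_sites)
        ]
    )
    matrix_list = (
        [identity]
        + [mats[("restricted", ci)] for ci in range(len(class_names))]
        + [mats[("free", ci)] for ci in range(len(class_names))]
    )

    root_states = np.array(
        [_pick_codon(residues[s], rng) for s in range(n_sites)], dtype=np.int64
    )

    def walk(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            t = (child.branch_length or 0.0) * config.subst_rate
            child_states = states.copy()
            for mid in np.unique(matrix_id):
                if matrix_list[mid] is identity:
                    continue
                sel = matrix_id == mid
                P = matrix_list[mid].transition(t)
                cum = P[states[sel]].cumsum(axis=1)
                u = rng.random(sel.sum())
                child_states[sel] = (u[:, None] > cum).sum(axis=1)
            if child.is_leaf():
                family.leaf_codons[child.label] = child_states
            else:
                walk(child, child_states)

    if family.gene_tree.is_leaf():
        walk(TreeNode(children=[family.gene_tree]), root_states)
    else:
        walk(family.gene_tree, root_states)
    family.layout = layout
    family.site_class = np.where(
        category == 0, -1, omega_class
    )  # -1 marks frozen signature sites


def _pick_codon(aa: str, rng) -> int:
    options = _AA_TO_CODONS[aa]
    return options[rng.integers(len(options))]


def _segment_range(layout, name: str) -> tuple[int, int]:
    for seg in layout["segments"]:
        if seg["name"] == name:
            return seg["start"], seg["start"] + seg["length"]
    raise KeyError(name)


def assemble_gene(
    family: Family,
    gene_id: str,
    families: dict[str, Family],
) -> tuple[str, str]:
    """(protein, cds) for one leaf gene, honoring its architecture."""
    species = gene_id.split("__")[0]
    arch = leaf_architecture(family, species)
    codons = family.leaf_codons[gene_id]
    layout = family.layout
    pieces: list[np.ndarray] = []
    lo, hi = _segment_range(layout, "lead")
    pieces.append(codons[lo:hi])
    for k, slot in enumerate(arch):
        if slot.kind in ("own", "copy"):
            lo, hi = _segment_range(layout, f"dom{slot.template_index}")
            pieces.append(codons[lo:hi])
        else:  # partner segment from the co-resident donor gene
            donor = families[slot.source_family]
            donor_genes = sorted(
                g for g in donor.leaf_codons if g.split("__")[0] == species
            )
            donor_codons = donor.leaf_codons[donor_genes[0]]
            dlo, dhi = _segment_range(donor.layout, f"dom{slot.template_index}")
            pieces.append(donor_codons[dlo:dhi])
        llo, lhi = _segment_range(
            layout, f"linker{min(k, len(family.templates) - 1)}"
        )
        pieces.append(codons[llo:lhi])
    lo, hi = _segment_range(layout, "tail")
    pieces.append(codons[lo:hi])
    idx = np.concatenate(pieces)
    cds = "".join(CODONS[i] for i in idx)
    protein = "".join(GENETIC_CODE[CODONS[i]] for i in idx)
    return protein, cds


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def emit_annotation(config: SimConfig, families: dict[str, Family],
                    gene_spans: Optional[dict[str, int]] = None) -> dict:
    """Chromosome placement for every leaf gene.

    Cluster 0 of each family sits at the family's home locus (the same
    chromosome/slot in every species, emulating synteny); each segmental
    cluster gets its own chromosome and slot.  Tandem-cluster members are
    adjacent (well inside the <=5 intervening genes / <=100 kb window);
    hot-spot families live on the distal 10% of chr11/chr12 and their
    segmental clusters preferentially hop between those two arms.
    """
    rng = np.random.default_rng([config.seed, 5])
    fam_ids = sorted(families)
    n_hot = int(round(config.hotspot_fraction * len(fam_ids)))
    hot = set(fam_ids[:n_hot])  # deterministic choice
    home: dict[str, tuple[str, int]] = {}
    regular_slot = 0
    hot_slot = 0
    slot_pitch = 400_000
    hot_pitch = 130_000
    tip_limit = int(0.095 * config.chromosome_length)
    for fid in fam_ids:
        if fid in hot:
            chrom = f"chr{11 + hot_slot % 2}"
            pos = 150_000 + (hot_slot // 2) * hot_pitch
            if pos > tip_limit:
                raise ValueError("hot-spot region capacity exceeded")
            home[fid] = (chrom, pos)
            hot_slot += 1
        else:
            chrom_i = regular_slot % (config.n_chromosomes - 2)  # keep 11/12 tips clear
            pos = 400_000 + (regular_slot // (config.n_chromosomes - 2)) * slot_pitch
            if pos + slot_pitch > config.chromosome_length:
                raise ValueError(
                    "chromosome capacity exceeded; increase chromosome_length"
                )
            home[fid] = (f"chr{chrom_i + 1}", pos)
            regular_slot += 1
    # segmental clusters: one fresh slot per cluster, shared across species
    cluster_locus: dict[tuple[str, int], tuple[str, int]] = {}
    seg_serial = 0
    hot_seg_serial = 0
    for fid in fam_ids:
        fam = families[fid]
        clusters = sorted(set(fam.cluster_of.values()))
        for cl in clusters:
            if cl == 0:
                cluster_locus[(fid, 0)] = home[fid]
                continue
            if fid in hot and rng.random() < 0.8:
                src_chrom = home[fid][0]
                chrom = "chr12" if src_chrom == "chr11" else "chr11"
                pos = 150_000 + 65_000 + hot_seg_serial * hot_pitch
                hot_seg_serial += 1
                if pos > tip_limit:
                    chrom = f"chr{1 + seg_serial % (config.n_chromosomes - 2)}"
                    pos = int(config.chromosome_length * 0.55) + \
                        (seg_serial // (config.n_chromosomes - 2)) * slot_pitch
                    seg_serial += 1
            else:
                choices = [
                    f"chr{i + 1}" for i in range(config.n_chromosomes)
                    if f"chr{i + 1}" != home[fid][0]
                ]
                chrom = choices[rng.integers(len(choices))]
                pos = int(config.chromosome_length * 0.55) + \
                    (seg_serial // 1) * slot_pitch // 2 + seg_serial * 17_000
                seg_serial += 1
            if pos > config.chromosome_length - 100_000:
                raise ValueError(
                    "chromosome capacity exceeded; increase chromosome_length"
                )
            cluster_locus[(fid, cl)] = (chrom, pos)
    placements: dict[str, tuple[str, int, int, str]] = {}
    for fid in fam_ids:
        fam = families[fid]
        genes_by_cluster: dict[tuple[str, int], list[str]] = {}
        for gene_id, cl in sorted(fam.cluster_of.items()):
            species = gene_id.split("__")[0]
            genes_by_cluster.setdefault((species, cl), []).append(gene_id)
        for (species, cl), gene_ids in sorted(genes_by_cluster.items()):
            chrom, base = cluster_locus[(fid, cl)]
            for k, gene_id in enumerate(gene_ids):
                if gene_spans and gene_id in gene_spans:
                    span = gene_spans[gene_id]
                else:
                    span = len(fam.leaf_codons[gene_id]) * 3 + 300
                start = base + k * config.tandem_gap + 1
                strand = "+" if rng.random() < 0.5 else "-"
                placements[gene_id] = (chrom, start, start + span - 1, strand)
    return placements


# ---------------------------------------------------------------------------
# dataset driver
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    config: SimConfig
    families: dict[str, Family]
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    gff: list[GffFeature]
    truth: dict
    skipped_log: list[str]


def simulate_dataset(config: SimConfig) -> SimResult:
    config.validate()
    sp_tree = config.tree()
    families: dict[str, Family] = {}
    for i in range(config.n_families):
        fam = make_family(config, i)
        simulate_family(config, fam)
        families[fam.family_id] = fam
    pool = list(families.values())
    skipped: list[str] = []
    for fam in pool:
        inject_architecture_events(config, fam, pool, log=skipped)
    for fam in pool:
        emit_sequences(config, fam)

    iso_rng = np.random.default_rng([config.seed, 6])
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    gene_info: dict[str, dict] = {}
    for fid in sorted(families):
        fam = families[fid]
        if fam.extinct:
            continue
        for leaf in sorted(fam.gene_tree.leaves(), key=lambda l: l.label):
            gene_id = leaf.label
            species = gene_id.split("__")[0]
            protein, cds = assemble_gene(fam, gene_id, families)
            isoforms = {f"{gene_id}.t1": (protein, cds)}
            rep = f"{gene_id}.t1"
            has_complete = any(
                s["zf_type"] != "none"
                for s in (
                    {
                        "zf_type": families[sl.source_family]
                        .templates[sl.template_index].zf_type
                    }
                    for sl in leaf_architecture(fam, species)
                )
            )
            if iso_rng.random() < config.isoform_fraction:
                if iso_rng.random() < 0.5 or not has_complete:
                    # shorter, domain-free isoform: the longest still wins
                    cut = LEAD_LEN + 5
                    isoforms[f"{gene_id}.t2"] = (protein[:cut], cds[: cut * 3])
                else:
                    # longer but domain-free isoform: the complete shorter
                    # isoform must be chosen instead
                    extra = len(protein) + 20
                    junk_idx = iso_rng.integers(0, len(CODONS), size=extra)
                    junk_cds = "".join(CODONS[i] for i in junk_idx)
                    junk_prot = "".join(GENETIC_CODE[CODONS[i]] for i in junk_idx)
                    isoforms[f"{gene_id}.t2"] = (junk_prot, junk_cds)
            group, flags = expected_gene_group(fam, species, families)
            arch = leaf_architecture(fam, species)
            gene_info[gene_id] = {
                "species": species,
                "family": fid,
                "group": group,
                "flags": flags,
                "representative_isoform": rep,
                "isoforms": sorted(isoforms),
                "isoform_cds_lengths": {
                    iso: len(isoforms[iso][1]) for iso in sorted(isoforms)
                },
                "architecture": [
                    {
                        "source_family": s.source_family,
                        "template_index": s.template_index,
                        "kind": s.kind,
                        "hepta": families[s.source_family]
                        .templates[s.template_index].hepta,
                        "zf_type": families[s.source_family]
                        .templates[s.template_index].zf_type,
                    }
                    for s in arch
                ],
                "cluster": fam.cluster_of[gene_id],
            }
            for iso_id in sorted(isoforms):
                prot, c = isoforms[iso_id]
                proteins.append(SequenceRecord(iso_id, f"gene={gene_id}", prot))
                cds_records.append(SequenceRecord(iso_id, f"gene={gene_id}", c))

    gene_spans = {
        g: max(info["isoform_cds_lengths"].values()) + 300
        for g, info in gene_info.items()
    }
    placements = emit_annotation(config, families, gene_spans)
    gff: list[GffFeature] = []
    for gene_id in sorted(placements):
        chrom, start, end, strand = placements[gene_id]
        info = gene_info[gene_id]
        info.update({"chromosome": chrom, "start": start, "end": end,
                     "strand": strand})
        gff.append(
            GffFeature(chrom, "gene", start, end, strand, {"ID": gene_id})
        )
        for iso_id in info["isoforms"]:
            cds_len = info["isoform_cds_lengths"][iso_id]
            gff.append(
                GffFeature(chrom, "mRNA", start, end, strand,
                           {"ID": iso_id, "Parent": gene_id})
            )
            gff.append(
                GffFeature(chrom, "CDS", start + 100,
                           start + 100 + cds_len - 1, strand,
                           {"ID": f"{iso_id}.cds", "Parent": iso_id})
            )
    gff.sort(key=lambda f: (f.seqid, f.start, {"gene": 0, "mRNA": 1, "CDS": 2}[f.type],
                            f.attributes.get("ID", "")))

    truth = _build_truth(config, families, gene_info)
    return SimResult(
        config=config, families=families, proteins=proteins, cds=cds_records,
        gff=gff, truth=truth, skipped_log=skipped,
    )


def _pair_mode(fam: Family, a: str, b: str) -> str:
    return "tandem" if fam.cluster_of[a] == fam.cluster_of[b] else "segmental"


def _build_truth(config: SimConfig, families: dict[str, Family],
                 gene_info: dict[str, dict]) -> dict:
    events = []
    for fid in sorted(families):
        for e in families[fid].events:
            events.append(
                {
                    "kind": e.kind, "branch": e.branch, "family": e.family or fid,
                    "gene_ids": e.gene_ids, "time": e.time, "details": e.details,
                }
            )
    pairs = []
    for fid in sorted(families):
        fam = families[fid]
        by_species: dict[str, list[str]] = {}
        for g in sorted(fam.cluster_of):
            by_species.setdefault(g.split("__")[0], []).append(g)
        for species in sorted(by_species):
            gs = by_species[species]
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    pairs.append(
                        {
                            "species": species, "gene_a": gs[i], "gene_b": gs[j],
                            "family": fid, "mode": _pair_mode(fam, gs[i], gs[j]),
                        }
                    )
    motif_expected: dict[str, int] = {}
    for info in gene_info.values():
        for slot in info["architecture"]:
            motif_expected[slot["hepta"]] = motif_expected.get(slot["hepta"], 0) + 1
    fam_meta = {}
    for fid in sorted(families):
        fam = families[fid]
        fam_meta[fid] = {
            "group": fam.group,
            "extinct": fam.extinct,
            "heptas": [d.hepta for d in fam.templates],
            "zf_types": [d.zf_type for d in fam.templates],
            "omega_profile": {
                k: list(v) for k, v in sorted(config.omega_profile.items())
            },
            "site_class": None if fam.site_class is None
            else [int(x) for x in fam.site_class],
            "n_genes": len(fam.cluster_of),
        }
    return {
        "genes": gene_info,
        "events": events,
        "paralog_pairs": pairs,
        "motif_expected": dict(sorted(motif_expected.items())),
        "families": fam_meta,
        "chromosome_lengths": {
            f"chr{i + 1}": config.chromosome_length
            for i in range(config.n_chromosomes)
        },
        "species": sorted(config.tree().leaf_labels()),
    }


def write_run(result: SimResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.proteins, out / "proteins.faa")
    write_fasta(result.cds, out / "cds.fna")
    write_gff3(result.gff, out / "annotation.gff3")
    write_newick(result.config.tree(), out / "species_tree.nwk")
    trees_dir = out / "gene_trees"
    trees_dir.mkdir(exist_ok=True)
    for fid in sorted(result.families):
        fam = result.families[fid]
        if not fam.extinct:
            write_newick(fam.gene_tree, trees_dir / f"{fid}.nwk")
    with open(out / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = {
        k: v for k, v in asdict(result.config).items() if k != "species_tree"
    }
    cfg["species_tree_newick"] = to_newick_string(result.config.tree())
    import yaml

    with open(out / "config_echo.yml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
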