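"""Domain-architecture event inference on the species tree.

Each species' architecture for an ortholog group is encoded as a discrete
character: the ordered list of (zinc-finger type, clade affinity) of its
domains, where affinity is the reference domain set (ortholog group +
terminal) that best matches by mean Smith-Waterman score.  Ancestral
architectures are reconstructed by parsimony (Sankoff with unit changes,
all optimal labelings enumerated); each state change along an edge is
explained by the minimal sequence of events among N/C-terminal domain
loss, domain tandem duplication, and two-gene fusion.  Equally
parsimonious placements are reported together with an ambiguity flag
rather than guessed.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Optional

from .homology import sw_score
from .trees import TreeNode

MARGIN_FLOOR_FRAC = 0.10  # affinity margin floor, fraction of the best score
MAX_REFS_PER_LABEL = 4  # reference sequences scored per label
MAX_EVENTS_PER_EDGE = 3
MAX_OPTIMAL_LABELINGS = 64

#: one domain as a character component: (zinc-finger type, affinity label)
Domain = tuple[str, str]
ArchKey = tuple[Domain, ...]


@dataclass
class ArchState:
    gene_id: str
    species: str
    domains: list[Domain]  # ordered N -> C

    def key(self) -> ArchKey:
        return tuple(self.domains)


@dataclass
class ArchEventCall:
    kind: str  # domain_loss_N | domain_loss_C | domain_tandem_dup | fusion
    group: str  # ortholog group / family id
    branches: list[str]  # candidate species-tree branches (child-node labels)
    age_interval: tuple[float, float] = (0.0, 0.0)  # (min, max) Myr of branch(es)
    supporting_genes: list[str] = field(default_factory=list)
    donor_N: str = ""
    donor_C: str = ""
    #: True when the event is absent from (or placed differently in) some
    #: equally parsimonious reconstruction
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# affinity
# ---------------------------------------------------------------------------


#: cross/self score ratio above which two reference labels are judged to
#: describe the same domain lineage and merged.  Domains of one lineage
#: diverged across the genus keep ratios >= ~0.7; unrelated domains from the
#: same subgroup (identical heptapeptide, core and literal, independent
#: spacers) reach ~0.45-0.5, and unrelated domains without a shared literal
#: stay near 0.2-0.3.
REDUNDANCY_RATIO = 0.55


def affinity_family(label: str) -> str:
    """Ortholog group a reference label belongs to (label prefix)."""
    return label.rsplit(".", 1)[0]


def build_reference_sets(
    domains_by_gene: dict[str, list[tuple[str, str, str]]],
    family_of: dict[str, str],
    redundancy_ratio: float = REDUNDANCY_RATIO,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Reference domain sets per (ortholog group, terminal position).

    ``domains_by_gene`` maps gene -> [(terminal, zf_type, sequence)].
    Candidate labels ``family.only`` / ``family.N`` / ``family.C`` (etc.)
    are collected from every gene, then pruned so that each kept label
    represents a distinct domain lineage: a label whose sequences are
    nearly identical (cross/self Smith-Waterman score ratio above the
    redundancy threshold) to an already kept label is dropped.  This
    removes both the borrowed C-terminal domain of fusion products
    (redundant with the donor group's own set) and duplicate copies of a
    tandem-duplicated domain.  Priority: single-gene-majority ``.only``
    labels, then majority N/C labels, then minority labels.

    Returns (label -> sequences, label -> zinc-finger type).
    """
    by_family: dict[str, list[str]] = {}
    for gene in sorted(domains_by_gene):
        fam = family_of.get(gene)
        if fam is not None:
            by_family.setdefault(fam, []).append(gene)
    candidates: dict[str, list[str]] = {}
    meta: dict[str, str] = {}
    majority: dict[str, bool] = {}
    for fam, genes in sorted(by_family.items()):
        arch_counts = Counter(
            tuple((t, z) for t, z, _ in domains_by_gene[g]) for g in genes
        )
        modal = min(arch_counts, key=lambda a: (-arch_counts[a], a))
        for g in genes:
            doms = domains_by_gene[g]
            is_modal = tuple((t, z) for t, z, _ in doms) == modal
            for terminal, zf_type, seq in doms:
                if zf_type == "none":
                    continue  # incomplete (Group IV) motifs carry no signal
                label = f"{fam}.{terminal}"
                candidates.setdefault(label, []).append(seq)
                meta[label] = zf_type
                majority[label] = majority.get(label, False) or is_modal
    def _priority(label: str):
        only = 0 if label.endswith(".only") else 1
        return (not majority[label], only, label)

    kept: dict[str, list[str]] = {}
    self_score: dict[str, float] = {}
    for label in sorted(candidates, key=_priority):
        rep = candidates[label][0]
        self_score[label] = sw_score(rep, rep)
        redundant = False
        for other in kept:
            cross = max(sw_score(rep, s) for s in kept[other][:3])
            # a candidate is redundant only when an existing set recovers
            # most of the candidate's own self-score (containment in a
            # shorter reference does not count)
            if self_score[label] > 0 and cross >= redundancy_ratio * self_score[label]:
                redundant = True
                break
        if not redundant:
            kept[label] = candidates[label]
    return kept, {label: meta[label] for label in kept}


def domain_affinity(
    domain_seq: str,
    reference_sets: dict[str, list[str]],
    margin_floor_frac: float = MARGIN_FLOOR_FRAC,
) -> tuple[str, float]:
    """(best reference label, margin); "ambiguous" when the margin between
    the best and runner-up mean alignment scores is below the floor."""
    if not domain_seq:
        raise ValueError("empty domain sequence")
    if not reference_sets:
        raise ValueError("empty reference sets")
    means = {}
    for label in sorted(reference_sets):
        seqs = reference_sets[label][:MAX_REFS_PER_LABEL]
        means[label] = sum(sw_score(domain_seq, s) for s in seqs) / len(seqs)
    ranked = sorted(means, key=lambda l: (-means[l], l))
    best = ranked[0]
    margin = (
        means[best] - means[ranked[1]] if len(ranked) > 1 else means[best]
    )
    if len(ranked) > 1 and margin < margin_floor_frac * max(means[best], 1e-9):
        return "ambiguous", margin
    return best, margin


def detect_fusion(
    state: ArchState, ref_meta: dict[str, str]
) -> Optional[ArchEventCall]:
    """Fusion call for a two-domain gene whose domains match two different
    single-domain ortholog groups (both affinities confident)."""
    if len(state.domains) != 2:
        return None
    (zf_n, aff_n), (zf_c, aff_c) = state.domains
    if "ambiguous" in (aff_n, aff_c):
        return None
    fam_n, fam_c = affinity_family(aff_n), affinity_family(aff_c)
    if fam_n == fam_c:
        return None
    return ArchEventCall(
        kind="fusion",
        group=state.gene_id.split("__")[-1].split("n")[0] or state.gene_id,
        branches=[state.species],
        supporting_genes=[state.gene_id],
        donor_N=fam_n,
        donor_C=fam_c,
    )


# ---------------------------------------------------------------------------
# event inference on the species tree
# ---------------------------------------------------------------------------


def _edit_events(parent: ArchKey, child: ArchKey) -> Optional[list[dict]]:
    """Minimal event sequence turning one architecture into another.

    Breadth-first search over {loss_N, loss_C, tandem duplication,
    fusion} with at most MAX_EVENTS_PER_EDGE steps; returns the event
    dicts, or None when unexplainable.
    """
    if parent == child:
        return []
    target_domains = set(child)
    start: tuple[ArchKey, tuple] = (parent, ())
    seen = {parent}
    queue = deque([start])
    while queue:
        state, ops = queue.popleft()
        if len(ops) >= MAX_EVENTS_PER_EDGE:
            continue
        moves: list[tuple[ArchKey, dict]] = []
        if len(state) >= 2:
            moves.append((state[1:], {"kind": "domain_loss_N"}))
            moves.append((state[:-1], {"kind": "domain_loss_C"}))
        if len(state) == 1:
            moves.append((state + state, {"kind": "domain_tandem_dup"}))
            for dom in sorted(target_domains):
                # fusion joins domains from two distinct ortholog groups
                if dom != state[0] and affinity_family(dom[1]) != affinity_family(
                    state[0][1]
                ):
                    moves.append(
                        (
                            state + (dom,),
                            {
                                "kind": "fusion",
                                "donor_N": affinity_family(state[0][1]),
                                "donor_C": affinity_family(dom[1]),
                            },
                        )
                    )
        for new_state, op in moves:
            if new_state == child:
                return list(ops) + [op]
            if new_state not in seen and len(new_state) <= 3:
                seen.add(new_state)
                queue.append((new_state, tuple(ops) + (op,)))
    return None


def _sankoff(
    species_tree: TreeNode,
    leaf_states: dict[str, ArchKey],
    states: list[ArchKey],
):
    """Unit-cost Sankoff DP; yields optimal full labelings (node label ->
    state), up to MAX_OPTIMAL_LABELINGS."""
    INF = float("inf")
    cost: dict[int, list[float]] = {}
    nodes = list(species_tree.postorder())
    for node in nodes:
        if node.is_leaf():
            if node.label in leaf_states:
                cost[id(node)] = [
                    0.0 if s == leaf_states[node.label] else INF for s in states
                ]
            else:
                cost[id(node)] = [0.0] * len(states)  # missing data
        else:
            vec = []
            for si in range(len(states)):
                total = 0.0
                for c in node.children:
                    total += min(
                        cost[id(c)][sj] + (0.0 if si == sj else 1.0)
                        for sj in range(len(states))
                    )
                vec.append(total)
            cost[id(node)] = vec
    best_root = min(cost[id(species_tree)])

    def enum_subtree(node: TreeNode, si: int) -> list[dict[str, ArchKey]]:
        out: list[dict[str, ArchKey]] = [{node.label: states[si]}]
        for c in node.children:
            target = min(
                cost[id(c)][sj] + (0.0 if si == sj else 1.0)
                for sj in range(len(states))
            )
            opts = [
                sj
                for sj in range(len(states))
                if cost[id(c)][sj] + (0.0 if si == sj else 1.0) == target
            ]
            new_out: list[dict[str, ArchKey]] = []
            for partial in out:
                for sj in opts:
                    for sub in enum_subtree(c, sj):
                        if len(new_out) >= MAX_OPTIMAL_LABELINGS:
                            break
                        new_out.append({**partial, **sub})
                    if len(new_out) >= MAX_OPTIMAL_LABELINGS:
                        break
                if len(new_out) >= MAX_OPTIMAL_LABELINGS:
                    break
            out = new_out
        return out

    labelings: list[dict[str, ArchKey]] = []
    for si in range(len(states)):
        if cost[id(species_tree)][si] == best_root:
            labelings.extend(enum_subtree(species_tree, si))
            if len(labelings) >= MAX_OPTIMAL_LABELINGS:
                labelings = labelings[:MAX_OPTIMAL_LABELINGS]
                break
    return labelings, best_root


def call_architecture_events(
    states_by_species: dict[str, ArchState],
    species_tree: TreeNode,
    group: str = "",
) -> list[ArchEventCall]:
    """Infer architecture events for one ortholog group.

    Species missing the gene are treated as missing data.  Events present
    in every optimal labeling at the same branch are confident; events
    whose placement varies across labelings are merged into one call with
    several candidate branches and the ambiguity flag set.
    """
    known = set(species_tree.leaf_labels())
    for sp in states_by_species:
        if sp not in known:
            raise ValueError(f"species {sp!r} absent from species tree")
    if not states_by_species:
        return []
    leaf_states = {sp: st.key() for sp, st in states_by_species.items()}
    states = sorted(set(leaf_states.values()))
    if len(states) == 1:
        return []
    ages = species_tree.node_ages()
    node_by_label = {n.label: n for n in species_tree.postorder()}
    parents = species_tree.parent_map()
    labelings, _ = _sankoff(species_tree, leaf_states, states)

    # per labeling: multiset of (kind, donor_N, donor_C, branch)
    per_labeling: list[Counter] = []
    fully_explained: list[bool] = []
    for lab in labelings:
        found: Counter = Counter()
        ok = True
        for node in species_tree.preorder():
            if node is species_tree:
                continue
            parent = parents[id(node)]
            pstate, cstate = lab[parent.label], lab[node.label]
            if pstate == cstate:
                continue
            ops = _edit_events(pstate, cstate)
            if ops is None:
                ok = False
                continue
            for op in ops:
                found[
                    (op["kind"], op.get("donor_N", ""), op.get("donor_C", ""),
                     node.label)
                ] += 1
        per_labeling.append(found)
        fully_explained.append(ok)
    # prefer reconstructions whose every state change has an event
    # explanation; fall back to all reconstructions otherwise
    if any(fully_explained):
        per_labeling = [
            f for f, ok in zip(per_labeling, fully_explained) if ok
        ]

    confident: Counter = per_labeling[0].copy()
    for found in per_labeling[1:]:
        confident &= found
    leftovers: dict[tuple, set[str]] = {}
    for found in per_labeling:
        extra = found - confident
        for (kind, dn, dc, branch), count in extra.items():
            leftovers.setdefault((kind, dn, dc), set()).add(branch)

    def _call(kind, dn, dc, branches, ambiguous):
        lo = min(ages[id(node_by_label[b])] for b in branches)
        hi = max(ages[id(parents[id(node_by_label[b])])] for b in branches)
        supporting = sorted(
            st.gene_id
            for st in states_by_species.values()
            if _supports(st.key(), kind, dn, dc)
        )
        return ArchEventCall(
            kind=kind, group=group, branches=sorted(branches),
            age_interval=(round(lo, 4), round(hi, 4)),
            supporting_genes=supporting, donor_N=dn, donor_C=dc,
            ambiguous=ambiguous,
        )

    calls: list[ArchEventCall] = []
    for (kind, dn, dc, branch), count in sorted(confident.items()):
        for _ in range(count):
            calls.append(_call(kind, dn, dc, [branch], ambiguous=False))
    for (kind, dn, dc) in sorted(leftovers):
        calls.append(
            _call(kind, dn, dc, sorted(leftovers[(kind, dn, dc)]),
                  ambiguous=True)
        )
    return calls


def _supports(state: ArchKey, kind: str, donor_n: str, donor_c: str) -> bool:
    if kind == "fusion":
        return (
            len(state) == 2
            and affinity_family(state[0][1]) == donor_n
            and affinity_family(state[1][1]) == donor_c
        )
    if kind == "domain_tandem_dup":
        return len(state) >= 2 and state[0][1] == state[1][1]
    if kind.startswith("domain_loss"):
        return len(state) == 1
    return False
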