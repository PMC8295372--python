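"""Gene-tree construction and duplication-loss reconciliation.

Gene trees come from neighbor joining on Poisson-corrected protein
distances (with column-resampling bootstrap), or are imported as Newick.
Rooted gene trees are embedded in the rooted species tree by the LCA
mapping; internal nodes become duplications when their image equals a
child's image, losses are counted by the path-depth rule, and the
reconciliation cost is c_D * duplications + c_L * losses with default
weights 1.5 and 1.0.  Weakly supported edges (bootstrap below a
threshold, default 50) may be rearranged by greedy nearest-neighbor
interchange to the minimum-cost alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .trees import TreeNode


@dataclass
class ReconWeights:
    c_dup: float = 1.5
    c_loss: float = 1.0
    support_threshold: float = 50.0  # on [0, 100]


@dataclass
class ReconciledTree:
    gene_tree: TreeNode
    species_map: dict[int, TreeNode]  # id(gene node) -> species node
    events: dict[int, str]  # id(gene node) -> speciation | duplication | leaf
    losses: list[tuple[str, int]]  # (species node label, count)
    n_dup: int = 0
    n_loss: int = 0
    cost: float = 0.0

    def duplication_nodes(self) -> list[TreeNode]:
        return [
            n
            for n in self.gene_tree.postorder()
            if self.events.get(id(n)) == "duplication"
        ]


def default_species_of(label: str) -> str:
    """Gene leaves are named ``species__geneN`` by convention."""
    return label.split("__")[0]


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def protein_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p) over shared non-gap columns."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not shared:
        raise ValueError("no shared non-gap columns")
    p = sum(1 for x, y in shared if x != y) / len(shared)
    if p >= 1.0:
        raise ValueError("saturated: p >= 1")
    return -math.log(1.0 - p)


def distance_matrix(records) -> tuple[list[str], np.ndarray]:
    """Pairwise Poisson distances over an aligned set, taxa sorted by id."""
    recs = sorted(records, key=lambda r: r.id)
    ids = [r.id for r in recs]
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = protein_distance(recs[i].residues, recs[j].residues)
    return ids, D


def nj_tree(labels: list[str], D: np.ndarray) -> TreeNode:
    """Canonical neighbor joining (Saitou & Nei) with deterministic ties.

    Requires a symmetric matrix with zero diagonal and n >= 3.  Ties in
    the Q criterion are broken by the lexicographically smallest pair of
    clade labels.  Returns a tree whose root is the final trifurcation
    (the standard unrooted resolution); negative branch lengths are
    clamped to zero.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.any(~np.isfinite(D)) or np.any(D < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in labels}
    key: dict[str, str] = {lab: lab for lab in labels}  # tie-break key
    d = {frozenset((a, b)): D[i, j] for i, a in enumerate(labels)
         for j, b in enumerate(labels) if i < j}
    active = sorted(labels)
    serial = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * d[frozenset((a, b))] - r[a] - r[b]
            tie = tuple(sorted((key[a], key[b])))
            if best is None or (q, tie) < (best[0], best[1]):
                best = (q, tie, a, b)
        _, _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        na.branch_length = max(la, 0.0)
        nb.branch_length = max(lb, 0.0)
        serial += 1
        u = f"__nj{serial}"
        nodes[u] = TreeNode(children=[na, nb])
        key[u] = min(key[a], key[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((u, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
        active = sorted((set(active) - {a, b}) | {u}, key=lambda x: key[x])
    a, b, c = sorted(active, key=lambda x: key[x])
    dab, dac, dbc = d[frozenset((a, b))], d[frozenset((a, c))], d[frozenset((b, c))]
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].branch_length = max(0.5 * (dab + dac - dbc), 0.0)
    nodes[b].branch_length = max(0.5 * (dab + dbc - dac), 0.0)
    nodes[c].branch_length = max(0.5 * (dac + dbc - dab), 0.0)
    return root


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels."""
    all_leaves = frozenset(tree.leaf_labels())
    out = set()
    for n in tree.postorder():
        if n is tree or n.is_leaf():
            continue
        side = frozenset(n.leaf_labels())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        other = all_leaves - side
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap_support(records, n_reps: int, seed: int) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Builds the reference NJ tree on the full alignment, then resamples
    columns with replacement ``n_reps`` times; each internal edge's
    support is the percentage of replicate trees containing its
    bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    recs = sorted(records, key=lambda r: r.id)
    width = len(recs[0].residues)
    labels, D = distance_matrix(recs)
    tree = nj_tree(labels, D)
    all_leaves = frozenset(labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        resampled = [
            type(r)(r.id, r.description, "".join(r.residues[c] for c in cols))
            for r in recs
        ]
        try:
            _, Db = distance_matrix(resampled)
            rep = nj_tree(labels, Db)
        except ValueError:
            continue
        for bip in _bipartitions(rep):
            counts[bip] = counts.get(bip, 0) + 1
    for n in tree.postorder():
        if n is tree or n.is_leaf():
            continue
        side = frozenset(n.leaf_labels())
        other = all_leaves - side
        bip = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        n.support = round(100.0 * counts.get(bip, 0) / n_reps, 1)
    return tree


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------


def lca_reconcile(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    species_of: Callable[[str], str] = default_species_of,
    weights: Optional[ReconWeights] = None,
) -> ReconciledTree:
    """Duplication-loss reconciliation by the LCA mapping.

    Each internal gene node maps to the LCA of its children's images and
    is a duplication iff its image equals a child's image.  Losses on the
    gene edge (u, v) number depth(M(v)) - depth(M(u)) - 1, plus one if u
    is a duplication (the path-depth rule).  The LCA mapping minimizes
    the weighted cost for any positive weights.
    """
    w = weights or ReconWeights()
    table = species_tree.lca_table()
    sp_node = {n.label: n for n in species_tree.postorder()}
    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    for leaf in gene_tree.leaves():
        sp = species_of(leaf.label)
        if sp not in sp_node:
            raise ValueError(f"gene leaf {leaf.label!r} maps to unknown species {sp!r}")
        mapping[id(leaf)] = sp_node[sp]
        events[id(leaf)] = "leaf"
    n_dup = 0
    for node in gene_tree.postorder():
        if node.is_leaf():
            continue
        image = mapping[id(node.children[0])]
        for c in node.children[1:]:
            image = table.lca(image, mapping[id(c)])
        mapping[id(node)] = image
        if any(mapping[id(c)] is image for c in node.children):
            events[id(node)] = "duplication"
            n_dup += 1
        else:
            events[id(node)] = "speciation"
    # losses by the path-depth rule
    loss_counts: dict[str, int] = {}
    n_loss = 0
    for node in gene_tree.postorder():
        if node.is_leaf():
            continue
        is_dup = events[id(node)] == "duplication"
        for c in node.children:
            depth_gap = table.edge_distance(mapping[id(node)], mapping[id(c)])
            n_here = depth_gap - (0 if is_dup else 1)
            if n_here > 0:
                n_loss += n_here
                # attribute losses to the species branches skipped on the path
                sp = mapping[id(c)]
                path = []
                while sp is not mapping[id(node)]:
                    path.append(sp)
                    sp = table.parent[id(sp)]
                skipped = path[1:] if not is_dup else path
                for s in skipped[:n_here]:
                    lab = s.label or "<unnamed>"
                    loss_counts[lab] = loss_counts.get(lab, 0) + 1
    cost = w.c_dup * n_dup + w.c_loss * n_loss
    return ReconciledTree(
        gene_tree=gene_tree,
        species_map=mapping,
        events=events,
        losses=sorted(loss_counts.items()),
        n_dup=n_dup,
        n_loss=n_loss,
        cost=cost,
    )


# ---------------------------------------------------------------------------
# rooting and rearrangement
# ---------------------------------------------------------------------------


def _topology_signature(tree: TreeNode):
    def sig(n):
        if n.is_leaf():
            return n.label
        return "(" + ",".join(sorted(sig(c) for c in n.children)) + ")"

    return sig(tree)


def _adjacency(tree: TreeNode):
    """Undirected view: node -> [(neighbor, edge length, edge support)].

    Edge attributes come from the child side of each rooted edge.
    """
    adj: dict[int, list] = {id(n): [] for n in tree.postorder()}
    for n in tree.preorder():
        for c in n.children:
            adj[id(n)].append((c, c.branch_length, c.support))
            adj[id(c)].append((n, c.branch_length, c.support))
    return adj


def _grow(node: TreeNode, came_from: Optional[TreeNode], adj) -> TreeNode:
    """Rebuild the subtree rooted at ``node`` growing away from ``came_from``;
    unary pass-through nodes (the abandoned old root) are collapsed."""
    out_children = []
    for nbr, length, support in adj[id(node)]:
        if came_from is not None and nbr is came_from:
            continue
        child = _grow(nbr, node, adj)
        child.branch_length = (
            length if child.branch_length is None
            else child.branch_length + (length or 0.0)
        )
        if not child.is_leaf() and child.support is None:
            child.support = support
        out_children.append(child)
    if node.is_leaf():
        return TreeNode(label=node.label)
    if len(out_children) == 1:
        return out_children[0]  # collapse; caller adds the edge length
    return TreeNode(label=node.label, children=out_children)


def _rootings(tree: TreeNode):
    """All distinct rooted versions of a tree (one per edge).

    Accepts a rooted binary tree or a trifurcating NJ tree; branch
    lengths are preserved in sum and the chosen edge is split in half.
    """
    adj = _adjacency(tree)
    seen = set()
    for parent in tree.preorder():
        for child in parent.children:
            half = None if child.branch_length is None else child.branch_length / 2.0
            top = _grow(parent, child, adj)
            bottom = _grow(child, parent, adj)
            top.branch_length = (half or 0.0) + (top.branch_length or 0.0) \
                if top.branch_length is not None or half is not None else None
            bottom.branch_length = (half or 0.0) + (bottom.branch_length or 0.0) \
                if bottom.branch_length is not None or half is not None else None
            rooted = TreeNode(children=[top, bottom])
            sig = _topology_signature(rooted)
            if sig not in seen:
                seen.add(sig)
                yield rooted


def root_by_reconciliation(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    species_of: Callable[[str], str] = default_species_of,
    weights: Optional[ReconWeights] = None,
) -> tuple[TreeNode, ReconciledTree]:
    """Choose the rooting minimizing reconciliation cost (ties resolved by
    deterministic edge order)."""
    best = None
    for rooted in _rootings(gene_tree):
        rec = lca_reconcile(rooted, species_tree, species_of, weights)
        if best is None or rec.cost < best[1].cost:
            best = (rooted, rec)
    if best is None:
        raise ValueError("tree has no edges to root on")
    return best


def _node_at(tree: TreeNode, path: tuple[int, ...]) -> TreeNode:
    node = tree
    for i in path:
        node = node.children[i]
    return node


def _nni_alternatives(tree: TreeNode, path: tuple[int, ...]):
    """The <= 2 NNI rearrangements around the edge above the internal
    non-root node at ``path``: each swaps one of its children with its
    sibling."""
    if not path:
        return
    v = _node_at(tree, path)
    p = _node_at(tree, path[:-1])
    if v.is_leaf() or len(p.children) != 2:
        return
    v_idx = path[-1]
    s_idx = 1 - v_idx
    for k in range(len(v.children)):
        alt = tree.copy()
        ap = _node_at(alt, path[:-1])
        av = ap.children[v_idx]
        a_sib = ap.children[s_idx]
        moved = av.children[k]
        av.children[k] = a_sib
        ap.children[s_idx] = moved
        yield alt


def rearrange_weak_edges(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    species_of: Callable[[str], str] = default_species_of,
    weights: Optional[ReconWeights] = None,
) -> tuple[TreeNode, float, float]:
    """Greedy NNI over weakly supported edges, minimizing reconciliation cost.

    Only internal edges whose support is present and below the threshold
    are eligible; each round applies the single most cost-reducing NNI
    and stops when none improves (ties keep the current tree).  Returns
    (tree, cost before, cost after).
    """
    w = weights or ReconWeights()
    current = gene_tree.copy()
    cost0 = lca_reconcile(current, species_tree, species_of, w).cost
    cost = cost0

    def weak_paths(tree):
        out = []

        def walk(n, path):
            for i, c in enumerate(n.children):
                child_path = path + (i,)
                if (
                    not c.is_leaf()
                    and c.support is not None
                    and c.support < w.support_threshold
                ):
                    out.append(child_path)
                walk(c, child_path)

        walk(tree, ())
        return out

    for _ in range(64):  # cost strictly decreases; terminates early
        best_alt, best_cost = None, cost
        for path in weak_paths(current):
            for alt in _nni_alternatives(current, path):
                c = lca_reconcile(alt, species_tree, species_of, w).cost
                if c < best_cost:
                    best_alt, best_cost = alt, c
        if best_alt is None:
            break
        current, cost = best_alt, best_cost
    return current, cost0, cost


# ---------------------------------------------------------------------------
# duplication screen
# ---------------------------------------------------------------------------


def duplication_screen(reconciliations: dict[str, ReconciledTree]) -> list[dict]:
    """Per-family duplication nodes with their species branch and the
    descendant gene-tree branches (the foreground sets handed to the
    branch-model selection screen)."""
    rows = []
    for family in sorted(reconciliations):
        rec = reconciliations[family]
        for k, node in enumerate(rec.duplication_nodes()):
            rows.append(
                {
                    "family": family,
                    "dup_node": f"{family}.d{k + 1}",
                    "species_branch": rec.species_map[id(node)].label or "<root>",
                    "descendant_branches": [
                        frozenset(c.leaf_labels()) for c in node.children
                    ],
                }
            )
    return rows
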