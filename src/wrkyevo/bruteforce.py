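"""Independent brute-force reference implementations used for validation.

These deliberately avoid the algorithms used by the main modules:
reconciliation cost by exhaustive enumeration of all valid species-map
assignments, phylogenetic likelihood by exhaustive summation over
internal-node states, and NG86 counting by explicit enumeration of
mutational pathways (position permutations).  They are only practical on
tiny inputs and exist as oracles for the fast implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .reconcile import ReconWeights, default_species_of
from .selection.codon import BASES, GENETIC_CODE, STOP_CODONS
from .trees import TreeNode


# ---------------------------------------------------------------------------
# reconciliation by exhaustive mapping enumeration
# ---------------------------------------------------------------------------


def bruteforce_reconcile_cost(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    species_of=default_species_of,
    weights: ReconWeights | None = None,
) -> float:
    """Minimum weighted duplication-loss cost over all valid monotone
    mappings of gene-tree nodes onto species-tree nodes."""
    w = weights or ReconWeights()
    table = species_tree.lca_table()
    sp_nodes = list(species_tree.postorder())
    sp_by_label = {n.label: n for n in sp_nodes}
    gene_nodes = list(gene_tree.postorder())
    internal = [n for n in gene_nodes if not n.is_leaf()]
    fixed = {}
    for leaf in gene_tree.leaves():
        fixed[id(leaf)] = sp_by_label[species_of(leaf.label)]

    def cost_of(assignment: dict[int, TreeNode]) -> float | None:
        mapping = {**fixed, **assignment}
        n_dup = n_loss = 0
        for u in internal:
            images = [mapping[id(c)] for c in u.children]
            mu = mapping[id(u)]
            for img in images:
                if not table.is_ancestor_or_self(mu, img):
                    return None
            lca = images[0]
            for img in images[1:]:
                lca = table.lca(lca, img)
            if not table.is_ancestor_or_self(mu, lca):
                return None
            is_dup = (mu is not lca) or any(img is mu for img in images)
            if is_dup:
                n_dup += 1
            for img in images:
                d = table.depth[id(img)] - table.depth[id(mu)]
                n_loss += d - (0 if is_dup else 1)
        return w.c_dup * n_dup + w.c_loss * n_loss

    best = math.inf
    for combo in itertools.product(sp_nodes, repeat=len(internal)):
        assignment = {id(n): s for n, s in zip(internal, combo)}
        c = cost_of(assignment)
        if c is not None and c < best:
            best = c
    return best


def enumerate_rooted_topologies(leaves: list[str]) -> list[TreeNode]:
    """All rooted binary tree topologies over the given (distinct) leaf
    labels."""
    if len(leaves) == 1:
        return [TreeNode(label=leaves[0])]
    out = []
    first, rest = leaves[0], leaves[1:]
    # non-empty proper subsets of `rest` joined with `first` on the left
    for r in range(0, len(rest)):
        for left_rest in itertools.combinations(rest, r):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in enumerate_rooted_topologies([first, *left_rest]):
                for rt in enumerate_rooted_topologies(right):
                    out.append(TreeNode(children=[lt.copy(), rt.copy()]))
    return out


# ---------------------------------------------------------------------------
# exhaustive likelihood
# ---------------------------------------------------------------------------


def bruteforce_site_likelihood(
    tree: TreeNode,
    leaf_states: dict[str, int],
    pi: np.ndarray,
    transition,
) -> float:
    """Likelihood of one site by summing over every assignment of states
    to internal nodes.  ``transition(t)`` returns the transition matrix
    for a branch of length t."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf()]
    n_states = len(pi)
    P = {
        id(n): transition(n.branch_length or 0.0) for n in nodes if n is not tree
    }
    # explicit sum over every internal-state assignment, laid out as one
    # axis per internal node (vectorized but still a full enumeration)
    axis = {id(n): k for k, n in enumerate(internal)}
    grids = np.indices((n_states,) * len(internal))
    prob = pi[grids[axis[id(tree)]]].astype(float)
    for n in nodes:
        for c in n.children:
            parent_idx = grids[axis[id(n)]]
            if c.is_leaf():
                prob = prob * P[id(c)][parent_idx, leaf_states[c.label]]
            else:
                prob = prob * P[id(c)][parent_idx, grids[axis[id(c)]]]
    return float(prob.sum())


# ---------------------------------------------------------------------------
# NG86 by explicit pathway enumeration
# ---------------------------------------------------------------------------


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: per position,
    the fraction of the three alternative bases giving a synonymous
    change (stops nonsynonymous); total sites per codon = 3."""
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def oracle_codon_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over every
    position-permutation pathway between two codons, equal weights."""
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0
    paths = list(itertools.permutations(diff))
    syn = nonsyn = 0.0
    for path in paths:
        current = codon1
        for pos in path:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            aa1 = GENETIC_CODE.get(current)
            aa2 = GENETIC_CODE.get(nxt)
            if aa1 is not None and aa1 == aa2:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
    return syn / len(paths), nonsyn / len(paths)


def oracle_ng86_counts(
    codons_a: list[str], codons_b: list[str]
) -> tuple[float, float, float, float]:
    """(S sites, N sites, S diffs, N diffs) for two codon sequences."""
    S = N = Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b, strict=True):
        sa, na = oracle_codon_sites(a)
        sb, nb = oracle_codon_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = oracle_codon_diffs(a, b)
        Sd += ds
        Nd += dn
    return S, N, Sd, Nd
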