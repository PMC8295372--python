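"""GY94-style codon rate matrices and Felsenstein pruning.

The instantaneous rate between codons differing at one position is
pi_j * (kappa if transition) * (omega if nonsynonymous); multi-step
changes have rate zero.  Matrices are scaled to one expected substitution
per codon per unit time, and the process is time-reversible, so
transition matrices are computed through a symmetric eigendecomposition.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .codon import BASES, CODONS, GENETIC_CODE, N_CODONS, is_transition

# single-step neighbor structure, built once:
#   (i, j, transition?, synonymous?) for all ordered pairs i != j
_PAIR_I: list[int] = []
_PAIR_J: list[int] = []
_PAIR_TS: list[bool] = []
_PAIR_SYN: list[bool] = []
for _i, _a in enumerate(CODONS):
    for _j, _b in enumerate(CODONS):
        if _i == _j:
            continue
        diffs = [(x, y) for x, y in zip(_a, _b) if x != y]
        if len(diffs) != 1:
            continue
        _PAIR_I.append(_i)
        _PAIR_J.append(_j)
        _PAIR_TS.append(is_transition(*diffs[0]))
        _PAIR_SYN.append(GENETIC_CODE[_a] == GENETIC_CODE[_b])
PAIR_I = np.array(_PAIR_I)
PAIR_J = np.array(_PAIR_J)
PAIR_TS = np.array(_PAIR_TS)
PAIR_SYN = np.array(_PAIR_SYN)


def f1x4_frequencies(codon_matrix_or_seqs) -> np.ndarray:
    """F1x4 codon frequencies from observed nucleotide composition.

    Accepts an iterable of codon strings (gaps ignored).  pi_codon is
    proportional to the product of its nucleotide frequencies, normalized
    over the 61 sense codons.
    """
    counts = dict.fromkeys(BASES, 1.0)  # pseudocount
    for codon in codon_matrix_or_seqs:
        for ch in codon:
            if ch in counts:
                counts[ch] += 1.0
    total = sum(counts.values())
    f = {b: counts[b] / total for b in BASES}
    pi = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in CODONS])
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled 61x61 generator; rows sum to zero; mean rate 1."""
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be positive and sum to 1")
    q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_SYN, 1.0, omega)
    q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    if scale > 0:
        q /= scale
    return q


class CodonMatrix:
    """Eigendecomposed reversible codon rate matrix.

    ``transition(t)`` returns P(t) = exp(Qt); an optional allowed-state
    mask restricts the target alphabet (used by the sequence simulator to
    keep structurally constrained sites away from C/H/W residues)."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray,
                 allowed: Optional[np.ndarray] = None):
        self.kappa, self.omega = kappa, omega
        q = codon_rate_matrix(kappa, omega, pi)
        if allowed is not None:
            q = q.copy()
            q[:, ~allowed] = 0.0
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            # restricted process is no longer reversible wrt pi; fall back
            # to dense eigendecomposition
            self._general = True
            vals, vecs = np.linalg.eig(q)
            self._vals, self._vecs = vals, vecs
            self._vecs_inv = np.linalg.inv(vecs)
        else:
            self._general = False
            d = np.sqrt(pi)
            sym = (q * d[:, None]) / d[None, :]
            vals, vecs = np.linalg.eigh(0.5 * (sym + sym.T))
            self._vals = vals
            self._left = vecs / d[:, None]  # D^{-1/2} U
            self._right = (vecs * d[:, None]).T  # U^T D^{1/2}
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        if self._general:
            p = (self._vecs * np.exp(self._vals * t)) @ self._vecs_inv
            p = np.real(p)
        else:
            p = (self._left * np.exp(self._vals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a whole vector of branch lengths: (len(ts), 61, 61)."""
        if self._general:
            return np.array([self.transition(t) for t in ts])
        scaled = self._left[None, :, :] * np.exp(
            self._vals[None, None, :] * np.asarray(ts)[:, None, None]
        )
        p = scaled @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


class PruningEngine:
    """Felsenstein pruning over a fixed rooted tree and codon alignment.

    Gaps/missing data enter as all-ones partials (summed over states).
    Branch lengths are expected substitutions per codon.
    """

    def __init__(self, tree, taxa: Sequence[str]):
        self.taxa = list(taxa)
        nodes = list(tree.postorder())
        self.n_nodes = len(nodes)
        self.node_index = {id(n): k for k, n in enumerate(nodes)}
        self.children: list[list[int]] = [
            [self.node_index[id(c)] for c in n.children] for n in nodes
        ]
        self.branch_lengths = np.array(
            [n.branch_length if n.branch_length is not None else 0.0 for n in nodes]
        )
        self.root = self.n_nodes - 1
        self.leaf_rows: dict[int, int] = {}
        labels = {t: i for i, t in enumerate(self.taxa)}
        for k, n in enumerate(nodes):
            if n.is_leaf():
                if n.label not in labels:
                    raise ValueError(f"tree leaf {n.label!r} absent from alignment")
                self.leaf_rows[k] = labels[n.label]
        if len(self.leaf_rows) != len(self.taxa):
            raise ValueError("tree leaves and alignment taxa differ")
        self.nodes = nodes

    # -- likelihood --------------------------------------------------------

    def _partials(self, X: np.ndarray, probs: list[np.ndarray]):
        """Per-site root partials and log scaling, for one rate class.

        ``X`` is (n_taxa, n_sites) of codon indices with -1 for gaps;
        ``probs[k]`` is the transition matrix on the branch above node k.
        """
        n_sites = X.shape[1]
        logscale = np.zeros(n_sites)
        partial: list[Optional[np.ndarray]] = [None] * self.n_nodes
        for k in range(self.n_nodes):
            if not self.children[k]:
                row = X[self.leaf_rows[k]]
                p = np.zeros((N_CODONS, n_sites))
                gap = row < 0
                p[:, gap] = 1.0
                obs = ~gap
                p[row[obs], np.nonzero(obs)[0]] = 1.0
                partial[k] = p
            else:
                p = np.ones((N_CODONS, n_sites))
                for c in self.children[k]:
                    p *= probs[c] @ partial[c]
                    partial[c] = None
                m = p.max(axis=0)
                m[m == 0.0] = 1.0
                p /= m
                logscale += np.log(m)
                partial[k] = p
        return partial[self.root], logscale

    def site_likelihoods(
        self,
        X: np.ndarray,
        matrices: Sequence[CodonMatrix],
        branch_lengths: Optional[np.ndarray] = None,
        branch_class: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Per-site likelihoods for each rate class: array (n_classes, n_sites).

        ``branch_class`` optionally assigns one matrix per branch (branch
        models); otherwise each class applies on every branch (site
        models).
        """
        bl = self.branch_lengths if branch_lengths is None else branch_lengths
        out = []
        if branch_class is not None:
            probs = [
                matrices[branch_class[k]].transition(bl[k])
                for k in range(self.n_nodes)
            ]
            root_partial, logscale = self._partials(X, probs)
            lik = matrices[0].pi @ root_partial
            return (lik * np.exp(logscale))[None, :]
        for mat in matrices:
            probs = mat.transitions(bl)
            root_partial, logscale = self._partials(X, probs)
            lik = mat.pi @ root_partial
            out.append(lik * np.exp(logscale))
        return np.array(out)

    def log_likelihood_mixture(
        self,
        X: np.ndarray,
        weights: np.ndarray,
        matrices: Sequence[CodonMatrix],
        branch_lengths: Optional[np.ndarray] = None,
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """(total lnL, per-site lnL, per-class per-site likelihoods)."""
        class_liks = self.site_likelihoods(X, matrices, branch_lengths)
        site_lik = weights @ class_liks
        if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
            bad = int(np.argmin(site_lik))
            raise FloatingPointError(f"non-finite likelihood at site {bad}")
        site_lnl = np.log(site_lik)
        return float(site_lnl.sum()), site_lnl, class_liks

    # -- simulation --------------------------------------------------------

    def evolve(
        self,
        rng: np.random.Generator,
        site_matrices: Sequence[CodonMatrix],
        site_class: np.ndarray,
        branch_lengths: Optional[np.ndarray] = None,
        branch_class: Optional[np.ndarray] = None,
        root_states: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Sample codon states at the leaves: array (n_taxa, n_sites).

        ``site_class[s]`` picks the matrix for site s (ignored on branches
        where ``branch_class`` overrides the matrix choice for all sites).
        """
        bl = self.branch_lengths if branch_lengths is None else branch_lengths
        n_sites = len(site_class)
        states = np.empty((self.n_nodes, n_sites), dtype=np.int64)
        if root_states is None:
            pi = site_matrices[0].pi
            root_states = rng.choice(N_CODONS, size=n_sites, p=pi)
        order = list(range(self.n_nodes - 1, -1, -1))  # root first (postorder rev)
        states[self.root] = root_states
        for k in order:
            for c in self.children[k]:
                child = np.empty(n_sites, dtype=np.int64)
                if branch_class is not None:
                    mats = [site_matrices[branch_class[c]]] * len(site_matrices)
                else:
                    mats = site_matrices
                for ci in range(len(site_matrices)):
                    sel = site_class == ci
                    if not sel.any():
                        continue
                    P = mats[ci].transition(bl[c])
                    cum = P[states[k][sel]].cumsum(axis=1)
                    u = rng.random(sel.sum())
                    child[sel] = (u[:, None] > cum).sum(axis=1)
                states[c] = child
        rows = np.empty((len(self.taxa), n_sites), dtype=np.int64)
        for k, row in self.leaf_rows.items():
            rows[row] = states[k]
        return rows
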