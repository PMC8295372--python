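"""Maximum-likelihood fitting of codon site and branch models.

Site models: M0 (one ratio), M1a (nearly neutral: 0 <= omega0 < 1 and
omega = 1), M2a (adds omega2 > 1), M7 (10-class discretized Beta on
omega <= 1), M8 (M7 plus one class with omega_s > 1).  Branch model:
two-ratio (background omega0, foreground omega1) against M0.  Paired
LRTs (M1a vs M2a, M7 vs M8, df 2; two-ratio vs M0, df 1) test for
positive selection; per-site identification uses Naive Empirical Bayes
posteriors over the fitted site classes.

Optimization: bounded L-BFGS-B with seeded random restarts; kappa in
[0.1, 20], omega in [1e-4, 99]; branch lengths either taken from the
input tree, estimated under M0, or fixed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .likelihood import CodonMatrix, PruningEngine, f1x4_frequencies, uniform_frequencies

OMEGA_BOUNDS = (1e-4, 99.0)
KAPPA_BOUNDS = (0.1, 20.0)
PROP_BOUNDS = (1e-4, 1.0 - 1e-4)
BETA_BOUNDS = (5e-2, 99.0)
BL_LOG_BOUNDS = (np.log(1e-6), np.log(20.0))
LRT_TOLERANCE = 0.5

MODEL_DF = {"M0": 2, "M1a": 3, "M2a": 5, "M7": 3, "M8": 5, "branch2": 3}


@dataclass
class SelectionFit:
    model_id: str
    params: dict[str, float]
    lnL: float
    class_weights: np.ndarray
    class_omegas: np.ndarray
    site_class_liks: Optional[np.ndarray] = None  # (n_classes, n_sites)
    converged: bool = True
    branch_lengths: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)


def _beta_class_omegas(p: float, q: float, n_classes: int = 10) -> np.ndarray:
    quantiles = (2 * np.arange(n_classes) + 1) / (2 * n_classes)
    return stats.beta.ppf(quantiles, p, q)


def _resolve_pi(pi, X) -> np.ndarray:
    if isinstance(pi, np.ndarray):
        return pi
    if pi in (None, "f1x4"):
        from .codon import CODONS

        seqs = [CODONS[i] for i in X.ravel() if i >= 0]
        return f1x4_frequencies(seqs)
    if pi == "uniform":
        return uniform_frequencies()
    raise ValueError(f"unknown codon frequency mode {pi!r}")


def _model_structure(model_id: str, theta: np.ndarray):
    """Map a parameter vector to (kappa, class weights, class omegas)."""
    if model_id == "M0":
        kappa, omega = theta
        return kappa, np.array([1.0]), np.array([omega])
    if model_id == "M1a":
        kappa, p0, omega0 = theta
        return kappa, np.array([p0, 1 - p0]), np.array([omega0, 1.0])
    if model_id == "M2a":
        kappa, p0, p1f, omega0, omega2 = theta
        p1 = (1 - p0) * p1f
        p2 = 1 - p0 - p1
        return kappa, np.array([p0, p1, p2]), np.array([omega0, 1.0, omega2])
    if model_id == "M7":
        kappa, p, q = theta
        omegas = _beta_class_omegas(p, q)
        return kappa, np.full(10, 0.1), omegas
    if model_id == "M8":
        kappa, p, q, p0, omega_s = theta
        omegas = np.append(_beta_class_omegas(p, q), omega_s)
        weights = np.append(np.full(10, p0 / 10), 1 - p0)
        return kappa, weights, omegas
    raise ValueError(f"unknown model {model_id!r}")


_INITS = {
    "M0": [2.0, 0.4],
    "M1a": [2.0, 0.7, 0.2],
    "M2a": [2.0, 0.6, 0.5, 0.2, 3.0],
    "M7": [2.0, 0.5, 1.5],
    "M8": [2.0, 0.5, 1.5, 0.9, 3.0],
}

_BOUNDS = {
    "M0": [KAPPA_BOUNDS, OMEGA_BOUNDS],
    "M1a": [KAPPA_BOUNDS, PROP_BOUNDS, (1e-4, 1.0)],
    "M2a": [KAPPA_BOUNDS, PROP_BOUNDS, PROP_BOUNDS, (1e-4, 1.0), (1.0, 99.0)],
    "M7": [KAPPA_BOUNDS, BETA_BOUNDS, BETA_BOUNDS],
    "M8": [KAPPA_BOUNDS, BETA_BOUNDS, BETA_BOUNDS, PROP_BOUNDS, (1.0, 99.0)],
}

_PARAM_NAMES = {
    "M0": ["kappa", "omega"],
    "M1a": ["kappa", "p0", "omega0"],
    "M2a": ["kappa", "p0", "p1_frac", "omega0", "omega2"],
    "M7": ["kappa", "beta_p", "beta_q"],
    "M8": ["kappa", "beta_p", "beta_q", "p0", "omega_s"],
}


def _random_init(model_id: str, rng: np.random.Generator) -> list[float]:
    init = []
    for name, (lo, hi) in zip(_PARAM_NAMES[model_id], _BOUNDS[model_id]):
        if name == "kappa":
            init.append(rng.uniform(1.0, 5.0))
        elif name.startswith("omega") or name == "omega_s":
            init.append(float(np.clip(np.exp(rng.uniform(-3.0, 1.2)), lo, hi)))
        elif name.startswith("beta"):
            init.append(rng.uniform(0.2, 3.0))
        else:
            init.append(rng.uniform(0.2, 0.9))
    return init


def fit_model(
    alignment: CodonAlignment | np.ndarray,
    tree,
    model_id: str,
    pi="f1x4",
    branch_lengths: Optional[np.ndarray] = None,
    optimize_branch_lengths: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    engine: Optional[PruningEngine] = None,
) -> SelectionFit:
    """Fit one codon site model by bounded quasi-Newton with restarts.

    Branch lengths (expected substitutions/codon) are taken from the tree
    unless ``branch_lengths`` overrides them or ``optimize_branch_lengths``
    estimates them jointly (recommended once, under M0, then fixed for the
    other site models).
    """
    if isinstance(alignment, CodonAlignment):
        X = alignment.to_matrix()
        taxa = alignment.taxa
    else:
        X = alignment
        taxa = None
    if engine is None:
        engine = PruningEngine(tree, taxa if taxa is not None else tree.leaf_labels())
    if X.shape[0] < 3:
        raise ValueError("alignment must have >= 3 taxa")
    pi_vec = _resolve_pi(pi, X)
    base_bl = engine.branch_lengths if branch_lengths is None else np.asarray(branch_lengths)
    n_bl = engine.n_nodes

    names = _PARAM_NAMES[model_id]
    bounds = list(_BOUNDS[model_id])
    if optimize_branch_lengths:
        bounds += [BL_LOG_BOUNDS] * n_bl

    def unpack(theta):
        core = theta[: len(names)]
        kappa, weights, omegas = _model_structure(model_id, core)
        bl = np.exp(theta[len(names):]) if optimize_branch_lengths else base_bl
        if optimize_branch_lengths:
            bl = bl.copy()
            bl[engine.root] = 0.0
        return kappa, weights, omegas, bl

    def negloglik(theta):
        kappa, weights, omegas, bl = unpack(theta)
        mats = [CodonMatrix(kappa, w, pi_vec) for w in omegas]
        try:
            lnl, _, _ = engine.log_likelihood_mixture(X, weights, mats, bl)
        except FloatingPointError:
            return 1e12
        return -lnl

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        init = list(_INITS[model_id]) if r == 0 else _random_init(model_id, rng)
        if optimize_branch_lengths:
            init = init + list(np.log(np.clip(base_bl, 1e-5, None)))
        res = optimize.minimize(
            negloglik, np.array(init), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, weights, omegas, bl = unpack(best.x)
    mats = [CodonMatrix(kappa, w, pi_vec) for w in omegas]
    lnl, _, class_liks = engine.log_likelihood_mixture(X, weights, mats, bl)
    params = dict(zip(names, best.x[: len(names)]))
    if model_id == "M2a":
        params["p1"] = (1 - params["p0"]) * params.pop("p1_frac")
        params["p2"] = 1 - params["p0"] - params["p1"]
    fit = SelectionFit(
        model_id=model_id,
        params={k: float(v) for k, v in params.items()},
        lnL=float(lnl),
        class_weights=weights,
        class_omegas=omegas,
        site_class_liks=class_liks,
        converged=bool(best.success),
        branch_lengths=bl,
    )
    if not best.success:
        fit.extra["optimizer_message"] = str(best.message)
    if np.all(X == X[0]):
        fit.extra["warning"] = "no sequence variation; omega unidentifiable"
    return fit


def lrt(lnL_null: float, lnL_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2*(alt - null) and chi-square p-value.

    Small negative statistics (within optimizer tolerance) are clamped to
    zero; larger ones indicate an optimizer failure and raise.
    """
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -LRT_TOLERANCE:
        raise RuntimeError(
            f"alternative lnL {lnL_alt:.3f} below null {lnL_null:.3f}: "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def site_posteriors(
    fit: SelectionFit, levels: tuple[float, float] = (0.95, 0.99)
) -> dict:
    """Naive Empirical Bayes class posteriors per site.

    Returns the posterior matrix plus the 0-based site indices whose
    positive-selection-class (omega > 1) posterior reaches each level.
    """
    if fit.site_class_liks is None:
        raise ValueError("fit carries no per-site class likelihoods")
    joint = fit.class_weights[:, None] * fit.site_class_liks
    posterior = joint / joint.sum(axis=0, keepdims=True)
    positive = fit.class_omegas > 1.0
    pos_post = posterior[positive].sum(axis=0) if positive.any() else np.zeros(
        posterior.shape[1]
    )
    flagged = {
        level: [int(i) for i in np.nonzero(pos_post >= level)[0]] for level in levels
    }
    return {"posterior": posterior, "positive_posterior": pos_post, "flagged": flagged}


# ---------------------------------------------------------------------------
# branch (two-ratio) model
# ---------------------------------------------------------------------------


def _clade_sets(engine: PruningEngine) -> list[frozenset]:
    sets: list[frozenset] = [frozenset()] * engine.n_nodes
    for k, node in enumerate(engine.nodes):
        if not engine.children[k]:
            sets[k] = frozenset([node.label])
        else:
            acc: frozenset = frozenset()
            for c in engine.children[k]:
                acc |= sets[c]
            sets[k] = acc
    return sets


def branch_test(
    alignment: CodonAlignment | np.ndarray,
    tree,
    foreground: Sequence[frozenset | set | str],
    pi="f1x4",
    branch_lengths: Optional[np.ndarray] = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> dict:
    """Two-ratio branch model vs one-ratio null.

    ``foreground`` designates branches either by the leaf-label set of the
    clade below the branch or, for terminal branches, by the leaf label.
    Returns omega0 (background), omega1 (foreground), the LRT, and the
    relaxation call (significant AND omega1 > omega0).
    """
    if isinstance(alignment, CodonAlignment):
        X = alignment.to_matrix()
        taxa = alignment.taxa
    else:
        X = alignment
        taxa = tree.leaf_labels()
    engine = PruningEngine(tree, taxa)
    clades = _clade_sets(engine)
    fg_sets = set()
    for f in foreground:
        fg_sets.add(frozenset([f]) if isinstance(f, str) else frozenset(f))
    branch_class = np.array(
        [1 if clades[k] in fg_sets else 0 for k in range(engine.n_nodes)]
    )
    branch_class[engine.root] = 0
    if branch_class.sum() == 0:
        raise ValueError("empty foreground branch set")
    if all(branch_class[k] == 1 for k in range(engine.n_nodes) if k != engine.root):
        raise ValueError("foreground covers every branch: unidentifiable")
    pi_vec = _resolve_pi(pi, X)
    bl = engine.branch_lengths if branch_lengths is None else np.asarray(branch_lengths)

    null_fit = fit_model(
        X, tree, "M0", pi=pi_vec, branch_lengths=bl,
        n_restarts=n_restarts, seed=seed, engine=engine,
    )

    def negloglik(theta):
        kappa, omega0, omega1 = theta
        mats = [CodonMatrix(kappa, omega0, pi_vec), CodonMatrix(kappa, omega1, pi_vec)]
        liks = engine.site_likelihoods(X, mats, bl, branch_class=branch_class)
        if np.any(liks <= 0):
            return 1e12
        return -float(np.log(liks[0]).sum())

    bounds = [KAPPA_BOUNDS, OMEGA_BOUNDS, OMEGA_BOUNDS]
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = [null_fit.params["kappa"], null_fit.params["omega"],
                    null_fit.params["omega"]]
        else:
            init = [rng.uniform(1, 5), np.exp(rng.uniform(-3, 1)),
                    np.exp(rng.uniform(-3, 1))]
        res = optimize.minimize(
            negloglik, np.array(init), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega0, omega1 = best.x
    stat, p = lrt(null_fit.lnL, -best.fun, df=1)
    return {
        "kappa": float(kappa),
        "omega0": float(omega0),
        "omega1": float(omega1),
        "lnL_null": null_fit.lnL,
        "lnL_alt": float(-best.fun),
        "stat": stat,
        "p": p,
        "relaxed": bool(p < 0.05 and omega1 > omega0),
    }


def classify_selection(
    fits: dict[str, SelectionFit], alpha: float = 0.05, require_both: bool = True
) -> dict:
    """Positive vs conserved call from the M1a/M2a and M7/M8 LRT pairs.

    Positive selection requires significant LRTs AND a fitted
    positive-class omega > 1 in M2a and M8 (both pairs by default;
    ``require_both=False`` accepts either pair).
    """
    for m in ("M1a", "M2a", "M7", "M8"):
        if m not in fits:
            raise ValueError(f"missing fit for {m}")
    stat12, p12 = lrt(fits["M1a"].lnL, fits["M2a"].lnL, df=2)
    stat78, p78 = lrt(fits["M7"].lnL, fits["M8"].lnL, df=2)
    pos12 = p12 < alpha and fits["M2a"].params["omega2"] > 1.0
    pos78 = p78 < alpha and fits["M8"].params["omega_s"] > 1.0
    positive = (pos12 and pos78) if require_both else (pos12 or pos78)
    return {
        "call": "positive" if positive else "conserved",
        "m1a_m2a": {"stat": stat12, "p": p12},
        "m7_m8": {"stat": stat78, "p": p78},
    }
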