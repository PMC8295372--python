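"""Codon alignments, NG86 counting, likelihood machinery, and model fits."""

import math

import numpy as np
import pytest
from scipy import integrate

from wrkyevo.bruteforce import bruteforce_site_likelihood, oracle_ng86_counts
from wrkyevo.io import SequenceRecord
from wrkyevo.selection import (
    CODONS,
    CodonMatrix,
    PruningEngine,
    SelectionFit,
    branch_test,
    classify_selection,
    codon_rate_matrix,
    fit_model,
    lrt,
    ng86,
    occupancy_filter,
    site_posteriors,
    thread_codons,
)
from wrkyevo.selection.alignment import AlignmentError
from wrkyevo.selection.codon import SaturationError, translate_cds
from wrkyevo.selection.likelihood import uniform_frequencies
from wrkyevo.trees import parse_newick


class TestOccupancyFilter:
    def _recs(self, rows):
        return [SequenceRecord(f"t{i}", "", r) for i, r in enumerate(rows)]

    def test_gapless_unchanged(self):
        recs = self._recs(["MKT", "MKA"])
        out, colmap = occupancy_filter(recs)
        assert [r.residues for r in out] == ["MKT", "MKA"]
        assert colmap == [0, 1, 2]

    def test_gappy_column_removed(self):
        recs = self._recs(["M-T", "MKA"])
        out, colmap = occupancy_filter(recs, min_fraction=0.93)
        assert [r.residues for r in out] == ["MT", "MA"]
        assert colmap == [0, 2]

    def test_threshold_zero_keeps_everything(self):
        recs = self._recs(["M-T", "M-A"])
        out, _ = occupancy_filter(recs, min_fraction=0.0)
        assert [r.residues for r in out] == ["M-T", "M-A"]

    def test_all_removed_is_error(self):
        with pytest.raises(AlignmentError, match="gappy"):
            occupancy_filter(self._recs(["--", "AA"]), min_fraction=1.0)


class TestThreadCodons:
    def test_direct_threading_with_gap(self):
        aln = [SequenceRecord("a", "", "M-K")]
        out = thread_codons(aln, {"a": "ATGAAA"})
        assert out.codons[0] == ["ATG", "---", "AAA"]

    def test_internal_stop_rejected(self):
        with pytest.raises(AlignmentError, match="stop"):
            thread_codons([SequenceRecord("a", "", "MXK")],
                          {"a": "ATGTAAAAA"})

    def test_mismatch_names_taxon_and_position(self):
        with pytest.raises(AlignmentError, match="a.*column 2"):
            thread_codons([SequenceRecord("a", "", "MK")], {"a": "ATGATG"})

    def test_translation_helper(self):
        assert translate_cds("ATGAAATGA") == "MK"
        with pytest.raises(ValueError):
            translate_cds("ATGTAAAAA")


class TestNg86:
    def test_identical_sequences(self):
        res = ng86(["ATG", "AAA"], ["ATG", "AAA"])
        assert res.dN == 0 and res.dS == 0 and res.ratio is None

    def test_fourfold_third_positions_only_synonymous(self):
        a = ["GGA", "CCA"] * 50
        b = list(a)
        for k in range(0, 20, 2):
            b[k] = "GGC"  # four-fold degenerate third-position change
        res = ng86(a, b)
        assert res.dN == 0 and res.dS > 0

    def test_saturation_error(self):
        a = ["AAA"] * 5
        b = ["GGG"] * 5
        with pytest.raises(SaturationError):
            ng86(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_pathway_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = [CODONS[i] for i in rng.integers(0, 61, 60)]
        b = list(a)
        for k in rng.choice(60, size=12, replace=False):
            b[k] = CODONS[rng.integers(0, 61)]
        S, N, Sd, Nd = oracle_ng86_counts(a, b)
        res = ng86(a, b)
        assert res.syn_sites == pytest.approx(S)
        assert res.nonsyn_sites == pytest.approx(N)
        assert res.syn_diffs == pytest.approx(Sd)
        assert res.nonsyn_diffs == pytest.approx(Nd)

    def test_diff_counts_match_biopython(self):
        """Independent cross-check of the pathway-averaged difference
        counts against Bio.Align.analysis' NG86 internals."""
        from Bio.Align.analysis import _count_diff_NG86
        from Bio.Data.CodonTable import standard_dna_table

        from wrkyevo.selection.codon import _pair_diffs

        def intermediates_are_sense(c1, c2):
            import itertools as it

            diff = [i for i in range(3) if c1[i] != c2[i]]
            for order in it.permutations(diff):
                cur = c1
                for pos in order:
                    cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if cur not in CODONS:
                        return False
            return True

        rng = np.random.default_rng(7)
        checked = 0
        while checked < 40:
            c1, c2 = (CODONS[i] for i in rng.integers(0, 61, 2))
            if not intermediates_are_sense(c1, c2):
                continue  # stop-codon conventions differ between tools
            sd, nd = _count_diff_NG86(c1, c2, standard_dna_table)
            assert _pair_diffs(c1, c2) == pytest.approx((sd, nd))
            checked += 1


class TestRateMatrix:
    PI = np.random.default_rng(1).dirichlet(np.ones(61) * 3)

    def test_rows_sum_to_zero(self):
        q = codon_rate_matrix(3.1, 0.7, self.PI)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_uniform_neutral_symmetric_neighbors(self):
        q = codon_rate_matrix(1.0, 1.0, uniform_frequencies())
        off = q[q > 0]
        assert np.allclose(off, off[0])

    def test_detailed_balance(self):
        q = codon_rate_matrix(2.5, 0.4, self.PI)
        flux = self.PI[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_mean_rate_is_one(self):
        q = codon_rate_matrix(2.0, 0.5, self.PI)
        assert -np.dot(self.PI, np.diag(q)) == pytest.approx(1.0)


class TestPruning:
    def _setup(self, newick="(A:0.2,B:0.3,C:0.1);"):
        tree = parse_newick(newick)
        engine = PruningEngine(tree, tree.leaf_labels())
        pi = np.random.default_rng(2).dirichlet(np.ones(61) * 5)
        return tree, engine, CodonMatrix(2.0, 0.5, pi), pi

    def test_matches_exhaustive_state_summation(self):
        tree, engine, mat, pi = self._setup(
            "((A:0.2,B:0.1):0.15,(C:0.3,D:0.05):0.2);"
        )
        X = np.array([[3], [17], [60], [7]])
        _, site_lnl, _ = engine.log_likelihood_mixture(X, np.array([1.0]), [mat])
        brute = bruteforce_site_likelihood(
            tree, {"A": 3, "B": 17, "C": 60, "D": 7}, pi, mat.transition
        )
        assert math.exp(site_lnl[0]) == pytest.approx(brute, rel=1e-10)

    def test_zero_branch_lengths_collapse_to_pi(self):
        tree = parse_newick("(A:0,B:0);")
        engine = PruningEngine(tree, ["A", "B"])
        pi = uniform_frequencies()
        mat = CodonMatrix(2.0, 0.5, pi)
        _, site_lnl, _ = engine.log_likelihood_mixture(
            np.array([[5], [5]]), np.array([1.0]), [mat]
        )
        assert site_lnl[0] == pytest.approx(math.log(pi[5]))
        # conflicting states on a zero-length tree: (numerically) impossible
        try:
            _, bad_lnl, _ = engine.log_likelihood_mixture(
                np.array([[5], [6]]), np.array([1.0]), [mat]
            )
        except FloatingPointError:
            pass
        else:
            assert bad_lnl[0] < math.log(1e-12)

    def test_duplicated_column_doubles_contribution(self):
        _, engine, mat, _ = self._setup()
        X1 = np.array([[3], [17], [60]])
        X2 = np.hstack([X1, X1])
        lnl1, _, _ = engine.log_likelihood_mixture(X1, np.array([1.0]), [mat])
        lnl2, _, _ = engine.log_likelihood_mixture(X2, np.array([1.0]), [mat])
        assert lnl2 == pytest.approx(2 * lnl1, rel=1e-12)

    def test_gap_treated_as_missing(self):
        _, engine, mat, _ = self._setup()
        X = np.array([[3], [-1], [-1]])
        lnl, _, _ = engine.log_likelihood_mixture(X, np.array([1.0]), [mat])
        assert np.isfinite(lnl)


class TestLrt:
    def test_zero_statistic_p_one(self):
        stat, p = lrt(-100.0, -100.0, 2)
        assert stat == 0.0 and p == 1.0

    def test_chi2_tail_matches_numeric_integration(self):
        stat, p = lrt(-100.0, -100.0 + 5.99 / 2, 2)

        def chi2_pdf(x, df=2):
            return x ** (df / 2 - 1) * math.exp(-x / 2) / (
                2 ** (df / 2) * math.gamma(df / 2)
            )

        tail, _ = integrate.quad(chi2_pdf, 5.99, np.inf)
        assert p == pytest.approx(tail, rel=1e-8)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_small_negative_clamped_large_negative_raises(self):
        stat, p = lrt(-100.0, -100.1, 2)
        assert stat == 0.0 and p == 1.0
        with pytest.raises(RuntimeError):
            lrt(-100.0, -120.0, 2)


@pytest.fixture(scope="module")
def simulated_m1a():
    tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
    engine = PruningEngine(tree, tree.leaf_labels())
    pi = uniform_frequencies()
    mats = [CodonMatrix(2.0, 0.2, pi), CodonMatrix(2.0, 1.0, pi)]
    rng = np.random.default_rng(42)
    X = engine.evolve(rng, mats, (rng.random(150) > 0.8).astype(np.int64))
    return tree, X


class TestFits:
    def test_model_nesting_on_one_dataset(self, simulated_m1a):
        tree, X = simulated_m1a
        fits = {
            m: fit_model(X, tree, m, pi="uniform", n_restarts=1, seed=0)
            for m in ("M0", "M1a", "M2a", "M7", "M8")
        }
        tol = 0.02
        assert fits["M2a"].lnL >= fits["M1a"].lnL - tol
        assert fits["M8"].lnL >= fits["M7"].lnL - tol
        assert fits["M1a"].lnL >= fits["M0"].lnL - tol

    def test_no_variation_flagged(self):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        X = np.full((3, 40), 7)
        fit = fit_model(X, tree, "M0", pi="uniform", n_restarts=1, seed=0)
        assert "unidentifiable" in fit.extra.get("warning", "")

    def test_branch_test_foreground_validation(self, simulated_m1a):
        tree, X = simulated_m1a
        with pytest.raises(ValueError, match="foreground"):
            branch_test(X, tree, [], pi="uniform", n_restarts=1)
        all_branches = [frozenset({t}) for t in "ABCD"] + [
            frozenset({"A", "B"}), frozenset({"C", "D"}),
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            branch_test(X, tree, all_branches, pi="uniform", n_restarts=1)


class TestNg86M0Concordance:
    def test_rank_correlation_across_omega_gradient(self):
        """NG86 dN/dS and the M0 omega-hat order genes the same way across
        a simulated omega gradient."""
        from scipy.stats import spearmanr

        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        engine = PruningEngine(tree, tree.leaf_labels())
        pi = uniform_frequencies()
        rng = np.random.default_rng(8)
        omegas = np.geomspace(0.1, 3.0, 12)
        ng_vals, m0_vals = [], []
        for omega in omegas:
            mat = CodonMatrix(2.0, float(omega), pi)
            X = engine.evolve(rng, [mat], np.zeros(200, dtype=np.int64))
            fit = fit_model(X, tree, "M0", pi="uniform", n_restarts=1, seed=0)
            m0_vals.append(fit.params["omega"])
            a = [CODONS[i] for i in X[0]]
            b = [CODONS[i] for i in X[3]]
            res = ng86(a, b)
            ng_vals.append(res.ratio if res.ratio is not None else 0.0)
        rho, _ = spearmanr(ng_vals, m0_vals)
        assert rho > 0.9


class TestPosteriors:
    def test_posteriors_normalize_and_m1a_has_no_positive_class(self, simulated_m1a):
        tree, X = simulated_m1a
        fit = fit_model(X, tree, "M1a", pi="uniform", n_restarts=1, seed=0)
        post = site_posteriors(fit)
        assert np.allclose(post["posterior"].sum(axis=0), 1.0)
        assert post["flagged"][0.95] == []

    def test_positive_sites_ranked_above_purifying_sites(self):
        """Sites simulated at omega 5 get higher positive-class posteriors
        than sites at omega 0.2 (ROC-style recovery)."""
        tree = parse_newick(
            "((A:0.25,B:0.25):0.1,((C:0.25,D:0.25):0.1,(E:0.25,F:0.25):0.1):0.05);"
        )
        engine = PruningEngine(tree, tree.leaf_labels())
        pi = uniform_frequencies()
        mats = [CodonMatrix(2.0, 0.2, pi), CodonMatrix(2.0, 5.0, pi)]
        rng = np.random.default_rng(3)
        site_class = np.zeros(300, dtype=np.int64)
        site_class[250:] = 1
        X = engine.evolve(rng, mats, site_class)
        fit = fit_model(X, tree, "M2a", pi="uniform", n_restarts=2, seed=0)
        post = site_posteriors(fit)["positive_posterior"]
        assert post[250:].mean() > post[:250].mean()
        flagged = np.array(site_posteriors(fit)["flagged"][0.95])
        if flagged.size:
            tpr = (flagged >= 250).mean()
            assert tpr > 0.5


class TestClassifySelection:
    def _fit(self, model, lnl, omega=None):
        params = {}
        if model == "M2a":
            params["omega2"] = omega
        if model == "M8":
            params["omega_s"] = omega
        return SelectionFit(
            model_id=model, params=params, lnL=lnl,
            class_weights=np.array([1.0]), class_omegas=np.array([0.5]),
        )

    def test_both_tests_required(self):
        fits = {
            "M1a": self._fit("M1a", -1000.0),
            "M2a": self._fit("M2a", -990.0, omega=3.0),
            "M7": self._fit("M7", -1000.0),
            "M8": self._fit("M8", -999.9, omega=3.0),  # not significant
        }
        assert classify_selection(fits)["call"] == "conserved"
        assert classify_selection(fits, require_both=False)["call"] == "positive"

    def test_nonsignificant_with_omega_above_one_is_conserved(self):
        fits = {
            "M1a": self._fit("M1a", -1000.0),
            "M2a": self._fit("M2a", -999.9, omega=5.0),
            "M7": self._fit("M7", -1000.0),
            "M8": self._fit("M8", -999.9, omega=5.0),
        }
        assert classify_selection(fits)["call"] == "conserved"
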