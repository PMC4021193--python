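"""Codon likelihood engine, site-model fits, LRTs, empirical-Bayes calls."""

import numpy as np
import pytest
from scipy import stats

import famevol as fv
from famevol.gy94 import uniform_codon_freqs
from famevol.likelihood import LikelihoodEngine
from famevol.selection import SITE_MODEL_FREE_PARAMS, discretize_beta

from conftest import oracle_tree_log_likelihood


def sim_m0(tree, omega, n_codons, seed, kappa=2.0):
    spec = fv.SimModelSpec(
        "M0", kappa=kappa, omega_classes=[(1.0, omega)], seed=seed
    )
    return fv.simulate_codon_alignment(tree, spec, n_codons)[0]


class TestLikelihoodEngine:
    def test_single_sequence_tree_is_sum_of_log_frequencies(self):
        tree = fv.Tree.from_newick("A:0;")
        aln = fv.CodonAlignment(["A"], ["ATGGGTCTT"])
        pi = uniform_codon_freqs()
        lnl = fv.codon_log_likelihood(aln, tree, 2.0, 0.5, pi)
        assert lnl == pytest.approx(3 * np.log(1 / 61), abs=1e-10)

    def test_zero_branches_identical_sequences(self):
        tree = fv.Tree.from_newick("(A:0,B:0,C:0);")
        aln = fv.CodonAlignment(["A", "B", "C"], ["ATGCTT"] * 3)
        pi = uniform_codon_freqs()
        lnl = fv.codon_log_likelihood(aln, tree, 2.0, 0.5, pi)
        assert lnl == pytest.approx(2 * np.log(1 / 61), abs=1e-10)

    @pytest.mark.parametrize(
        "newick,n_codons",
        [
            ("(A:0.3,B:0.2,C:0.4);", 5),
            ("(A:0.25,B:0.15,(C:0.3,D:0.1):0.2);", 5),
        ],
    )
    @pytest.mark.parametrize("omega", [0.2, 1.5])
    def test_matches_exhaustive_state_enumeration(self, newick, n_codons, omega):
        """Pruning equals brute-force summation over all internal-node codon
        states (independent expm oracle) on small toys."""
        tree = fv.Tree.from_newick(newick)
        aln = sim_m0(tree, omega, n_codons, seed=8)
        pi = uniform_codon_freqs()
        mine = fv.codon_log_likelihood(aln, tree, 2.0, omega, pi)
        oracle = oracle_tree_log_likelihood(aln, tree, 2.0, omega, pi)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_rate_matrix_rows_and_stationarity(self):
        from famevol.gy94 import rate_matrix

        pi = uniform_codon_freqs()
        Q = rate_matrix(2.3, 0.4, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert np.abs(pi @ Q).max() < 1e-10
        # scaled to one expected substitution per codon per unit time
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_leaf_mismatch_raises(self):
        tree = fv.Tree.from_newick("(A:0.1,B:0.1,C:0.1);")
        aln = fv.CodonAlignment(["A", "B", "X"], ["ATG"] * 3)
        with pytest.raises(ValueError, match="differ"):
            LikelihoodEngine(aln, tree, uniform_codon_freqs())


class TestBetaDiscretization:
    def test_category_means_average_to_beta_mean(self):
        for p, q in [(0.5, 0.5), (2.0, 5.0), (0.99176, 5.71801)]:
            cats = discretize_beta(p, q, 10)
            assert len(cats) == 10
            assert cats.mean() == pytest.approx(p / (p + q), abs=1e-6)
            assert (np.diff(cats) > 0).all()

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            discretize_beta(-1.0, 2.0)


class TestSiteModelFits:
    def test_free_parameter_counts(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.4, 60, seed=2)
        model = fv.CodonSiteModel(aln, quartet_tree)
        for name, k in SITE_MODEL_FREE_PARAMS.items():
            assert k == {"M0": 1, "M3": 5, "M7": 2, "M8": 4}[name]
        fit = model.fit("M3", n_starts=1)
        assert fit.n_free_params == 5
        assert fit.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_m0_omega_recovery_within_tolerance(self, quartet_tree):
        """omega-hat lands within +-0.1 of the generating value."""
        aln = sim_m0(quartet_tree, 0.5, 300, seed=17)
        fit = fv.CodonSiteModel(aln, quartet_tree, codon_freqs="equal").fit(
            "M0", n_starts=2
        )
        assert abs(fit.omegas[0] - 0.5) < 0.1

    def test_multistart_stability(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.4, 80, seed=5)
        model = fv.CodonSiteModel(aln, quartet_tree)
        f1 = model.fit("M0", n_starts=1, seed=0)
        f2 = model.fit("M0", n_starts=3, seed=99)
        assert abs(f1.lnL - f2.lnL) < 1e-4

    def test_nested_model_dominance(self, quartet_tree):
        """lnL(M3) >= lnL(M0) and lnL(M8) >= lnL(M7) up to optimizer
        tolerance, on the same data."""
        spec = fv.SimModelSpec(
            "M3",
            kappa=2.0,
            omega_classes=[(0.6, 0.05), (0.3, 0.5), (0.1, 2.0)],
            seed=23,
        )
        aln, _ = fv.simulate_codon_alignment(quartet_tree, spec, 150)
        model = fv.CodonSiteModel(aln, quartet_tree)
        m0 = model.fit("M0", n_starts=2)
        m3 = model.fit("M3", n_starts=2)
        m7 = model.fit("M7", n_starts=2)
        m8 = model.fit("M8", n_starts=2)
        assert m3.lnL >= m0.lnL - 1e-4
        assert m8.lnL >= m7.lnL - 1e-4


class TestLikelihoodRatioTest:
    def test_published_m0_m3_arithmetic(self):
        res = fv.likelihood_ratio_test(-14554.8, -14274.8, df=4)
        assert res.two_delta_l == pytest.approx(560.0, abs=1e-9)
        assert res.p_value < 0.01

    def test_equal_likelihoods(self):
        res = fv.likelihood_ratio_test(-10.0, -10.0, df=2)
        assert res.two_delta_l == 0.0 and res.p_value == 1.0

    def test_huge_statistic_matches_chi2_survival_oracle(self):
        res = fv.likelihood_ratio_test(-1000.0, -720.0, df=4)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(560.0, 4)))
        assert res.p_value < 1e-100

    def test_negative_statistic_flagged(self):
        res = fv.likelihood_ratio_test(-9.0, -10.0, df=1)
        assert res.flagged and res.p_value == 1.0

    def test_mixture_halves_p(self):
        plain = fv.likelihood_ratio_test(-10.0, -8.0, df=1)
        mixed = fv.likelihood_ratio_test(-10.0, -8.0, df=1, mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class TestSitePosteriors:
    def test_rows_sum_to_one(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.5, 60, seed=31)
        fit = fv.CodonSiteModel(aln, quartet_tree).fit("M3", n_starts=1)
        post = fit.site_posteriors()
        assert post.shape == (60, 3)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_m7_positive_sites_not_allowed(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.5, 40, seed=33)
        fit = fv.CodonSiteModel(aln, quartet_tree).fit("M7", n_starts=1)
        with pytest.raises(ValueError, match="not allowed"):
            fit.positive_sites()

    def test_m8_simulation_enriches_true_positive_sites(self, quartet_tree):
        """Sites generated with omega=3 are strongly enriched among NEB
        calls at the 0.95 cutoff."""
        spec = fv.SimModelSpec(
            "M3",  # discrete mixture: 90% purifying, 10% omega=4
            kappa=2.0,
            omega_classes=[(0.9, 0.1), (0.1, 4.0)],
            seed=41,
        )
        big_tree = fv.Tree.from_newick(
            "((A:0.5,B:0.5):0.2,(C:0.5,D:0.5):0.2,(E:0.5,F:0.5):0.2);"
        )
        aln, classes = fv.simulate_codon_alignment(big_tree, spec, 500)
        fit = fv.CodonSiteModel(aln, big_tree).fit("M8", n_starts=2)
        calls = [s for s, _ in fit.positive_sites(threshold=0.95)]
        assert calls, "no positive sites called"
        truth = set(np.nonzero(classes == 1)[0] + 1)
        precision = len(truth & set(calls)) / len(calls)
        base_rate = len(truth) / 500
        assert precision > 5 * base_rate

    def test_grid_beb_close_to_neb(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.5, 50, seed=51)
        fit = fv.CodonSiteModel(aln, quartet_tree).fit("M8", n_starts=1)
        neb = fit.site_posteriors("NEB")
        beb = fit.site_posteriors("gridBEB")
        assert beb.shape == neb.shape
        assert np.allclose(beb.sum(axis=1), 1.0, atol=1e-6)


class TestBranchSite:
    def test_proportion_structure(self, quartet_tree):
        aln = sim_m0(quartet_tree, 0.3, 80, seed=61)
        model = fv.BranchSiteModel(aln, quartet_tree, foreground_branches={"A"})
        fit = model.fit(n_starts=1)
        p = fit.proportions
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        # 2a:2b ratio equals p0:p1
        if p[3] > 1e-12 and p[1] > 1e-12:
            assert p[2] / p[3] == pytest.approx(p[0] / p[1], rel=1e-6)
        assert fit.omega2 >= 1.0

    def test_all_foreground_rejected(self, star3_tree):
        # a 3-leaf star has exactly its 3 leaf branches: marking them all
        # leaves no background lineage to contrast against
        aln = sim_m0(star3_tree, 0.3, 30, seed=63)
        with pytest.raises(ValueError, match="background"):
            fv.BranchSiteModel(
                aln, star3_tree, foreground_branches=set(star3_tree.leaf_names)
            )

    def test_power_against_foreground_selection(self):
        """Foreground omega2=4 on 10% of sites (a 4-leaf foreground clade)
        is detected by the LRT in a clear majority of replicates."""
        tree = fv.Tree.from_newick(
            "(((A:0.25,B:0.25):0.15,(C:0.25,D:0.25):0.15):0.1,"
            "((E:0.5,F:0.5)G1:0.3,(G:0.5,H:0.5)G2:0.3)G0:0.1);"
        )
        fg = frozenset({"E", "F", "G", "H", "G1", "G2", "G0"})
        rejections = 0
        n_reps = 8
        for rep in range(n_reps):
            spec = fv.SimModelSpec(
                "branch_site_A",
                kappa=2.0,
                omega_classes=[
                    (0.855, 0.05, 0.05),
                    (0.045, 1.0, 1.0),
                    (0.095, 0.05, 4.0),
                    (0.005, 1.0, 4.0),
                ],
                foreground_branches=fg,
                seed=900 + rep,
            )
            aln, _ = fv.simulate_codon_alignment(tree, spec, 500)
            m0 = fv.CodonSiteModel(aln, tree).fit("M0", n_starts=1)
            model = fv.BranchSiteModel(aln, tree, foreground_branches=fg)
            _, _, lrt = model.fit_with_lrt(
                n_starts=1, fix_kappa=m0.kappa, fix_scale=m0.scale
            )
            rejections += lrt.p_value < 0.05
        assert rejections >= 0.6 * n_reps
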