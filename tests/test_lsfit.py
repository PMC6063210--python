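"""Constrained least-squares branch-length fitting and the quartet algebra."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from distimpute import (LabeledDistanceMatrix, fit_branch_lengths,
                        path_incidence, quartet_closed_form, rss)
from distimpute.evalsim import additive_matrix, mask_random, random_tree
from distimpute.lsfit import IdentifiabilityError
from distimpute.trees import UnrootedTree
from conftest import internal_length, terminal_length


class TestWorkedQuartet:
    """The five-distance example with D13 missing: three topologies, three
    characteristic fits (RSS / TL / imputed D13 and the branch vectors)."""

    def test_sister_s1s2_topology_fits_exactly(self, quartet_missing,
                                               topology_a):
        fit = fit_branch_lengths(topology_a, quartet_missing)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.tl == pytest.approx(7.0)
        assert fit.imputed[("S1", "S3")] == pytest.approx(3.0)
        assert fit.unique
        for leaf, expect in [("S1", 1), ("S2", 1), ("S3", 1), ("S4", 3)]:
            assert terminal_length(fit.tree, leaf) == pytest.approx(expect)
        assert internal_length(fit.tree) == pytest.approx(1.0)

    def test_masked_sisters_topology_has_multiple_optima(self, quartet_missing,
                                                         topology_b):
        fit = fit_branch_lengths(topology_b, quartet_missing,
                                 compute_intervals=True)
        assert fit.rss == pytest.approx(1.0)
        assert fit.tl == pytest.approx(6.0)
        assert fit.imputed[("S1", "S3")] == pytest.approx(0.0, abs=1e-9)
        assert not fit.unique
        lo, hi = fit.imputed_interval[("S1", "S3")]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(2.0, abs=1e-6)
        for leaf, expect in [("S1", 0), ("S2", 1.5), ("S3", 0), ("S4", 3.5)]:
            assert terminal_length(fit.tree, leaf) == pytest.approx(expect)
        assert internal_length(fit.tree) == pytest.approx(1.0)

    def test_s1s4_topology_pins_internal_branch_at_zero(self, quartet_missing,
                                                        topology_c):
        fit = fit_branch_lengths(topology_c, quartet_missing)
        assert fit.rss == pytest.approx(1.0)
        assert fit.tl == pytest.approx(7.0)
        assert fit.imputed[("S1", "S3")] == pytest.approx(2.0)
        assert fit.unique  # constrained optimum is a single point here
        assert internal_length(fit.tree) == pytest.approx(0.0)
        for leaf, expect in [("S1", 1), ("S2", 1.5), ("S3", 1), ("S4", 3.5)]:
            assert terminal_length(fit.tree, leaf) == pytest.approx(expect)

    def test_unconstrained_s1s4_solve_goes_negative(self, quartet_missing,
                                                    topology_c):
        fit = fit_branch_lengths(topology_c, quartet_missing, nonneg=False)
        assert internal_length(fit.tree) == pytest.approx(-1.0)

    def test_rss_evaluation_matches_hand_arithmetic(self, quartet_missing,
                                                    topology_b):
        """The sister-masked fit leaves four residuals of 0.5: RSS = 1."""
        fit = fit_branch_lengths(topology_b, quartet_missing)
        assert rss(fit.tree, quartet_missing) == pytest.approx(4 * 0.25)

    def test_rss_zero_when_patristic_equals_observed(self, topology_a):
        topology_a.set_branch_lengths([1.0] * 5)
        from distimpute import patristic_matrix
        d = patristic_matrix(topology_a)
        assert rss(topology_a, d) == pytest.approx(0.0, abs=1e-24)


class TestQuartetClosedForm:
    def test_exact_solution_of_path_equations(self, quartet_missing,
                                              topology_a):
        x, implied = quartet_closed_form(quartet_missing, topology_a)
        tree = topology_a.copy().set_branch_lengths(x)
        assert implied == pytest.approx(3.0)
        for leaf, expect in [("S1", 1), ("S2", 1), ("S3", 1), ("S4", 3)]:
            assert terminal_length(tree, leaf) == pytest.approx(expect)
        assert internal_length(tree) == pytest.approx(1.0)
        assert sum(x) == pytest.approx(7.0)

    def test_s1s4_sisters_need_negative_internal_branch(self, quartet_missing,
                                                        topology_c):
        x, _ = quartet_closed_form(quartet_missing, topology_c)
        tree = topology_c.copy().set_branch_lengths(x)
        assert internal_length(tree) == pytest.approx(-1.0)

    def test_masked_sister_pair_is_singular(self, quartet_missing, topology_b):
        with pytest.raises(IdentifiabilityError):
            quartet_closed_form(quartet_missing, topology_b)

    def test_equidistant_data_collapses_internal_branch(self, topology_a):
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 2] = mask[2, 0] = True
        d = LabeledDistanceMatrix(["S1", "S2", "S3", "S4"], vals, mask)
        x, implied = quartet_closed_form(d, topology_a)
        tree = topology_a.copy().set_branch_lengths(x)
        for leaf in ("S1", "S2", "S3", "S4"):
            assert terminal_length(tree, leaf) == pytest.approx(1.0)
        assert internal_length(tree) == pytest.approx(0.0)
        assert implied == pytest.approx(2.0)


class TestFitProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_full_additive_matrix_recovers_generating_lengths(self, seed):
        tree = random_tree(6, seed=seed)
        d = additive_matrix(tree)
        fit = fit_branch_lengths(tree, d)
        assert fit.rss < 1e-18
        assert np.allclose(fit.x, tree.branch_lengths(), atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_constrained_rss_at_least_unconstrained(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(5, seed=seed)
        n = 5
        vals = rng.uniform(0.2, 3.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        d = LabeledDistanceMatrix(tree.labels, vals)
        con = fit_branch_lengths(tree, d, nonneg=True)
        unc = fit_branch_lengths(tree, d, nonneg=False)
        assert con.rss >= unc.rss - 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_imputed_equals_patristic_at_masked_pairs(self, seed):
        tree = random_tree(7, seed=seed)
        d = mask_random(additive_matrix(tree, noise_sd=0.02, seed=seed),
                        n_missing=3, seed=seed)
        fit = fit_branch_lengths(tree, d)
        for p, v in fit.imputed.items():
            assert v == pytest.approx(fit.patristic.get(*p), abs=1e-12)

    def test_rss_invariant_under_label_permutation(self, quartet_missing,
                                                   topology_a):
        base = fit_branch_lengths(topology_a, quartet_missing).rss
        # consistently renaming taxa cannot change the attained optimum
        ren = {"S1": "Sz", "S2": "Sy", "S3": "Sx", "S4": "Sw"}
        labels = [ren[l] for l in quartet_missing.labels]
        d2 = LabeledDistanceMatrix(labels, quartet_missing.entries,
                                   quartet_missing.missing_mask)
        t2 = UnrootedTree.quartet((ren["S1"], ren["S2"]),
                                  (ren["S3"], ren["S4"]))
        assert fit_branch_lengths(t2, d2).rss == pytest.approx(base)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_numeric_minimizer_oracle(self, seed):
        """Active-set NNLS agrees with a direct bounded numeric minimization
        of the same objective on random 4-5 taxon instances."""
        rng = np.random.default_rng(seed)
        n = 4 + seed % 2
        tree = random_tree(n, seed=seed)
        vals = rng.uniform(0.2, 3.0, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        d = LabeledDistanceMatrix(tree.labels, vals)
        fit = fit_branch_lengths(tree, d)
        A = path_incidence(tree)
        b, _ = d.condensed()

        def objective(x):
            r = b - A @ x
            return float(r @ r)

        res = minimize(objective, np.full(A.shape[1], 0.5), method="L-BFGS-B",
                       bounds=[(0, None)] * A.shape[1],
                       options={"ftol": 1e-15, "gtol": 1e-12})
        assert fit.rss == pytest.approx(res.fun, abs=1e-6)

    def test_zero_distance_with_m_weighting_warns(self, topology_a):
        vals = np.array([[0, 0.0, 1, 1], [0.0, 0, 1, 1],
                         [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float)
        d = LabeledDistanceMatrix(["S1", "S2", "S3", "S4"], vals)
        with pytest.warns(RuntimeWarning, match="zero distance"):
            fit_branch_lengths(topology_a, d, m=2)

    @pytest.mark.parametrize("m", [1, 2])
    def test_weighted_fit_still_exact_on_additive_data(self, m):
        tree = random_tree(5, seed=9)
        d = additive_matrix(tree)
        fit = fit_branch_lengths(tree, d, m=m)
        assert fit.rss < 1e-15
        assert np.allclose(fit.x, tree.branch_lengths(), atol=1e-7)
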