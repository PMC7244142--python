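"""Penalized-likelihood dating: objective, fits, cross-validation."""

import numpy as np
import pytest

from migpipe.dating import (
    CalibrationConstraint,
    cross_validate_lambda,
    default_lambda_grid,
    fit_clock,
    fit_pl,
    pl_objective,
    pl_objective_parts,
)
from migpipe.simulate import simulate_phylogram, simulate_species_tree

from conftest import true_internal_ages


def _setup(seed, n=10, rate=0.002, n_sites=10000, sigma=0.0, poisson=True):
    tree = simulate_species_tree(n, 0.1, 45.0, seed=seed)
    phylo, rates = simulate_phylogram(
        tree, rate, n_sites, seed=seed + 1000, rate_sigma=sigma, poisson=poisson
    )
    tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    return tree, phylo, tips


def _ages_rates_at_truth(tree, rate):
    ages = np.array([n.age for n in tree.preorder_node_iter()])
    n_branches = sum(1 for n in tree.preorder_node_iter() if n.parent_node)
    return ages, np.full(n_branches, rate)


class TestCalibrations:
    def test_needs_two_tips(self):
        with pytest.raises(ValueError):
            CalibrationConstraint(frozenset({"A"}), 10, 20)

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            CalibrationConstraint(frozenset({"A", "B"}), 30, 20)

    def test_conflicting_boxes_named(self):
        tree, phylo, tips = _setup(0, n=6)
        leaves = sorted(tips)
        constraints = [
            CalibrationConstraint(frozenset(tips), None, 40.0),
            CalibrationConstraint(frozenset(leaves[:2]), 48.0, None),
        ]
        with pytest.raises(ValueError, match="MRCA"):
            fit_pl(phylo, constraints, 1.0, 10000)

    def test_no_upper_bound_unidentifiable(self):
        tree, phylo, tips = _setup(1, n=6)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_pl(phylo, [CalibrationConstraint(frozenset(tips), 10.0, None)],
                   1.0, 10000)


class TestObjective:
    def test_clock_truth_zero_penalty(self):
        tree, _, _ = _setup(2, n=8)
        ages, rates = _ages_rates_at_truth(tree, 0.002)
        phylo, _ = simulate_phylogram(tree, 0.002, 10000, 0, poisson=False)
        _, phi = pl_objective_parts(phylo, ages, rates, 10000)
        assert phi == pytest.approx(0.0, abs=1e-18)

    def test_lambda_linearity(self):
        tree, phylo, _ = _setup(3, n=8)
        rng = np.random.default_rng(0)
        ages = np.array([n.age for n in tree.preorder_node_iter()])
        n_branches = sum(1 for n in tree.preorder_node_iter() if n.parent_node)
        rates = 0.002 * np.exp(rng.normal(0, 0.3, n_branches))
        nll, phi = pl_objective_parts(phylo, ages, rates, 10000)
        o1 = pl_objective(phylo, ages, rates, 5.0, 10000)
        o2 = pl_objective(phylo, ages, rates, 10.0, 10000)
        assert o2 - o1 == pytest.approx(5.0 * phi, rel=1e-9)

    def test_truth_beats_age_perturbations_on_clock_data(self):
        tree, _, _ = _setup(4, n=8)
        phylo, _ = simulate_phylogram(tree, 0.002, 10000, 0, poisson=False)
        ages, rates = _ages_rates_at_truth(tree, 0.002)
        base = pl_objective(phylo, ages, rates, 1.0, 10000, r_ref=0.002)
        rng = np.random.default_rng(5)
        is_internal = np.array(
            [not n.is_leaf() and n.parent_node is not None
             for n in tree.preorder_node_iter()]
        )
        for _ in range(100):
            pert = ages.copy()
            jitter = rng.uniform(0.9, 1.1, is_internal.sum())
            pert[is_internal] = ages[is_internal] * jitter
            # keep ordering valid; skip invalid draws
            try:
                obj = pl_objective(phylo, pert, rates, 1.0, 10000, r_ref=0.002)
            except ValueError:
                continue
            assert base <= obj + 1e-9

    def test_zero_duration_branch_infinite_not_crash(self):
        tree, phylo, _ = _setup(6, n=6)
        ages = np.array([n.age for n in tree.preorder_node_iter()])
        # collapse the first internal child onto its parent
        idx = next(
            i for i, n in enumerate(tree.preorder_node_iter())
            if i > 0 and not n.is_leaf()
        )
        parent_age = ages[0]
        ages[idx] = parent_age
        n_branches = sum(1 for n in tree.preorder_node_iter() if n.parent_node)
        val = pl_objective(phylo, ages, np.full(n_branches, 0.002), 1.0, 10000)
        assert np.isinf(val)


class TestFits:
    def test_root_fixed_clock_recovery_within_1_percent(self):
        tree, _, tips = _setup(7)
        phylo, _ = simulate_phylogram(tree, 0.002, 10000, 0, poisson=False)
        constraints = [CalibrationConstraint(frozenset(tips), 45.0, 45.0)]
        fit = fit_pl(phylo, constraints, 1e4, 10000, seed=0)
        truth = true_internal_ages(tree)
        for i, age in truth.items():
            assert abs(fit.node_ages[i] - age) / age < 0.01
        assert np.all(np.abs(fit.rates / 0.002 - 1) < 0.01)

    def test_large_lambda_matches_clock_fit(self):
        tree, phylo, tips = _setup(8)
        constraints = [CalibrationConstraint(frozenset(tips), 33.9, 53.0)]
        fit_hi = fit_pl(phylo, constraints, 1e5, 10000, seed=0)
        cv = np.std(fit_hi.rates) / np.mean(fit_hi.rates)
        assert cv < 0.01
        clock = fit_clock(phylo, constraints, 10000, seed=0)
        a = np.array([fit_hi.node_ages[i] for i in sorted(fit_hi.node_ages)])
        b = np.array([clock.node_ages[i] for i in sorted(clock.node_ages)])
        assert np.max(np.abs(a - b)) < 0.005 * clock.root_age()

    def test_autocorrelated_rates_recovered_within_10_percent(self):
        """Moderate autocorrelated rate variation: node ages recovered to
        ~10% with the root constrained only by the fossil box."""
        errs = []
        for seed in (16, 23, 30):
            tree = simulate_species_tree(10, 0.1, 45.0, seed=seed)
            phylo, _ = simulate_phylogram(
                tree, 0.002, 10000, seed + 1000, rate_sigma=0.15,
                autocorrelated=True,
            )
            tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
            constraints = [CalibrationConstraint(tips, 33.9, 53.0)]
            fit = fit_pl(phylo, constraints, 100.0, 10000, seed=0)
            truth = true_internal_ages(tree)
            errs += [abs(fit.node_ages[i] - a) / a for i, a in truth.items()]
        assert np.median(errs) < 0.10

    def test_chronogram_invariants(self):
        tree, phylo, tips = _setup(10)
        constraints = [CalibrationConstraint(frozenset(tips), 33.9, 53.0)]
        fit = fit_pl(phylo, constraints, 10.0, 10000, seed=1)
        for node in fit.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.parent_node.age > node.age - 1e-6
        assert 33.9 - 1e-6 <= fit.root_age() <= 53.0 + 1e-6
        assert (fit.rates > 0).all()

    def test_objective_trace_monotone(self):
        tree, phylo, tips = _setup(11)
        constraints = [CalibrationConstraint(frozenset(tips), 33.9, 53.0)]
        fit = fit_pl(phylo, constraints, 10.0, 10000, seed=2)
        for trace in fit.objective_trace:
            diffs = np.diff(trace)
            assert (diffs <= 1e-6).all()

    def test_deterministic_given_seed(self):
        tree, phylo, tips = _setup(12)
        constraints = [CalibrationConstraint(frozenset(tips), 33.9, 53.0)]
        f1 = fit_pl(phylo, constraints, 10.0, 10000, seed=3)
        f2 = fit_pl(phylo, constraints, 10.0, 10000, seed=3)
        assert f1.objective == f2.objective
        assert f1.root_age() == f2.root_age()


class TestCrossValidation:
    def test_default_grid_span(self):
        grid = default_lambda_grid()
        assert grid.max() == pytest.approx(1e5)
        assert grid.min() == pytest.approx(1e-3)

    def test_clock_prefers_heavy_smoothing(self):
        tree, phylo, tips = _setup(13, n=6)
        constraints = [CalibrationConstraint(frozenset(tips), 33.9, 53.0)]
        table, lam = cross_validate_lambda(
            phylo, constraints, 10000, lambda_grid=np.logspace(5, -3, 5), seed=0
        )
        scores = {row["lambda"]: row["cv_score"] for row in table}
        assert lam >= 1.0

    def test_clade_rate_shift_prefers_less_smoothing_than_clock(self):
        """A 4x lineage rate shift is unsmoothable: its chosen lambda
        never exceeds the paired clock simulation's choice."""
        wins = 0
        for seed in range(2):
            tree = simulate_species_tree(8, 0.1, 45.0, seed=500 + seed)
            tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
            constraints = [CalibrationConstraint(tips, 33.9, 53.0)]
            ck, _ = simulate_phylogram(tree, 0.002, 10000, 600 + seed)
            ht, _ = simulate_phylogram(tree, 0.002, 10000, 600 + seed,
                                       clade_shift_factor=4.0)
            grid = np.logspace(5, -3, 5)
            _, lam_ck = cross_validate_lambda(ck, constraints, 10000,
                                              lambda_grid=grid, seed=seed)
            _, lam_ht = cross_validate_lambda(ht, constraints, 10000,
                                              lambda_grid=grid, seed=seed)
            wins += lam_ck >= lam_ht
        assert wins == 2

    def test_empty_grid_rejected(self):
        tree, phylo, tips = _setup(14, n=6)
        with pytest.raises(ValueError):
            cross_validate_lambda(
                phylo,
                [CalibrationConstraint(frozenset(tips), 33.9, 53.0)],
                10000,
                lambda_grid=np.array([]),
            )
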