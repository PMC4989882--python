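"""Best-fitting-root search: objective evaluation, per-edge quadratics,
and the global scan, checked against explicit-reroot oracles."""

import numpy as np
import pytest

import tiptempo as tt
from tiptempo.errors import IsochronousDataError, MissingDatesError

from conftest import explicit_objective, fit_tree, grid_rss


def _random_placements(tree, rng, k):
    edges = tree.edges()
    for _ in range(k):
        child = edges[int(rng.integers(len(edges)))]
        yield tt.RootPlacement(child, float(rng.uniform()))


class TestObjectiveAt:
    def test_consistent_with_regression_at_current_root(self):
        tree = tt.read_newick("((A:1,B:1):1,C:2);")
        dates = tt.TipDateSet(times={"A": 2001.0, "B": 2003.0, "C": 2005.0})
        fit, _ = fit_tree(tree, dates)
        placement = tt.RootPlacement(tree.root.children[0], 0.0)
        value = tt.objective_at(tree, placement, dates, tt.Criterion.RSS)
        assert value == pytest.approx(fit.rss, abs=1e-12)

    def test_variance_zero_at_star_tree_root(self, star_tree):
        placement = tt.RootPlacement(star_tree.root.children[0], 0.0)
        value = tt.objective_at(star_tree, placement, None,
                                tt.Criterion.VARIANCE)
        assert value == pytest.approx(0.0, abs=1e-15)

    def test_matches_explicit_reroot_and_refit(self, noisy_sim):
        tree, dates, _ = noisy_sim
        rng = np.random.default_rng(31)
        for placement in _random_placements(tree, rng, 20):
            analytic = tt.objective_at(tree, placement, dates,
                                       tt.Criterion.RSS)
            explicit = explicit_objective(tree, placement, dates,
                                          tt.Criterion.RSS)
            assert analytic == pytest.approx(explicit, abs=1e-10)

    def test_variance_matches_explicit_reroot(self, noisy_sim):
        tree, _, _ = noisy_sim
        rng = np.random.default_rng(12)
        for placement in _random_placements(tree, rng, 10):
            analytic = tt.objective_at(tree, placement, None,
                                       tt.Criterion.VARIANCE)
            explicit = explicit_objective(tree, placement, None,
                                          tt.Criterion.VARIANCE)
            assert analytic == pytest.approx(explicit, abs=1e-12)

    def test_rss_requires_dates(self, star_tree):
        placement = tt.RootPlacement(star_tree.root.children[0], 0.5)
        with pytest.raises(MissingDatesError):
            tt.objective_at(star_tree, placement, None, tt.Criterion.RSS)


class TestOptimizeOnEdge:
    def test_two_tip_variance_minimised_at_equidistant_point(self):
        # variance hits 0 at the point equidistant from both tips: halfway
        # along the B edge here (fractions measured from the parent end)
        tree = tt.read_newick("(A:0,B:2);")
        edge = next(n for n in tree.edges() if n.label == "B")
        eo = tt.optimize_on_edge(tree, edge, None, tt.Criterion.VARIANCE)
        assert eo.argmin == pytest.approx(0.5, abs=1e-12)
        assert eo.value == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_tree_already_rooted_at_optimum(self):
        tree = tt.read_newick("(A:1,B:1);")
        edge = tree.root.children[0]
        eo = tt.optimize_on_edge(tree, edge, None, tt.Criterion.VARIANCE)
        assert eo.argmin == 0.0 and eo.value == pytest.approx(0.0,
                                                              abs=1e-15)

    def test_true_root_position_has_zero_rss_noise_free(self, noisefree_sim):
        tree, dates, _ = noisefree_sim
        # on the original rooting, fraction 0 of any root-child edge IS
        # the true root: a perfect fit exists there
        eo = tt.optimize_on_edge(tree, tree.root.children[0], dates,
                                 tt.Criterion.RSS)
        assert eo.value <= 1e-15

    def test_quadratic_matches_direct_evaluation(self, noisy_sim):
        tree, dates, _ = noisy_sim
        for child in tree.edges():
            eo = tt.optimize_on_edge(tree, child, dates, tt.Criterion.RSS)
            for x in (0.0, 0.5, 1.0):
                direct = tt.objective_at(
                    tree, tt.RootPlacement(child, x), dates,
                    tt.Criterion.RSS)
                assert eo(x) == pytest.approx(direct, abs=1e-10)
            assert 0.0 <= eo.argmin <= 1.0

    def test_argmin_matches_dense_grid_search(self):
        cfg = tt.SimulationConfig(n_tips=10, rate_noise=0.15, seed=77)
        tree, dates, _ = tt.simulate_clock_tree(cfg)
        grid = np.linspace(0.0, 1.0, 10_001)
        for child in tree.edges()[:6]:
            if child.length == 0:
                continue
            eo = tt.optimize_on_edge(tree, child, dates, tt.Criterion.RSS)
            rss = grid_rss(tree, child, dates, grid)
            best = int(np.argmin(rss))
            assert abs(eo.argmin - grid[best]) <= grid[1] - grid[0]
            assert eo.value <= rss[best] + 1e-10


class TestFindBestRoot:
    def test_noise_free_recovery_from_scrambled_rooting(self):
        cfg = tt.SimulationConfig(n_tips=20, rate=3e-3, rate_noise=0.0,
                                  seed=1)
        tree, dates, truth = tt.simulate_clock_tree(cfg)
        true_depths = tt.root_to_tip_distances(tree)
        scrambled, _ = tt.scramble_root(tree, seed=99)
        res = tt.find_best_root(scrambled, dates, tt.Criterion.RSS)
        assert res.fit.slope == pytest.approx(3e-3, abs=1e-8)
        assert res.objective <= 1e-15
        # recovered root point reproduces the true rooting's metric
        got = tt.root_to_tip_distances(res.tree)
        for label, depth in true_depths.items():
            assert got[label] == pytest.approx(depth, abs=1e-6)

    def test_idempotent_when_already_optimal(self):
        cfg = tt.SimulationConfig(n_tips=15, rate_noise=0.1, seed=8)
        tree, dates, _ = tt.simulate_clock_tree(cfg)
        first = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        second = tt.find_best_root(first.tree, dates, tt.Criterion.RSS)
        assert second.objective == pytest.approx(first.objective, abs=1e-12)

    def test_never_worse_than_input_rooting(self, noisy_sim):
        tree, dates, _ = noisy_sim
        input_rss = fit_tree(tree, dates)[0].rss
        res = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        assert res.objective <= input_rss + 1e-12

    def test_global_minimum_matches_brute_force(self):
        grid = np.linspace(0.0, 1.0, 2001)
        for seed in (101, 102, 103):
            cfg = tt.SimulationConfig(n_tips=12, rate_noise=0.15, seed=seed)
            tree, dates, _ = tt.simulate_clock_tree(cfg)
            brute = min(
                float(np.min(grid_rss(tree, child, dates, grid)))
                for child in tree.edges()
            )
            res = tt.find_best_root(tree, dates, tt.Criterion.RSS)
            assert res.objective <= brute + 1e-10
            assert res.objective == pytest.approx(brute, abs=1e-8)

    def test_optimal_among_random_placements(self, noisy_sim):
        tree, dates, _ = noisy_sim
        res = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        rng = np.random.default_rng(55)
        for placement in _random_placements(tree, rng, 1000):
            assert res.objective <= tt.objective_at(
                tree, placement, dates, tt.Criterion.RSS) + 1e-12

    def test_refit_on_returned_tree_equals_reported_fit(self, noisy_sim):
        tree, dates, _ = noisy_sim
        res = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        refit, _ = fit_tree(res.tree, dates)
        assert refit.rss == pytest.approx(res.fit.rss, abs=1e-10)
        assert refit.slope == pytest.approx(res.fit.slope, rel=1e-10)

    def test_variance_recovers_root_of_ultrametric_tree(self):
        cfg = tt.SimulationConfig(n_tips=25, rate_noise=0.0, seed=6)
        tree, _, _ = tt.simulate_clock_tree(cfg)
        ultra = tt.make_ultrametric(tree)
        true_depths = tt.root_to_tip_distances(ultra)
        scrambled, _ = tt.scramble_root(ultra, seed=13)
        res = tt.find_best_root(scrambled, None, tt.Criterion.VARIANCE)
        assert res.variance == pytest.approx(0.0, abs=1e-12)
        got = tt.root_to_tip_distances(res.tree)
        for label, depth in true_depths.items():
            assert got[label] == pytest.approx(depth, abs=1e-8)

    def test_deterministic_output(self, noisy_sim):
        tree, dates, _ = noisy_sim
        a = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        b = tt.find_best_root(tree, dates, tt.Criterion.RSS)
        assert a.placement.fraction == b.placement.fraction
        assert a.placement.child is b.placement.child
        assert tt.write_newick(a.tree) == tt.write_newick(b.tree)

    def test_isochronous_dates_rejected_for_rss(self, star_tree):
        dates = tt.TipDateSet(times={"A": 2000.0, "B": 2000.0, "C": 2000.0})
        with pytest.raises(IsochronousDataError, match="VARIANCE"):
            tt.find_best_root(star_tree, dates, tt.Criterion.RSS)
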