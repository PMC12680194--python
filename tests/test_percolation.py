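"""Newman-Ziff percolation, robustness measures, susceptibility peaks."""

import itertools

import numpy as np
import pytest

import networkx as nx

from nncrn import (
    GeneratorSpec,
    Graph,
    PercolationCurve,
    RemovalPlan,
    ensemble_curves,
    erdos_renyi,
    f_threshold,
    fixture_graph,
    make_removal_plan,
    newman_ziff_run,
    robustness_R,
    summarize_robustness,
    susceptibility_peaks,
)


def exact_mean_lcc_by_subset(g: Graph, mode: str) -> np.ndarray:
    """Independent oracle: exact E[N_LCC] at each occupation number by
    enumerating all subsets (uniform n-subsets = uniform removal orders)."""
    gx = g.to_networkx()
    if mode == "random_edge":
        items = list(gx.edges())
    else:
        items = list(gx.nodes())
    out = np.zeros(len(items) + 1)
    for n in range(len(items) + 1):
        sizes = []
        for subset in itertools.combinations(items, n):
            if mode == "random_edge":
                h = nx.Graph()
                h.add_nodes_from(gx.nodes())
                h.add_edges_from(subset)
            else:
                h = gx.subgraph(subset)
            comps = list(nx.connected_components(h))
            sizes.append(max((len(c) for c in comps), default=0))
        out[n] = np.mean(sizes)
    if mode == "random_edge" and g.n_nodes > 0:
        out[0] = 1  # all nodes present; a lone node is a component of size 1
    return out


class TestRemovalPlans:
    def test_star_targeted_removes_center_first(self, rng):
        g = fixture_graph("star_5")
        plan = make_removal_plan(g, "targeted_degree", rng)
        assert plan.elements[-1] == 0  # last added = first removed = the hub

    def test_edge_plan_is_permutation(self, rng):
        g = fixture_graph("clique_3")
        plan = make_removal_plan(g, "random_edge", rng)
        assert sorted(map(tuple, np.sort(plan.elements, axis=1))) == sorted(g.edges())

    def test_targeted_ties_broken_uniformly(self):
        """On a regular graph all targeted orders are valid; every node
        should be removed first with roughly equal frequency."""
        g = fixture_graph("cycle_4")
        rng = np.random.default_rng(0)
        first_removed = np.zeros(4)
        n_trials = 1000
        for _ in range(n_trials):
            plan = make_removal_plan(g, "targeted_degree", rng)
            first_removed[plan.elements[-1]] += 1
        p = 0.25
        se = np.sqrt(p * (1 - p) / n_trials)
        assert np.all(np.abs(first_removed / n_trials - p) < 5 * se)

    def test_unknown_mode_raises(self, p4, rng):
        with pytest.raises(ValueError):
            make_removal_plan(p4, "cascade", rng)


class TestNewmanZiffRun:
    def test_k3_every_edge_order(self):
        g = fixture_graph("clique_3")
        for perm in itertools.permutations(g.edges()):
            plan = RemovalPlan("random_edge", np.array(perm), 3, 3)
            assert newman_ziff_run(g, plan).tolist() == [1, 2, 3, 3]

    def test_single_node_site_sequence(self):
        g = Graph(1)
        plan = RemovalPlan("random_node", np.array([0]), 1, 0)
        assert newman_ziff_run(g, plan).tolist() == [0, 1]

    def test_path_node_addition_hand_case(self, p4):
        plan = RemovalPlan("random_node", np.array([0, 3, 1, 2]), 4, 3)
        assert newman_ziff_run(p4, plan).tolist() == [0, 1, 1, 2, 4]

    def test_sequences_nondecreasing(self, rng):
        g = erdos_renyi(GeneratorSpec.er(100, 3.0, seed=1))
        for mode in ("random_edge", "random_node", "targeted_degree"):
            seq = newman_ziff_run(g, make_removal_plan(g, mode, rng))
            assert np.all(np.diff(seq) >= 0)

    def test_plan_graph_mismatch_raises(self, p4, star4, rng):
        plan = make_removal_plan(p4, "random_edge", rng)
        with pytest.raises(ValueError):
            newman_ziff_run(fixture_graph("path_5"), plan)

    def test_all_modes_agree_at_full_occupation(self, rng):
        g = erdos_renyi(GeneratorSpec.er(80, 2.0, seed=2))
        finals = {
            mode: newman_ziff_run(g, make_removal_plan(g, mode, rng))[-1]
            for mode in ("random_edge", "random_node", "targeted_degree")
        }
        gx = g.to_networkx()
        lcc = max(len(c) for c in nx.connected_components(gx))
        assert set(finals.values()) == {lcc}


class TestEnsembleCurves:
    def test_k3_mean_curve_exact(self, rng):
        g = fixture_graph("clique_3")
        curve = ensemble_curves(g, "random_edge", 7, rng)
        assert np.allclose(curve.mean_lcc, [1, 2, 3, 3])
        assert np.allclose(curve.chi, 0.0)

    def test_single_run_curve_equals_run(self, rng):
        g = erdos_renyi(GeneratorSpec.er(50, 3.0, seed=3))
        curve = ensemble_curves(g, "random_edge", 1, rng)
        assert np.allclose(curve.chi, 0.0)
        assert curve.mean_lcc[-1] == curve.mean_lcc.max()

    @pytest.mark.parametrize("mode", ["random_edge", "random_node"])
    @pytest.mark.parametrize("name", ["path_4", "star_4", "cycle_5", "clique_4"])
    def test_matches_exhaustive_enumeration_oracle(self, name, mode):
        """Ensemble means at 1e4 runs agree with exact subset-enumeration
        expectations within 5 standard errors at every grid point."""
        g = fixture_graph(name)
        exact = exact_mean_lcc_by_subset(g, mode)
        n_runs = 10_000
        curve = ensemble_curves(g, mode, n_runs, np.random.default_rng(99))
        var = curve.second_moment_lcc - curve.mean_lcc**2
        se = np.sqrt(np.maximum(var, 0) / n_runs)
        assert np.all(np.abs(curve.mean_lcc - exact) <= 5 * se + 1e-12)

    def test_six_node_graph_against_oracle(self):
        # 6 nodes, 8 edges: a denser irregular test case
        g = Graph(6, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (3, 5), (1, 4)])
        for mode in ("random_edge", "random_node"):
            exact = exact_mean_lcc_by_subset(g, mode)
            n_runs = 10_000
            curve = ensemble_curves(g, mode, n_runs, np.random.default_rng(7))
            var = curve.second_moment_lcc - curve.mean_lcc**2
            se = np.sqrt(np.maximum(var, 0) / n_runs)
            assert np.all(np.abs(curve.mean_lcc - exact) <= 5 * se + 1e-12)

    def test_second_moment_dominates_mean_squared(self, rng):
        g = erdos_renyi(GeneratorSpec.er(100, 3.0, seed=4))
        curve = ensemble_curves(g, "random_node", 20, rng)
        assert np.all(curve.second_moment_lcc >= curve.mean_lcc**2 - 1e-9)


class TestFThreshold:
    def test_read_off_definition(self):
        curve = PercolationCurve(
            mode="random_edge",
            n_nodes=1000,
            n_edges=10,
            n_runs=10,
            occupied=np.array([1, 2, 3, 4]),
            mean_lcc=np.array([1.0, 5.0, 20.0, 500.0]),
            second_moment_lcc=np.zeros(4),
        )
        # p grid = (0.1, 0.2, 0.3, 0.4); threshold 1% of N = 10
        p_x, f_x = f_threshold(curve, 0.01)
        assert (p_x, f_x) == (0.2, 0.8)

    def test_empty_set_convention(self, rng):
        # K3 edge mode: mean LCC >= 1 > 0.03 everywhere -> p=0, f=1
        curve = ensemble_curves(fixture_graph("clique_3"), "random_edge", 3, rng)
        assert f_threshold(curve, 0.01) == (0.0, 1.0)

    def test_node_mode_always_defined(self, rng):
        g = erdos_renyi(GeneratorSpec.er(200, 3.0, seed=5))
        curve = ensemble_curves(g, "random_node", 5, rng)
        p_x, f_x = f_threshold(curve, 0.01)
        assert 0.0 <= p_x <= 1.0 and f_x == 1.0 - p_x


class TestRobustnessR:
    def test_k3_exact(self, rng):
        curve = ensemble_curves(fixture_graph("clique_3"), "random_edge", 5, rng)
        assert robustness_R(curve) == pytest.approx(0.75)

    def test_single_isolated_node(self):
        g = Graph(1)
        curve = ensemble_curves(g, "random_node", 2, np.random.default_rng(0))
        assert robustness_R(curve) == pytest.approx(0.5)

    def test_empty_edge_graph(self, rng):
        g = Graph(10)
        curve = ensemble_curves(g, "random_edge", 2, rng)
        assert robustness_R(curve) == pytest.approx(1 / 10)


class TestSusceptibilityPeaks:
    def test_synthetic_two_peaks(self):
        curve = PercolationCurve(
            mode="random_edge",
            n_nodes=100,
            n_edges=10,
            n_runs=5,
            occupied=np.array([1, 2, 3, 4, 5]),
            mean_lcc=np.ones(5),
            second_moment_lcc=np.array([1.0, 2.0, 1.0, 3.0, 1.0]),
        )
        # chi = (0, 1, 0, 2, 0) on p = (0.1..0.5)
        peaks = susceptibility_peaks(curve)
        assert [pk.p_star for pk in peaks] == [pytest.approx(0.2), pytest.approx(0.4)]
        assert peaks[0].f_star == pytest.approx(0.8)
        assert peaks[1].f_star == pytest.approx(0.6)

    def test_unimodal_single_peak(self):
        curve = PercolationCurve(
            mode="random_edge",
            n_nodes=100,
            n_edges=4,
            n_runs=5,
            occupied=np.arange(1, 6),
            mean_lcc=np.ones(5),
            second_moment_lcc=np.array([1.0, 2.0, 4.0, 2.0, 1.0]),
        )
        assert len(susceptibility_peaks(curve)) == 1

    def test_too_few_grid_points_raises(self):
        curve = PercolationCurve(
            mode="random_edge",
            n_nodes=2,
            n_edges=1,
            n_runs=5,
            occupied=np.array([0, 1]),
            mean_lcc=np.ones(2),
            second_moment_lcc=np.ones(2),
        )
        with pytest.raises(ValueError):
            susceptibility_peaks(curve)


def test_er_bond_percolation_threshold(rng):
    """For ER with <k>=5 the bond-percolation threshold is 1/<k> = 0.2;
    the dominant susceptibility peak must fall within +-0.05 of it."""
    g = erdos_renyi(GeneratorSpec.er(1000, 5.0, seed=42))
    curve = ensemble_curves(g, "random_edge", 100, rng)
    peaks = susceptibility_peaks(curve, smooth_window=31, min_prominence_frac=0.25)
    assert len(peaks) >= 1
    top = max(peaks, key=lambda pk: pk.chi_star)
    assert abs(top.p_star - 0.2) < 0.05


def test_summarize_robustness_payload(rng):
    g = erdos_renyi(GeneratorSpec.er(300, 5.0, seed=6))
    summary = summarize_robustness(
        ensemble_curves(g, "random_edge", 20, rng), x=0.01
    )
    d = summary.to_dict()
    assert set(d) >= {"mode", "p_x", "f_x", "R", "peaks", "runs"}
    assert d["f_x"] == pytest.approx(1 - d["p_x"])
    assert 0 < d["R"] <= 1
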