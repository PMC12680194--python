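"""Metropolis rewiring chains: hard constraints, acceptance rule, trends."""

import math

import numpy as np
import pytest

from nncrn import (
    GeneratorSpec,
    Graph,
    PairMomentStats,
    RewiringConfig,
    acceptance_probability,
    conditional_degree_profile,
    erdos_renyi,
    estimate_r2ext,
    generate_1nncrn,
    generate_2nncrn,
    mh_step,
    powerlaw_configuration,
)


def two_state_graph():
    """The degree sequence (1,1,2,2) admits exactly two labeled simple
    graphs; start from one of them (path 0-2-3-1)."""
    return Graph(4, [(0, 2), (2, 3), (1, 3)])


class TestAcceptanceRule:
    def test_zero_coupling_always_accepts(self):
        assert acceptance_probability(0.0, -0.3) == 1.0
        assert acceptance_probability(0.0, 0.3) == 1.0

    def test_formula_value(self):
        assert acceptance_probability(10.0, -0.1) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )
        assert acceptance_probability(10.0, 0.1) == 1.0

    def test_paper_sign_flag_flips_coupling(self):
        for j, dr in [(2.0, 0.1), (3.0, -0.2), (-1.5, 0.05)]:
            assert acceptance_probability(j, dr, paper_sign=True) == pytest.approx(
                acceptance_probability(-j, dr)
            )

    def test_detailed_balance_ratio(self):
        """For any state pair connected by one swap, the forward/backward
        acceptance ratio equals exp(J·(r' − r))."""
        for j in (-3.0, 0.5, 2.0):
            for dr in (-0.2, 0.01, 0.15):
                fwd = acceptance_probability(j, dr)
                bwd = acceptance_probability(j, -dr)
                assert fwd / bwd == pytest.approx(math.exp(j * dr), rel=1e-12)


class TestConfigValidation:
    def test_bad_target_distance(self):
        with pytest.raises(ValueError):
            RewiringConfig(target_distance=3)

    def test_bad_lazy_probability(self):
        with pytest.raises(ValueError):
            RewiringConfig(target_distance=1, lazy_prob=1.5)

    def test_coupling_in_units_of_m(self):
        cfg = RewiringConfig(target_distance=1, J=2.0, j_units="M")
        assert cfg.effective_J(100) == 200.0
        assert cfg.budget(100) == int(1e4) * 100


class TestMhStep:
    def test_step_keeps_stats_in_sync(self, p4, rng):
        cfg = RewiringConfig(target_distance=1, J=0.5, lazy_prob=0.3)
        g = p4.copy()
        stats = PairMomentStats.from_graph(g, 1)
        seen = set()
        for _ in range(300):
            outcome, stats = mh_step(g, stats, cfg, rng)
            seen.add(outcome)
        ref = PairMomentStats.from_graph(g, 1)
        assert (stats.n, stats.s1, stats.s2, stats.s11) == (
            ref.n,
            ref.s1,
            ref.s2,
            ref.s11,
        )
        assert sorted(g.degrees()) == [1, 1, 2, 2]
        assert "rejected-lazy" in seen and "applied" in seen

    def test_distance_two_step_preserves_profile(self, rng):
        g = powerlaw_configuration(GeneratorSpec.powerlaw(60, seed=2))
        before = conditional_degree_profile(g, 1).counts.copy()
        cfg = RewiringConfig(target_distance=2, J=1.0, lazy_prob=0.0)
        stats = PairMomentStats.from_graph(g, 2)
        for _ in range(200):
            _, stats = mh_step(g, stats, cfg, rng)
        after = conditional_degree_profile(g, 1).counts
        assert np.array_equal(before, after)

    def test_mismatched_stats_distance_raises(self, p4, rng):
        cfg = RewiringConfig(target_distance=2)
        with pytest.raises(ValueError):
            mh_step(p4, PairMomentStats.from_graph(p4, 1), cfg, rng)


class TestZeroCouplingUniformity:
    def test_uniform_over_two_state_space(self):
        """At J = 0 the chain is uniform over the two labeled graphs with
        degree sequence (1,1,2,2) (chi-square on thinned samples)."""
        from scipy.stats import chisquare

        g = two_state_graph()
        cfg = RewiringConfig(target_distance=1, J=0.0, lazy_prob=0.5)
        rng = np.random.default_rng(2024)
        stats = PairMomentStats.from_graph(g, 1)
        counts = [0, 0]
        n_steps, thin = 150_000, 30
        for step in range(n_steps):
            _, stats = mh_step(g, stats, cfg, rng)
            if (step + 1) % thin == 0:
                counts[int(g.has_edge(0, 2))] += 1
        assert min(counts) > 0
        assert chisquare(counts).pvalue > 0.01


class TestGenerate1NNCRN:
    def test_degree_sequence_hard_constraint(self):
        g0 = erdos_renyi(GeneratorSpec.er(300, 5.0, seed=3))
        cfg = RewiringConfig(
            target_distance=1, J=2.0, j_units="M", budget_sweeps=50, seed=4
        )
        g1, trace = generate_1nncrn(g0, cfg)
        assert np.array_equal(np.sort(g0.degrees()), np.sort(g1.degrees()))
        assert np.array_equal(g0.degrees(), g1.degrees())  # per-node, in fact
        assert sum(trace.outcome_counts.values()) == trace.n_proposals

    def test_same_seed_reproducible(self):
        g0 = erdos_renyi(GeneratorSpec.er(200, 5.0, seed=5))
        cfg = RewiringConfig(
            target_distance=1, J=1.0, j_units="M", budget_sweeps=20, seed=6
        )
        a, ta = generate_1nncrn(g0, cfg)
        b, tb = generate_1nncrn(g0, cfg)
        assert a.edges() == b.edges()
        assert ta.final_r1 == tb.final_r1

    def test_monotone_response_of_r1_to_coupling(self):
        """Mean equilibrium r1 is strictly ordered with J across
        {-2M, 0, +2M} (5 seeds each, reduced scale)."""
        means = []
        for j in (-2.0, 0.0, 2.0):
            vals = []
            for s in range(5):
                g0 = erdos_renyi(GeneratorSpec.er(400, 5.0, seed=30 + s))
                cfg = RewiringConfig(
                    target_distance=1,
                    J=j,
                    j_units="M",
                    budget_sweeps=100,
                    seed=50 + s,
                )
                _, tr = generate_1nncrn(g0, cfg)
                vals.append(tr.final_r1)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[0] < -0.3 and means[2] > 0.3

    def test_regular_graph_raises(self, cycle5):
        cfg = RewiringConfig(target_distance=1, J=0.0, budget_sweeps=1)
        from nncrn import ZeroVarianceError

        with pytest.raises(ZeroVarianceError):
            generate_1nncrn(cycle5, cfg)

    def test_trace_dataframe_layout(self):
        g0 = erdos_renyi(GeneratorSpec.er(100, 5.0, seed=8))
        cfg = RewiringConfig(
            target_distance=1, J=0.0, budget_sweeps=10, seed=9, trace_points=20
        )
        _, tr = generate_1nncrn(g0, cfg)
        df = tr.to_dataframe()
        assert list(df.columns) == ["proposal_index", "r1", "r2", "outcome"]
        assert len(df) == 20


@pytest.fixture(scope="module")
def chain_pair():
    g1 = powerlaw_configuration(GeneratorSpec.powerlaw(300, seed=12))
    cfg = RewiringConfig(
        target_distance=2,
        J=2.0,
        j_units="M",
        n_proposals=200_000,
        seed=13,
        full_recompute_interval=20_000,
    )
    g2, trace = generate_2nncrn(g1, cfg)
    return g1, g2, trace


class TestGenerate2NNCRN:

    def test_joint_degree_profile_exactly_preserved(self, chain_pair):
        g1, g2, _ = chain_pair
        before = conditional_degree_profile(g1, 1)
        after = conditional_degree_profile(g2, 1)
        assert np.array_equal(before.counts, after.counts)
        assert before.degrees.tolist() == after.degrees.tolist()

    def test_r1_unchanged_within_float_tolerance(self, chain_pair):
        from nncrn import pearson_r_at_distance

        g1, g2, trace = chain_pair
        assert pearson_r_at_distance(g2, 1) == pytest.approx(
            pearson_r_at_distance(g1, 1), abs=1e-9
        )
        assert trace.final_r1 == pytest.approx(pearson_r_at_distance(g1, 1), abs=1e-9)

    def test_final_r2_matches_from_scratch_recomputation(self, chain_pair):
        """Kernel-maintained incremental statistics agree exactly with an
        independent pure-python recomputation on the final graph."""
        _, g2, trace = chain_pair
        assert trace.final_r2 == pytest.approx(
            PairMomentStats.from_graph(g2, 2).r, abs=1e-12
        )

    def test_monotone_response_of_r2_to_coupling(self):
        means = []
        for j in (-2.0, 2.0):
            vals = []
            for s in range(3):
                g1 = erdos_renyi(GeneratorSpec.er(400, 5.0, seed=70 + s))
                cfg = RewiringConfig(
                    target_distance=2,
                    J=j,
                    j_units="M",
                    budget_sweeps=60,
                    seed=90 + s,
                )
                _, tr = generate_2nncrn(g1, cfg)
                vals.append(tr.final_r2)
            means.append(np.mean(vals))
        assert means[0] < 0 < means[1]


class TestEstimateR2Ext:
    def test_single_sample_has_no_sd(self):
        g1 = erdos_renyi(GeneratorSpec.er(150, 5.0, seed=14))
        cfg = RewiringConfig(
            target_distance=2, J=0.0, budget_sweeps=20, seed=15
        )
        mean, sd = estimate_r2ext(g1, 1, cfg)
        assert sd is None and np.isfinite(mean)

    def test_uncorrelated_baseline_near_zero(self):
        """An ER-derived network with r1 about 0 has r2_ext about 0."""
        g0 = erdos_renyi(GeneratorSpec.er(1000, 5.0, seed=16))
        g1, _ = generate_1nncrn(
            g0,
            RewiringConfig(
                target_distance=1, J=0.0, budget_sweeps=50, seed=17
            ),
        )
        cfg = RewiringConfig(target_distance=2, J=0.0, budget_sweeps=80, seed=18)
        mean, sd = estimate_r2ext(g1, 20, cfg)
        assert sd is not None
        assert abs(mean) < 0.03

    def test_nonzero_coupling_rejected(self):
        g1 = erdos_renyi(GeneratorSpec.er(100, 5.0, seed=19))
        cfg = RewiringConfig(target_distance=2, J=1.0, budget_sweeps=10)
        with pytest.raises(ValueError):
            estimate_r2ext(g1, 5, cfg)
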