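import numpy as np
import pytest

from immunet.dynamics import (
    SimulationParams,
    _sigmoid,
    advance_state,
    blockade_rescue_experiment,
    rescue_score,
    resolve_target_state,
    simulate_ensemble,
)
from immunet.graph import SignedWeightedDigraph
from immunet.intervention import apply_blockade

from .conftest import random_signed_graph


class TestTargetResolution:
    def test_unregulated_node_returns_basal(self):
        g = SignedWeightedDigraph.empty(("a", "b"))
        assert resolve_target_state(np.array([0.3, 0.7]), g, "a", 0.25) == 0.25

    def test_saturated_activator(self):
        g = SignedWeightedDigraph.from_edges(("a", "b"), [("a", "b", 1.0)])
        assert resolve_target_state(np.array([1.0, 0.0]), g, "b", 0.25) == 1.0

    def test_activation_and_inhibition_combine_fuzzy(self):
        # activator contribution 0.8, inhibitor contribution 0.5 -> 0.4
        g = SignedWeightedDigraph.from_edges(
            ("act", "inh", "t"), [("act", "t", 1.0), ("inh", "t", -1.0)]
        )
        target = resolve_target_state(np.array([0.8, 0.5, 0.0]), g, "t", 0.25)
        assert target == pytest.approx(0.8 * (1 - 0.5))

    def test_result_always_in_unit_interval(self, rng):
        for _ in range(30):
            g = random_signed_graph(5, 0.5, rng)
            states = rng.uniform(0, 1, 5)
            for node in g.node_names:
                t = resolve_target_state(states, g, node, rng.uniform(0, 1))
                assert 0.0 <= t <= 1.0


class TestAdvance:
    def test_fixed_point_under_empty_graph(self):
        g = SignedWeightedDigraph.empty(("a", "b"))
        params = SimulationParams(basal=0.3)
        fix = np.full(2, _sigmoid(0.3, params.steepness))
        out = advance_state(fix, g, params, np.full(2, 10.0))
        assert np.allclose(out, fix)

    def test_unit_ratio_jumps_to_shaped_target(self):
        g = SignedWeightedDigraph.empty(("a",))
        params = SimulationParams(basal=0.8, dt=1.0)
        out = advance_state(np.array([0.1]), g, params, np.array([1.0]))
        assert out[0] == pytest.approx(float(_sigmoid(0.8, params.steepness)))

    def test_monotone_approach_from_below(self):
        g = SignedWeightedDigraph.empty(("a",))
        params = SimulationParams(basal=0.9)
        x = np.array([0.05])
        prev = x[0]
        for _ in range(50):
            x = advance_state(x, g, params, np.array([8.0]))
            assert x[0] >= prev - 1e-12
            prev = x[0]

    def test_nonpositive_time_constant_rejected(self):
        g = SignedWeightedDigraph.empty(("a",))
        with pytest.raises(ValueError, match="positive"):
            advance_state(np.array([0.5]), g, SimulationParams(), np.array([0.0]))


class TestEnsemble:
    def test_zero_sd_makes_runs_identical(self, rng):
        g = random_signed_graph(4, 0.5, rng)
        params = SimulationParams(
            time_constant_sd=0.0, n_runs=5, horizon=20, seed=3
        )
        trace = simulate_ensemble(g, np.full(4, 0.9), params)
        assert np.allclose(trace.runs, trace.runs[0])
        assert np.allclose(trace.sd, 0.0)

    def test_states_bounded_for_random_parameters(self, rng):
        for _ in range(5):
            g = random_signed_graph(5, 0.5, rng, weight_scale=3.0)
            params = SimulationParams(
                steepness=float(rng.uniform(1, 20)),
                time_constant_mean=float(rng.uniform(2, 20)),
                time_constant_sd=float(rng.uniform(0, 5)),
                n_runs=3,
                horizon=40,
                basal=float(rng.uniform(0, 1)),
                seed=int(rng.integers(1000)),
            )
            trace = simulate_ensemble(g, rng.uniform(0, 1, 5), params)
            assert np.all(trace.runs >= 0.0) and np.all(trace.runs <= 1.0)

    def test_trace_length_and_horizon_zero(self, rng):
        g = random_signed_graph(3, 0.5, rng)
        trace = simulate_ensemble(
            g, np.full(3, 0.5), SimulationParams(horizon=0, n_runs=2)
        )
        assert trace.runs.shape == (2, 3, 1)

    def test_deterministic_per_seed(self, rng):
        g = random_signed_graph(4, 0.5, rng)
        params = SimulationParams(n_runs=4, horizon=15, seed=11)
        a = simulate_ensemble(g, np.full(4, 0.9), params)
        b = simulate_ensemble(g, np.full(4, 0.9), params)
        assert np.array_equal(a.runs, b.runs)

    def test_empty_graph_relaxes_to_shaped_basal(self):
        g = SignedWeightedDigraph.empty(("a", "b"))
        params = SimulationParams(basal=0.4, horizon=300, n_runs=1,
                                  time_constant_sd=0.0)
        trace = simulate_ensemble(g, np.array([0.95, 0.05]), params)
        target = float(_sigmoid(0.4, params.steepness))
        assert np.allclose(trace.runs[0, :, -1], target, atol=1e-6)


class TestBlockadeEquivalence:
    def test_edited_graph_matches_structural_removal(self, rng):
        g = random_signed_graph(5, 0.6, rng)
        blocked = apply_blockade(g, {"n1"})
        # structurally built twin without n1's outgoing edges
        twin = g.copy()
        twin.A[:, 1] = 0.0
        twin.A[1, 1] = g.A[1, 1]
        params = SimulationParams(n_runs=3, horizon=25, seed=5)
        x0 = np.full(5, 0.9)
        a = simulate_ensemble(blocked, x0, params)
        b = simulate_ensemble(twin, x0, params)
        assert np.array_equal(a.runs, b.runs)


class TestRescue:
    def _traces(self, rng):
        g_src = random_signed_graph(4, 0.5, rng)
        g_tgt = random_signed_graph(4, 0.5, rng)
        params = SimulationParams(n_runs=3, horizon=20, seed=2)
        x0 = np.full(4, 0.9)
        src = simulate_ensemble(g_src, x0, params, "source")
        tgt = simulate_ensemble(g_tgt, x0, params, "target")
        return src, tgt

    def test_perfect_null_and_midpoint_scores(self, rng):
        src, tgt = self._traces(rng)
        scores = rescue_score(src, tgt, tgt)
        assert all(v == pytest.approx(1.0) for v in scores.values())
        scores = rescue_score(src, tgt, src)
        assert all(v == pytest.approx(0.0) for v in scores.values())
        mid = simulate_ensemble(
            SignedWeightedDigraph.empty(src.node_names),
            np.full(4, 0.5),
            SimulationParams(n_runs=3, horizon=20, seed=2),
            "treated",
        )
        mid.runs = 0.5 * (src.runs + tgt.runs)
        mid.__post_init__()
        scores = rescue_score(src, tgt, mid)
        assert all(v == pytest.approx(0.5) for v in scores.values())

    def test_degenerate_denominator_flagged_zero(self, rng, caplog):
        src, tgt = self._traces(rng)
        with caplog.at_level("WARNING"):
            scores = rescue_score(src, src, tgt)
        assert all(v == 0.0 for v in scores.values())

    def test_shared_parameters_across_scenarios(self, rng):
        source = random_signed_graph(4, 0.5, rng)
        target = random_signed_graph(4, 0.5, rng)
        treated = apply_blockade(source, {"n0"})
        params = SimulationParams(n_runs=4, horizon=15, seed=9)
        traces, scores = blockade_rescue_experiment(
            source, target, treated, np.full(4, 0.9), params
        )
        assert set(traces) == {"source", "target", "treated"}
        assert set(scores) == set(source.node_names)
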