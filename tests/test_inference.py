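import numpy as np
import pytest

from immunet.aggregates import AggregateTimeCourse
from immunet.graph import AGGREGATE_NODES, SignedWeightedDigraph
from immunet.inference import (
    InferenceConfig,
    SAConfig,
    broken_stick_select,
    broken_stick_thresholds,
    calibrate_inference,
    edge_fscore,
    estimate_derivatives,
    fit_rate_matrix,
    infer_subject_network,
    prune_to_network,
)
from immunet.knowledge import ReferenceNetwork, SignedEdge
from immunet.synthetic import sample_group_network, simulate_trajectory


def course(scores, times=None, names=AGGREGATE_NODES):
    scores = np.asarray(scores, dtype=float)
    if times is None:
        times = 3.0 * np.arange(scores.shape[1])
    return AggregateTimeCourse(
        subject_id="s", group="HC", node_names=tuple(names[: scores.shape[0]]),
        times=np.asarray(times, float), scores=scores,
    )


def reference_from_matrix(A, names=AGGREGATE_NODES):
    g = prune_to_network(A, 0.0, names)
    return ReferenceNetwork(
        node_names=tuple(names),
        edges={
            (s, t): SignedEdge(s, t, int(np.sign(w))) for s, t, w in g.edges()
        },
    )


class TestDerivatives:
    def test_linear_series_give_constant_slope(self):
        x = np.vstack([2.0 * np.arange(10), np.full(10, 3.0)])
        c = course(x, times=3.0 * np.arange(10), names=("a", "b"))
        rates = estimate_derivatives(c)
        assert np.allclose(rates[0], 2.0 / 3.0)
        assert np.allclose(rates[1], 0.0)

    def test_quadratic_exact_at_interior_points(self):
        t = 3.0 * np.arange(12)
        x = (0.25 * t**2)[None, :].repeat(2, axis=0)
        rates = estimate_derivatives(course(x, times=t, names=("a", "b")))
        assert np.allclose(rates[:, 1:-1], 0.5 * t[1:-1])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_derivatives(course(np.ones((2, 2)), names=("a", "b")))


def broken_stick_oracle(p):
    # independent double-loop evaluation of the expected stick fractions
    return np.array([sum(1.0 / i for i in range(k, p + 1)) / p
                     for k in range(1, p + 1)])


class TestBrokenStick:
    @pytest.mark.parametrize("p", range(1, 21))
    def test_thresholds_match_closed_form(self, p):
        assert np.allclose(broken_stick_thresholds(p), broken_stick_oracle(p))

    def test_documented_examples(self):
        assert broken_stick_select([0.6, 0.25, 0.1, 0.05], 1.0) == 1
        assert broken_stick_select([0.97, 0.03], 1.0) == 1
        assert broken_stick_select([0.4, 0.3, 0.2, 0.1], 1e-12) == 4

    def test_selection_matches_rule_across_lambda_grid(self, rng):
        for p in (3, 5, 9, 14, 20):
            b = broken_stick_oracle(p)
            for lam in (0.1, 0.5, 1.0, 2.0, 4.0):
                fr = np.sort(rng.dirichlet(np.ones(p)))[::-1]
                K = broken_stick_select(fr, lam, p)
                expected = 0
                for k in range(p):
                    if fr[k] > lam * b[k]:
                        expected += 1
                    else:
                        break
                assert K == max(expected, 1)


class TestRateFit:
    def test_noiseless_recovery_with_exact_rates(self):
        A = sample_group_network(9, 0.3, weight_scale=1.0, seed=11)
        times = 0.1 * np.arange(81)
        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 1, 9)
        traj = simulate_trajectory(A, x0, np.zeros(9), times)
        rates = A @ traj
        cfg = InferenceConfig(broken_stick_scale=1e-12)
        dense = fit_rate_matrix(course(traj, times=times), rates, cfg)
        assert np.max(np.abs(dense.A - A)) < 0.05

    def test_single_active_source_yields_single_column(self):
        rngl = np.random.default_rng(3)
        x = np.zeros((4, 40))
        x[0] = rngl.normal(0, 1, 40)
        A = np.zeros((4, 4))
        A[:, 0] = [0.0, 0.7, -0.4, 0.2]
        rates = A @ x
        dense = fit_rate_matrix(
            course(x, names=("a", "b", "c", "d")), rates,
            InferenceConfig(broken_stick_scale=1e-12),
        )
        off = np.abs(dense.A[:, 1:])
        assert np.max(off) < 0.05 * np.max(np.abs(dense.A))

    def test_node_permutation_equivariance(self):
        A = sample_group_network(5, 0.5, weight_scale=1.0, seed=4)
        times = 0.1 * np.arange(60)
        traj = simulate_trajectory(
            A, np.random.default_rng(1).normal(0, 1, 5), np.zeros(5), times
        )
        rates = A @ traj
        names = ("a", "b", "c", "d", "e")
        cfg = InferenceConfig(broken_stick_scale=1e-12)
        base = fit_rate_matrix(course(traj, times, names), rates, cfg)
        perm = [2, 0, 4, 1, 3]
        permuted = fit_rate_matrix(
            course(traj[perm], times, tuple(names[i] for i in perm)),
            rates[perm], cfg,
        )
        assert np.allclose(
            permuted.reorder(names).A, base.A, atol=1e-6
        )

    def test_degenerate_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_rate_matrix(
                course(np.ones((3, 30)), names=("a", "b", "c")),
                np.zeros((3, 30)),
            )


class TestPruning:
    def test_zero_threshold_keeps_everything(self):
        A = np.array([[0.0, 1.0], [0.4, -0.2]])
        g = prune_to_network(A, 0.0, ("a", "b"))
        assert g.n_edges() == 2

    def test_relative_threshold_drops_weak_edge(self):
        A = np.array([[0.0, 1.0], [0.4, 0.0]])
        g = prune_to_network(A, 0.5, ("a", "b"))
        assert g.edge_set() == {("b", "a")}

    def test_near_one_threshold_keeps_single_strongest(self):
        rngl = np.random.default_rng(0)
        A = rngl.normal(0, 1, (6, 6))
        g = prune_to_network(A, 0.999, [f"n{i}" for i in range(6)])
        assert g.n_edges() <= 1

    def test_all_zero_matrix_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            g = prune_to_network(np.zeros((3, 3)), 0.1, ("a", "b", "c"))
        assert g.n_edges() == 0

    def test_diagonal_preserved(self):
        A = np.diag([-1.0, -2.0]) + np.array([[0.0, 0.001], [0.9, 0.0]])
        g = prune_to_network(A, 0.5, ("a", "b"))
        assert g.A[0, 0] == -1.0 and g.A[1, 1] == -2.0


class TestEdgeFscore:
    def test_identity_half_and_disjoint(self):
        names = ("a", "b", "c")
        ref = SignedWeightedDigraph.from_edges(
            names, [("a", "b", 1.0), ("b", "c", 1.0)]
        )
        assert edge_fscore(ref, ref) == (1.0, 1.0, 1.0)
        half = SignedWeightedDigraph.from_edges(names, [("a", "b", 1.0)])
        r, p, f = edge_fscore(half, ref)
        assert (r, p) == (0.5, 1.0) and f == pytest.approx(2.0 / 3.0)
        disjoint = SignedWeightedDigraph.from_edges(names, [("c", "a", 1.0)])
        assert edge_fscore(disjoint, ref) == (0.0, 0.0, 0.0)

    def test_counting_identity_on_random_graphs(self, rng):
        from .conftest import random_signed_graph

        for _ in range(20):
            a = random_signed_graph(6, 0.4, rng)
            b = random_signed_graph(6, 0.4, rng)
            r, p, _ = edge_fscore(a, b)
            matches = len(a.edge_set() & b.edge_set())
            assert r * b.n_edges() == pytest.approx(matches)
            assert p * a.n_edges() == pytest.approx(matches)

    def test_empty_inferred_reports_zero_ppv(self, caplog):
        names = ("a", "b")
        ref = SignedWeightedDigraph.from_edges(names, [("a", "b", 1.0)])
        empty = SignedWeightedDigraph.empty(names)
        with caplog.at_level("WARNING"):
            r, p, f = edge_fscore(empty, ref)
        assert (r, p, f) == (0.0, 0.0, 0.0)


class TestCalibration:
    def _training(self, seed=0, n_subjects=4):
        A = sample_group_network(9, 0.3, seed=seed)
        times = 3.0 * np.arange(81)
        rngl = np.random.default_rng(seed)
        courses = [
            course(
                simulate_trajectory(
                    A, 1 + rngl.normal(0.5, 0.15, 9), np.ones(9), times
                ) - 1.0,
                times=times,
            )
            for _ in range(n_subjects)
        ]
        return courses, reference_from_matrix(A), A

    def test_collapsed_bounds_return_that_point(self):
        courses, ref, _ = self._training()
        cfg, _ = calibrate_inference(
            courses, ref, lambda_bounds=(0.5, 0.5), theta_bounds=(0.2, 0.2),
            sa_config=SAConfig(iterations=10), seed=0,
        )
        assert cfg.broken_stick_scale == 0.5
        assert cfg.prune_threshold == 0.2

    def test_deterministic_given_seed(self):
        courses, ref, _ = self._training()
        a, traj_a = calibrate_inference(courses, ref, seed=5)
        b, traj_b = calibrate_inference(courses, ref, seed=5)
        assert a == b and traj_a == traj_b

    def test_calibrated_config_beats_naive_default(self):
        courses, ref, A = self._training(seed=2)
        cfg, _ = calibrate_inference(courses, ref, seed=1)
        truth = prune_to_network(A, 0.0, AGGREGATE_NODES)
        f_cal = np.mean(
            [edge_fscore(infer_subject_network(c, cfg), truth)[2] for c in courses]
        )
        f_def = np.mean(
            [
                edge_fscore(infer_subject_network(c, InferenceConfig()), truth)[2]
                for c in courses
            ]
        )
        assert f_cal >= f_def

    def test_empty_bounds_rejected(self):
        courses, ref, _ = self._training()
        with pytest.raises(ValueError, match="bounds"):
            calibrate_inference(courses, ref, lambda_bounds=(2.0, 1.0))
        with pytest.raises(ValueError, match="training"):
            calibrate_inference([], ref)
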