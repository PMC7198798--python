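import heapq
import itertools

import numpy as np
import pytest

from immunet.graph import SignedWeightedDigraph
from immunet.netmetrics import (
    FFL_TYPES,
    classify_ffls,
    find_feedback_loops,
    ged_significance,
    graph_edit_distance,
    hits_scores,
    node_centralities,
)

from .conftest import random_signed_graph


class TestGED:
    def test_identity_and_documented_raw_example(self):
        a = SignedWeightedDigraph(("x", "y"), np.array([[0.0, 1.0], [0.0, 0.0]]))
        b = SignedWeightedDigraph(("x", "y"), np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert graph_edit_distance(a, a) == 0.0
        assert graph_edit_distance(a, b, normalize=False) == 2.0

    def test_raw_mode_matches_elementwise_oracle(self, rng):
        for _ in range(50):
            A = rng.normal(0, 1, (9, 9))
            B = rng.normal(0, 1, (9, 9))
            expected = sum(
                abs(A[i, j] - B[i, j])
                for i in range(9)
                for j in range(9)
                if i != j
            )
            assert graph_edit_distance(A, B, normalize=False) == pytest.approx(
                expected
            )

    def test_normalized_mode_is_a_metric_on_normalized_matrices(self, rng):
        mats = [rng.normal(0, 1, (5, 5)) for _ in range(3)]
        a, b, c = mats
        dab = graph_edit_distance(a, b)
        assert dab == pytest.approx(graph_edit_distance(b, a))
        assert dab + graph_edit_distance(b, c) >= graph_edit_distance(a, c) - 1e-12
        assert 0.0 <= dab <= 2.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_edit_distance(np.zeros((3, 3)), np.zeros((4, 4)))


class TestGEDSignificance:
    def test_deterministic_and_reports_direction(self, rng):
        e1 = [random_signed_graph(5, 0.4, rng) for _ in range(6)]
        e2 = [random_signed_graph(5, 0.4, rng) for _ in range(6)]
        a = ged_significance(e1, e2, n_draws=10, seed=3)
        b = ged_significance(e1, e2, n_draws=10, seed=3)
        assert a["inter"] == b["inter"]
        assert a["direction"] in ("inter>intra", "intra>inter")

    def test_identical_ensembles_give_p_one(self, rng):
        g = random_signed_graph(5, 0.5, rng)
        ens = [g.copy() for _ in range(5)]
        out = ged_significance(ens, [g.copy() for _ in range(5)], seed=0)
        assert out["ranksum_p_inter_vs_intra"] == 1.0

    def test_singleton_ensembles_rejected(self, rng):
        g = random_signed_graph(4, 0.5, rng)
        with pytest.raises(ValueError, match=">= 2"):
            ged_significance([g], [g, g], seed=0)


def dijkstra_oracle(lengths, source):
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v in range(n):
            if np.isfinite(lengths[u, v]):
                nd = d + lengths[u, v]
                if nd < dist[v] - 1e-15:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    return dist


def betweenness_oracle(g):
    """Brute-force shortest-path enumeration over all simple paths."""
    import networkx as nx

    G = g.to_networkx()
    names = list(g.node_names)
    n = len(names)
    count_through = {v: 0.0 for v in names}
    for s, t in itertools.permutations(names, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t, weight="length"))
        except nx.NetworkXNoPath:
            continue
        for v in names:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            count_through[v] += frac
    scale = (n - 1) * (n - 2)
    return {v: c / scale for v, c in count_through.items()}


class TestCentralities:
    def test_path_betweenness_hand_value(self):
        g = SignedWeightedDigraph.from_edges(
            ("x", "y", "z"), [("x", "y", 1.0), ("y", "z", 1.0)]
        )
        table = node_centralities(g)
        assert table.loc["y", "betweenness"] == pytest.approx(0.5)

    def test_isolated_node_all_zero(self):
        g = SignedWeightedDigraph.from_edges(
            ("x", "y", "z"), [("x", "y", 1.0)]
        )
        table = node_centralities(g)
        assert (table.loc["z"] == 0).all()

    def test_weight_doubling_leaves_betweenness_unchanged(self, rng):
        g = random_signed_graph(6, 0.4, rng)
        doubled = SignedWeightedDigraph(g.node_names, 2.0 * g.A)
        a = node_centralities(g)["betweenness"]
        b = node_centralities(doubled)["betweenness"]
        assert np.allclose(a, b)

    def test_degrees_sum_absolute_weights(self, rng):
        g = random_signed_graph(6, 0.5, rng)
        table = node_centralities(g)
        absA = np.abs(g.A.copy())
        np.fill_diagonal(absA, 0.0)
        assert np.allclose(table["indegree"], absA.sum(axis=1))
        assert np.allclose(table["outdegree"], absA.sum(axis=0))

    def test_closeness_matches_dijkstra_oracle(self, rng):
        for _ in range(10):
            g = random_signed_graph(7, 0.35, rng)
            with np.errstate(divide="ignore"):
                lengths = np.where(
                    (np.abs(g.A) > 0) & ~np.eye(7, dtype=bool),
                    1.0 / np.where(np.abs(g.A) > 0, np.abs(g.A), 1.0), np.inf,
                )
            table = node_centralities(g)
            for i in range(7):
                # incloseness of i: sum over sources j of 1/d(j -> i);
                # d uses lengths[target, source] = A-orientation paths
                harm_in = 0.0
                harm_out = 0.0
                for j in range(7):
                    if i == j:
                        continue
                    # graph edges: src -> tgt with length on (tgt, src)
                    d_ji = dijkstra_oracle(lengths.T, j)[i]
                    d_ij = dijkstra_oracle(lengths.T, i)[j]
                    if np.isfinite(d_ji):
                        harm_in += 1.0 / d_ji
                    if np.isfinite(d_ij):
                        harm_out += 1.0 / d_ij
                assert table["incloseness"].iloc[i] == pytest.approx(harm_in)
                assert table["outcloseness"].iloc[i] == pytest.approx(harm_out)

    def test_betweenness_matches_path_enumeration_oracle(self, rng):
        for _ in range(5):
            g = random_signed_graph(6, 0.4, rng)
            expected = betweenness_oracle(g)
            got = node_centralities(g)["betweenness"]
            for v, e in expected.items():
                assert got[v] == pytest.approx(e, abs=1e-9)


class TestHITS:
    def test_fan_out_fixed_point(self):
        g = SignedWeightedDigraph.from_edges(
            ("x", "y", "z"), [("x", "y", 1.0), ("x", "z", 1.0)]
        )
        hub, auth = hits_scores(g)
        assert np.allclose(hub, [1.0, 0.0, 0.0])
        assert np.allclose(auth, [0.0, 0.5, 0.5])

    def test_symmetric_two_cycle(self):
        g = SignedWeightedDigraph.from_edges(
            ("x", "y"), [("x", "y", 1.0), ("y", "x", 1.0)]
        )
        hub, auth = hits_scores(g)
        assert np.allclose(hub, [0.5, 0.5]) and np.allclose(auth, [0.5, 0.5])

    def test_agrees_with_dominant_eigenvectors(self, rng):
        for _ in range(10):
            g = random_signed_graph(7, 0.4, rng)
            if g.n_edges() == 0:
                continue
            hub, auth = hits_scores(g, tol=1e-12)
            B = np.abs(g.A.copy())
            np.fill_diagonal(B, 0.0)
            for M, vec in ((B @ B.T, auth), (B.T @ B, hub)):
                w, V = np.linalg.eigh(M)
                lead = np.abs(V[:, np.argmax(w)])
                if lead.sum() > 0 and vec.sum() > 0:
                    assert np.allclose(vec, lead / lead.sum(), atol=1e-6)

    def test_relabeling_permutes_scores(self, rng):
        g = random_signed_graph(5, 0.5, rng)
        perm = [3, 1, 4, 0, 2]
        names = tuple(g.node_names[i] for i in perm)
        pg = g.reorder(names)
        hub, auth = hits_scores(g)
        hub_p, auth_p = hits_scores(pg)
        assert np.allclose(hub_p, hub[perm]) and np.allclose(auth_p, auth[perm])

    def test_edgeless_graph_warns_zero(self, caplog):
        g = SignedWeightedDigraph.empty(("x", "y"))
        with caplog.at_level("WARNING"):
            hub, auth = hits_scores(g)
        assert not hub.any() and not auth.any()


class TestMotifs:
    @pytest.mark.parametrize("signs,expected", list(FFL_TYPES.items()))
    def test_all_eight_sign_triples(self, signs, expected):
        s1, s2, s3 = signs
        g = SignedWeightedDigraph.from_edges(
            ("X", "Y", "Z"),
            [("X", "Y", float(s1)), ("Y", "Z", float(s2)), ("X", "Z", float(s3))],
        )
        records = classify_ffls(g)
        rec = next(r for r in records if r.nodes == ("X", "Y", "Z"))
        assert rec.classification == expected
        coherent = expected.startswith("C")
        assert (s1 * s2 == s3) == coherent

    def test_triad_scan_matches_brute_force(self, rng):
        for _ in range(10):
            g = random_signed_graph(9, 0.3, rng)
            sign = np.sign(g.A)
            expected = 0
            n = len(g.node_names)
            for x, y, z in itertools.permutations(range(n), 3):
                if sign[y, x] and sign[z, y] and sign[z, x]:
                    expected += 1
            assert len(classify_ffls(g)) == expected

    def test_positive_feedback_two_cycle(self):
        g = SignedWeightedDigraph.from_edges(
            ("MK2", "MK23"), [("MK2", "MK23", 1.0), ("MK23", "MK2", 1.0)]
        )
        loops = find_feedback_loops(g)
        assert len(loops) == 1
        assert loops[0].classification == "positive"
        assert loops[0].kind == "feedback_2cycle"

    def test_mixed_sign_cycle_is_negative(self):
        g = SignedWeightedDigraph.from_edges(
            ("a", "b"), [("a", "b", 1.0), ("b", "a", -1.0)]
        )
        assert find_feedback_loops(g)[0].classification == "negative"

    def test_acyclic_graph_has_no_loops(self):
        g = SignedWeightedDigraph.from_edges(
            ("a", "b", "c"), [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", -1.0)]
        )
        assert find_feedback_loops(g) == []

    def test_cycle_signs_equal_edge_sign_products(self, rng):
        for _ in range(10):
            g = random_signed_graph(6, 0.4, rng)
            idx = g.index
            for rec in find_feedback_loops(g, max_len=3):
                prod = 1
                cyc = list(rec.nodes)
                for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                    prod *= int(np.sign(g.A[idx[v], idx[u]]))
                assert rec.classification == (
                    "positive" if prod > 0 else "negative"
                )
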