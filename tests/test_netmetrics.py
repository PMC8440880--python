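"""Weighted graph measures vs independent oracles and invariances."""
import itertools

import networkx as nx
import numpy as np
import pytest

import neuromass as nm
from neuromass.netmetrics import (
    betweenness, node_strength, metric_table, recruitment_order_profile,
    threshold_metric_analysis, weighted_clustering, weighted_shortest_paths,
)


def barrat_brute(W):
    """Triple-enumeration oracle for the Barrat coefficient."""
    A = (W > 0).astype(int)
    n = W.shape[0]
    s, k = W.sum(1), A.sum(1)
    c = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != h and A[i, j] and A[i, h] and A[j, h]:
                    acc += (W[i, j] + W[i, h]) / 2.0
        c[i] = acc / (s[i] * (k[i] - 1))
    return c


def floyd_warshall(W):
    L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    D = L.copy()
    for k in range(W.shape[0]):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    return D


def betweenness_brute(W):
    """Exhaustive shortest-path enumeration (unordered pairs)."""
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    cb = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        try:
            paths = list(nx.all_shortest_paths(G, i, j, weight="length"))
        except nx.NetworkXNoPath:
            continue
        for s in range(n):
            if s in (i, j):
                continue
            cb[s] += sum(1 for p in paths if s in p) / len(paths)
    return cb


class TestStrength:
    def test_complete_graph(self):
        n, w = 5, 0.3
        W = np.full((n, n), w)
        np.fill_diagonal(W, 0.0)
        s, S = node_strength(nm.ConnectomeMatrix(W))
        assert np.allclose(s, (n - 1) * w) and S == pytest.approx((n - 1) * w)

    def test_chain_and_isolated(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.2
        W[1, 2] = W[2, 1] = 0.8
        s, _ = node_strength(nm.ConnectomeMatrix(W))
        assert np.allclose(s, [0.2, 1.0, 0.8, 0.0])


class TestClustering:
    def test_uniform_triangle_is_one(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]) * 0.4
        c, C = weighted_clustering(nm.ConnectomeMatrix(W))
        assert np.allclose(c, 1.0) and C == pytest.approx(1.0)

    def test_star_center_zero(self, star_conn):
        c, _ = weighted_clustering(star_conn)
        assert c[0] == 0.0

    def test_matches_triple_enumeration(self, random_graph_8):
        c, _ = weighted_clustering(random_graph_8)
        assert np.allclose(c, barrat_brute(random_graph_8.weights),
                           atol=1e-12)

    def test_matches_igraph_barrat(self, random_graph_8):
        igraph = pytest.importorskip("igraph")
        W = random_graph_8.weights
        g = igraph.Graph.Weighted_Adjacency(W.tolist(), mode="undirected")
        ref = np.array(g.transitivity_local_undirected(mode="zero",
                                                       weights="weight"))
        c, _ = weighted_clustering(random_graph_8)
        assert np.allclose(c, ref, atol=1e-12)


class TestShortestPaths:
    def test_chain_distance(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        sp = weighted_shortest_paths(nm.ConnectomeMatrix(W))
        assert sp.D[0, 2] == pytest.approx(4.0)

    def test_doubling_weights_halves_distances(self, random_graph_8):
        d1 = weighted_shortest_paths(random_graph_8).D
        d2 = weighted_shortest_paths(
            nm.ConnectomeMatrix(2.0 * random_graph_8.weights)
        ).D
        finite = np.isfinite(d1)
        assert np.allclose(d2[finite], d1[finite] / 2.0)

    def test_matches_floyd_warshall(self, random_graph_8):
        sp = weighted_shortest_paths(random_graph_8)
        D_fw = floyd_warshall(random_graph_8.weights)
        finite = np.isfinite(D_fw)
        assert np.allclose(sp.D[finite], D_fw[finite], atol=1e-12)
        assert np.array_equal(np.isfinite(sp.D), finite)


class TestBetweenness:
    def test_star_center_and_leaves(self, star_conn):
        cb = betweenness(star_conn)
        n = star_conn.n_regions
        assert cb[0] == pytest.approx((n - 1) * (n - 2) / 2.0)
        assert np.allclose(cb[1:], 0.0)

    def test_matches_exhaustive_enumeration(self, random_graph_8):
        cb = betweenness(random_graph_8)
        assert np.allclose(cb, betweenness_brute(random_graph_8.weights),
                           atol=1e-12)


class TestInvariances:
    def test_permutation_invariance(self, random_graph_8):
        rng = np.random.default_rng(3)
        perm = rng.permutation(random_graph_8.n_regions)
        Wp = random_graph_8.weights[np.ix_(perm, perm)]
        t0 = metric_table(random_graph_8)
        t1 = metric_table(nm.ConnectomeMatrix(Wp))
        for col in ("strength", "clustering", "path_length", "betweenness"):
            assert np.allclose(
                t1[col].to_numpy(), t0[col].to_numpy()[perm], atol=1e-10
            )

    def test_scale_covariance(self, random_graph_8):
        c = 3.7
        t0 = metric_table(random_graph_8)
        t1 = metric_table(nm.ConnectomeMatrix(c * random_graph_8.weights))
        assert np.allclose(t1["strength"], c * t0["strength"])
        assert np.allclose(t1["path_length"], t0["path_length"] / c)
        assert np.allclose(t1["clustering"], t0["clustering"], atol=1e-12)
        assert np.allclose(t1["betweenness"], t0["betweenness"], atol=1e-12)


class TestThresholdMetricAnalysis:
    def _map(self, eta_asy, eta_gen):
        from neuromass.protocols import ThresholdMap

        n = len(eta_asy)
        return ThresholdMap(
            eta_grid=np.arange(1), areas=np.arange(n),
            eta_asy=np.asarray(eta_asy, float),
            eta_gen=np.asarray(eta_gen, float),
            n_recruited=np.zeros((n, 1), int),
            saturated=np.zeros(1, bool),
        )

    def test_perfect_anticorrelation(self, random_graph_8):
        mt = metric_table(random_graph_8)
        tmap = self._map(-mt["strength"], -mt["strength"])
        df = threshold_metric_analysis(tmap, mt)
        row = df[(df.metric == "strength") & (df.threshold == "eta_gen")]
        assert row.pearson_r.iloc[0] == pytest.approx(-1.0)

    def test_shuffled_metric_uncorrelated(self, random_graph_8):
        mt = metric_table(random_graph_8).copy()
        rng = np.random.default_rng(11)
        thr = rng.permutation(mt["strength"].to_numpy())
        df = threshold_metric_analysis(self._map(thr, thr), mt)
        row = df[(df.metric == "strength") & (df.threshold == "eta_gen")]
        assert abs(row.pearson_r.iloc[0]) < 0.6

    def test_constant_metric_undefined(self, random_graph_8):
        mt = metric_table(random_graph_8)
        mt["strength"] = 1.0
        df = threshold_metric_analysis(
            self._map(mt["clustering"], mt["clustering"]), mt
        )
        row = df[(df.metric == "strength") & (df.threshold == "eta_asy")]
        assert np.isnan(row.pearson_r.iloc[0])


class TestOrderProfile:
    def _result(self, stimulated, order, times, n):
        rt = np.full(n, np.nan)
        for k, t in zip(order, times):
            rt[k] = t
        from neuromass.protocols import RecruitmentResult

        return RecruitmentResult(recruit_time=rt, stimulated=stimulated,
                                 r_c=np.full(n, 0.05))

    def test_star_fixture_exact_values(self, star_conn):
        W = star_conn.weights
        res = self._result((0,), [0, 1, 2, 3], [0.0, 10.0, 20.0, 30.0], 8)
        prof = recruitment_order_profile([res], star_conn)
        assert prof.loc[prof.position == 1, "weight_to_ez"].iloc[0] == \
            pytest.approx(W[1, 0])
        # position-1 weight dominates later positions by construction
        w = prof.sort_values("position")["weight_to_ez"].to_numpy()
        assert np.all(w[0] >= w[1:])
        # EZ-excluded strength equals s_i minus the EZ link: leaves of a
        # star lose their only edge
        assert prof.loc[prof.position == 1, "strength_ex"].iloc[0] == 0.0

    def test_ez_excluded_strength_hand_computed(self):
        W = np.array([
            [0.0, 0.5, 0.2, 0.0],
            [0.5, 0.0, 0.4, 0.1],
            [0.2, 0.4, 0.0, 0.3],
            [0.0, 0.1, 0.3, 0.0],
        ])
        conn = nm.ConnectomeMatrix(W)
        res = self._result((0,), [0, 1, 2, 3], [0.0, 5.0, 9.0, 14.0], 4)
        prof = recruitment_order_profile([res], conn)
        # first recruited is node 1: strength without the EZ link
        assert prof.loc[prof.position == 1, "strength_ex"].iloc[0] == \
            pytest.approx(W[1, 2] + W[1, 3])
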