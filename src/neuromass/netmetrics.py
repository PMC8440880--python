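"""Weighted graph measures of connectomes and topology-vs-dynamics analyses.

Edge weights and distances have a reciprocal relation: the length of an
edge is 1/w, so doubling every weight halves every shortest path.  The
clustering coefficient is Barrat's weighted form,

    c_i^w = 1 / (s_i (k_i - 1)) * sum_{j,h} (w_ij + w_ih)/2 a_ij a_ih a_jh,

with s_i the node strength (weighted degree) and a the binary adjacency.
Betweenness is the raw Brandes pair-fraction sum (endpoints excluded,
unnormalised); on symmetric matrices pairs are counted unordered, on
asymmetric ones ordered.
"""
from __future__ import annotations

from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr

from .connectomes import ConnectomeMatrix

__all__ = [
    "node_strength",
    "weighted_clustering",
    "weighted_shortest_paths",
    "betweenness",
    "metric_table",
    "threshold_metric_analysis",
    "recruitment_order_profile",
]


def _weights(conn) -> np.ndarray:
    return conn.weights if isinstance(conn, ConnectomeMatrix) else \
        np.asarray(conn, dtype=float)


def node_strength(conn) -> tuple[np.ndarray, float]:
    """Per-area strength s_i = sum_j w_ij (row sum) and the average S."""
    W = _weights(conn)
    s = W.sum(axis=1)
    return s, float(s.mean())


def weighted_clustering(conn) -> tuple[np.ndarray, float]:
    """Barrat weighted clustering coefficient per area and its average.

    Areas with degree < 2 (no possible triplet) get coefficient 0.
    """
    W = _weights(conn)
    A = (W > 0).astype(float)
    s = W.sum(axis=1)
    k = A.sum(axis=1)
    # ordered-pair form: 0.5 * [sum_j W_ij (A A^T)_ij + sum_j A_ij (W A^T)_ij]
    AAT = A @ A.T
    WAT = W @ A.T
    num = 0.5 * ((W * AAT).sum(axis=1) + (A * WAT).sum(axis=1))
    c = np.zeros_like(s)
    ok = (k >= 2) & (s > 0)
    c[ok] = num[ok] / (s[ok] * (k[ok] - 1.0))
    return c, float(c.mean())


class ShortestPaths(NamedTuple):
    """All-pairs reciprocal-weight distances and their node/network means."""

    D: np.ndarray  # distance matrix, inf where unreachable
    L_node: np.ndarray  # mean distance to reachable others, per node
    L_global: float
    n_unreachable: int  # ordered pairs (i, j), i != j, with no path


def weighted_shortest_paths(conn) -> ShortestPaths:
    """Dijkstra all-pairs distances with edge length 1/w (absent = no edge)."""
    W = _weights(conn)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    D = dijkstra(lengths, directed=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    L_node = np.full(n, np.inf)
    counts = finite.sum(axis=1)
    has = counts > 0
    L_node[has] = np.where(finite, D, 0.0).sum(axis=1)[has] / counts[has]
    n_unreach = int(off.sum() - finite.sum())
    L_global = float(D[finite].mean()) if finite.any() else np.inf
    return ShortestPaths(D, L_node, L_global, n_unreach)


def betweenness(conn, weighted: bool = True) -> np.ndarray:
    """Brandes betweenness c_B(s) = sum_{i!=j!=s} d(i,j|s)/d(i,j).

    Shortest paths use reciprocal-weight lengths when ``weighted``;
    unnormalised, endpoints excluded.  Unordered pairs on symmetric
    matrices, ordered pairs otherwise.
    """
    W = _weights(conn)
    symmetric = np.allclose(W, W.T)
    G = nx.from_numpy_array(
        W, create_using=nx.Graph if symmetric else nx.DiGraph
    )
    if weighted:
        for _, _, d in G.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        cb = nx.betweenness_centrality(G, normalized=False, weight="length")
    else:
        cb = nx.betweenness_centrality(G, normalized=False)
    return np.array([cb[i] for i in range(W.shape[0])])


def metric_table(conn) -> pd.DataFrame:
    """Per-area node measures as a tidy table (0-based ``area`` index).

    Columns: strength, clustering, path_length (mean shortest path to the
    reachable rest), betweenness.  Network averages are stored in
    ``df.attrs["averages"]``.
    """
    s, S = node_strength(conn)
    c, C_W = weighted_clustering(conn)
    sp = weighted_shortest_paths(conn)
    cb = betweenness(conn, weighted=True)
    df = pd.DataFrame({
        "area": np.arange(len(s)),
        "strength": s,
        "clustering": c,
        "path_length": sp.L_node,
        "betweenness": cb,
    })
    df.attrs["averages"] = {
        "strength": S, "clustering": C_W, "path_length": sp.L_global,
        "n_unreachable_pairs": sp.n_unreachable,
    }
    return df


def threshold_metric_analysis(
    threshold_map, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Correlate per-area thresholds with per-area node measures.

    Returns one row per (metric, threshold kind) with the Pearson r and
    two-sided p over areas where both are defined; degenerate (constant)
    columns yield NaN correlations.
    """
    rows = []
    thr = {
        "eta_asy": np.asarray(threshold_map.eta_asy, dtype=float),
        "eta_gen": np.asarray(threshold_map.eta_gen, dtype=float),
    }
    for mname in ("strength", "clustering", "path_length", "betweenness"):
        x_all = metrics[mname].to_numpy(dtype=float)
        for tname, t_all in thr.items():
            ok = np.isfinite(x_all) & np.isfinite(t_all)
            x, t = x_all[ok], t_all[ok]
            if ok.sum() < 3 or np.ptp(x) == 0 or np.ptp(t) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(x, t)
            rows.append({
                "metric": mname, "threshold": tname,
                "pearson_r": r, "p_value": p, "n_areas": int(ok.sum()),
            })
    return pd.DataFrame(rows)


def _submatrix_metrics(W: np.ndarray, exclude: set[int]):
    keep = np.array([i for i in range(W.shape[0]) if i not in exclude])
    Ws = W[np.ix_(keep, keep)]
    sub = ConnectomeMatrix(Ws)
    s, _ = node_strength(sub)
    c, _ = weighted_clustering(sub)
    sp = weighted_shortest_paths(sub)
    cb = betweenness(sub)
    back = {int(a): i for i, a in enumerate(keep)}
    return back, s, c, sp.L_node, cb


def recruitment_order_profile(results, conn) -> pd.DataFrame:
    """Average node measures by recruitment-order position.

    ``results`` is a sequence of recruitment results (each from
    stimulating one EZ on this connectome).  Non-EZ areas are sorted by
    recruitment time; for every order position the table reports the mean
    weight of the direct connection to the EZ, the mean shortest path to
    the EZ, and the mean EZ-excluded node measures (strength, clustering,
    path length, betweenness computed with the EZ removed from the graph).
    """
    W = _weights(conn)
    sp_full = weighted_shortest_paths(conn)
    acc: dict[int, dict[str, list[float]]] = {}
    for res in results:
        ez = set(res.stimulated)
        back, s_ex, c_ex, L_ex, cb_ex = _submatrix_metrics(W, ez)
        order = [a for a in res.order if a not in ez]
        for pos, area in enumerate(order, start=1):
            w_to_ez = float(
                sum(0.5 * (W[area, e] + W[e, area]) for e in ez)
            )
            d_to_ez = float(min(sp_full.D[area, e] for e in ez))
            j = back[area]
            d = acc.setdefault(pos, {k: [] for k in (
                "weight_to_ez", "path_to_ez", "strength_ex",
                "clustering_ex", "path_length_ex", "betweenness_ex",
            )})
            d["weight_to_ez"].append(w_to_ez)
            d["path_to_ez"].append(d_to_ez)
            d["strength_ex"].append(float(s_ex[j]))
            d["clustering_ex"].append(float(c_ex[j]))
            d["path_length_ex"].append(float(L_ex[j]))
            d["betweenness_ex"].append(float(cb_ex[j]))
    rows = []
    for pos in sorted(acc):
        row = {"position": pos,
               "n_runs": len(acc[pos]["weight_to_ez"])}
        for k, vals in acc[pos].items():
            row[k] = float(np.mean(vals))
        rows.append(row)
    return pd.DataFrame(rows)
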