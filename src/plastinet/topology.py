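"""Directed-simplex machinery for connectome-style analyses.

A directed k-simplex is a set of k+1 nodes that are all-to-all connected in a
feed-forward fashion: there is an ordering v0, ..., vk with an edge vi -> vj for
every i < j.  0-simplices are nodes, 1-simplices edges, 2-simplices transitive
triads.  The *k-edge indegree* of an edge (u, v) is the number of k-simplices
all of whose nodes innervate both u and v — equivalently, the number of
(k+2)-simplices in which (u, v) is the edge from the next-to-last to the last
node.  For k=0 this reduces to the common-in-neighbour count of the edge.

Counting uses vertex-ordered DFS with successive out-neighbourhood
intersections (sorted integer arrays); exactness is checked against brute-force
permutation enumeration in the test-suite.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "adjacency_sets",
    "simplex_counts",
    "simplex_counts_brute",
    "k_edge_indegree",
    "k_edge_indegree_brute",
    "subgraph_edge_centrality",
    "pattern_indegree",
    "prob_change_vs_metric",
]


def _as_edge_array(edges) -> np.ndarray:
    """Coerce an edge list (iterable of pairs, (E,2) array, or DirectedNetwork)."""
    if hasattr(edges, "edges") and not isinstance(edges, (list, tuple, np.ndarray)):
        edges = edges.edges  # DirectedNetwork duck-typing
    arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("edge list must be an (E, 2) array of (pre, post) pairs")
    if np.any(arr[:, 0] == arr[:, 1]):
        raise ValueError("self-loops are not allowed")
    return arr


def adjacency_sets(edges, nodes: Iterable[int] | None = None):
    """Return (nodes, out_nbrs, in_nbrs): sorted int arrays per node."""
    arr = _as_edge_array(edges)
    if nodes is None:
        nodes = np.unique(arr) if arr.size else np.empty(0, dtype=np.int64)
    else:
        nodes = np.asarray(sorted(set(int(n) for n in nodes)), dtype=np.int64)
    out_nbrs = {int(n): [] for n in nodes}
    in_nbrs = {int(n): [] for n in nodes}
    for u, v in arr:
        out_nbrs[int(u)].append(int(v))
        in_nbrs[int(v)].append(int(u))
    out_nbrs = {n: np.asarray(sorted(set(s)), dtype=np.int64) for n, s in out_nbrs.items()}
    in_nbrs = {n: np.asarray(sorted(set(s)), dtype=np.int64) for n, s in in_nbrs.items()}
    return nodes, out_nbrs, in_nbrs


def _count_from(candidates: np.ndarray, out_nbrs, counts: np.ndarray, dim: int, max_dim: int):
    """Extend a partial simplex whose joint out-neighbourhood is `candidates`."""
    if dim >= max_dim:
        return
    for u in candidates:
        nxt = np.intersect1d(candidates, out_nbrs[int(u)], assume_unique=True)
        counts[dim + 1] += 1
        if nxt.size:
            _count_from(nxt, out_nbrs, counts, dim + 1, max_dim)


def simplex_counts(edges, max_dim: int = 6, nodes=None) -> np.ndarray:
    """Count directed k-simplices for k = 0..max_dim.

    counts[0] = number of nodes, counts[1] = number of edges.  The DFS never
    visits dimensions above the largest non-empty one, so the scan stops early
    by construction once a dimension yields zero.
    """
    node_ids, out_nbrs, _ = adjacency_sets(edges, nodes)
    counts = np.zeros(max_dim + 1, dtype=np.int64)
    counts[0] = len(node_ids)
    if max_dim == 0:
        return counts
    for v in node_ids:
        cand = out_nbrs[int(v)]
        if cand.size:
            _count_from(cand, out_nbrs, counts, 0, max_dim)
    return counts


def simplex_counts_brute(edges, max_dim: int = 6, nodes=None) -> np.ndarray:
    """Brute-force enumeration oracle (graphs of ~12 nodes at most)."""
    node_ids, out_nbrs, _ = adjacency_sets(edges, nodes)
    edge_set = {(int(u), int(v)) for u, v in _as_edge_array(edges)}
    counts = np.zeros(max_dim + 1, dtype=np.int64)
    counts[0] = len(node_ids)
    for k in range(1, max_dim + 1):
        c = 0
        for subset in combinations(node_ids.tolist(), k + 1):
            # a directed simplex is an ordered tuple: with reciprocal edges one
            # node set can support several feed-forward orderings, each counted
            for perm in permutations(subset):
                if all((perm[i], perm[j]) in edge_set for i in range(k + 1) for j in range(i + 1, k + 1)):
                    c += 1
        counts[k] = c
        if c == 0:
            break
    return counts


def k_edge_indegree(edges, k_max: int = 6, nodes=None) -> pd.DataFrame:
    """k-edge indegree for every edge, k = 0..k_max.

    For an edge (u, v), induce the subgraph on the common in-neighbours
    {w : w->u and w->v}; the k-edge indegree is the number of directed
    k-simplices of that subgraph (k=0: its node count).  Output rows are
    sorted by (pre, post) for reproducible files.
    """
    arr = _as_edge_array(edges)
    node_ids, out_nbrs, in_nbrs = adjacency_sets(arr, nodes)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    cols = {f"k{k}": np.zeros(len(arr), dtype=np.int64) for k in range(k_max + 1)}
    for i, (u, v) in enumerate(arr):
        common = np.intersect1d(in_nbrs[int(u)], in_nbrs[int(v)], assume_unique=True)
        cols["k0"][i] = common.size
        if common.size and k_max >= 1:
            common_set = set(common.tolist())
            sub_edges = [(int(a), int(b)) for a in common for b in out_nbrs[int(a)]
                         if int(b) in common_set]
            sub = simplex_counts(sub_edges, max_dim=k_max, nodes=common)
            for k in range(1, k_max + 1):
                cols[f"k{k}"][i] = sub[k]
    out = pd.DataFrame({"pre": arr[:, 0], "post": arr[:, 1], **cols})
    return out


def k_edge_indegree_brute(edges, k_max: int = 4, nodes=None) -> pd.DataFrame:
    """Oracle: count (k+2)-simplices whose last edge is (u, v), directly."""
    arr = _as_edge_array(edges)
    node_ids, out_nbrs, _ = adjacency_sets(arr, nodes)
    edge_set = {(int(u), int(v)) for u, v in arr}
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    rows = {(int(u), int(v)): np.zeros(k_max + 1, dtype=np.int64) for u, v in arr}
    ids = node_ids.tolist()
    for k in range(0, k_max + 1):
        m = k + 3  # nodes of a (k+2)-simplex
        if m > len(ids):
            break
        for subset in combinations(ids, m):
            for perm in permutations(subset):
                if all((perm[i], perm[j]) in edge_set for i in range(m) for j in range(i + 1, m)):
                    key = (perm[-2], perm[-1])
                    if key in rows:
                        rows[key][k] += 1
    out = pd.DataFrame(
        {"pre": arr[:, 0], "post": arr[:, 1],
         **{f"k{k}": [rows[(int(u), int(v))][k] for u, v in arr] for k in range(k_max + 1)}}
    )
    return out


def subgraph_edge_centrality(edges, node_subset: Sequence[int], k_max: int = 6) -> pd.DataFrame:
    """k-edge indegree on the subgraph induced by ``node_subset``."""
    subset = set(int(n) for n in node_subset)
    if not subset:
        raise ValueError("node_subset is empty")
    arr = _as_edge_array(edges)
    keep = np.array([(int(u) in subset and int(v) in subset) for u, v in arr], dtype=bool)
    sub_edges = arr[keep]
    return k_edge_indegree(sub_edges, k_max=k_max, nodes=sorted(subset))


def pattern_indegree(innervation_edges, pattern_fibers: Iterable[int], node: int) -> int:
    """Number of a pattern's fibers with an edge onto ``node``.

    ``innervation_edges``: iterable of (fiber_id, neuron_id) pairs.
    """
    # bipartite fiber -> neuron map: ids live in separate namespaces, so the
    # digraph coercion (and its self-loop check) does not apply here
    fibers = set(int(f) for f in pattern_fibers)
    return int(sum(1 for u, v in innervation_edges
                   if int(v) == int(node) and int(u) in fibers))


def prob_change_vs_metric(
    edge_flags: Sequence[str],
    metric_values: Sequence[float],
    int_bin_max: int = 2,
    n_log_bins: int = 6,
    min_count: int = 50,
) -> pd.DataFrame:
    """Binned probability-of-change curves against an edge-centrality metric.

    ``edge_flags`` take values in {"unchanged", "depressed", "potentiated"}.
    Integer bins are used for metric values 0..int_bin_max and logarithmic bins
    above; bins with fewer than ``min_count`` edges are suppressed.
    Returns per bin: P(changed), P(depressed | changed), P(potentiated | changed).
    """
    flags = np.asarray(edge_flags, dtype=object)
    vals = np.asarray(metric_values, dtype=float)
    if flags.shape != vals.shape:
        raise ValueError("edge_flags and metric_values must align")
    bad = set(flags.tolist()) - {"unchanged", "depressed", "potentiated"}
    if bad:
        raise ValueError(f"unknown flags: {bad}")
    edges_int = [(-0.5 + i, 0.5 + i) for i in range(int_bin_max + 1)]
    vmax = vals.max() if vals.size else 0
    bins = [lo for lo, _ in edges_int] + [edges_int[-1][1]]
    if vmax > int_bin_max + 0.5:
        log_edges = np.geomspace(int_bin_max + 0.5, max(vmax, int_bin_max + 1.5), n_log_bins + 1)[1:]
        bins = bins + log_edges.tolist()
    bins = np.asarray(bins)
    idx = np.digitize(vals, bins) - 1
    recs = []
    changed = flags != "unchanged"
    for b in range(len(bins) - 1):
        m = idx == b
        n = int(m.sum())
        if n < min_count:
            continue
        n_changed = int(changed[m].sum())
        rec = {
            "bin_left": bins[b],
            "bin_right": bins[b + 1],
            "bin_center": 0.5 * (bins[b] + bins[b + 1]),
            "n": n,
            "p_changed": n_changed / n,
            "p_dep_given_changed": np.nan,
            "p_pot_given_changed": np.nan,
        }
        if n_changed:
            rec["p_dep_given_changed"] = int((flags[m] == "depressed").sum()) / n_changed
            rec["p_pot_given_changed"] = int((flags[m] == "potentiated").sum()) / n_changed
        recs.append(rec)
    return pd.DataFrame(recs)
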