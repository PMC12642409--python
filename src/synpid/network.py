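"""Two-layer interaction networks and partial network decomposition.

From Z-scored per-pair synergy and redundancy values, each layer keeps the
top-k strongest partners per neuron (kNN sparsification, unweighted,
symmetric by union of the directed selections).  The combined network is
the union of the two layers' edge sets.  For each node pair (i, j)
reachable in the union, the shortest-path hop counts dA, dB (per layer)
and dAuB (union) classify the pair:

* complementary — dAuB < min(dA, dB): mixing layers gives a strictly
  shorter route than either layer alone;
* shared — dAuB = max(dA, dB) (hence dA = dB = dAuB);
* unique to A — dAuB = dA < dB; unique to B — dAuB = dB < dA.

Unreachable layer distances are infinite and participate through the
min/max rules; pairs unreachable in the union are excluded and counted.
The categories are exhaustive and mutually exclusive because the union
can only shorten paths (dAuB <= min(dA, dB)).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionLayer",
    "CombinedNetwork",
    "PathClassCounts",
    "build_knn_layer",
    "combine_layers",
    "layer_shortest_paths",
    "classify_paths",
    "path_proportions",
]

CATEGORIES = ("complementary", "shared", "unique_a", "unique_b")


@dataclass(frozen=True)
class InteractionLayer:
    """Unweighted kNN graph over neurons for one interaction metric."""

    graph: nx.Graph
    metric: str      # e.g. "z_si" or "z_ri"
    k: int


@dataclass(frozen=True)
class CombinedNetwork:
    layer_a: InteractionLayer
    layer_b: InteractionLayer
    union: nx.Graph

    def __post_init__(self) -> None:
        if set(self.layer_a.graph) != set(self.layer_b.graph):
            raise ValueError("layers must share the same node set")


@dataclass(frozen=True)
class PathClassCounts:
    """Per-path-length counts of the four pair categories.

    ``counts`` is indexed by combined-network path length L with one column
    per category; ``excluded`` counts pairs unreachable in the union.
    """

    counts: pd.DataFrame
    excluded: int


def build_knn_layer(pair_values: pd.DataFrame, node_ids, k: int,
                    metric: str = "value", mode: str = "union") -> InteractionLayer:
    """Keep each neuron's k strongest partners by a per-pair scalar.

    ``pair_values`` needs columns i, j and ``metric``; pairs with a
    non-finite value are ignored (undefined Z-scores are excluded before
    graph construction).  ``mode='union'`` includes an edge when either
    endpoint selects the other; ``'mutual'`` requires both.  Ties are
    broken toward the smaller neuron id.  Nodes with fewer than k finite
    partners keep all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("union", "mutual"):
        raise ValueError("mode must be 'union' or 'mutual'")
    node_ids = list(node_ids)
    neighbours: dict[int, list] = {u: [] for u in node_ids}
    vals = pair_values[["i", "j", metric]].to_numpy()
    for i, j, v in vals:
        if not np.isfinite(v):
            continue
        i, j = int(i), int(j)
        neighbours[i].append((v, j))
        neighbours[j].append((v, i))
    selected: dict[int, set] = {}
    for u, cand in neighbours.items():
        cand.sort(key=lambda t: (-t[0], t[1]))  # strongest first, then id
        selected[u] = {v for _, v in cand[:k]}
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for u in node_ids:
        for v in selected[u]:
            if mode == "union" or u in selected[v]:
                graph.add_edge(u, v)
    return InteractionLayer(graph=graph, metric=metric, k=k)


def combine_layers(layer_a: InteractionLayer,
                   layer_b: InteractionLayer) -> CombinedNetwork:
    """Union of the two layers' edge sets over the shared node set."""
    union = nx.Graph()
    union.add_nodes_from(layer_a.graph)
    union.add_edges_from(layer_a.graph.edges)
    union.add_edges_from(layer_b.graph.edges)
    return CombinedNetwork(layer_a=layer_a, layer_b=layer_b, union=union)


def layer_shortest_paths(graph: nx.Graph, nodes=None) -> np.ndarray:
    """All-pairs unweighted shortest-path hop counts; inf when unreachable.

    Rows/columns follow ``nodes`` order (default: sorted node ids).
    """
    nodes = sorted(graph) if nodes is None else list(nodes)
    index = {u: a for a, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, lengths in nx.all_pairs_shortest_path_length(graph):
        a = index[u]
        for v, d in lengths.items():
            dist[a, index[v]] = d
    return dist


def classify_paths(net: CombinedNetwork,
                   length_axis: str = "union") -> PathClassCounts:
    """Classify every union-reachable pair and tally by path length.

    ``length_axis`` chooses the tabulation axis: hop count in the union
    graph ('union', default) or the best single-layer distance
    ('min_layer').
    """
    if length_axis not in ("union", "min_layer"):
        raise ValueError("length_axis must be 'union' or 'min_layer'")
    nodes = sorted(net.union)
    d_a = layer_shortest_paths(net.layer_a.graph, nodes)
    d_b = layer_shortest_paths(net.layer_b.graph, nodes)
    d_u = layer_shortest_paths(net.union, nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    da, db, du = d_a[iu, ju], d_b[iu, ju], d_u[iu, ju]
    lo = np.minimum(da, db)
    if np.any(du > lo):
        raise AssertionError("union distance exceeds a layer distance")
    reachable = np.isfinite(du)
    excluded = int((~reachable).sum())
    da, db, du, lo = da[reachable], db[reachable], du[reachable], lo[reachable]
    comp = du < lo
    shared = (du == da) & (du == db)
    uniq_a = (du == da) & (da < db)
    uniq_b = (du == db) & (db < da)
    axis = du if length_axis == "union" else lo
    # on the min_layer axis, pairs connected only through the union have no
    # finite single-layer length and cannot be tabulated
    finite_axis = np.isfinite(axis)
    comp, shared = comp[finite_axis], shared[finite_axis]
    uniq_a, uniq_b = uniq_a[finite_axis], uniq_b[finite_axis]
    lengths = axis[finite_axis].astype(int)
    rows = {}
    for length in np.unique(lengths):
        m = lengths == length
        rows[int(length)] = [int(comp[m].sum()), int(shared[m].sum()),
                             int(uniq_a[m].sum()), int(uniq_b[m].sum())]
    counts = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(CATEGORIES)
    ).rename_axis("path_length").sort_index()
    return PathClassCounts(counts=counts, excluded=excluded)


def path_proportions(counts: PathClassCounts,
                     long_threshold: int = 4) -> tuple[pd.DataFrame, dict]:
    """Per-length category proportions plus the long-path aggregate.

    Returns the per-L proportion table (rows sum to 1) and a dict of
    aggregate proportions over lengths >= ``long_threshold`` (NaN when no
    such pairs exist).
    """
    table = counts.counts
    totals = table.sum(axis=1)
    props = table.div(totals, axis=0)
    long_rows = table[table.index >= long_threshold]
    long_total = long_rows.to_numpy().sum()
    if long_total > 0:
        long_props = {c: float(long_rows[c].sum() / long_total)
                      for c in CATEGORIES}
    else:
        long_props = {c: float("nan") for c in CATEGORIES}
    return props, long_props
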