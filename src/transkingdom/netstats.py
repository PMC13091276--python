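"""Graph metrics, signed community detection, keystones and robustness.

Graphs are undirected, signed and weighted (`networkx.Graph` with ``weight``
and ``sign`` edge attributes).  Path-based metrics interpret edge lengths as
1/|weight| so strong associations are short; unweighted mode is available.
Community detection runs Leiden on the signed modularity Q+ - Q- (the
resolution parameter applies to the positive layer).  Keystones are the top
5% of nodes by summed z-scored degree, betweenness, closeness and
eigenvector centrality.  Robustness curves track the largest connected
component (LCC) under node removal, summarised by the trapezoidal AUC over
the fraction-removed axis and R50, the smallest removed fraction at which
the LCC falls to half its initial size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx


class NetworkStatsError(ValueError):
    pass


def _with_lengths(G: nx.Graph, weighted: bool) -> nx.Graph:
    H = G.copy()
    for u, v, d in H.edges(data=True):
        w = abs(d.get("weight", 1.0))
        d["abs_weight"] = w
        d["length"] = 1.0 / w if (weighted and w > 0) else 1.0
    return H


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_network(G: nx.Graph, for_visualization: bool = False,
                  min_community_size: int = 3) -> nx.Graph:
    """Remove isolated vertices; for visualisation exports additionally drop
    connected components of fewer than ``min_community_size`` nodes.

    Metrics always run on the isolated-vertex-pruned graph only; the small
    component rule is a display convention.
    """
    H = G.copy()
    H.remove_nodes_from(list(nx.isolates(H)))
    if for_visualization:
        small = [c for c in nx.connected_components(H)
                 if len(c) < min_community_size]
        for comp in small:
            H.remove_nodes_from(comp)
    return H


# ---------------------------------------------------------------------------
# Global and node metrics
# ---------------------------------------------------------------------------

def _signed_subgraphs(G: nx.Graph):
    pos = nx.Graph()
    neg = nx.Graph()
    pos.add_nodes_from(G.nodes)
    neg.add_nodes_from(G.nodes)
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        if w >= 0:
            pos.add_edge(u, v, weight=w)
        else:
            neg.add_edge(u, v, weight=-w)
    return pos, neg


def signed_modularity(G: nx.Graph, partition, resolution: float = 1.0) -> float:
    """Q+ - Q-: positive-layer modularity minus negative-layer modularity.

    ``resolution`` applies to the positive layer only.  Layers without edges
    contribute 0.
    """
    pos, neg = _signed_subgraphs(G)
    q = 0.0
    if pos.number_of_edges():
        q += nx.community.modularity(pos, partition, weight="weight",
                                     resolution=resolution)
    if neg.number_of_edges():
        q -= nx.community.modularity(neg, partition, weight="weight")
    return q


def global_metrics(G: nx.Graph, partition=None, resolution: float = 0.5,
                   weighted_paths: bool = True) -> dict:
    """Network-level metric set.

    Modularity (signed, on the supplied partition), global transitivity,
    edge density, average path length and diameter (largest component,
    1/|weight| lengths by default), and edge counts by sign.
    """
    n = G.number_of_nodes()
    m = G.number_of_edges()
    signs = [d.get("sign", "+" if d.get("weight", 1.0) >= 0 else "-")
             for _, _, d in G.edges(data=True)]
    out = {
        "n_nodes": n, "n_edges": m,
        "n_positive_edges": signs.count("+"),
        "n_negative_edges": signs.count("-"),
        "density": (2 * m / (n * (n - 1))) if n > 1 else 0.0,
        "transitivity": nx.transitivity(G) if n else 0.0,
    }
    if partition is not None and n:
        out["modularity"] = signed_modularity(G, partition, resolution)
    else:
        out["modularity"] = np.nan
    if n == 0:
        out.update({"average_path_length": np.nan, "diameter": np.nan,
                    "lcc_flagged": False})
        return out
    H = _with_lengths(G, weighted_paths)
    components = list(nx.connected_components(H))
    lcc = H.subgraph(max(components, key=len))
    out["lcc_flagged"] = len(components) > 1
    if lcc.number_of_nodes() > 1:
        out["average_path_length"] = nx.average_shortest_path_length(
            lcc, weight="length")
        ecc = nx.eccentricity(lcc, sp=dict(
            nx.shortest_path_length(lcc, weight="length")))
        out["diameter"] = max(ecc.values())
    else:
        out["average_path_length"] = np.nan
        out["diameter"] = np.nan
    return out


def node_metrics(G: nx.Graph, weighted_paths: bool = True) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness (harmonic), eigenvector
    centrality, hub score and local transitivity.

    On an undirected graph the HITS hub score coincides with eigenvector
    centrality on |weight|; both columns are reported.
    """
    if G.number_of_nodes() < 2:
        raise NetworkStatsError("need at least two nodes")
    H = _with_lengths(G, weighted_paths)
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(H, weight="length", normalized=True)
    n = H.number_of_nodes()
    harm = nx.harmonic_centrality(H, distance="length")
    closeness = {v: harm[v] / (n - 1) for v in H}
    if G.number_of_edges():
        # dense symmetric eigendecomposition: deterministic, unlike the
        # ARPACK route, which starts from a random vector
        nodes = list(H.nodes)
        A = nx.to_numpy_array(H, nodelist=nodes, weight="abs_weight")
        vals, vecs = np.linalg.eigh(A)
        lead = np.abs(vecs[:, int(np.argmax(vals))])
        norm = np.linalg.norm(lead)
        if norm > 0:
            lead = lead / norm
        eig = dict(zip(nodes, lead))
    else:
        eig = {v: 0.0 for v in H}
    clust = nx.clustering(G)
    df = pd.DataFrame({
        "degree": pd.Series(deg, dtype=float),
        "betweenness": pd.Series(btw),
        "closeness": pd.Series(closeness),
        "eigen_centrality": pd.Series(eig),
        "hub_score": pd.Series(eig),
        "local_transitivity": pd.Series(clust, dtype=float),
    })
    return df.loc[list(G.nodes)]


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def detect_communities(G: nx.Graph, resolution: float = 0.5,
                       seed: int = 0) -> list[set]:
    """Signed Leiden partition (positive minus negative layer).

    Optimises Q+ - Q- by running the Leiden optimiser on a two-layer
    multiplex: the positive subgraph with the given resolution (layer weight
    +1) and the negative subgraph (layer weight -1).  Deterministic for a
    fixed seed.
    """
    import igraph as ig
    import leidenalg as la

    nodes = list(G.nodes)
    if not nodes:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    pos_edges, pos_w, neg_edges, neg_w = [], [], [], []
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        if w >= 0:
            pos_edges.append((index[u], index[v]))
            pos_w.append(w)
        else:
            neg_edges.append((index[u], index[v]))
            neg_w.append(-w)
    g_pos = ig.Graph(n=len(nodes), edges=pos_edges)
    g_neg = ig.Graph(n=len(nodes), edges=neg_edges)
    part_pos = la.RBConfigurationVertexPartition(
        g_pos, weights=pos_w, resolution_parameter=resolution)
    part_neg = la.RBConfigurationVertexPartition(g_neg, weights=neg_w)
    opt = la.Optimiser()
    opt.set_rng_seed(seed)
    opt.optimise_partition_multiplex([part_pos, part_neg],
                                     layer_weights=[1, -1])
    membership = part_pos.membership
    out: dict[int, set] = {}
    for v, c in zip(nodes, membership):
        out.setdefault(c, set()).add(v)
    return [out[c] for c in sorted(out)]


# ---------------------------------------------------------------------------
# Keystones
# ---------------------------------------------------------------------------

def keystone_taxa(metrics: pd.DataFrame,
                  top_fraction: float = 0.05) -> pd.DataFrame:
    """Top ceil(top_fraction * n) nodes by combined centrality z-score.

    The four centralities (degree, betweenness, closeness, eigenvector) are
    z-scored across nodes (population SD; zero-variance metrics contribute
    zeros) and summed.  Ties at the cutoff are all included and flagged.
    """
    cols = ["degree", "betweenness", "closeness", "eigen_centrality"]
    if len(metrics) < 2:
        raise NetworkStatsError("need at least two nodes")
    z = pd.DataFrame(index=metrics.index)
    for c in cols:
        v = metrics[c].to_numpy(dtype=float)
        sd = v.std()
        # guard numerically-constant metrics (e.g. vertex-transitive graphs)
        if sd <= 1e-9 * (np.abs(v).max() + 1e-30):
            z[c + "_z"] = 0.0
        else:
            z[c + "_z"] = (v - v.mean()) / sd
    combined = z.sum(axis=1)
    k = math.ceil(top_fraction * len(metrics))
    # ranking ties are structural, not floating-point artefacts
    order = combined.round(9).sort_values(ascending=False, kind="stable")
    cutoff = order.iloc[k - 1]
    eps = 1e-12
    if cutoff > order.iloc[-1] + eps:
        # ties at the cutoff are all included and flagged
        selected = order[order >= cutoff - eps]
        tied = len(selected) > k
    else:
        # cutoff falls on the minimum score (e.g. hub-and-spokes, or a
        # vertex-transitive graph): keep only nodes strictly above it, or
        # the first k in stable order when every score is identical
        selected = order[order > cutoff + eps]
        tied = True
        if selected.empty:
            selected = order.iloc[:k]
    out = pd.DataFrame({"combined_z": selected})
    out["tied_at_cutoff"] = tied
    return out


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessCurve:
    """LCC trajectory under node removal with AUC and R50 summaries."""

    strategy: str
    fraction_removed: np.ndarray
    lcc_fraction: np.ndarray
    auc: float
    r50: float
    seed: int | None = None
    n_random_reps: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction_removed": self.fraction_removed,
                             "lcc_fraction": self.lcc_fraction})

    def summary(self) -> str:
        return (f"robustness ({self.strategy}): AUC = {self.auc:.3f}, "
                f"R50 = {self.r50:.3f}")


def _lcc_size(G: nx.Graph) -> int:
    if G.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(G))


def _attack_curve(G: nx.Graph, order_fn) -> np.ndarray:
    """LCC sizes after removing 0..n nodes, removal order by ``order_fn``."""
    H = G.copy()
    n0 = H.number_of_nodes()
    sizes = [_lcc_size(H)]
    for _ in range(n0):
        victim = order_fn(H)
        H.remove_node(victim)
        sizes.append(_lcc_size(H))
    return np.array(sizes, dtype=float)


def robustness(G: nx.Graph, strategy: str = "targeted_betweenness",
               n_random_reps: int = 50, seed: int | None = 0,
               adaptive: bool = True,
               weighted_paths: bool = True) -> RobustnessCurve:
    """Attack-robustness curve on the largest connected component.

    Targeted mode removes the currently highest-betweenness node one at a
    time (recomputed after each removal by default; ``adaptive=False`` ranks
    once on the intact graph).  Random mode averages uniform removal orders
    over ``n_random_reps`` replicates.  Curves are normalised by the initial
    LCC size; AUC is the trapezoidal integral over fraction removed in
    [0, 1]; R50 is the smallest fraction at which the LCC is at or below
    half its initial size.
    """
    if G.number_of_nodes() == 0:
        raise NetworkStatsError("empty graph")
    H0 = _with_lengths(G, weighted_paths)
    lcc_nodes = max(nx.connected_components(H0), key=len)
    H0 = H0.subgraph(lcc_nodes).copy()
    n0 = H0.number_of_nodes()

    if strategy == "targeted_betweenness":
        if adaptive:
            def order_fn(H):
                btw = nx.betweenness_centrality(H, weight="length")
                return max(sorted(btw), key=lambda v: btw[v])
            sizes = _attack_curve(H0, order_fn)
        else:
            btw = nx.betweenness_centrality(H0, weight="length")
            ranked = sorted(H0.nodes, key=lambda v: (-btw[v], str(v)))
            queue = iter(ranked)

            def order_fn(H):
                return next(queue)
            sizes = _attack_curve(H0, order_fn)
        curves = sizes[None, :]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        curves = []
        nodes = list(H0.nodes)
        for _ in range(n_random_reps):
            perm = list(rng.permutation(nodes))
            queue = iter(perm)
            curves.append(_attack_curve(H0, lambda H: next(queue)))
        curves = np.array(curves)
    else:
        raise NetworkStatsError(f"unknown strategy {strategy!r}")

    lcc_fraction = curves.mean(axis=0) / n0
    fraction_removed = np.arange(n0 + 1) / n0
    auc = float(np.trapezoid(lcc_fraction, fraction_removed))
    below = np.where(lcc_fraction <= 0.5)[0]
    r50 = float(fraction_removed[below[0]]) if len(below) else 1.0
    return RobustnessCurve(strategy, fraction_removed, lcc_fraction, auc,
                           r50, seed if strategy == "random" else None,
                           n_random_reps if strategy == "random" else None)


def write_visualization(G: nx.Graph, partition, keystones,
                        path) -> nx.Graph:
    """GraphML export for external viewers.

    Applies the display pruning rule (components of <= 2 nodes removed) and
    annotates every node with its community index and keystone flag.  The
    pruned, annotated graph is returned as well as written.
    """
    H = prune_network(G, for_visualization=True)
    community_of = {}
    for i, comm in enumerate(partition):
        for v in comm:
            community_of[v] = i
    keyset = set(keystones.index) if hasattr(keystones, "index") else \
        set(keystones)
    for v in H.nodes:
        H.nodes[v]["community"] = int(community_of.get(v, -1))
        H.nodes[v]["keystone"] = bool(v in keyset)
    nx.write_graphml(H, path)
    return H


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def network_report(G: nx.Graph, resolution: float = 0.5,
                   keystone_fraction: float = 0.05, seed: int = 0,
                   robustness_reps: int = 50) -> dict:
    """Complete metric bundle for one association network.

    Prunes isolated vertices, detects signed Leiden communities, computes
    global and node metrics, keystones, and targeted plus random robustness
    curves.  Empty graphs yield an empty report rather than an error.
    """
    H = prune_network(G)
    if H.number_of_nodes() == 0:
        return {"empty": True, "global": {}, "nodes": pd.DataFrame(),
                "communities": [], "keystones": pd.DataFrame(),
                "robustness": {}}
    partition = detect_communities(H, resolution=resolution, seed=seed)
    gm = global_metrics(H, partition, resolution=resolution)
    nm = node_metrics(H) if H.number_of_nodes() >= 2 else pd.DataFrame()
    keystones = keystone_taxa(nm, keystone_fraction) if len(nm) >= 2 else \
        pd.DataFrame()
    rob = {
        "targeted": robustness(H, "targeted_betweenness"),
        "random": robustness(H, "random", n_random_reps=robustness_reps,
                             seed=seed),
    }
    return {"empty": False, "global": gm, "nodes": nm,
            "communities": [sorted(c) for c in partition],
            "keystones": keystones, "robustness": rob}
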