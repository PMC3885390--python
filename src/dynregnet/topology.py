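"""Topological metrics for directed regulatory (sub-)networks.

Per-node: in/out/total degree, directed clustering coefficient
E_n / (k (k - 1)) over the union neighborhood, normalized betweenness, and
closeness over reachable nodes.  Network-level: their means plus diameter,
average shortest-path length over reachable ordered pairs, and Freeman
degree centralization.  A role-stratified random-subnetwork ensemble gives
the null distribution the observed sub-network metrics are compared to.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import TF, RegulatoryNetwork

NETWORK_METRICS = (
    "n_nodes",
    "n_edges",
    "n_tfs",
    "n_tgs",
    "average_degree",
    "clustering_coefficient",
    "diameter",
    "average_path_length",
    "betweenness",
    "closeness",
    "centralization",
)


def degrees(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node in, out and total degree (total = in + out)."""
    nodes = list(graph.nodes)
    din = dict(graph.in_degree())
    dout = dict(graph.out_degree())
    return pd.DataFrame(
        {
            "in_degree": [din[n] for n in nodes],
            "out_degree": [dout[n] for n in nodes],
            "degree": [din[n] + dout[n] for n in nodes],
        },
        index=nodes,
    )


def clustering_coefficient(graph, node, directed: bool = True) -> float:
    """Neighborhood interconnectivity of a node.

    k is the number of distinct neighbors (union of predecessors and
    successors, self excluded) and E_n the number of edges among them:
    E_n/(k(k-1)) for directed graphs, 2E_n/(k(k-1)) for undirected.
    Nodes with fewer than two neighbors score 0.
    """
    if directed:
        nbrs = (set(graph.predecessors(node)) | set(graph.successors(node))) - {node}
    else:
        nbrs = set(graph.neighbors(node)) - {node}
    k = len(nbrs)
    if k < 2:
        return 0.0
    if directed:
        e_n = sum(1 for u in nbrs for v in nbrs if u != v and graph.has_edge(u, v))
        return e_n / (k * (k - 1))
    e_n = sum(1 for u in nbrs for v in nbrs if u < v and graph.has_edge(u, v))
    return 2.0 * e_n / (k * (k - 1))


def betweenness(graph: nx.DiGraph) -> dict:
    """Normalized betweenness: sum over ordered pairs s!=t!=n of
    sigma_st(n)/sigma_st, divided by (|V|-1)(|V|-2)."""
    n = graph.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def closeness(graph: nx.DiGraph) -> dict:
    """Closeness over reachable nodes: R / sum of distances to them.

    R counts the other nodes reachable from n along directed paths; nodes
    reaching nothing score 0.
    """
    out = {}
    for node in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, node)
        dists.pop(node, None)
        total = sum(dists.values())
        out[node] = len(dists) / total if total > 0 else 0.0
    return out


def path_metrics(graph: nx.DiGraph) -> tuple[float, float]:
    """(diameter, average path length) over reachable ordered pairs.

    Both are 0 when no pair is connected.
    """
    lengths = [
        d
        for node, dists in nx.all_pairs_shortest_path_length(graph)
        for other, d in dists.items()
        if other != node
    ]
    if not lengths:
        return 0.0, 0.0
    return float(max(lengths)), float(np.mean(lengths))


def centralization(graph: nx.DiGraph) -> float:
    """Freeman degree centralization.

    sum_n (k_max - k(n)) / ((|V|-1)(|V|-2)) with degrees taken on the
    undirected collapse (each connected pair counted once), which keeps the
    statistic in [0, 1]: 1 for a star, 0 for any degree-regular graph and
    for |V| < 3.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return 0.0
    und = graph.to_undirected() if graph.is_directed() else graph
    deg = np.array([d for _, d in und.degree()], dtype=float)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


@dataclass
class TopologyReport:
    per_node: pd.DataFrame
    network: dict[str, float]


def summarize(graph: nx.DiGraph) -> TopologyReport:
    """Per-node metrics plus their network-level means and size counts."""
    nodes = list(graph.nodes)
    per_node = degrees(graph)
    per_node["clustering"] = [clustering_coefficient(graph, v) for v in nodes]
    bc = betweenness(graph)
    cc = closeness(graph)
    per_node["betweenness"] = [bc[v] for v in nodes]
    per_node["closeness"] = [cc[v] for v in nodes]
    roles = nx.get_node_attributes(graph, "role")
    per_node["role"] = [roles.get(v, "") for v in nodes]

    diameter, apl = path_metrics(graph)
    n = graph.number_of_nodes()
    network = {
        "n_nodes": float(n),
        "n_edges": float(graph.number_of_edges()),
        "n_tfs": float(sum(1 for v in nodes if roles.get(v) == TF)),
        "n_tgs": float(sum(1 for v in nodes if roles.get(v, "") not in ("", TF))),
        "average_degree": 2.0 * graph.number_of_edges() / n if n else 0.0,
        "clustering_coefficient": float(per_node["clustering"].mean()) if n else 0.0,
        "diameter": diameter,
        "average_path_length": apl,
        "betweenness": float(per_node["betweenness"].mean()) if n else 0.0,
        "closeness": float(per_node["closeness"].mean()) if n else 0.0,
        "centralization": centralization(graph),
    }
    return TopologyReport(per_node=per_node, network=network)


@dataclass
class EnsembleStats:
    mean: dict[str, float]
    sd: dict[str, float]
    n_reps: int


def random_subnetwork_ensemble(
    static: RegulatoryNetwork,
    n_tfs: int,
    n_tgs: int,
    n_reps: int = 100,
    seed: int = 0,
) -> EnsembleStats:
    """Null distribution of metrics for size-matched random sub-networks.

    Each replicate samples n_tfs TFs and n_tgs TGs uniformly without
    replacement from the static network (role-stratified, matching the
    observed sub-network's composition), takes the induced subgraph and
    summarizes it; returns the per-metric mean and SD (ddof=1).
    """
    tfs, tgs = static.tfs, static.tgs
    if n_tfs > len(tfs) or n_tgs > len(tgs):
        raise ValueError("requested more TFs/TGs than the static network has")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        pick_tfs = rng.choice(len(tfs), size=n_tfs, replace=False)
        pick_tgs = rng.choice(len(tgs), size=n_tgs, replace=False)
        nodes = [tfs[i] for i in pick_tfs] + [tgs[i] for i in pick_tgs]
        sub = static.graph.subgraph(nodes)
        rows.append(summarize(sub).network)
    frame = pd.DataFrame(rows)
    sd = frame.std(ddof=1) if n_reps > 1 else frame.iloc[0] * 0.0
    return EnsembleStats(
        mean=frame.mean().to_dict(), sd=sd.to_dict(), n_reps=n_reps
    )
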