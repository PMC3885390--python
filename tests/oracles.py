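"""Independent brute-force oracles used to validate graph computations.

Everything here is deliberately naive: hand-rolled BFS over adjacency
dicts and closed-form shortest-path counting, with no reliance on the
library routines the implementation uses.
"""

from collections import deque
from itertools import combinations

import numpy as np


def adjacency(graph) -> dict:
    return {n: sorted(graph.successors(n)) for n in graph.nodes}


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_counts(adj: dict, source) -> tuple[dict, dict]:
    """(distance, number of shortest paths) from source to every node."""
    dist = bfs_distances(adj, source)
    order = sorted(dist, key=dist.get)
    sigma = {v: 0 for v in dist}
    sigma[source] = 1
    for u in order:
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(graph) -> dict:
    """sigma_st(n)/sigma_st summed over ordered pairs, normalized."""
    adj = adjacency(graph)
    nodes = list(graph.nodes)
    n = len(nodes)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = shortest_path_counts(adj, s)
    out = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                if (
                    v in dist[s]
                    and t in dist[v]
                    and dist[s][v] + dist[v][t] == dist[s][t]
                ):
                    out[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    if n > 2:
        for v in out:
            out[v] /= (n - 1) * (n - 2)
    return out


def brute_closeness(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        dist.pop(v)
        out[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def brute_path_metrics(graph) -> tuple[float, float]:
    adj = adjacency(graph)
    lengths = []
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        dist.pop(v)
        lengths.extend(dist.values())
    if not lengths:
        return 0.0, 0.0
    return float(max(lengths)), float(np.mean(lengths))


def brute_motif_counts(graph, k: int, labeler) -> dict:
    """Census over all C(n, k) subsets; connectivity checked by hand BFS."""
    und = {n: set() for n in graph.nodes}
    for u, v in graph.edges:
        if u != v:
            und[u].add(v)
            und[v].add(u)
    counts: dict = {}
    for subset in combinations(sorted(graph.nodes), k):
        chosen = set(subset)
        seen = {subset[0]}
        queue = deque([subset[0]])
        while queue:
            u = queue.popleft()
            for w in und[u] & chosen:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        if len(seen) < k:
            continue
        nodes = sorted(subset)
        adj = np.array(
            [[1 if graph.has_edge(a, b) else 0 for b in nodes] for a in nodes]
        )
        label = labeler(adj)
        counts[label] = counts.get(label, 0) + 1
    return counts
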