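"""Directed network-motif census and enrichment.

Counts weakly-connected induced k-node subgraphs (k = 3, 4, 5) by
isomorphism class with an ESU-style enumeration (each node subset visited
exactly once), builds a degree-preserving null by repeated directed
double-edge swaps, and scores each class with
Z = (count_original - mean_random) / sd_random and an add-one empirical
p-value.  The familiar transcriptional motifs appear as classes here:
feed-forward loops, bi-fans, single- and multiple-input motifs, TF cliques.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np

_PERMS = {k: list(permutations(range(k))) for k in (3, 4, 5)}

#: canonical labels of well-known 3-node motifs, for readable reports
FFL_LABEL = None  # filled in below


def canonical_form(adjacency: np.ndarray) -> str:
    """Lexicographically minimal row-major bit-string over node relabelings.

    The label is identical for isomorphic k-node digraphs (k <= 5, no
    self-loops) and differs otherwise.
    """
    adj = np.asarray(adjacency)
    k = adj.shape[0]
    if adj.shape != (k, k):
        raise ValueError("adjacency must be square")
    if k > 5:
        raise ValueError("subgraphs larger than 5 nodes are not supported")
    if np.any(np.diag(adj)):
        raise ValueError("self-loops are not supported")
    best = None
    for perm in _PERMS.get(k, [tuple(range(k))]):
        bits = tuple(int(adj[perm[i], perm[j]]) for i in range(k) for j in range(k))
        if best is None or bits < best:
            best = bits
    return "".join(map(str, best))


FFL_LABEL = canonical_form(np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]]))
BIFAN_LABEL = canonical_form(
    np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0]])
)


def _esu_subsets(neighbors: list[set[int]], k: int):
    """Yield every weakly-connected k-node subset exactly once (ESU)."""
    n = len(neighbors)
    for v in range(n):
        ext = {u for u in neighbors[v] if u > v}
        stack = [([v], ext, set(neighbors[v]))]
        while stack:
            sub, extension, nbhd = stack.pop()
            if len(sub) == k - 1:
                for w in extension:
                    yield sub + [w]
                continue
            extension = set(extension)
            while extension:
                w = extension.pop()
                new_ext = extension | {
                    u for u in neighbors[w] if u > v and u not in nbhd and u not in sub
                }
                stack.append((sub + [w], new_ext, nbhd | neighbors[w]))


def enumerate_subgraphs(graph: nx.DiGraph, k: int) -> dict[str, int]:
    """Exact census of induced connected k-subgraphs by isomorphism class.

    Each weakly-connected k-node subset contributes once to the class of
    its induced directed subgraph; the counts therefore sum to the number
    of connected k-subsets.
    """
    if k not in (3, 4, 5):
        raise ValueError("k must be 3, 4 or 5")
    nodes = list(graph.nodes)
    if len(nodes) < k:
        return {}
    index = {v: i for i, v in enumerate(nodes)}
    neighbors = [set() for _ in nodes]
    edge_bits: dict[tuple[int, int], bool] = {}
    for u, v in graph.edges:
        iu, iv = index[u], index[v]
        if iu == iv:
            continue  # self-loops are outside the census
        neighbors[iu].add(iv)
        neighbors[iv].add(iu)
        edge_bits[(iu, iv)] = True

    counts: dict[str, int] = {}
    label_cache: dict[tuple[int, ...], str] = {}
    for subset in _esu_subsets(neighbors, k):
        subset.sort()
        raw = tuple(
            1 if (subset[i], subset[j]) in edge_bits else 0
            for i in range(k)
            for j in range(k)
        )
        label = label_cache.get(raw)
        if label is None:
            label = canonical_form(np.array(raw).reshape(k, k))
            label_cache[raw] = label
        counts[label] = counts.get(label, 0) + 1
    return counts


def switch_randomize(
    graph: nx.DiGraph, switches_per_edge: int = 3, seed: int = 0
) -> nx.DiGraph:
    """Degree-preserving randomization by directed double-edge swaps.

    Attempts switches_per_edge * |E| swaps (a->b, c->d) => (a->d, c->b),
    rejecting any that would create a self-loop or duplicate an edge.
    Every node's in- and out-degree is exactly preserved, which also keeps
    regulation sources as sources (TFs) and pure targets as targets.
    """
    edges = list(graph.edges)
    m = len(edges)
    out = graph.__class__()
    out.add_nodes_from(graph.nodes(data=True))
    if m < 2 or switches_per_edge == 0:
        out.add_edges_from(graph.edges(data=True))
        return out
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_attempts = switches_per_edge * m
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    for i, j in pairs:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    roles = nx.get_node_attributes(graph, "role")
    for u, v in edges:
        kind = "interacts" if roles.get(v) == "TF" else "regulates"
        out.add_edge(u, v, kind=kind) if roles else out.add_edge(u, v)
    return out


@dataclass
class MotifResult:
    canonical_label: str
    k: int
    count_original: int
    mean_random: float
    sd_random: float
    z_score: float  # nan when sd_random == 0
    p_empirical: float
    n_random: int
    significant: bool

    @property
    def adjacency(self) -> np.ndarray:
        bits = np.array([int(b) for b in self.canonical_label])
        return bits.reshape(self.k, self.k)


def motif_significance(
    graph: nx.DiGraph,
    k: int = 3,
    n_random: int = 100,
    switches_per_edge: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[MotifResult]:
    """Z-scores and empirical p-values against the edge-switch null.

    For every class seen in the original network or any random replicate:
    Z = (count_original - mean_random) / sd_random (sample SD; nan when the
    null is degenerate) and p = (#{random >= original} + 1)/(n_random + 1).
    Degree preservation is asserted on every replicate.
    """
    if n_random < 2:
        raise ValueError("need at least 2 random replicates")
    original = enumerate_subgraphs(graph, k)
    in_deg = dict(graph.in_degree())
    out_deg = dict(graph.out_degree())
    rng = np.random.default_rng(seed)
    replicate_counts: list[dict[str, int]] = []
    for s in rng.integers(0, 2**31 - 1, size=n_random):
        rand = switch_randomize(graph, switches_per_edge, seed=int(s))
        if dict(rand.in_degree()) != in_deg or dict(rand.out_degree()) != out_deg:
            raise AssertionError("randomization altered a degree sequence")
        replicate_counts.append(enumerate_subgraphs(rand, k))

    classes = set(original)
    for counts in replicate_counts:
        classes.update(counts)
    results = []
    for label in sorted(classes):
        orig = original.get(label, 0)
        rand_counts = np.array([c.get(label, 0) for c in replicate_counts], float)
        mean, sd = float(rand_counts.mean()), float(rand_counts.std(ddof=1))
        z = (orig - mean) / sd if sd > 0 else float("nan")
        p = (int(np.sum(rand_counts >= orig)) + 1) / (n_random + 1)
        results.append(
            MotifResult(
                canonical_label=label,
                k=k,
                count_original=orig,
                mean_random=mean,
                sd_random=sd,
                z_score=z,
                p_empirical=p,
                n_random=n_random,
                significant=p < alpha,
            )
        )
    return results
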