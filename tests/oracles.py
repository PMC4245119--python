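"""Brute-force oracles, independent of the library's algorithms.

Centralities are recomputed by exhaustive enumeration of all simple paths;
clique percolation by enumerating every k-subset of nodes.  Only usable on
tiny graphs, which is the point.
"""
import itertools

import networkx as nx
import numpy as np

TIE_RTOL = 1e-9


def _close(a, b):
    return abs(a - b) <= TIE_RTOL * max(1.0, abs(a), abs(b))


def _all_shortest_paths(graph, source, target, weight="w"):
    """(min length, list of node tuples) over all simple paths."""
    best, paths = None, []
    for nodes in nx.all_simple_paths(graph, source, target):
        length = sum(graph[u][v].get(weight, 1.0)
                     for u, v in zip(nodes, nodes[1:]))
        if best is None:
            best, paths = length, [tuple(nodes)]
        elif _close(length, best):
            paths.append(tuple(nodes))
        elif length < best:
            best, paths = length, [tuple(nodes)]
    if best is None:
        return np.inf, []
    return best, paths


def brute_closeness(graph, nodes, weight="w"):
    """Per-component normalized closeness by exhaustive enumeration."""
    out = np.zeros(len(nodes))
    for comp in nx.connected_components(graph):
        comp = sorted(comp, key=nodes.index)
        if len(comp) == 1:
            continue
        for i in comp:
            total = 0.0
            for j in comp:
                if i == j:
                    continue
                best, _ = _all_shortest_paths(graph, i, j, weight)
                total += best
            out[nodes.index(i)] = (len(comp) - 1) / total
    return out


def brute_betweenness(graph, nodes, weight="w"):
    """Normalized betweenness from explicit path enumeration."""
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        _, paths = _all_shortest_paths(graph, s, t, weight)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return np.array([bc[v] / norm for v in nodes])


def brute_cpm(graph, k):
    """Clique percolation from every k-subset of nodes."""
    k_cliques = [frozenset(c) for c in
                 itertools.combinations(graph.nodes, k)
                 if all(graph.has_edge(u, v)
                        for u, v in itertools.combinations(c, 2))]
    adj = nx.Graph()
    adj.add_nodes_from(range(len(k_cliques)))
    for i, j in itertools.combinations(range(len(k_cliques)), 2):
        if len(k_cliques[i] & k_cliques[j]) == k - 1:
            adj.add_edge(i, j)
    communities = set()
    for comp in nx.connected_components(adj):
        members = frozenset().union(*(k_cliques[i] for i in comp))
        communities.add(members)
    return communities


def brute_suboptimal(graph, source, target, tolerance, weight="w"):
    """All simple paths within tolerance of the optimum, sorted."""
    entries = []
    for nodes in nx.all_simple_paths(graph, source, target):
        length = sum(graph[u][v].get(weight, 1.0)
                     for u, v in zip(nodes, nodes[1:]))
        entries.append((length, tuple(nodes)))
    if not entries:
        return []
    best = min(e[0] for e in entries)
    keep = [e for e in entries if e[0] <= best + tolerance + 1e-12]
    return sorted(keep)


def random_weighted_graph(rng, n, p=0.4, w_low=0.1, w_high=2.0):
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            graph.add_edge(i, j, w=float(rng.uniform(w_low, w_high)))
    return graph
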