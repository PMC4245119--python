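"""Weighted protein structure networks and their analysis.

Residue nodes are connected when their percentage interaction strength

    I_ij = 100 * n_ij / sqrt(N_i * N_j)

exceeds the cutoff I_min (default 3.0 %), where n_ij counts in-scope
heavy-atom pairs within the contact cutoff and N_i is a per-residue-type
normalization constant.  Edge weights w_ij = -log|C_ij| are derived from
the residue cross-correlation matrix, so strongly correlated contacts are
"short" and carry communication flow.  Centralities follow the weighted
shortest-path definitions: closeness C(i) = (N-1)/sum_j d(i,j) and
betweenness as the pair-normalized fraction of shortest paths through a
node, computed from Floyd-Warshall all-pairs distances with explicit
shortest-path counting.  Communities are k-clique percolation clusters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .stability import _load_table
from .structure import Ensemble, StructureModel

DEFAULT_I_MIN = 3.0            # %
DEFAULT_HUB_MIN_DEGREE = 4
DEFAULT_K_CLIQUE = 3
DEFAULT_PERSISTENCE_MIN = 0.75
DEFAULT_MATCH_JACCARD = 0.75
DEFAULT_CORR_BOUNDS = (0.5, 1.0)
CORR_FLOOR = 1e-6              # |C| floor before -log
_TIE_RTOL = 1e-9               # shortest-path tie recognition
_W_FLOOR = 1e-12               # keeps path counting well defined at w = 0
_LIGAND_DEFAULT_ABS_CORR = 0.5


class NetworkError(ValueError):
    pass


# ----------------------------------------------------------------------
# Interaction strength
# ----------------------------------------------------------------------

def _scope_atoms(model: StructureModel, atom_scope: str,
                 include_ligands: bool):
    """(atom indices, node id per atom, node group ids) for the scope."""
    if atom_scope not in ("sidechain_heavy", "heavy"):
        raise NetworkError(f"unknown atom scope {atom_scope!r}")
    groups = list(model.residue_groups)
    if include_ligands:
        groups += list(model.ligand_groups)
    atom_idx, node_of_atom = [], []
    for node, g in enumerate(groups):
        atoms = model.atoms_of_group(g)
        names = model.atom_name[atoms]
        res_name = model.groups[g]["res_name"]
        if (model.groups[g]["is_ligand"] or atom_scope == "heavy"
                or res_name in ("GLY", "ALA")):
            chosen = atoms          # backbone fallback / full heavy scope
        else:
            chosen = atoms[~np.isin(names, ("N", "CA", "C", "O"))]
            if len(chosen) == 0:
                chosen = atoms
        atom_idx.extend(chosen)
        node_of_atom.extend([node] * len(chosen))
    return (np.array(atom_idx, dtype=int),
            np.array(node_of_atom, dtype=int), groups)


def _normalization_constants(model: StructureModel, groups,
                             normalization: dict | None,
                             strict: bool = False) -> np.ndarray:
    table = dict(_load_table("psn_normalization.json"))
    if normalization:
        table.update(normalization)
    out = np.empty(len(groups))
    for node, g in enumerate(groups):
        res_name = model.groups[g]["res_name"]
        if model.groups[g]["is_ligand"] or res_name not in table:
            if strict and not model.groups[g]["is_ligand"]:
                raise NetworkError(
                    f"no normalization constant for residue type {res_name!r}")
            out[node] = len(model.atoms_of_group(g))   # heavy-atom fallback
        else:
            out[node] = table[res_name]
    return out


def _eligible_pairs(model: StructureModel, groups) -> np.ndarray:
    """Boolean matrix of node pairs allowed to form edges
    (|i-j| >= 2 within a chain; ligand pairs always allowed)."""
    n = len(groups)
    ok = np.ones((n, n), dtype=bool)
    np.fill_diagonal(ok, False)
    chain_pos = {}
    counters: dict[str, int] = {}
    for node, g in enumerate(groups):
        if model.groups[g]["is_ligand"]:
            continue
        chain = model.groups[g]["chain_id"]
        pos = counters.get(chain, 0)
        counters[chain] = pos + 1
        chain_pos[node] = (chain, pos)
    for i, (ci, pi) in chain_pos.items():
        for j, (cj, pj) in chain_pos.items():
            if i < j and ci == cj and abs(pi - pj) < 2:
                ok[i, j] = ok[j, i] = False
    return ok


def interaction_strength_matrix(model: StructureModel,
                                ensemble: Ensemble | None = None,
                                contact_cutoff: float = 4.5,
                                atom_scope: str = "sidechain_heavy",
                                include_ligands: bool = True,
                                normalization: dict | None = None,
                                strict_normalization: bool = False,
                                frame_indices=None):
    """Percentage interaction-strength matrix, ensemble-averaged if an
    ensemble is given.  Returns (I, node_keys)."""
    if model.n_groups < 2:
        raise NetworkError("need at least 2 residues/groups")
    atom_idx, node_of_atom, groups = _scope_atoms(
        model, atom_scope, include_ligands)
    n_nodes = len(groups)
    norm = _normalization_constants(model, groups, normalization,
                                    strict_normalization)
    eligible = _eligible_pairs(model, groups)
    onehot = np.zeros((len(atom_idx), n_nodes), dtype=np.float32)
    onehot[np.arange(len(atom_idx)), node_of_atom] = 1.0

    if ensemble is None:
        coord_iter = model.coords[atom_idx][None]
    elif frame_indices is not None:
        coord_iter = ensemble.frames[frame_indices][:, atom_idx, :]
    else:
        coord_iter = ensemble.frames[:, atom_idx, :]

    cutoff2 = contact_cutoff ** 2
    counts_sum = np.zeros((n_nodes, n_nodes), dtype=np.float64)
    n_frames = coord_iter.shape[0]
    chunk = max(1, int(2e7 // (len(atom_idx) ** 2 + 1)))
    for start in range(0, n_frames, chunk):
        block = np.asarray(coord_iter[start:start + chunk], dtype=np.float32)
        for frame in block:
            d2 = ((frame[:, None, :] - frame[None, :, :]) ** 2).sum(axis=2)
            contact = (d2 <= cutoff2).astype(np.float32)
            counts_sum += onehot.T @ contact @ onehot
    counts = counts_sum / n_frames
    i_mat = 100.0 * counts / np.sqrt(np.outer(norm, norm))
    i_mat[~eligible] = 0.0
    i_mat = (i_mat + i_mat.T) / 2.0
    np.fill_diagonal(i_mat, 0.0)
    keys = [model.group_key(g) for g in groups]
    return i_mat, keys


# ----------------------------------------------------------------------
# Graph construction
# ----------------------------------------------------------------------

@dataclass
class PSNGraph:
    graph: nx.Graph
    keys: list
    i_min: float
    I: np.ndarray | None = None
    C: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.keys)

    @classmethod
    def from_networkx(cls, graph: nx.Graph, i_min: float = DEFAULT_I_MIN):
        """Wrap a plain graph; missing 'w' edge attributes default to 1."""
        g = graph.copy()
        for _, _, data in g.edges(data=True):
            data.setdefault("w", 1.0)
            data.setdefault("C", float(np.exp(-data["w"])))
        return cls(graph=g, keys=list(g.nodes), i_min=i_min)


def build_psn(i_matrix: np.ndarray, correlation, keys: list,
              i_min: float = DEFAULT_I_MIN,
              corr_floor: float = CORR_FLOOR) -> PSNGraph:
    """Build the weighted PSN from interaction strengths and correlations.

    An edge exists iff I_ij > i_min; its weight is w = -log(max(|C|, floor))
    with |C| clamped to 1.  When ligand nodes extend beyond the correlation
    matrix, their edges use a neutral |C| = 0.5.
    """
    i_matrix = np.asarray(i_matrix, dtype=float)
    n = len(keys)
    if i_matrix.shape != (n, n):
        raise NetworkError("interaction matrix does not match node keys")
    c = correlation.C if hasattr(correlation, "C") else np.asarray(correlation)
    nc = c.shape[0]
    if nc > n or c.shape != (nc, nc):
        raise NetworkError("correlation matrix does not match node keys")
    c_full = np.full((n, n), _LIGAND_DEFAULT_ABS_CORR)
    c_full[:nc, :nc] = c
    np.fill_diagonal(c_full, 1.0)

    graph = nx.Graph()
    graph.add_nodes_from(keys)
    rows, cols = np.nonzero(np.triu(i_matrix > i_min, k=1))
    for i, j in zip(rows, cols):
        abs_c = min(abs(float(c_full[i, j])), 1.0)
        w = -np.log(max(abs_c, corr_floor))
        graph.add_edge(keys[i], keys[j], I=float(i_matrix[i, j]),
                       C=float(c_full[i, j]), w=float(w))
    return PSNGraph(graph=graph, keys=list(keys), i_min=i_min,
                    I=i_matrix, C=c_full)


def _as_psn(graph_like) -> PSNGraph:
    if isinstance(graph_like, PSNGraph):
        return graph_like
    if isinstance(graph_like, nx.Graph):
        return PSNGraph.from_networkx(graph_like)
    raise NetworkError("expected a PSNGraph or networkx Graph")


# ----------------------------------------------------------------------
# Centrality
# ----------------------------------------------------------------------

@dataclass
class CentralityProfile:
    keys: list
    degree: np.ndarray
    hub: np.ndarray
    closeness: np.ndarray | None = None
    betweenness: np.ndarray | None = None
    isolated: np.ndarray | None = None
    hub_min_degree: int = DEFAULT_HUB_MIN_DEGREE


def degree_and_hubs(graph_like,
                    hub_min_degree: int = DEFAULT_HUB_MIN_DEGREE
                    ) -> CentralityProfile:
    """Node degrees and local-hub flags (degree >= hub_min_degree)."""
    psn = _as_psn(graph_like)
    if psn.n == 0:
        raise NetworkError("empty graph")
    degree = np.array([psn.graph.degree(k) for k in psn.keys], dtype=int)
    return CentralityProfile(keys=psn.keys, degree=degree,
                             hub=degree >= hub_min_degree,
                             hub_min_degree=hub_min_degree)


def _weight_matrix(psn: PSNGraph) -> np.ndarray:
    n = psn.n
    idx = {k: i for i, k in enumerate(psn.keys)}
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for u, v, data in psn.graph.edges(data=True):
        wt = float(data.get("w", 1.0))
        if wt < 0:
            raise NetworkError(f"negative edge weight on ({u}, {v})")
        wt = max(wt, _W_FLOOR)
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = wt
    return w


def _floyd_warshall(w: np.ndarray) -> np.ndarray:
    d = w.copy()
    for k in range(len(d)):
        np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :], out=d)
    return d


def _close(a, b):
    return np.abs(a - b) <= _TIE_RTOL * np.maximum(
        1.0, np.maximum(np.abs(a), np.abs(b)))


def _shortest_path_counts(w: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths (ties at 1e-9 rel tol)."""
    n = len(w)
    finite_edges = [np.flatnonzero(np.isfinite(w[v]) & (np.arange(n) != v))
                    for v in range(n)]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s], kind="stable")
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            preds = finite_edges[v]
            ok = _close(d[s, preds] + w[v, preds], d[s, v]) \
                & (d[s, preds] < d[s, v])
            sigma[s, v] = sigma[s, preds[ok]].sum()
    return sigma


def _components(d: np.ndarray):
    n = len(d)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if not seen[i]:
            members = np.flatnonzero(np.isfinite(d[i]))
            seen[members] = True
            comps.append(members)
    return comps


def closeness_profile(graph_like):
    """Normalized closeness C(i) = (N-1) / sum_j d(i, j) over weighted
    shortest paths; computed per connected component with that component's
    size.  Isolated nodes get closeness 0 and a flag.
    Returns (closeness, isolated_flags) aligned with the node keys."""
    psn = _as_psn(graph_like)
    if psn.n == 0:
        raise NetworkError("empty graph")
    d = _floyd_warshall(_weight_matrix(psn))
    closeness = np.zeros(psn.n)
    isolated = np.zeros(psn.n, dtype=bool)
    for comp in _components(d):
        if len(comp) == 1:
            isolated[comp[0]] = True
            continue
        sub = d[np.ix_(comp, comp)]
        closeness[comp] = (len(comp) - 1) / sub.sum(axis=1)
    return closeness, isolated


def betweenness_profile(graph_like):
    """Normalized betweenness from Floyd-Warshall distances with explicit
    shortest-path counting; normalization (N-1)(N-2)/2 for undirected
    graphs.  Returns an array aligned with the node keys."""
    psn = _as_psn(graph_like)
    n = psn.n
    if n == 0:
        raise NetworkError("empty graph")
    if n < 3:
        return np.zeros(n)
    w = _weight_matrix(psn)
    d = _floyd_warshall(w)
    sigma = _shortest_path_counts(w, d)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            on_path = _close(d[s] + d[:, t], d[s, t]) \
                & np.isfinite(d[s]) & np.isfinite(d[:, t])
            on_path[s] = on_path[t] = False
            if np.any(on_path):
                bc[on_path] += (sigma[s, on_path] * sigma[on_path, t]
                                / sigma[s, t])
    return bc / ((n - 1) * (n - 2) / 2.0)


# ----------------------------------------------------------------------
# Communities
# ----------------------------------------------------------------------

@dataclass
class Community:
    members: frozenset
    k: int
    persistence: float | None = None
    stable: bool | None = None

    def __post_init__(self):
        if len(self.members) < self.k:
            raise NetworkError("community smaller than clique size k")


def cpm_communities(graph_like, k: int = DEFAULT_K_CLIQUE):
    """k-clique percolation communities of the unweighted edge set.

    Two k-cliques are adjacent when they share k-1 nodes; a community is
    the node union of a connected set of k-cliques.  k larger than the
    largest clique yields an empty list.
    """
    if k < 3:
        raise NetworkError("clique percolation needs k >= 3")
    psn = _as_psn(graph_like)
    comms = nx.algorithms.community.k_clique_communities(psn.graph, k)
    out = [Community(members=frozenset(c), k=k) for c in comms]
    return sorted(out, key=lambda c: (-len(c.members), sorted(map(str, c.members))))


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def community_persistence(sample_graphs, k: int = DEFAULT_K_CLIQUE,
                          persistence_min: float = DEFAULT_PERSISTENCE_MIN,
                          match_jaccard: float = DEFAULT_MATCH_JACCARD):
    """Match communities across ensemble samples and score persistence.

    Communities from each sample graph are clustered by Jaccard overlap
    >= ``match_jaccard``; a cluster's persistence is the fraction of
    samples contributing a matching community, and it is stable when
    persistence exceeds ``persistence_min`` (strict, per the
    more-than-75 % convention).
    """
    psns = [_as_psn(g) for g in sample_graphs]
    if len(psns) < 2:
        raise NetworkError("need at least 2 sample graphs")
    node_set = set(psns[0].keys)
    for p in psns[1:]:
        if set(p.keys) != node_set:
            raise NetworkError("sample graphs have mismatching node sets")
    n_samples = len(psns)
    clusters: list[dict] = []
    for si, psn in enumerate(psns):
        for comm in cpm_communities(psn, k=k):
            best, best_j = None, 0.0
            for cl in clusters:
                j = _jaccard(cl["rep"], comm.members)
                if j >= match_jaccard and j > best_j:
                    best, best_j = cl, j
            if best is None:
                clusters.append({"rep": comm.members, "hits": {si}})
            else:
                best["hits"].add(si)
    out = []
    for cl in clusters:
        persistence = len(cl["hits"]) / n_samples
        out.append(Community(members=cl["rep"], k=k,
                             persistence=persistence,
                             stable=persistence > persistence_min))
    return sorted(out, key=lambda c: (-(c.persistence or 0.0),
                                      -len(c.members),
                                      sorted(map(str, c.members))))


def edge_persistence(sample_graphs, persistence_min: float =
                     DEFAULT_PERSISTENCE_MIN) -> dict:
    """Fraction of samples in which each edge is present (the edge-level
    reading of the persistence rule); reported alongside the
    community-level default."""
    psns = [_as_psn(g) for g in sample_graphs]
    counts: dict[tuple, int] = {}
    for psn in psns:
        for u, v in psn.graph.edges:
            key = tuple(sorted((str(u), str(v))))
            counts[key] = counts.get(key, 0) + 1
    n = len(psns)
    return {edge: {"persistence": c / n, "stable": c / n > persistence_min}
            for edge, c in sorted(counts.items())}


# ----------------------------------------------------------------------
# Allosteric paths
# ----------------------------------------------------------------------

@dataclass
class Path:
    nodes: tuple
    length: float
    connected: bool = True
    reason: str = ""


def _corr_filtered(psn: PSNGraph, corr_min: float, corr_max: float):
    g = nx.Graph()
    g.add_nodes_from(psn.graph.nodes)
    for u, v, data in psn.graph.edges(data=True):
        if corr_min <= abs(data.get("C", 1.0)) <= corr_max:
            g.add_edge(u, v, **data)
    return g


def shortest_allosteric_path(graph_like, source, target,
                             corr_min: float = DEFAULT_CORR_BOUNDS[0],
                             corr_max: float = DEFAULT_CORR_BOUNDS[1]) -> Path:
    """Minimum total-weight path restricted to sufficiently correlated
    edges (|C| within [corr_min, corr_max])."""
    psn = _as_psn(graph_like)
    if source == target:
        raise NetworkError("source and target must differ")
    for node in (source, target):
        if node not in psn.graph:
            raise NetworkError(f"node {node!r} not in graph")
    g = _corr_filtered(psn, corr_min, corr_max)
    try:
        nodes = nx.dijkstra_path(g, source, target, weight="w")
    except nx.NetworkXNoPath:
        return Path(nodes=(), length=np.inf, connected=False,
                    reason="disconnected under correlation filter")
    length = nx.path_weight(g, nodes, weight="w")
    return Path(nodes=tuple(nodes), length=float(length))


def suboptimal_paths(graph_like, source, target, tolerance: float,
                     corr_min: float = DEFAULT_CORR_BOUNDS[0],
                     corr_max: float = DEFAULT_CORR_BOUNDS[1],
                     max_paths: int = 10000):
    """All simple paths with length <= L_opt + tolerance, ascending.

    Enumerated with a bounded k-shortest-paths search on the
    correlation-filtered graph.
    """
    if tolerance < 0:
        raise NetworkError("tolerance must be >= 0")
    psn = _as_psn(graph_like)
    best = shortest_allosteric_path(psn, source, target, corr_min, corr_max)
    if not best.connected:
        return [best]
    g = _corr_filtered(psn, corr_min, corr_max)
    bound = best.length + tolerance + 1e-12
    out = []
    for nodes in nx.shortest_simple_paths(g, source, target, weight="w"):
        length = nx.path_weight(g, nodes, weight="w")
        if length > bound:
            break
        out.append(Path(nodes=tuple(nodes), length=float(length)))
        if len(out) >= max_paths:
            break
    return out


# ----------------------------------------------------------------------
# Ensemble block graphs and I/O
# ----------------------------------------------------------------------

def ensemble_block_graphs(model: StructureModel, ensemble: Ensemble,
                          correlation, n_blocks: int = 10,
                          i_min: float = DEFAULT_I_MIN,
                          contact_cutoff: float = 4.5,
                          atom_scope: str = "sidechain_heavy",
                          include_ligands: bool = True,
                          normalization: dict | None = None):
    """One PSN per equal frame block, built from block-averaged contacts."""
    if n_blocks < 2:
        raise NetworkError("need at least 2 blocks")
    bounds = np.linspace(0, ensemble.n_frames, n_blocks + 1).astype(int)
    graphs = []
    for b in range(n_blocks):
        idx = np.arange(bounds[b], bounds[b + 1])
        i_mat, keys = interaction_strength_matrix(
            model, ensemble, contact_cutoff=contact_cutoff,
            atom_scope=atom_scope, include_ligands=include_ligands,
            normalization=normalization, frame_indices=idx)
        graphs.append(build_psn(i_mat, correlation, keys, i_min=i_min))
    return graphs


def write_edge_tsv(psn: PSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tI\tC\tw\n")
        for u, v, data in sorted(psn.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['I']:.6f}\t{data['C']:.6f}"
                     f"\t{data['w']:.6f}\n")


def write_graphml(psn: PSNGraph, path) -> None:
    nx.write_graphml(psn.graph, path)


def communities_to_json(communities) -> list:
    return [{"members": sorted(map(str, c.members)), "k": c.k,
             "persistence": c.persistence, "stable": c.stable}
            for c in communities]


def paths_to_json(paths) -> list:
    items = paths if isinstance(paths, (list, tuple)) else [paths]
    return [{"nodes": list(p.nodes),
             "length": None if np.isinf(p.length) else p.length,
             "connected": p.connected, "reason": p.reason}
            for p in items]
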