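"""Skeleton graphs and sub-cellular morphometry.

A skeleton mesh (spheres + links) becomes a weighted undirected graph: one
node per skeleton point carrying position and radius, one edge per link with
weight equal to the Euclidean distance between the two centers. Neuron length
is the weight of the longest simple path in that graph (cycles are allowed in
skeleton meshes, so this is found by exhaustive backtracking, which marks a
node on entry and unmarks it on backtrack); branches are the longest simple
paths hanging off the main path at its branching nodes.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathResult",
    "build_graph",
    "build_graph_from_arrays",
    "longest_simple_path_from",
    "neuron_length",
    "find_branches",
    "read_swc",
    "write_swc",
    "write_edge_list",
    "read_edge_list",
]

#: above this node count the exact exponential search is refused and a
#: documented heuristic (best of a few high-eccentricity seeds) is used
EXACT_SEARCH_GUARD = 2000


@dataclass
class PathResult:
    """A simple path (no repeated nodes) and its total edge weight."""

    nodes: List[int]
    length: float


def build_graph_from_arrays(positions: np.ndarray, radii: np.ndarray,
                            edges: Sequence[Tuple[int, int]]) -> nx.Graph:
    """Weighted skeleton graph from node arrays and an edge index list.

    Zero-weight edges (coincident centers) are contracted; if the graph is
    disconnected only the largest connected component is kept.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    radii = np.atleast_1d(np.asarray(radii, float))
    g = nx.Graph()
    for i, (p, r) in enumerate(zip(positions, radii)):
        g.add_node(i, position=np.asarray(p, float), radius=float(r))
    for i, j in edges:
        if i == j:
            continue
        w = float(np.linalg.norm(positions[i] - positions[j]))
        g.add_edge(int(i), int(j), weight=w)
    # contract coincident centers so the path search never loops on 0-edges
    zero = [(i, j) for i, j, w in g.edges(data="weight") if w < 1e-12]
    while zero:
        i, j = zero[0]
        g = nx.contracted_nodes(g, i, j, self_loops=False)
        zero = [(a, b) for a, b, w in g.edges(data="weight") if w < 1e-12]
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        logger.warning("skeleton graph has %d components; keeping largest "
                       "(%d of %d nodes)", len(comps), len(comps[0]),
                       g.number_of_nodes())
        g = g.subgraph(comps[0]).copy()
    return g


def build_graph(mesh) -> nx.Graph:
    """Build the skeleton graph of a skeleton mesh (spheres + adjacency)."""
    adj = np.asarray(mesh.adjacency)
    if adj.sum() == 0:
        raise ValueError("mesh has no edges")
    ii, jj = np.nonzero(np.triu(adj, k=1))
    return build_graph_from_arrays(mesh.spheres.centers, mesh.spheres.radii,
                                   list(zip(ii.tolist(), jj.tolist())))


def longest_simple_path_from(g: nx.Graph, start,
                             forbidden: Optional[set] = None) -> PathResult:
    """Exact longest simple path starting at ``start``.

    Depth-first backtracking: a node is marked when entered and unmarked when
    the search backtracks past it, so cycles are never traversed but every
    simple path from ``start`` is explored. Ties in length are broken by the
    lexicographically smallest node sequence.
    """
    if start not in g:
        raise KeyError(f"unknown node id {start!r}")
    forbidden = forbidden or set()
    if g.number_of_nodes() > EXACT_SEARCH_GUARD:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes; exact longest-path "
            f"search refused above {EXACT_SEARCH_GUARD} (use neuron_length, "
            "which falls back to a heuristic)")
    best_len = -1.0
    best_path: List = []
    visited = {start} | set(forbidden)
    path = [start]
    sys.setrecursionlimit(max(sys.getrecursionlimit(),
                              10 * g.number_of_nodes() + 1000))

    def dfs(u, length):
        nonlocal best_len, best_path
        if length > best_len or (length == best_len and path < best_path):
            best_len = length
            best_path = list(path)
        for v in sorted(g.neighbors(u)):
            if v in visited:
                continue
            visited.add(v)
            path.append(v)
            dfs(v, length + g[u][v]["weight"])
            path.pop()
            visited.remove(v)

    dfs(start, 0.0)
    return PathResult(best_path, best_len)


def neuron_length(g: nx.Graph) -> Tuple[float, PathResult]:
    """Neuron length: the longest simple path over all start nodes.

    On graphs beyond the exact-search guard a heuristic is used: exact search
    restricted to the 32 most eccentric seed nodes of a BFS approximation.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    if g.number_of_nodes() > EXACT_SEARCH_GUARD:
        logger.warning("graph too large for exact search; using "
                       "high-eccentricity heuristic")
        ecc = nx.eccentricity(g)
        nodes = sorted(ecc, key=lambda n: -ecc[n])[:32]
    best = PathResult([nodes[0]], 0.0)
    for n in nodes:
        res = longest_simple_path_from(g, n)
        if res.length > best.length or (
                res.length == best.length and res.nodes < best.nodes):
            best = res
    return best.length, best


def find_branches(g: nx.Graph,
                  main_path: Optional[PathResult] = None,
                  ) -> Tuple[List[PathResult], int]:
    """Identify branches off the longest simple path.

    Branching-node set ``B``: nodes of the main path with at least one
    neighbor off the path. The branch at ``b`` is the longest simple path
    starting at ``b`` that avoids every other node of ``B`` and every non-b
    node of the main path. Zero-length branches are discarded.
    """
    if main_path is None:
        _, main_path = neuron_length(g)
    on_path = set(main_path.nodes)
    B = [b for b in main_path.nodes
         if any(v not in on_path for v in g.neighbors(b))]
    branches = []
    for b in B:
        forbidden = (on_path | set(B)) - {b}
        res = longest_simple_path_from(g, b, forbidden=forbidden)
        if res.length > 0:
            branches.append(res)
    return branches, len(branches)


# ---------------------------------------------------------------------------
# SWC and edge-list I/O
# ---------------------------------------------------------------------------


def read_swc(path: str) -> nx.Graph:
    """Read an SWC skeleton (``id type x y z r parent`` rows) as a graph."""
    g = nx.Graph()
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 7:
                raise ValueError(f"{path}:{lineno}: malformed SWC row {line!r}")
            rows.append((lineno, int(tok[0]), float(tok[2]), float(tok[3]),
                         float(tok[4]), float(tok[5]), int(tok[6])))
    for _, nid, x, y, z, r, _ in rows:
        g.add_node(nid, position=np.array([x, y, z]), radius=r)
    for lineno, nid, *_, parent in rows:
        if parent == -1:
            continue
        if parent not in g:
            raise ValueError(
                f"{path}:{lineno}: node {nid} references missing parent {parent}")
        w = float(np.linalg.norm(g.nodes[nid]["position"]
                                 - g.nodes[parent]["position"]))
        g.add_edge(nid, parent, weight=w)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty SWC file")
    return g


def write_swc(g: nx.Graph, path: str) -> None:
    """Write a cycle-free skeleton graph as SWC (1-based ids).

    Parents are assigned by breadth-first traversal rooted at the node with
    the largest radius. Cyclic graphs cannot be encoded in SWC and raise.
    """
    if g.number_of_edges() >= g.number_of_nodes() or not nx.is_forest(g):
        raise ValueError("graph contains cycles; SWC encodes trees only "
                         "(write_edge_list handles cyclic skeletons)")
    root = max(g.nodes, key=lambda n: g.nodes[n].get("radius", 0.0))
    order = {}
    parent_of = {root: -1}
    for u, v in nx.bfs_edges(g, root):
        parent_of[v] = u
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for new_id, n in enumerate(nx.bfs_tree(g, root).nodes, start=1):
            order[n] = new_id
            p = g.nodes[n]["position"]
            r = g.nodes[n].get("radius", 0.0)
            par = parent_of[n]
            par_id = -1 if par == -1 else order[par]
            fh.write(f"{new_id} 0 {p[0]:.8g} {p[1]:.8g} {p[2]:.8g} "
                     f"{r:.8g} {par_id}\n")


def write_edge_list(g: nx.Graph, path: str) -> None:
    """Node table (``id x y z r``) followed by ``i j`` edge pairs."""
    with open(path, "w") as fh:
        fh.write(f"nodes {g.number_of_nodes()}\n")
        index = {}
        for k, n in enumerate(sorted(g.nodes)):
            index[n] = k
            p = g.nodes[n]["position"]
            r = g.nodes[n].get("radius", 0.0)
            fh.write(f"{k} {p[0]:.8g} {p[1]:.8g} {p[2]:.8g} {r:.8g}\n")
        fh.write(f"edges {g.number_of_edges()}\n")
        for u, v in sorted((min(index[u], index[v]), max(index[u], index[v]))
                           for u, v in g.edges):
            fh.write(f"{u} {v}\n")


def read_edge_list(path: str) -> nx.Graph:
    with open(path) as fh:
        header = fh.readline().split()
        n_nodes = int(header[1])
        positions, radii = [], []
        for _ in range(n_nodes):
            tok = fh.readline().split()
            positions.append([float(t) for t in tok[1:4]])
            radii.append(float(tok[4]))
        n_edges = int(fh.readline().split()[1])
        edges = [tuple(int(t) for t in fh.readline().split())
                 for _ in range(n_edges)]
    return build_graph_from_arrays(np.array(positions), np.array(radii), edges)
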