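"""Score-filtered interaction graphs and MCODE dense-module detection.

Protein-protein association networks (STRING-style) attach a combined
confidence score in [0, 1] to each edge.  After thresholding the edges, the
MCODE algorithm finds densely connected modules in three steps: (1) weight
every vertex by the core number of the highest k-core of its closed
neighborhood times that core's density; (2) grow a module greedily from the
highest-weighted unvisited seed, admitting neighbors whose weight is within
``vwp`` (vertex weight percentage) of the seed's; (3) post-process with an
optional haircut (drop singly-connected members) and fluff pass.  Module
score is density times size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class NetworkModule:
    """A dense module: member vertices, its seed, score and density."""

    members: set[str]
    seed_vertex: str
    score: float
    density: float


def _density(g: nx.Graph) -> float:
    """Loopless density 2|E| / (|V| (|V|-1)); 0 for fewer than 2 vertices."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def edge_filter(edges: pd.DataFrame, min_score: float = 0.15) -> nx.Graph:
    """Build an undirected graph keeping edges with score >= min_score.

    The threshold is inclusive.  All vertices appearing in the input edge
    list are retained even if every incident edge is dropped (they become
    isolated).  Multi-edges collapse to the maximum score; self-loops are
    discarded.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    g = nx.Graph()
    for a, b, s in edges[["node1", "node2", "combined_score"]].itertuples(index=False):
        a, b = str(a), str(b)
        g.add_node(a)
        g.add_node(b)
        if a == b:
            continue
        s = float(s)
        if s < min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], s)
        else:
            g.add_edge(a, b, combined_score=s)
    return g


def vertex_weight(graph: nx.Graph, v: str) -> float:
    """MCODE vertex weight: k * density of the highest k-core of N[v].

    N[v] is the subgraph induced by v's closed neighborhood.  Isolated
    vertices weigh 0.
    """
    if v not in graph:
        raise KeyError(v)
    nbhd = set(graph.neighbors(v)) | {v}
    h = graph.subgraph(nbhd)
    if h.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(h)
    k = max(core.values())
    core_nodes = [u for u, c in core.items() if c >= k]
    return k * _density(h.subgraph(core_nodes))


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with fewer than 2 within-module neighbors."""
    members = set(members)
    changed = True
    while changed and len(members) > 2:
        changed = False
        sub = graph.subgraph(members)
        weak = [u for u in members if sub.degree(u) < 2]
        if weak:
            members -= set(weak)
            changed = True
    return members


def mcode_complexes(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.5,
    max_depth: int = 100,
    min_size: int = 3,
) -> list[NetworkModule]:
    """Seeded greedy MCODE module detection.

    Seeds are unvisited vertices in decreasing weight order (ties broken by
    lexicographic id).  From a seed, neighbors with weight >= (1 - vwp) *
    seed weight are added breadth-first up to ``max_depth``; each vertex
    joins at most one module core, so module cores are disjoint.  The
    optional haircut removes singly-connected members; the optional fluff
    pass adds unvisited neighbors whose closed-neighborhood density exceeds
    ``fluff_density`` (fluff vertices may be shared between modules).
    Modules smaller than ``min_size`` are discarded.  Results are sorted by
    decreasing score, then size, then smallest member id.
    """
    if not 0.0 <= vwp <= 1.0:
        raise ValueError("vwp must lie in [0, 1]")
    weights = {v: vertex_weight(graph, v) for v in graph.nodes}
    order = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[NetworkModule] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [(seed, 0)]
        while frontier:
            u, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for nb in sorted(graph.neighbors(u)):
                if nb in visited or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    visited.add(nb)
                    frontier.append((nb, depth + 1))
        if haircut:
            members = _haircut(graph, members)
        if fluff:
            extra = set()
            for u in list(members):
                for nb in graph.neighbors(u):
                    if nb in members or nb in extra:
                        continue
                    if _density(graph.subgraph(set(graph.neighbors(nb)) | {nb})) > fluff_density:
                        extra.add(nb)
            members |= extra
        if len(members) < min_size:
            continue
        sub = graph.subgraph(members)
        if not nx.is_connected(sub):
            # keep the seed's component (haircut/fluff can disconnect)
            if seed in sub:
                comp = nx.node_connected_component(sub, seed)
            else:
                comp = max(nx.connected_components(sub), key=lambda c: (len(c), min(c)))
            members = set(comp)
            if len(members) < min_size:
                continue
            sub = graph.subgraph(members)
        dens = _density(sub)
        modules.append(
            NetworkModule(
                members=set(members),
                seed_vertex=seed,
                score=dens * len(members),
                density=dens,
            )
        )
    modules.sort(key=lambda m: (-m.score, -len(m.members), min(m.members)))
    return modules


def modules_to_frame(modules: list[NetworkModule]) -> pd.DataFrame:
    """Tabular view: module id, seed, score, size, density, members."""
    rows = [
        {
            "MODULE": f"M{i+1}",
            "SEED": m.seed_vertex,
            "SCORE": m.score,
            "SIZE": len(m.members),
            "DENSITY": m.density,
            "MEMBERS": ",".join(sorted(m.members)),
        }
        for i, m in enumerate(modules)
    ]
    return pd.DataFrame(rows, columns=["MODULE", "SEED", "SCORE", "SIZE", "DENSITY", "MEMBERS"])


def modules_to_catalog(modules: list[NetworkModule]) -> dict[str, tuple[str, list[str]]]:
    """GMT-style mapping of module memberships for downstream ORA."""
    return {
        f"M{i+1}": (f"MCODE module {i+1} (seed {m.seed_vertex})", sorted(m.members))
        for i, m in enumerate(modules)
    }
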