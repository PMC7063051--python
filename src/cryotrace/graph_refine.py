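"""Trace-graph construction and the four refinement passes.

Traces become an undirected graph whose nodes carry Calpha coordinates and
SSE labels. Refinement runs four passes, each to a fixpoint, in the order:
path combination (merge trace endpoints onto nearby nodes), side-chain
removal (at junctions, drop the unique shortest branch of depth <= 3 when all
other branches are strictly deeper), loop removal (of two branch paths
joining the same pair of junctions, drop the one with lower mean density in a
1 A cylinder), and dead-end removal (branches of depth <= 2 ending in a
degree-1 node). "Depth" counts nodes traversed beyond the junction; the
junction itself is depth 0.

Passes only merge or delete: node count never grows and edges only shrink
(path combination can rewire but not add parallel structure), and every pass
is idempotent.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np

from .mapsim import DensityMap
from .structure import CaTrace, SSE_LOOP

#: maximum physically plausible Calpha-Calpha connection (A)
MAX_EDGE_LENGTH = 4.5

TraceGraph = nx.Graph


def traces_to_graph(traces: list[CaTrace]) -> TraceGraph:
    """Each trace becomes a simple path; no cross-trace edges are added."""
    g = nx.Graph()
    nid = 0
    for t_idx, trace in enumerate(traces):
        prev = None
        for i, p in enumerate(trace.points):
            sse = trace.sse[i] if trace.sse is not None else SSE_LOOP
            g.add_node(nid, coord=np.asarray(p, dtype=float), sse=sse, trace=t_idx)
            if prev is not None:
                g.add_edge(prev, nid)
            prev = nid
            nid += 1
    return g


def node_coords(g: TraceGraph) -> dict[int, np.ndarray]:
    return {n: g.nodes[n]["coord"] for n in g.nodes}


def combine_paths(g: TraceGraph, merge_radius: float = 3.0) -> TraceGraph:
    """Merge path endpoints onto any other node within ``merge_radius``.

    The endpoint's location is reassigned to (i.e. it is absorbed by) the
    nearby node and its edges are rewired there; repeated to a fixpoint.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        endpoints = sorted(n for n in g.nodes if g.degree[n] <= 1)
        for e in endpoints:
            if e not in g:
                continue
            ce = g.nodes[e]["coord"]
            banned = {e} | set(g.neighbors(e))
            best: Optional[tuple[float, int]] = None
            for n in g.nodes:
                if n in banned:
                    continue
                d = float(np.linalg.norm(g.nodes[n]["coord"] - ce))
                if d <= merge_radius and (best is None or (d, n) < best):
                    best = (d, n)
            if best is None:
                continue
            target = best[1]
            for nb in list(g.neighbors(e)):
                if nb != target:
                    g.add_edge(nb, target)
            g.remove_node(e)
            changed = True
    return g


def _branch(g: TraceGraph, junction: int, first: int) -> tuple[list[int], int]:
    """Follow a branch from ``junction`` through ``first`` until an end node
    (degree 1) or another junction (degree >= 3).

    Returns (interior nodes incl. the terminal, terminal node). Depth is
    ``len(nodes)``.
    """
    nodes = [first]
    prev, cur = junction, first
    while g.degree[cur] == 2:
        nxt = next(n for n in g.neighbors(cur) if n != prev)
        nodes.append(nxt)
        prev, cur = cur, nxt
        if cur == junction:  # cycle back to the start
            break
    return nodes, nodes[-1]


def remove_side_chains(g: TraceGraph) -> TraceGraph:
    """Drop short spur branches at junctions.

    At every node of degree >= 3: walk each incident branch to its end or the
    next junction; if the unique shortest branch has depth <= 3 and every
    other branch is strictly deeper, that branch is a side-chain connection
    and is removed. Runs to a fixpoint.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for j in sorted(g.nodes):
            if j not in g or g.degree[j] < 3:
                continue
            branches = [_branch(g, j, nb) for nb in sorted(g.neighbors(j))]
            depths = [len(b[0]) for b in branches]
            shortest = min(depths)
            if shortest > 3:
                continue
            idx = [i for i, d in enumerate(depths) if d == shortest]
            if len(idx) != 1:
                continue
            others = [d for i, d in enumerate(depths) if i != idx[0]]
            if not all(d > shortest for d in others):
                continue
            _delete_branch(g, j, branches[idx[0]])
            changed = True
    return g


def _delete_branch(g: TraceGraph, junction: int, branch: tuple[list[int], int]) -> None:
    nodes, terminal = branch
    if terminal != junction and g.degree[terminal] >= 3:
        interior = nodes[:-1]
        if not interior:  # direct junction-junction shortcut edge
            if g.has_edge(junction, terminal):
                g.remove_edge(junction, terminal)
            return
        g.remove_nodes_from(interior)
    else:
        g.remove_nodes_from([n for n in nodes if n != junction])


def _cylinder_mean_density(density: DensityMap, polyline: np.ndarray,
                           radius: float = 1.0) -> float:
    """Mean density of voxel centers within ``radius`` of the polyline.

    An empty sample set scores -inf so that such a path always loses.
    """
    lo_w = polyline.min(axis=0) - radius - density.voxel_size
    hi_w = polyline.max(axis=0) + radius + density.voxel_size
    lo = np.clip(np.floor(density.world_to_voxel(lo_w)).astype(int), 0,
                 np.array(density.shape) - 1)
    hi = np.clip(np.ceil(density.world_to_voxel(hi_w)).astype(int), 0,
                 np.array(density.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                             indexing="ij")
    centers = density.voxel_to_world(np.stack([ii, jj, kk], axis=-1)).reshape(-1, 3)
    d = _dist_to_polyline(centers, polyline)
    sel = d <= radius
    if not np.any(sel):
        return -np.inf
    vals = density.grid[ii.reshape(-1)[sel], jj.reshape(-1)[sel], kk.reshape(-1)[sel]]
    return float(vals.mean())


def _dist_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment of the polyline."""
    if len(polyline) == 1:
        return np.linalg.norm(points - polyline[0], axis=1)
    best = np.full(len(points), np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, points.shape)
        best = np.minimum(best, np.linalg.norm(points - proj, axis=1))
    return best


def remove_loops(g: TraceGraph, density: DensityMap) -> TraceGraph:
    """Resolve false-positive shortcut loops between the same two junctions.

    When two branch paths join the same pair of degree->=3 nodes, the one with
    the lower mean density inside a 1 A-radius cylinder around its polyline is
    removed (its interior nodes deleted). Exactly equal densities remove the
    longer path. Runs to a fixpoint.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for j in sorted(g.nodes):
            if j not in g or g.degree[j] < 3:
                continue
            branches = [_branch(g, j, nb) for nb in sorted(g.neighbors(j))]
            by_terminal: dict[int, list] = {}
            for br in branches:
                terminal = br[1]
                if terminal != j and terminal in g and g.degree[terminal] >= 3:
                    by_terminal.setdefault(terminal, []).append(br)
            pair = None
            for terminal in sorted(by_terminal):
                brs = by_terminal[terminal]
                if len(brs) >= 2:
                    pair = (terminal, brs[0], brs[1])
                    break
            if pair is None:
                continue
            terminal, br_a, br_b = pair
            poly = lambda br: np.stack(
                [g.nodes[j]["coord"]] + [g.nodes[n]["coord"] for n in br[0]])
            dens_a = _cylinder_mean_density(density, poly(br_a))
            dens_b = _cylinder_mean_density(density, poly(br_b))
            if dens_a == dens_b:
                loser = br_a if len(br_a[0]) >= len(br_b[0]) else br_b
            else:
                loser = br_a if dens_a < dens_b else br_b
            _delete_branch_interior(g, j, terminal, loser)
            changed = True
    return g


def _delete_branch_interior(g: TraceGraph, junction: int, terminal: int, branch) -> None:
    interior = [n for n in branch[0] if n not in (junction, terminal)]
    if interior:
        g.remove_nodes_from(interior)
    elif g.has_edge(junction, terminal):
        g.remove_edge(junction, terminal)


def remove_dead_ends(g: TraceGraph) -> TraceGraph:
    """Remove depth <= 2 branches from junctions that end in a degree-1 node."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for j in sorted(g.nodes):
            if j not in g or g.degree[j] < 3:
                continue
            for nb in sorted(g.neighbors(j)):
                branch = _branch(g, j, nb)
                nodes, terminal = branch
                if len(nodes) <= 2 and terminal != j and g.degree[terminal] == 1:
                    g.remove_nodes_from(nodes)
                    changed = True
                    break
    return g


def refine_graph(g: TraceGraph, density: DensityMap,
                 merge_radius: float = 3.0) -> TraceGraph:
    """All four passes in the standard order."""
    g = combine_paths(g, merge_radius)
    g = remove_side_chains(g)
    g = remove_loops(g, density)
    g = remove_dead_ends(g)
    return g


def graph_to_traces(g: TraceGraph) -> list[CaTrace]:
    """Decompose the graph into maximal simple paths (degree <= 2 chains).

    Components that still contain junctions are split at them; pure cycles
    are opened at their smallest node id.
    """
    traces: list[CaTrace] = []
    seen_edges: set[frozenset] = set()
    deg_special = [n for n in sorted(g.nodes) if g.degree[n] != 2]
    for start in deg_special:
        for nb in sorted(g.neighbors(start)):
            if frozenset((start, nb)) in seen_edges:
                continue
            chain = [start, nb]
            seen_edges.add(frozenset((start, nb)))
            prev, cur = start, nb
            while g.degree[cur] == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                seen_edges.add(frozenset((cur, nxt)))
                chain.append(nxt)
                prev, cur = cur, nxt
            traces.append(_chain_to_trace(g, chain))
    # isolated nodes and remaining pure cycles
    for comp in nx.connected_components(g):
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            n = comp_nodes[0]
            traces.append(_chain_to_trace(g, [n]))
            continue
        if all(g.degree[n] == 2 for n in comp_nodes):
            start = comp_nodes[0]
            chain = [start]
            prev, cur = None, start
            while True:
                nxts = [n for n in sorted(g.neighbors(cur)) if n != prev]
                nxt = nxts[0]
                if nxt == start:
                    break
                chain.append(nxt)
                prev, cur = cur, nxt
            traces.append(_chain_to_trace(g, chain))
    return traces


def _chain_to_trace(g: TraceGraph, chain: list[int]) -> CaTrace:
    pts = np.stack([g.nodes[n]["coord"] for n in chain])
    sse = [g.nodes[n].get("sse", SSE_LOOP) for n in chain]
    return CaTrace(points=pts, sse=sse)
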