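"""Feature graph construction and filament disambiguation.

Accepted line segments are fused into a *feature graph*: nodes are
subpixel points (filament endpoints, bends, branching points), edges are
maximal straight parts. Superposed and crossing filaments are then
disambiguated by decomposing the edge set into *edge trails* — walks
using each edge exactly once — under the single-filament model: a
filament has limited curvature, admitting **no bend enclosing less than
135 degrees**, and among all feasible decompositions one with minimal
in-trail curvature is chosen. Curvature of a trail is its total turning
sum(180 deg - enclosed angle) over interior nodes.

Because leaving every edge as its own trail always has zero turning, the
objective is lexicographic: first the fewest trails (a filament should
not be fragmented), then the least total turning, then the smallest
maximal single turn, then lexicographic edge order — making the result
deterministic. Per-node edge pairings are independent in both criteria,
so optimising each node locally is globally optimal whenever the induced
walks are open; components where the local optimum closes a cycle are
re-solved exactly by enumeration (small components) or the cycle is cut
at its sharpest bend (large ones).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .geometry import axial_angle_deg, enclosed_angle_deg
from .image import ParameterError
from .ridge import LineSegment

#: Minimal enclosed angle of a bend inside one filament, degrees.
MIN_ENCLOSED_DEG = 135.0

#: Perpendicular tolerance (px) when straightening chains of degree-2
#: nodes into maximal straight parts. One pixel: genuine bends deviate by
#: far more, detection jitter by less.
SIMPLIFY_TOL_PX = 1.5

#: Stub walks shorter than this (about the ridge's own width: ~2 x the
#: 2-sigma cross-section) are detection artifacts and are pruned.
SPUR_LEN_PX = 6.0

#: Chain tips of different components closer than this are joined: local
#: concavity dips (noise) break chains by a pixel or two, and a filament
#: should not fragment there.
LINK_RADIUS_PX = 3.0

#: Components with more edges fall back from exact enumeration to the
#: greedy cycle-cut repair when the local pairing closes a cycle.
_EXACT_EDGE_LIMIT = 24
_EXACT_COMBO_LIMIT = 200_000


@dataclass
class FilamentGraph:
    """Feature graph: subpixel nodes joined by straight parts.

    ``g`` is an undirected simple graph; node attribute ``pos`` holds the
    (row, col) coordinate, edge attributes ``length_px`` and
    ``angle_deg`` the Euclidean length and axial orientation.
    """

    g: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def pos(self, node) -> np.ndarray:
        return self.g.nodes[node]["pos"]

    def enclosed_at(self, a, v, b) -> float:
        return enclosed_angle_deg(self.pos(a), self.pos(v), self.pos(b))


@dataclass
class FilamentTrail:
    """One reconstructed filament: an ordered walk through the graph."""

    nodes: list
    length_px: float
    length_um: float
    bends_deg: list[float]  # enclosed angle at each interior node

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def total_turning_deg(self) -> float:
        return float(sum(180.0 - b for b in self.bends_deg))


@dataclass
class FilamentMetrics:
    """Per-image summary of the reconstructed filaments."""

    filament_number: int
    total_length_um: float
    average_length_um: float | None
    max_length_um: float | None

    def to_dict(self) -> dict:
        return {
            "filament_number": self.filament_number,
            "total_length_um": self.total_length_um,
            "average_length_um": self.average_length_um,
            "max_length_um": self.max_length_um,
        }


# ---------------------------------------------------------------------------
# graph construction

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_graph(segments: list[LineSegment], merge_tol_px: float = 0.75,
                simplify_tol_px: float = SIMPLIFY_TOL_PX,
                spur_len_px: float = SPUR_LEN_PX,
                link_radius_px: float = LINK_RADIUS_PX) -> FilamentGraph:
    """Fuse segment endpoints into nodes and straighten chains.

    Endpoints closer than ``merge_tol_px`` become one node (position =
    centroid of the fused endpoints). Chain tips of distinct components
    within ``link_radius_px`` are joined (healing 1-2 px breaks where
    noise locally weakened the ridge). Short spur edges hanging off
    branching points — side effects of the ridge's finite width — are
    pruned. Chains of degree-2 nodes are then straightened into maximal
    straight parts wherever they deviate from the chord by less than
    ``simplify_tol_px``; surviving degree-2 nodes are genuine bends and
    nodes of degree >= 3 are branching points.
    """
    g = nx.Graph()
    if not segments:
        return FilamentGraph(g)
    pts = np.array([c for s in segments for c in (s.p, s.q)])
    from scipy.spatial import cKDTree
    uf = _UnionFind(len(pts))
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(merge_tol_px):
        uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(len(pts))])
    node_of_root: dict[int, int] = {}
    positions: dict[int, np.ndarray] = {}
    for r in np.unique(roots):
        node = len(node_of_root)
        node_of_root[r] = node
        positions[node] = pts[roots == r].mean(axis=0)
    for node, pos in positions.items():
        g.add_node(node, pos=pos)
    for k in range(len(segments)):
        u = node_of_root[roots[2 * k]]
        v = node_of_root[roots[2 * k + 1]]
        if u != v:
            g.add_edge(u, v)
    _link_tips(g, link_radius_px)
    _prune_spurs(g, spur_len_px)
    _simplify_chains(g, simplify_tol_px)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    _set_edge_geometry(g)
    return FilamentGraph(g)


def _link_tips(g: nx.Graph, radius: float) -> None:
    """Join chain tips of different components that nearly touch.

    Pairs are taken nearest-first; each tip links at most once, and only
    across components (never closing a loop within one chain).
    """
    if radius <= 0 or g.number_of_nodes() == 0:
        return
    comp_of: dict = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = i
    tips = [n for n in g.nodes if g.degree(n) <= 1]
    if len(tips) < 2:
        return
    pos = np.array([g.nodes[n]["pos"] for n in tips])
    from scipy.spatial import cKDTree
    pairs = []
    for i, j in cKDTree(pos).query_pairs(radius):
        if comp_of[tips[i]] != comp_of[tips[j]]:
            d = float(np.hypot(*(pos[i] - pos[j])))
            pairs.append((d, tips[i], tips[j]))
    used: set = set()
    for d, u, v in sorted(pairs, key=lambda t: (t[0], t[1], t[2])):
        if u in used or v in used or comp_of[u] == comp_of[v]:
            continue
        if d <= 0.7 * radius:
            # overlapping tips: fuse into one node so the joint is a
            # plain continuation, not a sharp Z-shaped connector edge
            g.nodes[u]["pos"] = (g.nodes[u]["pos"] + g.nodes[v]["pos"]) / 2.0
            for w in list(g.neighbors(v)):
                if w != u:
                    g.add_edge(u, w)
            g.remove_node(v)
        else:
            g.add_edge(u, v)
        used.update((u, v))
        old, new = comp_of.pop(v), comp_of[u]
        for n, c in comp_of.items():
            if c == old:
                comp_of[n] = new


def _prune_spurs(g: nx.Graph, spur_len_px: float,
                 min_enclosed_deg: float = MIN_ENCLOSED_DEG) -> None:
    """Remove short stub walks hanging off the filament body.

    From every chain tip, walk inward while the chain continues smoothly
    (degree 2 and enclosed angle feasible under the bend bound). A walk
    that stops at a branching point or at a model-violating bend after
    less than ``spur_len_px`` is an artifact of the ridge's finite width
    or of end jitter — shorter than the ridge is wide — and is removed.
    Whole components are never removed: an isolated short chain may be a
    genuine short filament.
    """
    changed = True
    while changed:
        changed = False
        for tip in sorted(n for n in g.nodes if g.degree(n) == 1):
            if not g.has_node(tip) or g.degree(tip) != 1:
                continue
            walk = [tip]
            (cur,) = g.neighbors(tip)
            length = float(np.hypot(*(g.nodes[cur]["pos"] - g.nodes[tip]["pos"])))
            stopped_inside = False
            while length < spur_len_px:
                if g.degree(cur) >= 3:
                    stopped_inside = True
                    break
                if g.degree(cur) == 1:  # exhausted the whole component
                    break
                n1, n2 = g.neighbors(cur)
                nxt = n2 if n1 == walk[-1] else n1
                ang = enclosed_angle_deg(g.nodes[walk[-1]]["pos"],
                                         g.nodes[cur]["pos"],
                                         g.nodes[nxt]["pos"])
                if ang < min_enclosed_deg:
                    stopped_inside = True
                    break
                walk.append(cur)
                length += float(np.hypot(*(g.nodes[nxt]["pos"]
                                           - g.nodes[cur]["pos"])))
                cur = nxt
            if stopped_inside and length >= 0:
                for n in walk:
                    g.remove_node(n)
                changed = True


def _dp_keep(points: np.ndarray, tol: float) -> list[int]:
    """Indices kept by Douglas-Peucker simplification of a point chain."""
    keep = {0, len(points) - 1}
    stack = [(0, len(points) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        chord = points[j] - points[i]
        norm = np.hypot(*chord)
        rel = points[i + 1:j] - points[i]
        if norm == 0:
            dev = np.hypot(rel[:, 0], rel[:, 1])
        else:
            dev = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
        k = int(np.argmax(dev))
        if dev[k] > tol:
            mid = i + 1 + k
            keep.add(mid)
            stack.append((i, mid))
            stack.append((mid, j))
    return sorted(keep)


def _simplify_chains(g: nx.Graph, tol: float) -> None:
    """Straighten maximal degree-2 chains into maximal straight parts."""
    anchors = [v for v in g.nodes if g.degree(v) != 2]
    visited: set[tuple] = set()
    chains: list[list] = []
    for a in anchors:
        for b in list(g.neighbors(a)):
            if _edge_key(a, b) in visited:
                continue
            chain = [a, b]
            visited.add(_edge_key(a, b))
            while g.degree(chain[-1]) == 2 and chain[-1] not in anchors:
                n1, n2 = g.neighbors(chain[-1])
                nxt = n2 if n1 == chain[-2] else n1
                visited.add(_edge_key(chain[-1], nxt))
                chain.append(nxt)
            chains.append(chain)
    # pure cycles of degree-2 nodes have no anchor; start anywhere
    for v in g.nodes:
        if g.degree(v) != 2:
            continue
        if any(_edge_key(v, w) not in visited for w in g.neighbors(v)):
            chain = [v]
            n1, _ = g.neighbors(v)
            nxt = n1
            while True:
                visited.add(_edge_key(chain[-1], nxt))
                chain.append(nxt)
                if nxt == v:
                    break
                n1, n2 = g.neighbors(nxt)
                nxt = n2 if _edge_key(nxt, n2) not in visited else (
                    n1 if _edge_key(nxt, n1) not in visited else chain[-2])
                if nxt == chain[-2]:  # dead end safeguard
                    break
            chains.append(chain)
    for chain in chains:
        if len(chain) < 3:
            continue
        pos = np.array([g.nodes[n]["pos"] for n in chain])
        keep = set(_dp_keep(pos, tol))
        if chain[0] == chain[-1]:  # closed cycle: keep >= 2 interior nodes
            interior = sorted(keep - {0, len(chain) - 1})
            while len(interior) < 2:
                candidates = [k for k in range(1, len(chain) - 1)
                              if k not in keep]
                if not candidates:
                    break
                keep.add(candidates[len(candidates) // 2])
                interior = sorted(keep - {0, len(chain) - 1})
        kept = [chain[k] for k in sorted(keep)]
        removed = [chain[k] for k in range(len(chain))
                   if k not in keep and chain[k] != chain[0]]
        for n in removed:
            if g.has_node(n):
                g.remove_node(n)
        for u, v in zip(kept[:-1], kept[1:]):
            if u != v:
                g.add_edge(u, v)


def _set_edge_geometry(g: nx.Graph) -> None:
    for u, v in g.edges:
        pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
        g.edges[u, v]["length_px"] = float(np.hypot(*(pv - pu)))
        g.edges[u, v]["angle_deg"] = axial_angle_deg(pu, pv)


# ---------------------------------------------------------------------------
# trail decomposition

def _edge_key(u, v) -> tuple:
    return (u, v) if u <= v else (v, u)


def _turning(graph: FilamentGraph, e1: tuple, v, e2: tuple) -> float:
    """Turning (180 - enclosed) when passing from e1 to e2 through v."""
    a = e1[0] if e1[1] == v else e1[1]
    b = e2[0] if e2[1] == v else e2[1]
    return 180.0 - graph.enclosed_at(a, v, b)


def _node_matchings(graph: FilamentGraph, v, min_enclosed: float
                    ) -> list[list[tuple[tuple, tuple, float]]]:
    """All feasible partial matchings of the edges incident to v.

    Each matching is a list of (edge1, edge2, turning) with
    edge1 < edge2; pairs whose enclosed angle is below the bend bound
    are infeasible and never appear.
    """
    edges = sorted(_edge_key(v, w) for w in graph.g.neighbors(v))
    feasible: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(edges)), 2):
        turn = _turning(graph, edges[i], v, edges[j])
        if 180.0 - turn >= min_enclosed:
            feasible[(i, j)] = turn
    out: list[list] = []

    def rec(remaining: list[int], acc: list) -> None:
        if not remaining:
            out.append(list(acc))
            return
        first, rest = remaining[0], remaining[1:]
        rec(rest, acc)  # leave `first` unmatched
        for k, other in enumerate(rest):
            key = (first, other)
            if key in feasible:
                acc.append((edges[first], edges[other], feasible[key]))
                rec(rest[:k] + rest[k + 1:], acc)
                acc.pop()

    rec(list(range(len(edges))), [])
    return out


def _matching_rank(m: list) -> tuple:
    """Sort key: most pairs, least turning, smallest max turn, lexicographic."""
    turns = [t for _, _, t in m]
    return (-len(m), sum(turns), max(turns, default=0.0),
            tuple(sorted((e1, e2) for e1, e2, _ in m)))


def _walks_from_pairing(edges: list[tuple], pairing: dict
                        ) -> tuple[list[list[tuple]], list[list[tuple]]]:
    """Assemble open walks and cycles from per-node edge pairings.

    ``pairing[(edge, node)]`` gives the edge paired with `edge` at
    `node` (absent = trail ends there). Returns (open_walks, cycles) as
    lists of edge sequences.
    """
    visited: set[tuple] = set()
    opens: list[list[tuple]] = []
    cycles: list[list[tuple]] = []
    # open walks start at an unpaired edge-end
    for e in edges:
        if e in visited:
            continue
        for start_node in e:
            if (e, start_node) not in pairing and e not in visited:
                walk = [e]
                visited.add(e)
                prev, cur = start_node, (e[0] if e[1] == start_node else e[1])
                cur_edge = e
                while (cur_edge, cur) in pairing:
                    nxt = pairing[(cur_edge, cur)]
                    walk.append(nxt)
                    visited.add(nxt)
                    cur = nxt[0] if nxt[1] == cur else nxt[1]
                    cur_edge = nxt
                opens.append(walk)
                break
    for e in edges:  # what remains are pure cycles
        if e in visited:
            continue
        walk = [e]
        visited.add(e)
        cur = e[1]
        cur_edge = e
        while True:
            nxt = pairing[(cur_edge, cur)]
            if nxt == e:  # closed back onto the start edge
                break
            walk.append(nxt)
            visited.add(nxt)
            cur = nxt[0] if nxt[1] == cur else nxt[1]
            cur_edge = nxt
        cycles.append(walk)
    return opens, cycles


def _pairing_from_choice(choice: dict) -> dict:
    pairing: dict = {}
    for v, matching in choice.items():
        for e1, e2, _ in matching:
            pairing[(e1, v)] = e2
            pairing[(e2, v)] = e1
    return pairing


def _interior_nodes(walk: list[tuple]) -> list:
    """Shared node between consecutive edges of a walk."""
    out = []
    for e1, e2 in zip(walk[:-1], walk[1:]):
        shared = set(e1) & set(e2)
        # straight chains may revisit; consecutive trail edges share 1 node
        out.append(next(iter(shared)) if len(shared) == 1 else e1[1])
    return out


def _cut_cycle(walk: list[tuple], graph: FilamentGraph) -> list[tuple]:
    """Open a cyclic walk at its sharpest interior bend (max turning)."""
    n = len(walk)
    if n == 1:  # cannot happen for simple graphs (would be a self-loop)
        return walk
    turns = []
    for i in range(n):
        e1 = walk[i]
        e2 = walk[(i + 1) % n]
        shared = set(e1) & set(e2)
        v = next(iter(shared)) if len(shared) == 1 else e1[1]
        turns.append((_turning(graph, e1, v, e2), i))
    _, cut = max(turns)
    return walk[cut + 1:] + walk[:cut + 1]


def _component_decompose(graph: FilamentGraph, comp_nodes: list,
                         min_enclosed: float) -> list[list[tuple]]:
    """Decompose one connected component into edge walks."""
    sub = graph.g.subgraph(comp_nodes)
    edges = sorted(_edge_key(u, v) for u, v in sub.edges)
    if len(edges) == 1:
        return [edges]
    per_node = {v: _node_matchings(graph, v, min_enclosed) for v in sorted(sub.nodes)}
    best_local = {v: min(ms, key=_matching_rank) for v, ms in per_node.items()}
    pairing = _pairing_from_choice(best_local)
    opens, cycles = _walks_from_pairing(edges, pairing)
    if not cycles:
        return opens
    # The independent local optimum closed >= 1 cycle: re-solve exactly
    # when the component is small, otherwise cut each cycle greedily.
    n_combos = math.prod(len(ms) for ms in per_node.values())
    if len(edges) <= _EXACT_EDGE_LIMIT and n_combos <= _EXACT_COMBO_LIMIT:
        return _exact_component(graph, edges, per_node)
    return opens + [_cut_cycle(c, graph) for c in cycles]


def _exact_component(graph: FilamentGraph, edges: list[tuple],
                     per_node: dict) -> list[list[tuple]]:
    """Exhaustive search over per-node matching combinations.

    Every trail decomposition corresponds to a cycle-free combination,
    which is enumerated; combinations that close cycles are evaluated
    with their best cut, so the overall optimum is exact.
    """
    nodes = sorted(per_node)
    best = None
    best_walks = None
    for combo in itertools.product(*(sorted(per_node[v], key=_matching_rank)
                                     for v in nodes)):
        choice = dict(zip(nodes, combo))
        pairing = _pairing_from_choice(choice)
        opens, cycles = _walks_from_pairing(edges, pairing)
        walks = opens + [_cut_cycle(c, graph) for c in cycles]
        score = _score_walks(graph, walks)
        if best is None or score < best:
            best = score
            best_walks = walks
    return best_walks


def _score_walks(graph: FilamentGraph, walks: list[list[tuple]]) -> tuple:
    turns = []
    for w in walks:
        for e1, v, e2 in zip(w[:-1], _interior_nodes(w), w[1:]):
            turns.append(_turning(graph, e1, v, e2))
    return (len(walks), sum(turns), max(turns, default=0.0),
            tuple(sorted(tuple(w) for w in walks)))


def _walk_to_trail(graph: FilamentGraph, walk: list[tuple],
                   pixel_size_um: float) -> FilamentTrail:
    # reconstruct the node sequence of the walk
    if len(walk) == 1:
        nodes = list(walk[0])
    else:
        interior = _interior_nodes(walk)
        first = walk[0][0] if walk[0][1] == interior[0] else walk[0][1]
        nodes = [first]
        for e, v in zip(walk[:-1], interior):
            nodes.append(v)
        last_e = walk[-1]
        nodes.append(last_e[0] if last_e[1] == nodes[-1] else last_e[1])
    length_px = sum(graph.g.edges[e]["length_px"] for e in walk)
    bends = [graph.enclosed_at(a, v, b)
             for a, v, b in zip(nodes[:-2], nodes[1:-1], nodes[2:])]
    return FilamentTrail(nodes=nodes, length_px=float(length_px),
                         length_um=float(length_px) * pixel_size_um,
                         bends_deg=bends)


def decompose_trails(graph: FilamentGraph, min_enclosed_deg: float = MIN_ENCLOSED_DEG,
                     pixel_size_um: float = 1.0) -> list[FilamentTrail]:
    """Partition the graph's edges into filament trails.

    Each edge ends up in exactly one trail; no trail contains a bend
    enclosing less than ``min_enclosed_deg``; among feasible partitions
    the number of trails, then the total turning, is minimal.
    """
    trails: list[FilamentTrail] = []
    for comp in nx.connected_components(graph.g):
        for walk in _component_decompose(graph, list(comp), min_enclosed_deg):
            trail = _walk_to_trail(graph, walk, pixel_size_um)
            assert all(b >= min_enclosed_deg - 1e-9 for b in trail.bends_deg), \
                "infeasible bend in decomposed trail"
            trails.append(trail)
    trails.sort(key=lambda t: (-t.length_um, t.nodes))
    return trails


def measure(trails: list[FilamentTrail], pixel_size_um: float | None = None
            ) -> FilamentMetrics:
    """Filament count and total/average/maximum length in micrometres.

    Average and maximum are reported as missing (None) when no filament
    was found. If ``pixel_size_um`` is given, lengths are recomputed
    from the pixel lengths with that calibration.
    """
    if pixel_size_um is not None and pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be > 0")
    if pixel_size_um is None:
        lengths = [t.length_um for t in trails]
    else:
        lengths = [t.length_px * pixel_size_um for t in trails]
    n = len(lengths)
    total = float(sum(lengths))
    return FilamentMetrics(
        filament_number=n,
        total_length_um=total,
        average_length_um=total / n if n else None,
        max_length_um=max(lengths) if n else None,
    )


# ---------------------------------------------------------------------------
# decomposition cleanup: debris absorption and gap stitching

def _trail_polylines(graph: FilamentGraph, trails: list[FilamentTrail]
                     ) -> list[np.ndarray]:
    return [np.array([graph.pos(n) for n in t.nodes]) for t in trails]


def _dist_to_polyline(p: np.ndarray, poly: np.ndarray) -> float:
    from .geometry import point_segment_distance
    best = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        if np.allclose(a, b):
            continue
        best = min(best, float(point_segment_distance(p[None, :], a, b)[0]))
    return best


#: Trails shorter than this are below the detector's resolution (a pair
#: of subpixel points inside one ridge cross-section) and are dropped.
MIN_TRAIL_PX = 2.0


def _remove_debris(graph: FilamentGraph, trails: list[FilamentTrail],
                   debris_len_px: float, debris_dist_px: float,
                   min_trail_px: float = MIN_TRAIL_PX) -> bool:
    """Remove edges duplicating a longer trail's course, and micro-trails.

    The ridge's finite width occasionally produces a second, parallel
    trace of a stretch already represented by a longer trail: any edge of
    a shorter trail whose both endpoints lie within ``debris_dist_px`` of
    a strictly longer trail is removed. Trails shorter than
    ``min_trail_px`` (sub-resolution) are dropped outright; other
    isolated short trails are kept — they may be genuine short filaments.
    """
    order = sorted(range(len(trails)),
                   key=lambda i: (-trails[i].length_px, trails[i].nodes))
    polys = _trail_polylines(graph, trails)
    changed = False
    for rank, i in enumerate(order):
        t = trails[i]
        if t.length_px < min_trail_px:
            remove = list(zip(t.nodes[:-1], t.nodes[1:]))
        else:
            longer = [polys[j] for j in order[:rank]
                      if trails[j].length_px > t.length_px + 1e-9]
            if not longer:
                continue
            remove = []
            for u, v in zip(t.nodes[:-1], t.nodes[1:]):
                pu, pv = graph.pos(u), graph.pos(v)
                if (min(_dist_to_polyline(pu, lp) for lp in longer)
                        <= debris_dist_px
                        and min(_dist_to_polyline(pv, lp) for lp in longer)
                        <= debris_dist_px):
                    remove.append((u, v))
        for u, v in remove:
            if graph.g.has_edge(u, v):
                graph.g.remove_edge(u, v)
                changed = True
    if changed:
        graph.g.remove_nodes_from(
            [n for n in list(graph.g) if graph.g.degree(n) == 0])
    return changed


def _end_direction(graph: FilamentGraph, nodes: list,
                   lookback_px: float = 4.0) -> np.ndarray:
    """Outward direction at nodes[0], averaged over >= lookback_px of trail."""
    p_end = graph.pos(nodes[0])
    p_back = graph.pos(nodes[1])
    for n in nodes[2:]:
        if float(np.hypot(*(p_end - p_back))) >= lookback_px:
            break
        p_back = graph.pos(n)
    return p_end - p_back


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(float(np.dot(u, v)) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _stitch_ends(graph: FilamentGraph, trails: list[FilamentTrail],
                 stitch_radius_px: float, min_enclosed_deg: float) -> bool:
    """Bridge trail ends of different components that continue smoothly.

    A local concavity dip can break one filament into two trails a few
    pixels apart. Ends are joined when the bridge keeps every virtual
    bend feasible (>= the trail bend bound); nearest, straightest pairs
    are joined first, each end at most once.
    """
    max_turn = 180.0 - min_enclosed_deg
    comp_of: dict = {}
    for i, comp in enumerate(nx.connected_components(graph.g)):
        for n in comp:
            comp_of[n] = i
    ends = []  # (node, outward direction, trail idx)
    for ti, t in enumerate(trails):
        if len(t.nodes) < 2:
            continue
        if not all(graph.g.has_node(n) for n in t.nodes):
            continue  # trail was (partly) absorbed as debris in this pass
        # average the end direction over the last few pixels: the very
        # last edge may be short and angularly noisy
        ends.append((t.nodes[0], _end_direction(graph, t.nodes), ti))
        ends.append((t.nodes[-1], _end_direction(graph, t.nodes[::-1]), ti))
    candidates = []
    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            ni, di, ti = ends[i]
            nj, dj, tj = ends[j]
            if ti == tj or comp_of.get(ni) == comp_of.get(nj):
                continue
            if not (graph.g.has_node(ni) and graph.g.has_node(nj)):
                continue
            v = graph.pos(nj) - graph.pos(ni)
            dist = float(np.hypot(*v))
            if dist > stitch_radius_px:
                continue
            if dist > 0.5:
                turn = max(_angle_between(di, v), _angle_between(v, -dj))
            else:
                turn = _angle_between(di, -dj)
            if turn > max_turn:
                # passing tips: two traces of one filament may overlap by
                # a few pixels, putting the bridge vector backwards; join
                # anyway if the trails themselves continue collinearly
                collinear = _angle_between(di, -dj)
                if dist <= 0.75 * stitch_radius_px and collinear <= max_turn:
                    turn = collinear
                else:
                    continue
            candidates.append((turn, dist, ni, nj))
    used: set = set()
    changed = False
    for turn, dist, ni, nj in sorted(candidates):
        if ni in used or nj in used or comp_of[ni] == comp_of[nj]:
            continue
        graph.g.add_edge(ni, nj)
        used.update((ni, nj))
        old, new = comp_of[nj], comp_of[ni]
        for n, c in comp_of.items():
            if c == old:
                comp_of[n] = new
        changed = True
    return changed


def decompose_with_cleanup(graph: FilamentGraph,
                           min_enclosed_deg: float = MIN_ENCLOSED_DEG,
                           pixel_size_um: float = 1.0,
                           debris_len_px: float = 6.0,
                           debris_dist_px: float = 3.0,
                           stitch_radius_px: float = 8.0,
                           spur_len_px: float = SPUR_LEN_PX,
                           simplify_tol_px: float = SIMPLIFY_TOL_PX,
                           max_iter: int = 3) -> list[FilamentTrail]:
    """Trail decomposition with junction-debris removal and gap stitching.

    Alternates decomposition with two cleanup moves justified by the
    single-filament model: short trails duplicating a longer trail's
    course are absorbed, and trail ends whose continuation across a
    small gap stays within the bend bound are bridged. The graph is
    re-straightened and re-decomposed after each pass until stable.
    """
    trails = decompose_trails(graph, min_enclosed_deg, pixel_size_um)
    for _ in range(max_iter):
        changed = _remove_debris(graph, trails, debris_len_px, debris_dist_px)
        changed |= _stitch_ends(graph, trails, stitch_radius_px,
                                min_enclosed_deg)
        if not changed:
            break
        _prune_spurs(graph.g, spur_len_px, min_enclosed_deg)
        _simplify_chains(graph.g, simplify_tol_px)
        graph.g.remove_nodes_from(
            [n for n in list(graph.g) if graph.g.degree(n) == 0])
        _set_edge_geometry(graph.g)
        trails = decompose_trails(graph, min_enclosed_deg, pixel_size_um)
    return trails


# ---------------------------------------------------------------------------
# export

def graph_to_json(graph: FilamentGraph, path: str | Path) -> None:
    """Export nodes (coordinates) and edges (ids, lengths, angles)."""
    data = {
        "nodes": [{"id": int(n), "row": float(graph.pos(n)[0]),
                   "col": float(graph.pos(n)[1])} for n in graph.g.nodes],
        "edges": [{"u": int(u), "v": int(v),
                   "length_px": graph.g.edges[u, v]["length_px"],
                   "angle_deg": graph.g.edges[u, v]["angle_deg"]}
                  for u, v in graph.g.edges],
    }
    Path(path).write_text(json.dumps(data, indent=1))
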