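"""Feature graph: construction, trail decomposition, exhaustive oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from filatrace import LineSegment, build_graph, decompose_trails, measure
from filatrace.graph import FilamentGraph, _set_edge_geometry


def seg(p, q):
    return LineSegment(np.asarray(p, float), np.asarray(q, float), -1.0)


def make_graph(positions, edges) -> FilamentGraph:
    g = nx.Graph()
    for i, p in enumerate(positions):
        g.add_node(i, pos=np.asarray(p, dtype=float))
    g.add_edges_from(edges)
    _set_edge_geometry(g)
    return FilamentGraph(g)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of all trail partitions

def _enclosed(graph, a, v, b):
    return graph.enclosed_at(a, v, b)


def _all_feasible_trails(graph, unused, min_enclosed):
    """Every feasible walk (edge set -> minimal turning) in `unused`."""
    options = {}
    for e0 in unused:
        for start in (list(e0), list(e0)[::-1]):
            stack = [((e0,), tuple(start), 0.0)]
            while stack:
                edges_w, nodes_w, turn = stack.pop()
                key = frozenset(edges_w)
                if turn < options.get(key, np.inf):
                    options[key] = turn
                v = nodes_w[-1]
                for w in graph.g.neighbors(v):
                    e = (v, w) if v <= w else (w, v)
                    if e not in unused or e in edges_w:
                        continue
                    ang = _enclosed(graph, nodes_w[-2], v, w)
                    if ang < min_enclosed:
                        continue
                    stack.append((edges_w + (e,), nodes_w + (w,),
                                  turn + 180.0 - ang))
    return options


def brute_force_optimum(graph: FilamentGraph, min_enclosed=135.0):
    """Minimal (n_trails, total_turning) over ALL partitions of the edge
    set into feasible open trails, by exhaustive recursion."""
    all_edges = frozenset((u, v) if u <= v else (v, u) for u, v in graph.g.edges)
    cache = {}

    def rec(unused: frozenset):
        if not unused:
            return (0, 0.0)
        if unused in cache:
            return cache[unused]
        e0 = min(unused)
        options = _all_feasible_trails(graph, unused, min_enclosed)
        best = None
        for eset, turn in options.items():
            if e0 not in eset:
                continue
            n_sub, t_sub = rec(unused - eset)
            cand = (1 + n_sub, turn + t_sub)
            if best is None or cand < best:
                best = cand
        cache[unused] = best
        return best

    return rec(all_edges)


def random_geometric_graph(rng) -> FilamentGraph:
    """Random connected graph with <= 8 edges and random node positions."""
    n = int(rng.integers(3, 8))
    pos = rng.uniform(0, 30, size=(n, 2))
    edges = set()
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # random spanning tree
        edges.add((min(a, b), max(a, b)))
    extra = int(rng.integers(0, 3))
    candidates = [e for e in itertools.combinations(range(n), 2)
                  if e not in edges]
    rng.shuffle(candidates)
    for e in candidates[:extra]:
        if len(edges) < 8:
            edges.add(e)
    return make_graph(pos, [tuple(map(int, e)) for e in edges])


# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_empty_segment_list(self):
        g = build_graph([])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_collinear_segments_collapse_to_one_edge(self):
        g = build_graph([seg((0, 0), (0, 1)), seg((0, 1), (0, 2))])
        assert g.n_nodes == 2
        assert g.n_edges == 1
        (u, v) = next(iter(g.g.edges))
        assert g.g.edges[u, v]["length_px"] == pytest.approx(2.0)

    def test_l_shape_keeps_bend_node(self):
        g = build_graph([seg((0, 0), (0, 10)), seg((0, 10), (10, 10))])
        assert g.n_edges == 2
        degrees = sorted(d for _, d in g.g.degree)
        assert degrees == [1, 1, 2]

    def test_endpoints_fused_within_tolerance(self):
        g = build_graph([seg((0, 0), (0, 10)), seg((0, 10.5), (0, 20))],
                        merge_tol_px=0.75)
        assert g.n_edges == 1  # fused, then straight chain collapsed
        assert g.n_nodes == 2

    def test_edge_length_matches_node_distance(self):
        g = build_graph([seg((0, 0), (3, 4)), seg((3, 4), (10, 4))])
        for u, v in g.g.edges:
            d = float(np.hypot(*(g.pos(u) - g.pos(v))))
            assert g.g.edges[u, v]["length_px"] == pytest.approx(d)

    def test_no_self_loops_and_degrees_positive(self):
        rng = np.random.default_rng(0)
        segs = [seg(p, p + rng.uniform(1, 3, 2))
                for p in rng.uniform(0, 50, size=(30, 2))]
        g = build_graph(segs)
        assert not any(u == v for u, v in g.g.edges)
        assert all(d >= 1 for _, d in g.g.degree)


class TestDecompose:
    def test_straight_chain_single_trail(self):
        g = make_graph([(0, 0), (0, 10), (0, 20), (0, 30)],
                       [(0, 1), (1, 2), (2, 3)])
        trails = decompose_trails(g)
        assert len(trails) == 1
        assert trails[0].n_edges == 3
        assert trails[0].length_um == pytest.approx(30.0)
        assert trails[0].bends_deg == pytest.approx([180.0, 180.0])

    def test_l_graph_sharp_bend_splits(self):
        """A 90-degree bend encloses less than 135 deg and may not be
        traversed: the L decomposes into two single-edge trails."""
        g = make_graph([(0, 0), (0, 10), (10, 10)], [(0, 1), (1, 2)])
        trails = decompose_trails(g)
        assert len(trails) == 2
        assert all(t.n_edges == 1 for t in trails)

    def test_x_crossing_two_straight_trails(self):
        """Two straight lines crossing at a degree-4 node pass straight
        through: two trails with zero total turning (oracle-checked)."""
        g = make_graph([(0, 0), (10, 10), (20, 20), (20, 0), (0, 20)],
                       [(0, 1), (1, 2), (3, 1), (1, 4)])
        trails = decompose_trails(g)
        assert len(trails) == 2
        assert all(t.n_edges == 2 for t in trails)
        total_turn = sum(t.total_turning_deg for t in trails)
        assert total_turn == pytest.approx(0.0, abs=1e-5)
        assert brute_force_optimum(g) == (2, pytest.approx(0.0, abs=1e-5))

    def test_gentle_polygon_cycle_cut_once(self):
        """A closed gentle polygon (all bends feasible) is one trail cut
        at its sharpest bend."""
        n = 9
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pos = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang)])
        g = make_graph(pos, [(i, (i + 1) % n) for i in range(n)])
        trails = decompose_trails(g)
        assert len(trails) == 1
        assert trails[0].n_edges == n
        n_opt, t_opt = brute_force_optimum(g)
        assert n_opt == 1
        assert sum(t.total_turning_deg for t in trails) == pytest.approx(t_opt)

    def test_partition_and_feasibility_random(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_geometric_graph(rng)
            trails = decompose_trails(g)
            assert sum(t.n_edges for t in trails) == g.n_edges
            total_edge_len = sum(g.g.edges[e]["length_px"] for e in g.g.edges)
            assert sum(t.length_px for t in trails) == pytest.approx(total_edge_len)
            for t in trails:
                assert all(b >= 135.0 - 1e-9 for b in t.bends_deg)

    def test_matches_exhaustive_oracle_random(self):
        """Decomposition attains the exhaustive-enumeration optimum of
        (number of trails, total turning) on random small graphs."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_geometric_graph(rng)
            trails = decompose_trails(g)
            got = (len(trails), sum(t.total_turning_deg for t in trails))
            want = brute_force_optimum(g)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        g = random_geometric_graph(rng)
        t1 = decompose_trails(g)
        t2 = decompose_trails(g)
        assert [t.nodes for t in t1] == [t.nodes for t in t2]


class TestMeasure:
    def test_three_four_five_triangle(self):
        g = make_graph([(0, 0), (3, 4)], [(0, 1)])
        trails = decompose_trails(g, pixel_size_um=1.0)
        m = measure(trails)
        assert m.filament_number == 1
        assert m.total_length_um == pytest.approx(5.0)
        assert m.average_length_um == pytest.approx(5.0)
        assert m.max_length_um == pytest.approx(5.0)

    def test_empty_trails(self):
        m = measure([])
        assert m.filament_number == 0
        assert m.total_length_um == 0.0
        assert m.average_length_um is None
        assert m.max_length_um is None

    def test_two_trails_summary(self):
        from filatrace.graph import FilamentTrail
        trails = [FilamentTrail([0, 1], 2.0, 2.0, []),
                  FilamentTrail([2, 3], 6.0, 6.0, [])]
        m = measure(trails)
        assert m.filament_number == 2
        assert m.total_length_um == pytest.approx(8.0)
        assert m.average_length_um == pytest.approx(4.0)
        assert m.max_length_um == pytest.approx(6.0)

    def test_pixel_size_rescaling(self):
        from filatrace.graph import FilamentTrail
        trails = [FilamentTrail([0, 1], 10.0, 10.0, [])]
        m = measure(trails, pixel_size_um=0.25)
        assert m.total_length_um == pytest.approx(2.5)
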