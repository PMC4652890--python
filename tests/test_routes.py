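"""Route encoding, clustering, similarity and path-efficiency metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comanav.environments import (BoxObstacle, make_cubic_box,
                                  make_random_checkerboard)
from comanav.routes import (OUTSIDE, cell_sequence, cluster_routes,
                            delaunay_mesh, efficiency_metrics, route_distance,
                            route_dendrogram, shortest_path,
                            simplify_sequence, voronoi_path)

SEQ = st.lists(st.integers(min_value=0, max_value=6), max_size=12)


class TestMesh:
    def test_unit_square_two_triangles(self):
        mesh = delaunay_mesh(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert len(mesh.triangles) == 2

    def test_three_points_one_triangle(self):
        mesh = delaunay_mesh(np.array([[0, 0], [1, 0], [0.5, 1]]))
        assert len(mesh.triangles) == 1

    @pytest.mark.parametrize("pts", [
        [[0, 0], [1, 1]],
        [[0, 0], [1, 1], [2, 2], [3, 3]],
    ])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(ValueError):
            delaunay_mesh(np.array(pts, dtype=float))

    def test_deterministic_cell_ids(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        a = delaunay_mesh(pts)
        b = delaunay_mesh(pts)
        assert np.array_equal(a.triangles, b.triangles)


class TestCellSequence:
    @pytest.fixture(scope="class")
    def mesh(self):
        return delaunay_mesh(np.array([[0, 0], [2, 0], [2, 2], [0, 2]]))

    def test_single_cell_trajectory(self, mesh):
        pts = np.array([[0.5, 0.4], [0.6, 0.4], [0.7, 0.45]])
        assert len(cell_sequence(pts, mesh)) == 1

    @pytest.fixture(scope="class")
    def two_cell_points(self, mesh):
        """One point in each of the two triangles of the square mesh."""
        candidates = [np.array([1.5, 0.2]), np.array([0.2, 1.5]),
                      np.array([1.8, 1.5]), np.array([0.2, 0.5])]
        cells = {int(mesh.locate(p[None, :])[0]): p for p in candidates}
        assert len(cells) == 2
        return list(cells.values())

    def test_crossing_two_cells(self, mesh, two_cell_points):
        a, b = two_cell_points
        pts = np.linspace(a, b, 20)
        seq = cell_sequence(pts, mesh)
        assert len(seq) == 2 and seq[0] != seq[1]

    def test_oscillation_kept_before_simplification(self, mesh,
                                                    two_cell_points):
        a, b = two_cell_points
        pts = np.vstack([a, b, a])
        seq = cell_sequence(pts, mesh)
        assert len(seq) == 3 and seq[0] == seq[2] and seq[0] != seq[1]

    def test_outside_points_get_reserved_token(self, mesh):
        pts = np.array([[0.5, 0.5], [5.0, 5.0], [6.0, 6.0], [0.5, 0.5]])
        seq = cell_sequence(pts, mesh)
        assert OUTSIDE in seq
        assert seq.count(OUTSIDE) == 1  # consecutive duplicates collapsed


class TestSimplify:
    @pytest.mark.parametrize("seq,expected", [
        ([], []),
        (["A", "B", "C"], ["A", "B", "C"]),
        (["A", "B", "A", "C"], ["A", "C"]),
        (["A", "B", "C", "B", "D", "B", "E"], ["A", "B", "E"]),
    ])
    def test_examples(self, seq, expected):
        assert simplify_sequence(seq) == expected

    @given(SEQ)
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_duplicate_free(self, seq):
        once = simplify_sequence(seq)
        assert simplify_sequence(once) == once
        assert len(once) == len(set(once))

    @given(SEQ)
    @settings(max_examples=100, deadline=None)
    def test_endpoints_preserved(self, seq):
        out = simplify_sequence(seq)
        if seq:
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_outside_marker_exempt_from_suppression(self):
        """A run that leaves and re-enters the hull keeps its interior
        cells: repeated OUTSIDE tokens do not trigger suppression."""
        from comanav.routes import OUTSIDE as O
        assert simplify_sequence([O, 1, 2, 3, O]) == [O, 1, 2, 3, O]
        assert simplify_sequence([O, 1, 2, 1, 3, O]) == [O, 1, 3, O]
        # cell revisits across an outside excursion still collapse
        assert simplify_sequence([1, O, 2, O, 1]) == [1]


class TestClusters:
    def test_identical_sequences_one_route(self):
        rs = cluster_routes([(1, 2, 3), (1, 2, 3)])
        assert rs.n_routes == 1 and rs.members[0] == [0, 1]

    def test_distinct_sequences_distinct_routes(self):
        rs = cluster_routes([(1,), (2,), (3,)])
        assert rs.n_routes == 3

    def test_empty_input(self):
        assert cluster_routes([]).n_routes == 0

    def test_partition_property(self):
        seqs = [(1, 2), (1, 2), (3,), (1, 2, 3), (3,)]
        rs = cluster_routes(seqs)
        members = sorted(i for m in rs.members.values() for i in m)
        assert members == list(range(len(seqs)))


class TestRouteDistance:
    @pytest.mark.parametrize("a,b,d", [
        ((1, 2, 3), (1, 2, 3), 0),
        ((1, 2, 3), (1, 4, 3), 2),
        ((1, 2), (3, 4), 4),
    ])
    def test_examples(self, a, b, d):
        assert route_distance(a, b) == d

    @given(SEQ, SEQ, SEQ)
    @settings(max_examples=200, deadline=None)
    def test_pseudo_metric(self, a, b, c):
        """Symmetry, identity on equal cell sets, triangle inequality —
        against the brute-force symmetric-difference definition."""
        def brute(x, y):
            return sum(1 for e in set(x) | set(y)
                       if (e in set(x)) != (e in set(y)))
        assert route_distance(a, b) == brute(a, b)
        assert route_distance(a, b) == route_distance(b, a)
        if set(a) == set(b):
            assert route_distance(a, b) == 0
        assert route_distance(a, c) <= route_distance(a, b) + \
            route_distance(b, c)


class TestDendrogram:
    def test_zero_distance_merges_at_zero(self):
        link = route_dendrogram([(1, 2, 3), (3, 2, 1), (7, 8, 9)])
        assert link[0, 2] == pytest.approx(0.0)

    def test_closest_pair_merges_first(self):
        link = route_dendrogram([(1, 2), (1, 2, 3), (8, 9, 10, 11)])
        assert sorted(link[0, :2].astype(int).tolist()) == [0, 1]

    def test_leaf_count(self):
        seqs = [(i,) for i in range(5)]
        link = route_dendrogram(seqs)
        assert link.shape == (4, 4)

    def test_single_route_rejected(self):
        with pytest.raises(ValueError):
            route_dendrogram([(1, 2)])


@pytest.fixture(scope="module")
def small_course():
    """1 m box with a picket of three bars blocking the direct line."""
    tex = make_random_checkerboard(8.0, (400.0, 400.0), seed=0)
    env = make_cubic_box(edge=1.0, wall_texture=tex)
    obstacles = tuple(
        BoxObstacle(center=c, base_edge=0.12, height=0.5, texture=tex)
        for c in [(0.5, 0.2), (0.5, 0.5), (0.5, 0.8)]
    )
    return type(env)(**{**env.__dict__, "obstacles": obstacles})


class TestPaths:
    def test_clear_arena_straight_line(self, checker_box):
        length, pts = shortest_path(checker_box, (0.1, 0.1), (0.3, 0.3))
        assert length == pytest.approx(np.hypot(0.2, 0.2), rel=1e-9)
        assert len(pts) == 2

    def test_detour_around_obstacle(self, small_course):
        start, goal = (0.1, 0.5), (0.9, 0.5)
        length, pts = shortest_path(small_course, start, goal, inflation=0.01)
        direct = 0.8
        assert length > direct
        assert len(pts) > 2

    def test_shortest_beats_dense_grid_search(self, small_course):
        """Visibility-graph length <= best collision-free grid path."""
        import networkx as nx
        from comanav._raycast import surface_distance
        start, goal = (0.1, 0.5), (0.9, 0.5)
        vis_len, _ = shortest_path(small_course, start, goal, inflation=0.01)
        n = 41
        xs = np.linspace(0.05, 0.95, n)
        ys = np.linspace(0.05, 0.95, n)
        G = nx.Graph()
        def free(i, j):
            return surface_distance(
                small_course, np.array([xs[i], ys[j], 0.25])) >= 0.01
        for i in range(n):
            for j in range(n):
                if not free(i, j):
                    continue
                for di, dj in [(1, 0), (0, 1), (1, 1), (1, -1)]:
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < n and free(a, b):
                        w = np.hypot(xs[a] - xs[i], ys[b] - ys[j])
                        G.add_edge((i, j), (a, b), weight=w)
        def nearest(p):
            return (int(np.argmin(np.abs(xs - p[0]))),
                    int(np.argmin(np.abs(ys - p[1]))))
        grid_len = nx.shortest_path_length(G, nearest(start), nearest(goal),
                                           weight="weight")
        assert vis_len <= grid_len + 1e-9

    def test_voronoi_path_exists_and_clears(self, small_course):
        length, pts = voronoi_path(small_course, (0.1, 0.5), (0.9, 0.5))
        assert length >= 0.8
        # skeleton waypoints keep clearance from every obstacle
        for x, y in pts[1:-1]:
            for ob in small_course.obstacles:
                gap = max(abs(x - ob.center[0]), abs(y - ob.center[1])) \
                    - ob.base_edge / 2.0
                assert gap > 0.01


class TestEfficiency:
    def test_straight_run_efficiency_one(self, checker_box):
        from comanav.simulate import Trajectory
        xs = np.linspace(0.1, 0.3, 50)
        tr = Trajectory(t_ms=np.arange(50.0), x=xs, y=np.full(50, 0.2),
                        heading_deg=np.zeros(50), phase=np.zeros(50, np.int8),
                        outcome="goal", saccades=[], seed=0)
        rep = efficiency_metrics([tr], checker_box, goal=(0.3, 0.2))
        assert rep.loc[0, "efficiency"] == pytest.approx(1.0, abs=0.01)

    def test_double_length_half_efficiency(self, checker_box):
        from comanav.simulate import Trajectory
        xs = np.concatenate([np.linspace(0.1, 0.3, 50),
                             np.linspace(0.3, 0.1, 50),
                             np.linspace(0.1, 0.3, 50)])
        tr = Trajectory(t_ms=np.arange(150.0), x=xs, y=np.full(150, 0.2),
                        heading_deg=np.zeros(150),
                        phase=np.zeros(150, np.int8),
                        outcome="goal", saccades=[], seed=0)
        rep = efficiency_metrics([tr], checker_box, goal=(0.3, 0.2))
        assert rep.loc[0, "efficiency"] == pytest.approx(1 / 3, abs=0.01)

    def test_crash_counted_in_reliability_not_efficiency(self, checker_box):
        from comanav.simulate import Trajectory
        def make(outcome):
            return Trajectory(t_ms=np.arange(10.0),
                              x=np.linspace(0.1, 0.15, 10),
                              y=np.full(10, 0.2), heading_deg=np.zeros(10),
                              phase=np.zeros(10, np.int8), outcome=outcome,
                              saccades=[], seed=0)
        rep = efficiency_metrics([make("crash"), make("goal"),
                                  make("timeout")],
                                 checker_box, goal=(0.15, 0.2))
        assert rep.loc[0, "outcome"] == "crash"
        assert np.isnan(rep.loc[0, "efficiency"])
        assert rep.loc[2, "outcome"] == "dead-end"
        assert (rep.outcome == "crash").mean() * 100 == pytest.approx(100 / 3)
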