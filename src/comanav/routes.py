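"""Route clustering and performance metrics for goal-directed trajectories.

Trajectories through a cluttered environment are encoded as sequences of
Delaunay cells: the obstacle centers are triangulated, each trajectory point
is assigned to the triangle containing it, consecutive duplicates are
collapsed, and revisits are removed by suppressing the subsequence between
the first and last occurrence of a repeated cell.  Trajectories sharing the
same simplified sequence form one route.  Route similarity is the number of
cells not shared by two routes (symmetric difference of their cell sets, a
Hamming-like distance), and routes are organized in a dendrogram by
agglomerative clustering on that distance.

Performance of a set of goal-directed runs is quantified by reliability (the
percentage of trajectories that crash before reaching the goal) and
efficiency (shortest collision-free path length divided by realized path
length, per goal-reaching trajectory); a maximal-clearance baseline path on
the Voronoi skeleton of the obstacles is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import Delaunay, Voronoi
from shapely.geometry import LineString, Point, box as shapely_box
from shapely.ops import unary_union

from .environments import Environment
from .simulate import Trajectory

__all__ = [
    "Mesh",
    "CellSequence",
    "RouteSet",
    "delaunay_mesh",
    "cell_sequence",
    "simplify_sequence",
    "cluster_routes",
    "route_distance",
    "route_dendrogram",
    "shortest_path",
    "voronoi_path",
    "efficiency_metrics",
]

OUTSIDE = -1  # reserved token for trajectory points outside the convex hull


@dataclass(frozen=True)
class Mesh:
    """Delaunay triangulation of the obstacle centers."""

    nodes: np.ndarray            # (n, 2) obstacle centers
    triangles: np.ndarray        # (m, 3) node indices per cell
    _delaunay: Delaunay = field(repr=False, compare=False, default=None)

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Cell id per point; OUTSIDE for points beyond the convex hull."""
        return self._delaunay.find_simplex(np.asarray(points, dtype=float))


def delaunay_mesh(centers: np.ndarray) -> Mesh:
    """Triangulate obstacle centers (>= 3 non-collinear points required).

    Co-circular quadruples are broken deterministically by scipy's 'Qbb Qz'
    default; the triangle list is re-sorted lexicographically so equal inputs
    always yield identical cell ids.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points in the plane")
    spread = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-12) < 2:
        raise ValueError("points are collinear")
    tri = Delaunay(pts)
    order = np.lexsort(np.sort(tri.simplices, axis=1).T[::-1])
    return Mesh(nodes=pts, triangles=np.sort(tri.simplices, axis=1)[order],
                _delaunay=tri)


def cell_sequence(trajectory: Trajectory | np.ndarray, mesh: Mesh
                  ) -> list[int]:
    """Raw cell sequence of a trajectory: per-point triangle lookup with
    consecutive duplicates collapsed.  Points outside the convex hull emit
    the reserved ``OUTSIDE`` token (likewise deduplicated), so wall-hugging
    detours still differentiate routes."""
    pts = (trajectory.positions if isinstance(trajectory, Trajectory)
           else np.asarray(trajectory, dtype=float))
    ids = mesh.locate(pts)
    ids = np.where(ids < 0, OUTSIDE, ids)
    if ids.size == 0:
        return []
    keep = np.ones(ids.size, dtype=bool)
    keep[1:] = ids[1:] != ids[:-1]
    return [int(v) for v in ids[keep]]


def simplify_sequence(seq: list[int],
                      protected: tuple[int, ...] = (OUTSIDE,)) -> list[int]:
    """Remove revisits: scanning from the front, for each element that recurs
    delete everything between its first and last occurrence (keeping one
    copy); repeat to convergence.  Idempotent.

    ``protected`` tokens are exempt from suppression: the reserved
    ``OUTSIDE`` marker is not a revisitable region (a trajectory that both
    starts and ends beyond the convex hull would otherwise collapse to the
    bare marker, erasing the route), so repeated outside excursions stay in
    place and still separate the cells between them."""
    out = list(seq)
    i = 0
    while i < len(out):
        if out[i] in protected:
            i += 1
            continue
        last = len(out) - 1 - out[::-1].index(out[i])
        if last != i:
            out = out[: i + 1] + out[last + 1:]
        i += 1
    return out


@dataclass(frozen=True)
class CellSequence:
    """Simplified Delaunay-cell encoding of one trajectory."""

    cells: tuple[int, ...]
    trajectory_id: int | None = None


def trajectory_sequence(trajectory: Trajectory | np.ndarray, mesh: Mesh,
                        trajectory_id: int | None = None) -> CellSequence:
    return CellSequence(
        cells=tuple(simplify_sequence(cell_sequence(trajectory, mesh))),
        trajectory_id=trajectory_id)


@dataclass
class RouteSet:
    """Trajectories grouped by identical simplified cell sequence.

    ``routes`` maps route id -> cell sequence; ``members`` maps route id ->
    member trajectory indices.  Route ids are ordered by descending member
    count, ties broken lexicographically by sequence.
    """

    routes: dict[int, tuple[int, ...]]
    members: dict[int, list[int]]

    @property
    def n_routes(self) -> int:
        return len(self.routes)


def cluster_routes(sequences: list[CellSequence] | list[tuple[int, ...]]
                   ) -> RouteSet:
    """Exact-match grouping of cell sequences into routes."""
    groups: dict[tuple[int, ...], list[int]] = {}
    for i, s in enumerate(sequences):
        key = s.cells if isinstance(s, CellSequence) else tuple(s)
        groups.setdefault(key, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return RouteSet(routes={rid: key for rid, (key, _) in enumerate(ordered)},
                    members={rid: mem for rid, (_, mem) in enumerate(ordered)})


def route_distance(seq_a, seq_b) -> int:
    """Number of cells not shared by two routes: the size of the symmetric
    difference of their cell sets (a pseudo-metric on sequences)."""
    a = set(seq_a.cells if isinstance(seq_a, CellSequence) else seq_a)
    b = set(seq_b.cells if isinstance(seq_b, CellSequence) else seq_b)
    return len(a ^ b)


def route_dendrogram(route_set: RouteSet | list[tuple[int, ...]]
                     ) -> np.ndarray:
    """Average-linkage agglomerative clustering on the route-distance matrix.

    Accepts a RouteSet or a plain list of sequences (e.g. routes pooled from
    two runs for a cross-texture comparison).  Returns the scipy linkage
    matrix; leaves are route ids in input order.
    """
    seqs = (list(route_set.routes.values())
            if isinstance(route_set, RouteSet) else list(route_set))
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two routes")
    condensed = [float(route_distance(seqs[i], seqs[j]))
                 for i in range(n) for j in range(i + 1, n)]
    return hierarchy.linkage(np.asarray(condensed), method="average")


# ---------------------------------------------------------------------------
# shortest-path / clearance baselines and performance metrics
# ---------------------------------------------------------------------------

def _inflated_obstacles(env: Environment, inflation: float):
    polys = []
    for ob in env.obstacles:
        h = ob.base_edge / 2.0 + inflation
        x, y = ob.center
        polys.append(shapely_box(x - h, y - h, x + h, y + h))
    return polys


def shortest_path(env: Environment, start: tuple[float, float],
                  goal: tuple[float, float], inflation: float = 0.01
                  ) -> tuple[float, np.ndarray]:
    """Shortest collision-free path via a visibility graph.

    Obstacles are inflated by the collision radius (square corners kept);
    graph nodes are the inflated corners plus start and goal, edges join
    mutually visible nodes that stay inside the walls.  Returns (length,
    waypoints).  Raises ``ValueError`` if the goal is unreachable.
    """
    polys = _inflated_obstacles(env, inflation)
    blocked = unary_union(polys) if polys else None
    lo = inflation
    nodes: list[tuple[float, float]] = [tuple(start), tuple(goal)]
    for p in polys:
        for x, y in np.asarray(p.exterior.coords)[:-1]:
            if env.walls and not (lo <= x <= env.width - lo
                                  and lo <= y <= env.depth - lo):
                continue
            nodes.append((float(x), float(y)))

    def free(a, b) -> bool:
        seg = LineString([a, b])
        if blocked is not None and seg.crosses(blocked):
            return False
        if blocked is not None and seg.within(blocked):
            return False
        return True

    graph = nx.Graph()
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            b = nodes[j]
            if free(a, b):
                graph.add_edge(i, j, weight=float(np.hypot(a[0] - b[0],
                                                           a[1] - b[1])))
    try:
        path = nx.shortest_path(graph, 0, 1, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound) as err:
        raise ValueError("goal unreachable on the visibility graph") from err
    pts = np.array([nodes[i] for i in path])
    length = float(np.hypot(*np.diff(pts, axis=0).T).sum())
    return length, pts


def voronoi_path(env: Environment, start: tuple[float, float],
                 goal: tuple[float, float], inflation: float = 0.01
                 ) -> tuple[float, np.ndarray]:
    """Maximal-clearance baseline: path along the Voronoi skeleton of the
    obstacle centers (wall midpoints added as sites), start and goal joined
    to their nearest skeleton vertices.  Returns (length, waypoints)."""
    sites = [ob.center for ob in env.obstacles]
    if env.walls:
        # mirror sites across the walls so ridges run mid-way to the walls
        for x, y in list(sites):
            sites += [(-x, y), (2 * env.width - x, y),
                      (x, -y), (x, 2 * env.depth - y)]
    if len(sites) < 4:
        raise ValueError("need at least 4 sites for a Voronoi skeleton")
    vor = Voronoi(np.asarray(sites))
    polys = _inflated_obstacles(env, inflation)
    blocked = unary_union(polys) if polys else None

    def admissible(p, slack=1e-9) -> bool:
        # mirror sites put skeleton vertices exactly on the walls: allow them
        x, y = p
        if env.walls and not (-slack <= x <= env.width + slack
                              and -slack <= y <= env.depth + slack):
            return False
        return blocked is None or not blocked.contains(Point(x, y))

    graph = nx.Graph()
    for (i, j) in vor.ridge_vertices:
        if i < 0 or j < 0:
            continue
        a, b = vor.vertices[i], vor.vertices[j]
        if admissible(a) and admissible(b) and admissible((a + b) / 2.0):
            graph.add_edge(i, j, weight=float(np.hypot(*(a - b))))
    if graph.number_of_edges() == 0:
        raise ValueError("empty Voronoi skeleton")

    skeleton_nodes = [v for v in graph.nodes if isinstance(v, (int, np.integer))]

    def attach(p, name):
        best, best_d = None, np.inf
        for v in skeleton_nodes:
            d = float(np.hypot(*(vor.vertices[v] - p)))
            if d < best_d:
                best, best_d = v, d
        graph.add_edge(name, best, weight=best_d)

    attach(np.asarray(start), "start")
    attach(np.asarray(goal), "goal")
    try:
        path = nx.shortest_path(graph, "start", "goal", weight="weight")
    except nx.NetworkXNoPath as err:
        raise ValueError("goal unreachable on the Voronoi skeleton") from err
    pts = [start] + [tuple(vor.vertices[v]) for v in path[1:-1]] + [goal]
    pts = np.asarray(pts)
    length = float(np.hypot(*np.diff(pts, axis=0).T).sum())
    return length, pts


def efficiency_metrics(
    trajectories: list[Trajectory],
    env: Environment,
    goal: tuple[float, float],
    inflation: float = 0.01,
) -> pd.DataFrame:
    """Per-trajectory performance report.

    Columns: outcome (goal / crash / dead-end), realized path length,
    visibility-graph shortest length from the same start, efficiency
    (shortest / realized, goal-reaching runs only) and the Voronoi baseline
    length.  Reliability (% crash) is ``(report.outcome == 'crash').mean() *
    100``.
    """
    rows = []
    for i, tr in enumerate(trajectories):
        start = (float(tr.x[0]), float(tr.y[0]))
        outcome = {"timeout": "dead-end"}.get(tr.outcome, tr.outcome)
        realized = tr.path_length()
        try:
            sp_len, _ = shortest_path(env, start, goal, inflation)
        except ValueError:
            sp_len = np.nan
        try:
            vor_len, _ = voronoi_path(env, start, goal, inflation)
        except ValueError:
            vor_len = np.nan
        eff = (sp_len / realized
               if outcome == "goal" and realized > 0 and np.isfinite(sp_len)
               else np.nan)
        rows.append({"trajectory": i, "outcome": outcome,
                     "realized_m": realized, "shortest_m": sp_len,
                     "voronoi_m": vor_len, "efficiency": eff})
    return pd.DataFrame(rows)


def linkage_to_json(linkage: np.ndarray) -> str:
    """Serialize a scipy linkage matrix to JSON (list of merge records)."""
    return json.dumps([
        {"left": int(a), "right": int(b), "height": float(h), "size": int(n)}
        for a, b, h, n in linkage
    ])
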