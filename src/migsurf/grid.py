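"""Triangular spatial lattice over a habitat polygon.

The lattice discretizes the habitat: nodes are demes, edges carry the
migration weights to be estimated.  Everything downstream (the GMRF
likelihood, the smoothness penalty) is expressed through this graph's
Laplacian and its pseudo-inverse, so this module also houses the sparse
"grounded Laplacian" solver that replaces dense pseudo-inversion.

Coordinates are always (longitude, latitude) in degrees.  Lattice geometry
is laid out in a local equirectangular projection of the habitat (kilometre
units) and clipped to the polygon; samples are attached to their nearest
node by great-circle distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import LineString, Point, Polygon

EARTH_RADIUS_KM = 6371.0088


class GraphConstructionError(ValueError):
    """Raised when the habitat polygon yields a degenerate or disconnected lattice."""


@dataclass
class SpatialGraph:
    """Triangular lattice with node coordinates and canonical edge ordering.

    Attributes
    ----------
    node_coords : (d, 2) float array
        Longitude/latitude of each lattice node, degrees.
    edges : (m, 2) int array
        Edge list with ``k < l`` and rows sorted lexicographically.
    resolution_km : float or None
        Target edge length used during construction (None for hand-built graphs).
    observed_ids : (o,) int array or None
        Sorted node indices that received at least one sample.
    assignment : (o, d) CSR matrix or None
        One-hot matrix mapping latent node frequencies to observed nodes.
    """

    node_coords: np.ndarray
    edges: np.ndarray
    resolution_km: float | None = None
    observed_ids: np.ndarray | None = None
    assignment: sp.csr_matrix | None = None
    _incidence: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an (m, 2) array")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy k < l")
        order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
        self.edges = self.edges[order]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def _project(coords: np.ndarray, lat0: float) -> np.ndarray:
    """Equirectangular lon/lat -> km about reference latitude lat0."""
    c = np.asarray(coords, dtype=float)
    x = np.radians(c[..., 0]) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(c[..., 1]) * EARTH_RADIUS_KM
    return np.stack([x, y], axis=-1)


def _unproject(xy: np.ndarray, lat0: float) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    lon = np.degrees(xy[..., 0] / (EARTH_RADIUS_KM * np.cos(np.radians(lat0))))
    lat = np.degrees(xy[..., 1] / EARTH_RADIUS_KM)
    return np.stack([lon, lat], axis=-1)


def great_circle_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise haversine distance in km between (n,2) and (m,2) lon/lat arrays."""
    a = np.radians(np.atleast_2d(a))
    b = np.radians(np.atleast_2d(b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _lattice_edges(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Triangular-lattice adjacency among (row, col) indexed nodes.

    Nodes on odd rows are shifted +1/2 in x, so the up-neighbours of (i, j)
    are (i+1, j) plus (i+1, j-1) on even rows / (i+1, j+1) on odd rows.
    """
    index = {(int(r), int(c)): k for k, (r, c) in enumerate(zip(rows, cols))}
    edges = []
    for (i, j), k in index.items():
        for di, dj in ((0, 1), (1, 0), (1, -1 if i % 2 == 0 else 1)):
            other = index.get((i + di, j + dj))
            if other is not None:
                a, b = (k, other) if k < other else (other, k)
                edges.append((a, b))
    if not edges:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.asarray(edges, dtype=np.int64), axis=0)


def build_triangular_grid(polygon: np.ndarray | Polygon, resolution: float) -> SpatialGraph:
    """Build a triangular lattice covering ``polygon`` with ~``resolution`` km edges.

    Parameters
    ----------
    polygon : (v, 2) array of lon/lat vertices, or a shapely Polygon.
    resolution : target edge length in km (> 0).

    Raises
    ------
    GraphConstructionError
        If the polygon is degenerate, fewer than two nodes fit inside it,
        or the clipped lattice is disconnected.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(polygon, Polygon):
        ring = np.asarray(polygon.exterior.coords, dtype=float)
    else:
        ring = np.asarray(polygon, dtype=float)
        if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
            raise GraphConstructionError("polygon needs at least 3 lon/lat vertices")
    lat0 = float(np.mean(ring[:, 1]))
    poly_xy = Polygon(_project(ring, lat0))
    if not poly_xy.is_valid or poly_xy.area <= 0:
        raise GraphConstructionError("degenerate polygon (zero area or self-intersecting)")

    minx, miny, maxx, maxy = poly_xy.bounds
    dy = resolution * np.sqrt(3.0) / 2.0
    n_rows = int(np.floor((maxy - miny) / dy)) + 1
    n_cols = int(np.floor((maxx - minx) / resolution)) + 2
    rows_all, cols_all, pts = [], [], []
    for i in range(n_rows):
        xoff = (resolution / 2.0) if i % 2 else 0.0
        for j in range(n_cols):
            x = minx + j * resolution + xoff
            y = miny + i * dy
            if poly_xy.covers(Point(x, y)):
                rows_all.append(i)
                cols_all.append(j)
                pts.append((x, y))
    if len(pts) < 2:
        raise GraphConstructionError(
            f"only {len(pts)} lattice node(s) fit inside the polygon at "
            f"resolution {resolution} km; no edges can be formed"
        )
    rows_all = np.asarray(rows_all)
    cols_all = np.asarray(cols_all)
    edges = _lattice_edges(rows_all, cols_all)
    # an edge must lie inside the habitat: neighbouring nodes separated by a
    # gap in the polygon (e.g. across a narrow inlet) are not connected
    pts_arr = np.asarray(pts)
    hull = poly_xy.buffer(1e-9 * max(1.0, resolution))
    inside = np.array(
        [hull.covers(LineString(pts_arr[e])) for e in edges], dtype=bool
    )
    edges = edges[inside]
    if edges.shape[0] == 0:
        raise GraphConstructionError("no lattice edges lie inside the polygon")
    coords = _unproject(pts_arr, lat0)
    graph = SpatialGraph(coords, edges, resolution_km=resolution)
    _check_connected(graph)
    return graph


def build_rectangle_lattice(
    n_rows: int, n_cols: int, spacing_km: float = 50.0, origin: tuple[float, float] = (0.0, 0.0)
) -> SpatialGraph:
    """Unclipped ``n_rows`` x ``n_cols`` triangular lattice (mainly for simulation).

    The lattice is laid out near ``origin`` (lon, lat) with ~``spacing_km``
    edge lengths; odd rows are offset by half a spacing.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise ValueError("lattice must contain at least 2 nodes")
    lat0 = origin[1]
    dy = spacing_km * np.sqrt(3.0) / 2.0
    rows, cols, pts = [], [], []
    x0, y0 = _project(np.asarray(origin, dtype=float), lat0)
    for i in range(n_rows):
        xoff = (spacing_km / 2.0) if i % 2 else 0.0
        for j in range(n_cols):
            rows.append(i)
            cols.append(j)
            pts.append((x0 + j * spacing_km + xoff, y0 + i * dy))
    edges = _lattice_edges(np.asarray(rows), np.asarray(cols))
    coords = _unproject(np.asarray(pts), lat0)
    graph = SpatialGraph(coords, edges, resolution_km=spacing_km)
    _check_connected(graph)
    return graph


def _check_connected(graph: SpatialGraph) -> None:
    adj = sp.coo_matrix(
        (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise GraphConstructionError(
            f"lattice is disconnected: {n_comp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)}; enlarge the polygon or "
            "reduce the grid resolution"
        )


def assign_samples(sample_coords: np.ndarray, graph: SpatialGraph) -> np.ndarray:
    """Attach each sample to its nearest lattice node (great-circle distance).

    Ties are broken by the lowest node index.  Samples farther than twice the
    grid resolution from every node trigger a warning but are still assigned.
    Populates ``graph.observed_ids`` and ``graph.assignment`` and returns the
    per-sample node index array.
    """
    coords = np.asarray(sample_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("sample_coords must be (n, 2) lon/lat")
    if not np.all(np.isfinite(coords)):
        raise ValueError("sample coordinates must be finite")
    dist = great_circle_km(coords, graph.node_coords)
    node_of_sample = np.argmin(dist, axis=1)  # argmin -> lowest index on ties
    if graph.resolution_km is not None:
        dmin = dist[np.arange(len(coords)), node_of_sample]
        far = dmin > 2.0 * graph.resolution_km
        if np.any(far):
            warnings.warn(
                f"{int(far.sum())} sample(s) lie more than twice the grid "
                "resolution from every node; assigned to the nearest node anyway",
                stacklevel=2,
            )
    observed = np.unique(node_of_sample)
    o = len(observed)
    A = sp.csr_matrix(
        (np.ones(o), (np.arange(o), observed)), shape=(o, graph.n_nodes)
    )
    graph.observed_ids = observed
    graph.assignment = A
    return node_of_sample


def laplacian(graph: SpatialGraph, w: np.ndarray) -> sp.csr_matrix:
    """Weighted graph Laplacian L = diag(W 1) - W as a sparse CSR matrix."""
    w = np.asarray(w, dtype=float)
    if w.shape != (graph.n_edges,):
        raise ValueError(f"expected {graph.n_edges} edge weights, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("edge weights must be finite")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    d = graph.n_nodes
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-w, -w, w, w])
    return sp.coo_matrix((vals, (rows, cols)), shape=(d, d)).tocsr()


class LaplacianSolver:
    """Solves L† B through a grounded-Laplacian factorization.

    Node 0 is grounded (its row/column removed); for right-hand sides that are
    centered against the ones vector the grounded solve reproduces the
    pseudo-inverse action exactly after re-centering the solution.  Arbitrary
    right-hand sides are centered implicitly, which is the same as applying
    L† (whose row space excludes the ones vector).

    Dense Cholesky is used for small graphs, sparse LU above ``dense_cutoff``
    nodes; correctness is independent of the grounded node.
    """

    def __init__(self, graph: SpatialGraph, w: np.ndarray, dense_cutoff: int = 800):
        self.d = graph.n_nodes
        L = laplacian(graph, w)
        if self.d <= dense_cutoff:
            Lg = L.toarray()[1:, 1:]
            self._cho = scipy.linalg.cho_factor(Lg, lower=True, check_finite=False)
            self._solve_g = lambda B: scipy.linalg.cho_solve(
                self._cho, B, check_finite=False
            )
        else:
            Lg = L.tocsc()[1:, :][:, 1:]
            lu = sp.linalg.splu(Lg)
            self._solve_g = lu.solve

    def solve_pinv(self, B: np.ndarray) -> np.ndarray:
        """Return L† B for a (d, r) right-hand side (implicitly centered)."""
        B = np.asarray(B, dtype=float)
        squeeze = B.ndim == 1
        if squeeze:
            B = B[:, None]
        Bc = B - B.mean(axis=0, keepdims=True)
        X = np.zeros_like(Bc)
        X[1:] = self._solve_g(Bc[1:])
        X -= X.mean(axis=0, keepdims=True)
        return X[:, 0] if squeeze else X


def pinv_quadform(graph: SpatialGraph, w: np.ndarray, B: np.ndarray) -> np.ndarray:
    """L† B via the grounded-Laplacian solver (never dense pseudo-inversion)."""
    return LaplacianSolver(graph, w).solve_pinv(B)


def resistance_distance(
    graph: SpatialGraph, w: np.ndarray, k: int | None = None, l: int | None = None
) -> np.ndarray | float:
    """Effective resistance r_kl = L†_kk - 2 L†_kl + L†_ll.

    With ``k``/``l`` given returns the scalar distance between that node
    pair; otherwise returns the full d x d matrix.
    """
    if (k is None) != (l is None):
        raise ValueError("give both k and l, or neither")
    solver = LaplacianSolver(graph, w)
    if k is not None:
        if k == l:
            return 0.0
        b = np.zeros(graph.n_nodes)
        b[k], b[l] = 1.0, -1.0
        return float(b @ solver.solve_pinv(b))
    Lp = solver.solve_pinv(np.eye(graph.n_nodes))
    dg = np.diag(Lp)
    return dg[:, None] + dg[None, :] - Lp - Lp.T


def edge_pair_incidence(graph: SpatialGraph) -> sp.csr_matrix:
    """Signed incidence over pairs of edges sharing a node.

    One row per unordered pair of distinct edges incident to a common node
    (counted once even if the pair shares both endpoints): +1 on the
    lexicographically smaller edge, -1 on the larger.  ``incidence @ g`` is
    the vector of adjacent-edge differences of any per-edge quantity g.
    """
    if graph._incidence is not None:
        return graph._incidence
    by_node: list[list[int]] = [[] for _ in range(graph.n_nodes)]
    for e, (a, b) in enumerate(graph.edges):
        by_node[a].append(e)
        by_node[b].append(e)
    pairs = set()
    for elist in by_node:
        for x in range(len(elist)):
            for y in range(x + 1, len(elist)):
                e1, e2 = elist[x], elist[y]
                pairs.add((e1, e2) if e1 < e2 else (e2, e1))
    pairs = sorted(pairs)
    n = len(pairs)
    rows = np.repeat(np.arange(n), 2)
    cols = np.array([e for pair in pairs for e in pair])
    vals = np.tile([1.0, -1.0], n)
    inc = sp.csr_matrix((vals, (rows, cols)), shape=(n, graph.n_edges))
    graph._incidence = inc
    return inc
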