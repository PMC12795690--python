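"""Geometric graph builders for surface point clouds.

Three constructions are provided:

* :func:`build_schull` — the hyperparameter-free spherical convex hull graph:
  points are projected onto a unit sphere about their centroid, the 3-D convex
  hull of the projections is taken, and hull edges are mapped back to the
  original points.  The result is connected and sparse (at most 3N undirected
  edges) without any distance or neighbour-count parameter.
* :func:`build_radius_graph` — classic radial cutoff.
* :func:`build_knn_graph` — k nearest neighbours, symmetrized by union.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegenerateGeometryError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Angular tolerance (radians) below which two sphere projections coincide.
DEDUP_ANGLE_TOL = 1e-8


@dataclass
class GeometricGraph:
    """Node positions/features plus a mirrored directed edge list.

    ``edge_index`` has shape (2, E) with row 0 = source, row 1 = target; every
    undirected edge is stored in both directions.  ``edge_attr`` rows are
    (distance in Å, dihedral in radians) aligned with ``edge_index`` columns.
    """

    pos: np.ndarray                      # (N, 3)
    x: np.ndarray | None = None          # (N, F) node features
    edge_index: np.ndarray = None        # (2, E) int
    edge_attr: np.ndarray | None = None  # (E, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, float).reshape(-1, 3)
        self.edge_index = np.asarray(self.edge_index, int).reshape(2, -1)
        n = len(self.pos)
        if self.edge_index.size:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise ValidationError("edge indices out of range")

    @property
    def num_nodes(self) -> int:
        return len(self.pos)

    @property
    def num_undirected_edges(self) -> int:
        return self.edge_index.shape[1] // 2

    def undirected_edge_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.edge_index.T if i != j}

    def is_connected(self) -> bool:
        n = self.num_nodes
        if n <= 1:
            return True
        if self.edge_index.size == 0:
            return False
        data = np.ones(self.edge_index.shape[1])
        adj = csr_matrix((data, (self.edge_index[0], self.edge_index[1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1

    # -- serialization ------------------------------------------------------
    def to_npz(self, path) -> None:
        payload = {"pos": self.pos, "edge_index": self.edge_index}
        if self.x is not None:
            payload["x"] = self.x
        if self.edge_attr is not None:
            payload["edge_attr"] = self.edge_attr
        np.savez(path, **payload)

    @classmethod
    def from_npz(cls, path) -> "GeometricGraph":
        d = np.load(path)
        return cls(d["pos"], d.get("x"), d["edge_index"], d.get("edge_attr"))

    def edges_to_table(self, path) -> None:
        np.savetxt(path, self.edge_index.T, fmt="%d", delimiter="\t")


def _mirror(undirected: np.ndarray) -> np.ndarray:
    """(E, 2) unique undirected pairs -> (2, 2E) mirrored edge index."""
    if len(undirected) == 0:
        return np.zeros((2, 0), dtype=int)
    fwd = undirected.T
    bwd = undirected[:, ::-1].T
    return np.concatenate([fwd, bwd], axis=1)


# ---------------------------------------------------------------------------
# Spherical convex hull construction
# ---------------------------------------------------------------------------

def build_schull(points: np.ndarray, node_features: np.ndarray | None = None,
                 jitter_retry: bool = False, jitter_seed: int = 0,
                 with_edge_attr: bool = True) -> GeometricGraph:
    """Spherical-convex-hull graph of a point cloud.

    Points are projected onto the unit sphere centred at the cloud centroid;
    near-coincident projections (angular distance < 1e-8 rad) are deduplicated
    keeping the point farthest from the centroid; edges of the 3-D convex hull
    of the projections are mapped back to the original indices.

    For fewer than 4 points the complete graph is returned with a warning.  A
    degenerate (coplanar-through-centroid) configuration raises
    :class:`DegenerateGeometryError` unless ``jitter_retry`` is set, in which
    case a seeded 1e-6 Å jitter is applied and the construction retried once.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    n = len(points)
    if n < 4:
        warnings.warn("SCHull needs >= 4 points; returning the complete graph")
        und = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], int)
        g = GeometricGraph(points, node_features, _mirror(und.reshape(-1, 2)))
        if with_edge_attr:
            g.edge_attr = _fallback_edge_attr(g)
        return g

    centroid = points.mean(axis=0)
    rel = points - centroid
    norms = np.linalg.norm(rel, axis=1)
    if np.max(norms) < 1e-12:
        raise DegenerateGeometryError("all points coincide with the centroid")
    proj_ok = norms > 1e-12
    z = np.zeros_like(rel)
    z[proj_ok] = rel[proj_ok] / norms[proj_ok, None]

    # deduplicate coincident projections, keeping the farthest-from-centroid
    kept = _dedup_directions(z, norms, proj_ok)
    if len(kept) < 4:
        raise DegenerateGeometryError(
            "fewer than 4 distinct projection directions")
    try:
        hull = ConvexHull(z[kept])
    except QhullError as exc:
        if jitter_retry:
            rng = np.random.default_rng(jitter_seed)
            return build_schull(points + rng.normal(scale=1e-6, size=points.shape),
                                node_features, jitter_retry=False,
                                with_edge_attr=with_edge_attr)
        raise DegenerateGeometryError(
            f"degenerate projection geometry (coplanar?): {exc}") from exc

    simplices = kept[hull.simplices]                 # faces in original indices
    pairs = np.concatenate([simplices[:, [0, 1]], simplices[:, [1, 2]],
                            simplices[:, [0, 2]]])
    pairs.sort(axis=1)
    und = np.unique(pairs, axis=0)
    graph = GeometricGraph(points, node_features, _mirror(und),
                           meta={"hull_faces": simplices,
                                 "hull_normals": _outward_face_normals(hull),
                                 "kept": kept})
    if with_edge_attr:
        graph.edge_attr = edge_features(graph, points)
    return graph


def _dedup_directions(z: np.ndarray, norms: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Indices of unique projection directions, keeping the farthest point."""
    idx = np.flatnonzero(ok)
    tree = cKDTree(z[idx])
    pairs = tree.query_pairs(DEDUP_ANGLE_TOL, output_type="ndarray")
    if len(pairs) == 0:
        return idx
    # union-find over coincident groups
    parent = np.arange(len(idx))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for a in range(len(idx)):
        groups.setdefault(find(a), []).append(a)
    kept = []
    for members in groups.values():
        orig = idx[members]
        best = orig[np.lexsort((orig, -norms[orig]))[0]]
        kept.append(best)
    return np.sort(np.array(kept, int))


def _outward_face_normals(hull: ConvexHull) -> np.ndarray:
    """Outward unit normals of hull faces (Qhull stores them in `equations`)."""
    nrm = hull.equations[:, :3]
    return nrm / np.linalg.norm(nrm, axis=1, keepdims=True)


def _fallback_edge_attr(graph: GeometricGraph) -> np.ndarray:
    d = np.linalg.norm(graph.pos[graph.edge_index[0]] - graph.pos[graph.edge_index[1]],
                       axis=1)
    return np.stack([d, np.full_like(d, np.pi)], axis=1)


def edge_features(graph: GeometricGraph, points: np.ndarray | None = None) -> np.ndarray:
    """Distance and dihedral attributes for a spherical-convex-hull graph.

    The dihedral of an edge is the interior angle between the two hull faces
    sharing the projected edge, in [0, pi].  Edges incident to fewer than two
    faces (degenerate hulls) receive pi, with a logged count.
    """
    points = graph.pos if points is None else np.asarray(points, float)
    if "hull_faces" not in graph.meta:
        rebuilt = build_schull(points, with_edge_attr=False)
        graph = GeometricGraph(points, None, graph.edge_index, meta=rebuilt.meta)
    faces = graph.meta["hull_faces"]
    normals = graph.meta["hull_normals"]

    face_of_edge: dict[tuple[int, int], list[int]] = {}
    for f, (a, b, c) in enumerate(faces):
        for i, j in ((a, b), (b, c), (a, c)):
            face_of_edge.setdefault((min(i, j), max(i, j)), []).append(f)

    src, dst = graph.edge_index
    dist = np.linalg.norm(points[src] - points[dst], axis=1)
    dihed = np.empty(len(dist))
    missing = 0
    for e, (i, j) in enumerate(zip(src, dst)):
        fs = face_of_edge.get((min(i, j), max(i, j)), [])
        if len(fs) >= 2:
            cosang = float(np.clip(normals[fs[0]] @ normals[fs[1]], -1.0, 1.0))
            dihed[e] = np.pi - np.arccos(cosang)
        else:
            dihed[e] = np.pi
            missing += 1
    if missing:
        logger.info("edge_features: %d edges lacked two incident faces", missing)
    return np.stack([dist, dihed], axis=1)


# ---------------------------------------------------------------------------
# Baseline builders
# ---------------------------------------------------------------------------

def build_radius_graph(points: np.ndarray, r: float,
                       node_features: np.ndarray | None = None) -> GeometricGraph:
    """Edges between every pair of points with 0 < distance <= r."""
    if r <= 0:
        raise ParameterError("radius must be positive")
    points = np.asarray(points, float).reshape(-1, 3)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0]
    und = np.unique(np.sort(pairs, axis=1), axis=0) if len(pairs) else np.zeros((0, 2), int)
    g = GeometricGraph(points, node_features, _mirror(und))
    iso = len(points) - len(np.unique(g.edge_index)) if g.edge_index.size else len(points)
    if iso:
        logger.info("build_radius_graph: %d isolated nodes at r=%.3g", iso, r)
    if g.edge_index.size:
        d = np.linalg.norm(points[g.edge_index[0]] - points[g.edge_index[1]], axis=1)
        g.edge_attr = np.stack([d, np.zeros_like(d)], axis=1)
    return g


def knn_neighbors(points: np.ndarray, k: int) -> np.ndarray:
    """(N, k) nearest-neighbour indices, ties broken by lower index."""
    points = np.asarray(points, float).reshape(-1, 3)
    n = len(points)
    if not 1 <= k < n:
        raise ParameterError(f"k must satisfy 1 <= k < N (got k={k}, N={n})")
    out = np.empty((n, k), dtype=int)
    block = max(1, int(2e7 // max(n, 1)))
    idx_all = np.arange(n)
    for lo in range(0, n, block):
        pts = points[lo:lo + block]
        d = np.linalg.norm(pts[:, None, :] - points[None, :, :], axis=2)
        d[np.arange(len(pts)), lo + np.arange(len(pts))] = np.inf  # exclude self
        order = np.lexsort((np.broadcast_to(idx_all, d.shape), d), axis=1)
        out[lo:lo + block] = order[:, :k]
    return out


def build_knn_graph(points: np.ndarray, k: int,
                    node_features: np.ndarray | None = None) -> GeometricGraph:
    """Directed k-NN edges symmetrized by union into an undirected graph."""
    nbrs = knn_neighbors(points, k)
    n = len(nbrs)
    src = np.repeat(np.arange(n), k)
    pairs = np.stack([src, nbrs.ravel()], axis=1)
    pairs.sort(axis=1)
    und = np.unique(pairs, axis=0)
    points = np.asarray(points, float).reshape(-1, 3)
    g = GeometricGraph(points, node_features, _mirror(und))
    d = np.linalg.norm(points[g.edge_index[0]] - points[g.edge_index[1]], axis=1)
    g.edge_attr = np.stack([d, np.zeros_like(d)], axis=1)
    return g


GRAPH_BUILDERS = {
    "schull": lambda pts, x=None, **kw: build_schull(pts, x),
    "radius": lambda pts, x=None, r=3.0, **kw: build_radius_graph(pts, r, x),
    "knn": lambda pts, x=None, k=8, **kw: build_knn_graph(pts, k, x),
}


def build_graph(points: np.ndarray, method: str = "schull",
                node_features: np.ndarray | None = None, **kwargs) -> GeometricGraph:
    """Dispatch to a named graph builder (schull | radius | knn)."""
    if method not in GRAPH_BUILDERS:
        raise ParameterError(f"unknown graph method {method!r}")
    return GRAPH_BUILDERS[method](points, node_features, **kwargs)
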