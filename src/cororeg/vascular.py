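"""Core domain types for vessel centerlines and trees.

Coordinates are millimetres throughout: 3D points live in patient space,
2D points on the detector plane (the detector centre is the origin; pixel
coordinates are converted at I/O boundaries via the imager pixel spacing).
Centerlines are piecewise-linear ordered point sequences; trees are graphs
whose edges carry one centerline each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "Centerline",
    "VesselTree",
    "MarkerPairs",
    "resample_centerline",
    "centerline_length",
    "mean_spacing",
    "tangent_slope",
    "tangent_direction",
]


@dataclass
class Centerline:
    """Ordered polyline with optional per-point radius (3D) or thickness (2D).

    Parameters
    ----------
    points : (N, d) array, d in {2, 3}, millimetres.
    radius : (N,) array or None. For 3D vessels this is the lumen radius;
        for 2D centerlines it holds the local half-thickness when known.
    """

    points: np.ndarray
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError("points must be (N, 2) or (N, 3)")
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive points must be distinct")
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
            if len(self.radius) != len(self.points):
                raise ValueError("radius length must equal point count")
            if np.any(self.radius <= 0):
                raise ValueError("radius must be positive")

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return len(self.points)

    def reversed(self) -> "Centerline":
        r = None if self.radius is None else self.radius[::-1].copy()
        return Centerline(self.points[::-1].copy(), r)


# Backwards-friendly aliases used throughout the code base.
Centerline3D = Centerline
Centerline2D = Centerline


def centerline_length(c: Centerline | np.ndarray) -> float:
    """Polyline arc length: sum of Euclidean distances between consecutive points."""
    pts = c.points if isinstance(c, Centerline) else np.asarray(c, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def mean_spacing(c: Centerline | np.ndarray) -> float:
    """Average distance between adjacent centerline points (the snake d-bar)."""
    pts = c.points if isinstance(c, Centerline) else np.asarray(c, dtype=float)
    return centerline_length(pts) / (len(pts) - 1)


def resample_centerline(c: Centerline, spacing: float) -> Centerline:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Points are placed at arc lengths 0, s, 2s, ..., L on the piecewise-linear
    curve; both endpoints are preserved exactly.  Radii are linearly
    interpolated in arc length.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = c.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        raise ValueError("degenerate zero-length centerline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_int = max(1, int(round(total / spacing)))
    s = np.linspace(0.0, total, n_int + 1)
    new_pts = np.empty((len(s), pts.shape[1]))
    for d in range(pts.shape[1]):
        new_pts[:, d] = np.interp(s, cum, pts[:, d])
    new_pts[0] = pts[0]
    new_pts[-1] = pts[-1]
    new_r = None
    if c.radius is not None:
        new_r = np.interp(s, cum, c.radius)
    # interpolation can regenerate duplicate points on exactly repeated knots
    keep = np.concatenate([[True], np.linalg.norm(np.diff(new_pts, axis=0), axis=1) > 0])
    return Centerline(new_pts[keep], None if new_r is None else new_r[keep])


def tangent_direction(c: Centerline | np.ndarray, i: int, window: int = 3) -> np.ndarray:
    """Unit tangent at point ``i`` from a symmetric least-squares line fit.

    The fit uses points ``i-window .. i+window`` (clamped at the curve ends).
    Returned as a unit direction vector, so vertical tangents are exact.  The
    sign follows the curve orientation (positive projection onto the chord).
    """
    pts = c.points if isinstance(c, Centerline) else np.asarray(c, dtype=float)
    n = len(pts)
    if not 0 <= i < n:
        raise IndexError("point index out of range")
    lo, hi = max(0, i - window), min(n, i + window + 1)
    w = pts[lo:hi]
    centered = w - w.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("all window points identical; tangent undefined")
    # principal axis of the window = total-least-squares line direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    chord = w[-1] - w[0]
    if np.dot(d, chord) < 0:
        d = -d
    return d / np.linalg.norm(d)


def tangent_slope(c: Centerline | np.ndarray, i: int, window: int = 3) -> float:
    """Slope dy/dx of the local tangent (2D curves).

    Vertical tangents return +/-inf; use :func:`tangent_direction` where a
    finite representation is required.
    """
    d = tangent_direction(c, i, window)
    if d.shape[0] != 2:
        raise ValueError("tangent_slope is defined for 2D centerlines")
    if d[0] == 0:
        return float(np.inf) if d[1] >= 0 else float(-np.inf)
    return float(d[1] / d[0])


class VesselTree:
    """Vessel graph T = (V, E, r): vertices with positions, edges carrying centerlines.

    3D trees are rooted, connected and acyclic.  2D structures may be a
    disconnected "segment soup" (smallest-unit segments), so connectivity is
    not enforced for them.  Each edge's endpoint vertex positions must agree
    with its centerline's first/last points to within 1e-6 mm.
    """

    _TOL = 1e-6

    def __init__(self, dim: int = 3, root: int | None = None):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.graph = nx.Graph()
        self.dim = dim
        self.root = root

    # -- construction -------------------------------------------------
    def add_vertex(self, vid: int, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.dim,):
            raise ValueError(f"vertex position must be {self.dim}-dimensional")
        self.graph.add_node(vid, pos=pos)

    def add_edge(self, u: int, v: int, centerline: Centerline, **attrs) -> None:
        if centerline.dim != self.dim:
            raise ValueError("centerline dimensionality mismatch")
        for vid, endpoint in ((u, centerline.points[0]), (v, centerline.points[-1])):
            if vid not in self.graph:
                raise KeyError(f"vertex {vid} not in tree")
            if np.linalg.norm(self.graph.nodes[vid]["pos"] - endpoint) > self._TOL:
                raise ValueError(
                    f"edge endpoint does not coincide with vertex {vid} position"
                )
        self.graph.add_edge(u, v, centerline=centerline, **attrs)

    # -- accessors ----------------------------------------------------
    def vertex_pos(self, vid: int) -> np.ndarray:
        return self.graph.nodes[vid]["pos"]

    def edge_centerline(self, u: int, v: int) -> Centerline:
        return self.graph.edges[u, v]["centerline"]

    def edges(self) -> Iterator[tuple[int, int]]:
        return iter(self.graph.edges())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def all_points(self) -> np.ndarray:
        """Concatenated edge centerline points, (sum N_e, dim)."""
        if self.n_edges == 0:
            return np.empty((0, self.dim))
        return np.vstack([d["centerline"].points for _, _, d in self.graph.edges(data=True)])

    def validate_tree(self) -> None:
        """Assert 3D-tree invariants: connected, acyclic, rooted."""
        if self.root is None or self.root not in self.graph:
            raise ValueError("tree has no valid root")
        if not nx.is_connected(self.graph):
            raise ValueError("3D vessel tree must be connected")
        if self.graph.number_of_edges() != self.graph.number_of_nodes() - 1:
            raise ValueError("3D vessel tree must be acyclic")

    def edges_leaf_to_root(self) -> list[tuple[int, int]]:
        """Edges ordered from deepest (leaf side) to shallowest, each as (parent, child)."""
        self.validate_tree()
        depth = nx.shortest_path_length(self.graph, self.root)
        directed = []
        for u, v in self.graph.edges():
            parent, child = (u, v) if depth[u] < depth[v] else (v, u)
            directed.append((parent, child))
        return sorted(directed, key=lambda e: -depth[e[1]])

    def parent_edge_of(self, parent: int, child: int) -> tuple[int, int] | None:
        """The edge one level up from (parent, child), or None at the root."""
        depth = nx.shortest_path_length(self.graph, self.root)
        for nb in self.graph.neighbors(parent):
            if depth[nb] < depth[parent]:
                return (nb, parent)
        return None

    def copy(self) -> "VesselTree":
        t = VesselTree(self.dim, self.root)
        for vid, data in self.graph.nodes(data=True):
            t.add_vertex(vid, data["pos"].copy())
        for u, v, data in self.graph.edges(data=True):
            c = data["centerline"]
            attrs = {k: val for k, val in data.items() if k != "centerline"}
            t.add_edge(u, v, Centerline(c.points.copy(),
                                        None if c.radius is None else c.radius.copy()),
                       **attrs)
        return t


@dataclass
class MarkerPairs:
    """Paired evaluation landmarks (p_i, q_i) on two vessels, used for ADD."""

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.p.shape != self.q.shape:
            raise ValueError("marker sets must have equal shapes")
        if len(self.p) < 1:
            raise ValueError("need at least one marker pair")

    @property
    def m(self) -> int:
        return len(self.p)
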