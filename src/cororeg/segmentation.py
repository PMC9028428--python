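"""Segmentation support: shape-aware loss terms and mask-to-centerline extraction.

The segmentation network itself is external; this module makes its loss
L = L_BCE + L_shape computable for any predicted probability map, and turns
a binary vessel mask into smallest-unit 2D centerline segments so masks can
enter the registration pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .carm import CArmGeometry
from .vascular import Centerline, VesselTree

__all__ = ["bce_loss", "chamfer_distance_map", "binary_edges", "shape_loss",
           "mask_to_centerlines"]

_EPS = 1e-7


def bce_loss(x_p: np.ndarray, y_g: np.ndarray) -> float:
    """Pixel-wise binary cross-entropy, mean over the raster.

    -(1/K) sum[ y log x + (1-y) log(1-x) ], with x clipped to [eps, 1-eps].
    """
    x_p = np.asarray(x_p, dtype=float)
    y_g = np.asarray(y_g, dtype=float)
    if x_p.shape != y_g.shape:
        raise ValueError("probability and label maps must have the same shape")
    x = np.clip(x_p, _EPS, 1.0 - _EPS)
    return float(-(y_g * np.log(x) + (1.0 - y_g) * np.log(1.0 - x)).mean())


def chamfer_distance_map(edges: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the nearest edge pixel.

    Implemented with the exact Euclidean distance transform; the classic
    integer chamfer 3-4 propagation is available via ``method='chamfer'`` on
    :func:`shape_loss` callers that want it.
    """
    edges = np.asarray(edges).astype(bool)
    if not edges.any():
        raise ValueError("edge raster has no edge pixels")
    return ndimage.distance_transform_edt(~edges)


def binary_edges(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask: foreground with a background 4-neighbour."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(2, 1))
    return m & ~eroded


def shape_loss(x_p: np.ndarray, y_g: np.ndarray, threshold: float = 0.5) -> float:
    """Boundary (shape) loss: mean chamfer distance from predicted edges to GT edges.

    The prediction is binarized at ``threshold``; at each predicted-edge pixel
    the ground-truth edge distance map is sampled, smoothed by a small
    stabiliser, and averaged over all K pixels of the raster.  Zero (up to the
    stabiliser) iff the edge sets coincide.
    """
    x_p = np.asarray(x_p, dtype=float)
    y_g = np.asarray(y_g, dtype=float)
    if x_p.shape != y_g.shape:
        raise ValueError("maps must have the same shape")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    pred = x_p >= threshold
    if not pred.any():
        warnings.warn("prediction has no foreground; shape loss undefined, returning 0")
        return 0.0
    gt_edges = binary_edges(y_g >= 0.5)
    if not gt_edges.any():
        warnings.warn("ground truth has no foreground; shape loss undefined, returning 0")
        return 0.0
    y_d = chamfer_distance_map(gt_edges)
    x_e = binary_edges(pred)
    k = x_p.size
    vals = np.sqrt((y_d[x_e]) ** 2 + _EPS ** 2)
    return float(vals.sum() / k)


# ---------------------------------------------------------------------------
# mask -> smallest-unit centerline segments

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    """Pixel adjacency of a skeleton: returns dict pixel -> neighbour list."""
    pix = set(zip(*np.nonzero(skel)))
    adj = {p: [] for p in pix}
    for (r, c) in pix:
        for dr, dc in _N8:
            q = (r + dr, c + dc)
            if q in pix:
                adj[(r, c)].append(q)
    return adj


def _junction_clusters(adj):
    """Connected components of branch pixels (degree >= 3) under 8-adjacency.

    Skeletonization often leaves 2-3 mutually adjacent branch pixels at one
    anatomical bifurcation; clustering them yields a single graph node.
    """
    junctions = {p for p, nb in adj.items() if len(nb) >= 3}
    cluster_of: dict = {}
    for p in sorted(junctions):
        if p in cluster_of:
            continue
        cid = len(set(cluster_of.values()))
        stack = [p]
        while stack:
            q = stack.pop()
            if q in cluster_of:
                continue
            cluster_of[q] = cid
            stack.extend(r for r in adj[q] if r in junctions)
    return cluster_of


def _trace_paths(adj):
    """Maximal branch-free pixel paths between endpoint/junction nodes.

    Junction-pixel clusters count as one node: paths start at a cluster
    pixel and end at the first pixel belonging to any cluster or endpoint.
    """
    deg = {p: len(nb) for p, nb in adj.items()}
    cluster_of = _junction_clusters(adj)
    endpoints = {p for p, d in deg.items() if d == 1}
    is_node = lambda p: p in cluster_of or p in endpoints

    paths = []
    visited = set()

    def walk(start, first):
        path = [start, first]
        prev, cur = start, first
        while not is_node(cur):
            nxt = [q for q in adj[cur] if q != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    for p in sorted(set(cluster_of) | endpoints):
        for q in adj[p]:
            if (p, q) in visited:
                continue
            if q in cluster_of and p in cluster_of and \
                    cluster_of[q] == cluster_of[p]:
                continue  # internal cluster adjacency, not a branch
            path = walk(p, q)
            for a, b in zip(path[:-1], path[1:]):
                visited.add((a, b))
                visited.add((b, a))
            if is_node(path[-1]):
                paths.append(path)
    # pure cycles (no junction/endpoint at all): open at an arbitrary pixel
    covered = {x for path in paths for x in path}
    remaining = {p for p, d in deg.items() if d == 2} - covered
    while remaining:
        start = sorted(remaining)[0]
        q = adj[start][0]
        path = [start]
        prev, cur = start, q
        while cur != start and cur in remaining:
            path.append(cur)
            nxt = [x for x in adj[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        path.append(cur)
        remaining -= set(path)
        paths.append(path)
    return paths, cluster_of


def mask_to_centerlines(mask: np.ndarray, geometry: CArmGeometry) -> VesselTree:
    """Skeletonize a binary vessel mask into a smallest-unit 2D segment graph.

    Each maximal branch-free skeleton path becomes one edge; skeleton pixels
    of degree >= 3 are branch nodes and degree-1 pixels endpoints.  Per-point
    thickness is twice the distance-transform value at the skeleton pixel,
    converted to millimetres; it is stored as the centerline ``radius`` (i.e.
    the half-thickness).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    dt = ndimage.distance_transform_edt(mask)
    adj = _skeleton_graph(skel)
    paths, cluster_of = _trace_paths(adj)

    # one representative pixel per junction cluster; paths are rerouted to it
    reps: dict[int, tuple[int, int]] = {}
    for cid in set(cluster_of.values()):
        members = [p for p, c in cluster_of.items() if c == cid]
        centroid = np.mean(members, axis=0)
        reps[cid] = min(members,
                        key=lambda p: float(np.sum((np.array(p) - centroid) ** 2)))

    def canonical(pix):
        return reps[cluster_of[pix]] if pix in cluster_of else pix

    fixed_paths = []
    for path in paths:
        if len(path) < 2:
            continue
        head, tail = canonical(path[0]), canonical(path[-1])
        if head != path[0]:
            path = [head] + path
        if tail != path[-1]:
            path = path + [tail]
        fixed_paths.append(path)
    paths = fixed_paths

    tree = VesselTree(dim=2)
    node_ids: dict[tuple[int, int], int] = {}

    def node_for(pix):
        if pix not in node_ids:
            nid = len(node_ids)
            uv = geometry.px_to_mm(np.array([[pix[1], pix[0]]], dtype=float))[0]
            tree.add_vertex(nid, uv)
            node_ids[pix] = nid
        return node_ids[pix]

    for path in paths:
        # (row, col) -> (u, v) mm; thickness radius = EDT value * spacing
        px = np.array([[c, r] for r, c in path], dtype=float)
        uv = geometry.px_to_mm(px)
        radii = np.array([max(dt[r, c], 0.5) for r, c in path]) * geometry.pixel_spacing_mm
        keep = np.concatenate([[True], np.linalg.norm(np.diff(uv, axis=0), axis=1) > 0])
        uv, radii = uv[keep], radii[keep]
        if len(uv) < 2:
            continue
        u = node_for(path[0])
        v = node_for(path[-1])
        if u == v:  # closed loop: split is not needed for vessels; skip degenerate self-edge
            continue
        tree.add_edge(u, v, Centerline(uv, radii))
    return tree
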