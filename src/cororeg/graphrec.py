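"""2D topology reconstruction against the 3D tree.

The 2D centerlines extracted from an angiogram carry false bifurcations,
gaps and crossings, so they are first decomposed into "smallest-unit"
segments (maximal branch-free pieces).  For every 3D vessel segment the
candidate 2D segments within a distance threshold are collected, every
connectable chain of candidates ("candi-line") is enumerated exhaustively,
and chains whose 3D edge has a parent are pruned when they do not touch any
surviving parent chain — exploiting that the 3D tree is seamlessly
connected from root to leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .vascular import Centerline, VesselTree

__all__ = ["CandiLine", "CandidateSet", "build_2d_graph", "candidate_segments",
           "enumerate_candilines", "prune_by_parent_connectivity"]


EdgeId = tuple[int, int]


@dataclass
class CandiLine:
    """One connected chain of smallest-unit 2D segments for one 3D edge."""

    edge_ids: tuple[EdgeId, ...]
    points: np.ndarray          # concatenated, consistently oriented
    radius: np.ndarray | None = None
    source_edge3d: EdgeId | None = None

    def key(self) -> tuple[EdgeId, ...]:
        """Orientation-independent identity."""
        rev = tuple(reversed(self.edge_ids))
        return min(self.edge_ids, rev)

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class CandidateSet:
    """Per-3D-edge candidate 2D segments, sorted by ascending mean distance."""

    candidates: dict[EdgeId, list[tuple[EdgeId, float]]] = field(default_factory=dict)
    threshold: float = 3.0

    def edges_for(self, edge3d: EdgeId) -> list[EdgeId]:
        return [e for e, _ in self.candidates.get(edge3d, [])]


def _snap_key(p: np.ndarray, tol: float) -> tuple[int, ...]:
    return tuple(np.round(np.asarray(p) / tol).astype(int))


def build_2d_graph(centerlines: list[Centerline] | VesselTree,
                   snap_tol: float = 1e-3) -> VesselTree:
    """Assemble 2D polylines into a smallest-unit segment graph.

    Polyline endpoints closer than ``snap_tol`` mm are merged into one
    vertex; chains of exactly two segments meeting at a degree-2 vertex are
    merged so that every edge is a maximal branch-free path.  Disconnected
    components are allowed.
    """
    if isinstance(centerlines, VesselTree):
        polylines = [centerlines.edge_centerline(u, v) for u, v in centerlines.edges()]
    else:
        polylines = list(centerlines)
    if not polylines:
        raise ValueError("no 2D centerlines supplied")

    tree = VesselTree(dim=2)
    key_to_id: dict[tuple, int] = {}

    def node_for(p: np.ndarray) -> int:
        k = _snap_key(p, snap_tol)
        if k not in key_to_id:
            nid = len(key_to_id)
            tree.add_vertex(nid, p)
            key_to_id[k] = nid
        return key_to_id[k]

    raw: list[tuple[int, int, Centerline]] = []
    for c in polylines:
        u = node_for(c.points[0])
        v = node_for(c.points[-1])
        # snap centerline ends onto the (possibly pre-existing) vertex positions
        pts = c.points.copy()
        pts[0] = tree.vertex_pos(u)
        pts[-1] = tree.vertex_pos(v)
        raw.append((u, v, Centerline(pts, c.radius)))

    # merge degree-2 chains into maximal branch-free edges
    from collections import defaultdict
    incident = defaultdict(list)
    for idx, (u, v, _) in enumerate(raw):
        incident[u].append(idx)
        incident[v].append(idx)

    merged = []
    used = [False] * len(raw)
    for idx in range(len(raw)):
        if used[idx]:
            continue
        u, v, c = raw[idx]
        used[idx] = True
        chain_pts = [c.points]
        chain_rad = [c.radius]
        # extend forward from v, backward from u through degree-2 vertices
        for end, grow_forward in ((v, True), (u, False)):
            cur_end, cur_idx = end, idx
            while len(incident[cur_end]) == 2:
                nxt_idx = [i for i in incident[cur_end] if i != cur_idx]
                if not nxt_idx or used[nxt_idx[0]]:
                    break
                ni = nxt_idx[0]
                nu, nv, nc = raw[ni]
                used[ni] = True
                pts, rad = nc.points, nc.radius
                if (nu == cur_end) != grow_forward:
                    # orient the new piece to continue the chain
                    pts = pts[::-1]
                    rad = None if rad is None else rad[::-1]
                if grow_forward:
                    chain_pts.append(pts[1:])
                    chain_rad.append(None if rad is None else rad[1:])
                    cur_end = nv if nu == cur_end else nu
                else:
                    chain_pts.insert(0, pts[:-1])
                    chain_rad.insert(0, None if rad is None else rad[:-1])
                    cur_end = nv if nu == cur_end else nu
                cur_idx = ni
                if cur_end in (u, v):  # closed loop guard
                    break
            if grow_forward:
                v = cur_end
            else:
                u = cur_end
        pts = np.vstack(chain_pts)
        rad = None if any(r is None for r in chain_rad) else np.concatenate(chain_rad)
        merged.append((u, v, pts, rad))

    out = VesselTree(dim=2)
    for u, v, pts, rad in merged:
        keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0])
        pts = pts[keep]
        rad = None if rad is None else rad[keep]
        if len(pts) < 2 or u == v:
            continue
        for nid in (u, v):
            if nid not in out.graph:
                out.add_vertex(nid, tree.vertex_pos(nid))
        out.add_edge(u, v, Centerline(pts, rad))
    return out


def candidate_segments(projected3d: dict[EdgeId, np.ndarray], graph2d: VesselTree,
                       d_cand: float = 3.0) -> CandidateSet:
    """Candidate 2D segments per projected 3D edge.

    A 2D edge is a candidate for a 3D edge when the directed mean
    nearest-point distance from the 2D segment's points to the projected 3D
    polyline is below ``d_cand``.  The 2D->3D direction matters: a short
    true piece of a long 3D segment must remain a candidate, while the
    reverse mean would dilute it.  Candidates are sorted by ascending
    distance.
    """
    cs = CandidateSet(threshold=d_cand)
    trees3 = {e: cKDTree(pts) for e, pts in projected3d.items()}
    for e3, kd in trees3.items():
        found = []
        for u, v in graph2d.edges():
            pts2 = graph2d.edge_centerline(u, v).points
            d, _ = kd.query(pts2)
            mean_d = float(d.mean())
            if mean_d < d_cand:
                found.append(((u, v), mean_d))
        found.sort(key=lambda t: (t[1], t[0]))
        cs.candidates[e3] = found
    return cs


def _oriented_chain(graph2d: VesselTree,
                    edge_seq: list[EdgeId]) -> tuple[np.ndarray, np.ndarray | None]:
    """Concatenate chain centerlines, orienting each segment by continuity.

    Junction vertices may be distinct graph nodes merged under the
    connection tolerance, so orientation is resolved geometrically: each
    segment is flipped to start nearest the current chain end (the first by
    whichever end is farther from the second segment).
    """
    curves = []
    for (u, v) in edge_seq:
        c = graph2d.edge_centerline(u, v)
        curves.append((c.points, c.radius))
    if len(curves) == 1:
        return curves[0]
    # orient the first segment so its exit end is nearest the second segment
    p0, r0 = curves[0]
    nxt = curves[1][0]
    d_keep = min(np.linalg.norm(p0[-1] - nxt[0]), np.linalg.norm(p0[-1] - nxt[-1]))
    d_flip = min(np.linalg.norm(p0[0] - nxt[0]), np.linalg.norm(p0[0] - nxt[-1]))
    if d_flip < d_keep:
        p0, r0 = p0[::-1], None if r0 is None else r0[::-1]
    pts_parts, rad_parts = [p0], [r0]
    end = p0[-1]
    for pts, rad in curves[1:]:
        if np.linalg.norm(pts[-1] - end) < np.linalg.norm(pts[0] - end):
            pts, rad = pts[::-1], None if rad is None else rad[::-1]
        pts_parts.append(pts)
        rad_parts.append(rad)
        end = pts[-1]
    pts = np.vstack(pts_parts)
    rad = None if any(r is None for r in rad_parts) else np.concatenate(rad_parts)
    return pts, rad


def enumerate_candilines(cands: CandidateSet, graph2d: VesselTree,
                         max_paths: int = 10000,
                         connect_tol: float = 2.0) -> dict[EdgeId, list[CandiLine]]:
    """Every simple connected chain of candidate segments, per 3D edge.

    Chains are simple paths in the candidate subgraph (no repeated edge, no
    repeated interior vertex); two candidate edges are connectable when they
    share a graph vertex or their endpoint vertices lie within
    ``connect_tol`` mm.  Output order is deterministic (lexicographic by the
    chain's canonical edge-id tuple).
    """
    result: dict[EdgeId, list[CandiLine]] = {}
    for e3, listed in cands.candidates.items():
        edges = [e for e, _ in listed]
        edge_set = set(edges)
        # vertex equivalence under connect_tol: union nearby endpoint vertices
        nodes = sorted({n for e in edges for n in e})
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(nodes):
            pa = graph2d.vertex_pos(a)
            for b in nodes[i + 1:]:
                if np.linalg.norm(pa - graph2d.vertex_pos(b)) <= connect_tol:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb

        from collections import defaultdict
        incident = defaultdict(list)   # merged node -> list of (edge, other merged node)
        for (u, v) in edges:
            mu, mv = find(u), find(v)
            incident[mu].append(((u, v), mv))
            incident[mv].append(((u, v), mu))

        seen: set[tuple[EdgeId, ...]] = set()
        chains: list[tuple[tuple[EdgeId, ...], list[int]]] = []

        def dfs(cur_node, edge_seq, node_seq, used_edges, used_nodes):
            key = min(tuple(edge_seq), tuple(reversed(edge_seq)))
            if key not in seen:
                seen.add(key)
                chains.append((tuple(edge_seq), list(node_seq)))
                if len(chains) > max_paths:
                    raise RuntimeError(
                        f"candi-line enumeration exceeded max_paths={max_paths}; "
                        "tighten the candidate distance threshold")
            for e, nxt in sorted(incident[cur_node]):
                # nxt == cur_node: a segment shorter than the merge tolerance
                # (self-loop after vertex merging) — traversable, stays put
                if e in used_edges or (nxt in used_nodes and nxt != cur_node):
                    continue
                dfs(nxt, edge_seq + [e], node_seq + [nxt],
                    used_edges | {e}, used_nodes | {nxt})

        for (u, v) in sorted(edge_set):
            mu, mv = find(u), find(v)
            # a chain may extend from either end of its first edge
            dfs(mv, [(u, v)], [mu, mv], {(u, v)}, {mu, mv})
            if mu != mv:
                dfs(mu, [(u, v)], [mv, mu], {(u, v)}, {mu, mv})

        lines = []
        for edge_seq, _node_seq in sorted(chains):
            pts, rad = _oriented_chain(graph2d, list(edge_seq))
            lines.append(CandiLine(tuple(edge_seq), pts, rad, source_edge3d=e3))
        result[e3] = lines
    return result


def prune_by_parent_connectivity(candilines: dict[EdgeId, list[CandiLine]],
                                 tree3d: VesselTree,
                                 connect_tol: float = 2.0,
                                 max_iter: int = 10) -> dict[EdgeId, list[CandiLine]]:
    """Remove candi-lines of child 3D edges not touching any parent candi-line.

    The 3D tree is traversed leaf to root; a non-root edge's candi-line
    survives only if one of its endpoints lies within ``connect_tol`` mm of
    some point of a surviving candi-line of its parent edge.  Root-edge
    candi-lines always survive.  Passes repeat until a fixed point so the
    result is idempotent.
    """
    surviving = {e: list(v) for e, v in candilines.items()}
    order = tree3d.edges_leaf_to_root()

    def norm(e: EdgeId) -> EdgeId:
        return e if e in surviving else (e[1], e[0])

    for _ in range(max_iter):
        changed = False
        for parent, child in order:
            e = norm((parent, child))
            pe = tree3d.parent_edge_of(parent, child)
            if pe is None:
                continue
            pe = norm(pe)
            parent_lines = surviving.get(pe, [])
            if not parent_lines:
                # no parent hypothesis at all: keep the child's lines (cannot test)
                continue
            kd = cKDTree(np.vstack([cl.points for cl in parent_lines]))
            kept = []
            for cl in surviving.get(e, []):
                a, b = cl.endpoints()
                d = min(kd.query(a)[0], kd.query(b)[0])
                if d <= connect_tol:
                    kept.append(cl)
            if len(kept) != len(surviving.get(e, [])):
                surviving[e] = kept
                changed = True
        if not changed:
            break
    return surviving
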