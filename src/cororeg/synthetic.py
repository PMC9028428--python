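"""Seeded synthetic coronary-tree simulator.

Generates branching 3D vessel trees with smooth curvature and tapering
radii, applies a known rigid offset and a known smooth nonrigid
displacement, projects the result through a C-arm geometry onto a 512x512
detector, and corrupts the projected centerlines with gaps and false
branches standing in for segmentation error.  Every 2D point keeps its
ground-truth label (true/false, source 3D edge), so stage-wise evaluation
is noise-free.  All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .carm import CArmGeometry, project, project_depth
from .rigid import RigidBounds, RigidParams, rigid_transform
from .vascular import Centerline, VesselTree, centerline_length, resample_centerline

__all__ = ["SimConfig", "SimulationCase", "generate_tree", "apply_deformation",
           "project_tree", "rasterize_and_corrupt", "make_case"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated case.

    Defaults emulate a left-coronary-like tree viewed on a 512x512 detector
    with 0.279 mm pixels (midpoint of the clinical 0.258-0.293 mm range) at
    SID 1000 mm / SOD 750 mm.  Corruption rates are per 3D branch.
    """

    n_branches: int = 7
    branch_length_mm: tuple[float, float] = (20.0, 35.0)
    radius_root_mm: float = 1.75
    taper: float = 0.8
    point_spacing_mm: float = 1.0
    curve_amp_frac: float = 0.12          # smooth in-branch curvature amplitude / length
    branching_angle_deg: tuple[float, float] = (25.0, 50.0)
    # acquisition
    pixel_spacing_mm: float = 0.279
    image_size_px: tuple[int, int] = (512, 512)
    sid_mm: float = 1000.0
    sod_mm: float = 750.0
    primary_range_deg: tuple[float, float] = (-40.0, 40.0)
    secondary_range_deg: tuple[float, float] = (-25.0, 25.0)
    # ground-truth deformation
    rigid_frac: float = 0.8               # offsets uniform in rigid_frac * bounds
    bounds: RigidBounds = field(default_factory=RigidBounds)
    field_amp_mm: float = 2.0
    field_modes: int = 3
    field_wavelength_mm: float = 120.0
    # 2D corruption
    gap_rate: float = 0.3                 # expected gaps per branch
    gap_width_mm: float = 1.5
    false_branch_rate: float = 0.3        # expected false branches per branch
    false_branch_length_mm: tuple[float, float] = (4.0, 10.0)
    crossing: bool = False
    n_markers: int = 10


@dataclass
class SimulationCase:
    tree3d: VesselTree                    # the pre-operative model
    true_rigid: RigidParams
    displacement: dict                    # edge id -> (N, 3) true nonrigid vectors
    deformed3d: VesselTree                # model after rigid + field (the true anatomy)
    geometry: CArmGeometry
    tree2d_clean: VesselTree              # uncorrupted projection of the anatomy
    tree2d: VesselTree                    # corrupted smallest-unit 2D segments
    mask2d: np.ndarray                    # binary 512x512 raster of the corrupted 2D set
    correspondences: dict                 # edge id -> (N, 2) projected true points
    markers: list                         # [(edge, index, true 3D point), ...]
    seed: int
    config: SimConfig

    def true_points(self, edge) -> np.ndarray:
        e = edge if edge in self.displacement else (edge[1], edge[0])
        u, v = e
        return self.deformed3d.edge_centerline(u, v).points

    def label_graph_edges(self, graph2d: VesselTree) -> dict:
        """Map smallest-unit graph edges to their corruption ground truth.

        Returns {graph2d edge id: (is_true, source 3D edge id or None)} by
        matching each graph edge's endpoints and point count against the
        labelled corrupted segments.
        """
        index = {}
        for (u, v) in self.tree2d.edges():
            c = self.tree2d.edge_centerline(u, v)
            data = self.tree2d.graph.edges[u, v]
            key = (len(c), tuple(np.round(c.points[0], 6)), tuple(np.round(c.points[-1], 6)))
            rkey = (len(c), key[2], key[1])
            index[key] = index[rkey] = (bool(data["true"]), data["source"])
        labels = {}
        for (u, v) in graph2d.edges():
            c = graph2d.edge_centerline(u, v)
            key = (len(c), tuple(np.round(c.points[0], 6)), tuple(np.round(c.points[-1], 6)))
            labels[(u, v)] = index.get(key, (False, None))
        return labels

    def true_chains(self, graph2d: VesselTree, connect_tol: float) -> dict:
        """Maximal connected chain of true same-source segments per 3D edge.

        A gap wider than ``connect_tol`` necessarily breaks the true chain,
        so the best achievable reconstruction for a 3D edge is the largest
        (by arc length) connected set of its surviving true segments.
        Returns {3D edge id: frozenset of graph2d edge ids}.
        """
        labels = self.label_graph_edges(graph2d)
        chains = {}
        for e3 in sorted(self.displacement):
            own = [e for e, (ok, src) in labels.items()
                   if ok and src is not None and (src == e3 or src == (e3[1], e3[0]))]
            if not own:
                chains[e3] = frozenset()
                continue
            # connect segments sharing a vertex or with endpoints within tol
            comp = {e: {e} for e in own}

            def endpoints(e):
                c = graph2d.edge_centerline(*e)
                return c.points[0], c.points[-1]

            for i, a in enumerate(own):
                for b in own[i + 1:]:
                    if set(a) & set(b):
                        near = True
                    else:
                        near = any(np.linalg.norm(p - q) <= connect_tol
                                   for p in endpoints(a) for q in endpoints(b))
                    if near:
                        merged = comp[a] | comp[b]
                        for e in merged:
                            comp[e] = merged
            best = max({frozenset(s) for s in comp.values()},
                       key=lambda s: (sum(centerline_length(graph2d.edge_centerline(*e))
                                          for e in s), sorted(s)))
            chains[e3] = best
        return chains


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(d: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, a))
    e2 = np.cross(d, e1)
    return e1, e2


def _branch_curve(start: np.ndarray, direction: np.ndarray, length: float,
                  spacing: float, amp_frac: float, rng) -> np.ndarray:
    """A smooth 3D curve: straight run plus low-order sinusoidal bending."""
    n = max(3, int(round(length / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    e1, e2 = _perp_basis(direction, rng)
    amp = amp_frac * length
    a1, a2 = rng.uniform(-amp, amp, 2)
    f1, f2 = rng.uniform(0.5, 1.5, 2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    # sin offsets vanish at t=0 so the branch leaves its start point exactly
    w1 = np.sin(np.pi * f1 * t + ph1) - np.sin(ph1)
    w2 = np.sin(np.pi * f2 * t + ph2) - np.sin(ph2)
    pts = (start[None, :] + np.outer(t * length, direction)
           + np.outer(a1 * w1 * t, e1) + np.outer(a2 * w2 * t, e2))
    return pts


def generate_tree(seed: int, n_branches: int = 7,
                  branch_length_mm: tuple[float, float] = (20.0, 35.0),
                  radius_root_mm: float = 1.75, taper: float = 0.8,
                  point_spacing_mm: float = 1.0, curve_amp_frac: float = 0.12,
                  branching_angle_deg: tuple[float, float] = (25.0, 50.0)) -> VesselTree:
    """Binary-branching coronary-like tree; radius non-increasing root to leaf."""
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(seed)
    tree = VesselTree(dim=3, root=0)
    root_dir = _unit(np.array([0.15, 1.0, 0.1]) + rng.normal(0, 0.1, 3))
    tree.add_vertex(0, np.zeros(3))
    # queue of growth fronts: (vertex id, direction, start radius, generation)
    queue = [(0, root_dir, radius_root_mm, 0)]
    next_vid = 1
    built = 0
    while built < n_branches and queue:
        vid, direction, r_start, gen = queue.pop(0)
        length = rng.uniform(*branch_length_mm)
        pts = _branch_curve(tree.vertex_pos(vid), direction, length,
                            point_spacing_mm, curve_amp_frac, rng)
        r_end = r_start * taper
        radii = np.linspace(r_start, r_end, len(pts))
        c = resample_centerline(Centerline(pts, radii), point_spacing_mm)
        end_vid = next_vid
        next_vid += 1
        tree.add_vertex(end_vid, c.points[-1])
        tree.add_edge(vid, end_vid, c, generation=gen)
        built += 1
        # spawn two children deflected to either side of the end tangent
        end_dir = _unit(c.points[-1] - c.points[-2])
        e1, e2 = _perp_basis(end_dir, rng)
        for sign in (+1, -1):
            ang = np.deg2rad(rng.uniform(*branching_angle_deg))
            azim = rng.uniform(0, 2 * np.pi)
            lateral = np.cos(azim) * e1 + np.sin(azim) * e2
            child_dir = _unit(np.cos(ang) * end_dir + sign * np.sin(ang) * lateral)
            queue.append((end_vid, child_dir, r_end, gen + 1))
    tree.validate_tree()
    return tree


def _smooth_field(rng, amp_mm: float, n_modes: int, wavelength_mm: float):
    """A smooth bounded displacement field p -> R^3, max |d| <= amp_mm."""
    modes = []
    for _ in range(n_modes):
        a = rng.normal(0, 1, 3)
        k = rng.normal(0, 1, 3)
        k = k / np.linalg.norm(k) * (2 * np.pi / rng.uniform(0.8, 1.5) / wavelength_mm)
        ph = rng.uniform(0, 2 * np.pi)
        modes.append((a, k, ph))

    def raw(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        out = np.zeros_like(p)
        for a, k, ph in modes:
            out += np.sin(p @ k + ph)[:, None] * a[None, :]
        return out

    return raw


def apply_deformation(tree: VesselTree, rigid: RigidParams, amp_mm: float,
                      seed: int, n_modes: int = 3,
                      wavelength_mm: float = 120.0,
                      bounds: RigidBounds | None = None
                      ) -> tuple[VesselTree, dict]:
    """Rigid offset about the tree centroid, then a smooth bounded field.

    Returns the deformed tree plus the per-edge record of the nonrigid
    vectors actually applied (max norm <= amp_mm).  Graph structure and
    point counts are unchanged.
    """
    if bounds is not None and not rigid.within(bounds):
        raise ValueError("rigid offset outside the stated bounds")
    rng = np.random.default_rng(seed)
    raw = _smooth_field(rng, amp_mm, n_modes, wavelength_mm)
    # normalise the field on the actual point set so max displacement == amp_mm
    all_pts = rigid_transform(tree.all_points(), rigid)
    norms = np.linalg.norm(raw(all_pts), axis=1)
    scale = amp_mm / norms.max() if (amp_mm > 0 and norms.max() > 0) else 0.0

    def displace(p: np.ndarray) -> np.ndarray:
        moved = rigid_transform(p, rigid)
        return moved + scale * raw(moved)

    out = tree.copy()
    record: dict = {}
    for vid in out.graph.nodes:
        out.graph.nodes[vid]["pos"] = displace(out.vertex_pos(vid))[0]
    for u, v, data in out.graph.edges(data=True):
        c = data["centerline"]
        moved = rigid_transform(c.points, rigid)
        disp = scale * raw(moved)
        record[(u, v)] = disp
        c.points = moved + disp
    return out, record


def project_tree(tree3d: VesselTree, geometry: CArmGeometry) -> VesselTree:
    """Project a 3D tree to a 2D tree; radii become projected half-thickness."""
    out = VesselTree(dim=2)
    for vid in tree3d.graph.nodes:
        out.add_vertex(vid, project(tree3d.vertex_pos(vid), geometry)[0])
    for u, v, data in tree3d.graph.edges(data=True):
        c = data["centerline"]
        uv = project(c.points, geometry)
        rad = None
        if c.radius is not None:
            mag = geometry.sid_mm / (geometry.sod_mm + project_depth(c.points, geometry))
            rad = c.radius * mag
        keep = np.concatenate([[True], np.linalg.norm(np.diff(uv, axis=0), axis=1) > 0])
        out.add_edge(u, v, Centerline(uv[keep], None if rad is None else rad[keep]),
                     **{k: val for k, val in data.items() if k != "centerline"})
    return out


def _rasterize(segments: list[Centerline], geometry: CArmGeometry) -> np.ndarray:
    from skimage.draw import disk

    rows, cols = geometry.image_size_px
    mask = np.zeros((rows, cols), dtype=bool)
    for c in segments:
        px = geometry.mm_to_px(c.points)
        radii_px = (c.radius / geometry.pixel_spacing_mm if c.radius is not None
                    else np.full(len(px), 1.5))
        for (x, y), r in zip(px, radii_px):
            rr, cc = disk((y, x), max(float(r), 1.0), shape=mask.shape)
            mask[rr, cc] = True
    return mask


def rasterize_and_corrupt(tree2d: VesselTree, geometry: CArmGeometry,
                          gap_rate: float = 0.3, gap_width_mm: float = 1.5,
                          false_branch_rate: float = 0.3,
                          false_branch_length_mm: tuple[float, float] = (4.0, 10.0),
                          crossing: bool = False, seed: int = 0
                          ) -> tuple[np.ndarray, VesselTree]:
    """Corrupt a projected 2D tree and rasterize the result.

    Gaps split edges into disconnected smallest-unit segments; false
    branches are short polylines attached to true vessels; crossings overlay
    a shifted copy of one branch across another.  Corruption acts on the
    centerlines (labels stay exact); the raster is derived afterwards.
    Every output edge carries ``true`` and ``source`` attributes.
    """
    rng = np.random.default_rng(seed)
    out = VesselTree(dim=2)
    next_vid = 0

    def new_vertex(p):
        nonlocal next_vid
        out.add_vertex(next_vid, p)
        next_vid += 1
        return next_vid - 1

    vid_map: dict[int, int] = {}

    def mapped_vertex(old_vid):
        if old_vid not in vid_map:
            vid_map[old_vid] = new_vertex(tree2d.vertex_pos(old_vid))
        return vid_map[old_vid]

    edges = sorted(tree2d.edges())
    for (u, v) in edges:
        c = tree2d.edge_centerline(u, v)
        pieces: list[np.ndarray] = [np.arange(len(c))]
        if gap_rate > 0 and rng.random() < gap_rate and len(c) >= 8:
            # one gap at a random interior arc position, removing ~gap_width of curve
            spacing2d = max(np.linalg.norm(np.diff(c.points, axis=0), axis=1).mean(), 1e-6)
            n_rm = max(1, int(round(gap_width_mm / spacing2d)) - 1)
            cut = int(rng.integers(2, max(3, len(c) - 2 - n_rm)))
            lo = cut
            hi = min(len(c) - 1, cut + n_rm)
            pieces = [idx for idx in (np.arange(0, lo), np.arange(hi, len(c)))
                      if len(idx) >= 2]
        false_branch = None
        if false_branch_rate > 0 and rng.random() < false_branch_rate and len(c) >= 5:
            # a short decoy leaves the vessel at an interior point of one piece,
            # creating a false bifurcation that splits the host segment there
            host = int(rng.integers(0, len(pieces)))
            idx = pieces[host]
            if len(idx) >= 5:
                k = int(rng.integers(2, len(idx) - 2))
                at = idx[k]
                pieces = (pieces[:host] + [idx[:k + 1], idx[k:]]
                          + pieces[host + 1:])
                start = c.points[at]
                ang = rng.uniform(0, 2 * np.pi)
                d = np.array([np.cos(ang), np.sin(ang)])
                length = rng.uniform(*false_branch_length_mm)
                npts = max(3, int(round(length / 0.75)))
                t = np.linspace(0, length, npts)
                bend = rng.uniform(-0.15, 0.15)
                perp = np.array([-d[1], d[0]])
                fpts = (start[None, :] + np.outer(t, d)
                        + np.outer(bend * t ** 2 / length, perp))
                frad = np.full(npts, 0.5 * (c.radius[at] if c.radius is not None else 0.5))
                false_branch = (int(at), fpts, frad)
        # vertices at piece boundaries, shared where pieces abut
        boundary_vids: dict[int, int] = {}

        def vertex_at(local_idx: int, pos: np.ndarray) -> int:
            if local_idx == 0:
                return mapped_vertex(u)
            if local_idx == len(c) - 1:
                return mapped_vertex(v)
            if local_idx not in boundary_vids:
                boundary_vids[local_idx] = new_vertex(pos)
            return boundary_vids[local_idx]

        for idx in pieces:
            pts = c.points[idx]
            rad = None if c.radius is None else c.radius[idx]
            a = vertex_at(int(idx[0]), pts[0])
            b = vertex_at(int(idx[-1]), pts[-1])
            out.add_edge(a, b, Centerline(pts, rad), true=True, source=(u, v),
                         index_range=(int(idx[0]), int(idx[-1])))
        if false_branch is not None:
            at, fpts, frad = false_branch
            a = vertex_at(at, fpts[0])
            b = new_vertex(fpts[-1])
            out.add_edge(a, b, Centerline(fpts, frad), true=False, source=None)
    if crossing and len(edges) >= 2:
        # overlay a shifted copy of the first branch so it crosses the second
        (u, v) = edges[0]
        c = tree2d.edge_centerline(u, v)
        target = tree2d.edge_centerline(*edges[1]).points
        shift = target[len(target) // 2] - c.points[len(c) // 2]
        pts = c.points + shift + rng.uniform(-2, 2, 2)
        a = new_vertex(pts[0])
        b = new_vertex(pts[-1])
        out.add_edge(a, b, Centerline(pts, c.radius), true=False, source=None)

    segments = [out.edge_centerline(u, v) for u, v in out.edges()]
    mask = _rasterize(segments, geometry)
    return mask, out


def make_case(config: SimConfig = SimConfig(), seed: int = 0) -> SimulationCase:
    """Full simulation case: tree, ground-truth deformation, projection, corruption."""
    rng = np.random.default_rng(seed)
    s_tree, s_field, s_corrupt = rng.integers(0, 2 ** 31 - 1, 3)
    tree = generate_tree(int(s_tree), config.n_branches, config.branch_length_mm,
                         config.radius_root_mm, config.taper,
                         config.point_spacing_mm, config.curve_amp_frac,
                         config.branching_angle_deg)
    centroid = tree.all_points().mean(axis=0)
    b = config.bounds
    true_rigid = RigidParams(
        translation=rng.uniform(-1, 1, 3) * config.rigid_frac * b.d_max,
        rotation_deg=rng.uniform(-1, 1, 3) * config.rigid_frac * b.th_r,
        center=centroid,
    )
    deformed, disp = apply_deformation(tree, true_rigid, config.field_amp_mm,
                                       int(s_field), config.field_modes,
                                       config.field_wavelength_mm, bounds=b)
    geometry = CArmGeometry(
        primary_angle_deg=float(rng.uniform(*config.primary_range_deg)),
        secondary_angle_deg=float(rng.uniform(*config.secondary_range_deg)),
        pixel_spacing_mm=config.pixel_spacing_mm,
        sid_mm=config.sid_mm, sod_mm=config.sod_mm,
        image_size_px=config.image_size_px,
    ).with_isocenter(deformed.all_points().mean(axis=0))
    tree2d_clean = project_tree(deformed, geometry)
    # real 2D skeletons are pixel-dense; resample to detector resolution
    for u, v, data in tree2d_clean.graph.edges(data=True):
        data["centerline"] = resample_centerline(data["centerline"],
                                                 config.pixel_spacing_mm)
    mask, tree2d = rasterize_and_corrupt(
        tree2d_clean, geometry, config.gap_rate, config.gap_width_mm,
        config.false_branch_rate, config.false_branch_length_mm,
        config.crossing, int(s_corrupt))
    correspondences = {}
    for (u, v) in tree.edges():
        correspondences[(u, v)] = project(deformed.edge_centerline(u, v).points, geometry)
    # markers: bifurcation vertices first, then mid-branch points
    markers = []
    bifs = [vid for vid in sorted(tree.graph.nodes) if tree.graph.degree(vid) >= 3]
    for vid in bifs:
        markers.append(("vertex", vid, deformed.vertex_pos(vid).copy()))
    edge_list = sorted(tree.edges())
    i = 0
    while len(markers) < config.n_markers:
        u, v = edge_list[i % len(edge_list)]
        c = deformed.edge_centerline(u, v)
        frac = 0.25 + 0.5 * ((i // len(edge_list)) % 2)
        idx = int(round(frac * (len(c) - 1)))
        markers.append(("edge", ((u, v), idx), c.points[idx].copy()))
        i += 1
    markers = markers[:config.n_markers]
    return SimulationCase(tree3d=tree, true_rigid=true_rigid, displacement=disp,
                          deformed3d=deformed, geometry=geometry,
                          tree2d_clean=tree2d_clean, tree2d=tree2d, mask2d=mask,
                          correspondences=correspondences, markers=markers,
                          seed=seed, config=config)
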