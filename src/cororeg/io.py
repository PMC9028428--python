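"""Readers and writers for trees, geometry, masks, markers and correspondences.

Tree JSON schema::

    {"vertices": {"0": [x, y(, z)], ...},
     "edges": [{"from": 0, "to": 1, "points": [[...], ...], "radius": [...]}],
     "root": 0}

3D trees can also be written/read as VTK legacy polyline files (POLYDATA
with LINES).  C-arm geometry round-trips through a YAML ``carm:`` block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .carm import CArmGeometry
from .vascular import Centerline, MarkerPairs, VesselTree

__all__ = ["tree_to_json", "tree_from_json", "save_tree", "load_tree",
           "save_geometry", "load_geometry", "save_mask", "load_mask",
           "save_markers", "load_markers", "tree_to_vtk", "tree_from_vtk"]


def tree_to_json(tree: VesselTree) -> dict:
    d = {
        "dim": tree.dim,
        "vertices": {str(vid): tree.vertex_pos(vid).tolist()
                     for vid in tree.graph.nodes},
        "edges": [],
        "root": tree.root,
    }
    for u, v, data in sorted(tree.graph.edges(data=True), key=lambda e: (e[0], e[1])):
        c = data["centerline"]
        e = {"from": int(u), "to": int(v), "points": c.points.tolist()}
        if c.radius is not None:
            e["radius"] = c.radius.tolist()
        for k, val in data.items():
            if k == "centerline":
                continue
            if isinstance(val, tuple):
                val = list(val)
            e[k] = val
        d["edges"].append(e)
    return d


def tree_from_json(d: dict) -> VesselTree:
    dim = int(d.get("dim") or len(next(iter(d["vertices"].values()))))
    tree = VesselTree(dim=dim, root=d.get("root"))
    for vid, pos in d["vertices"].items():
        tree.add_vertex(int(vid), np.asarray(pos, dtype=float))
    for e in d["edges"]:
        pts = np.asarray(e["points"], dtype=float)
        rad = np.asarray(e["radius"], dtype=float) if "radius" in e else None
        attrs = {k: v for k, v in e.items()
                 if k not in ("from", "to", "points", "radius")}
        tree.add_edge(int(e["from"]), int(e["to"]), Centerline(pts, rad), **attrs)
    return tree


def save_tree(tree: VesselTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_json(tree), indent=1))


def load_tree(path: str | Path) -> VesselTree:
    return tree_from_json(json.loads(Path(path).read_text()))


def save_geometry(g: CArmGeometry, path: str | Path) -> None:
    block = {"carm": {"primary": g.primary_angle_deg, "secondary": g.secondary_angle_deg,
                      "pixel_spacing": g.pixel_spacing_mm, "sid": g.sid_mm,
                      "sod": g.sod_mm, "size": list(g.image_size_px),
                      "isocenter": list(g.isocenter)}}
    Path(path).write_text(yaml.safe_dump(block))


def load_geometry(path: str | Path) -> CArmGeometry:
    block = yaml.safe_load(Path(path).read_text())["carm"]
    return CArmGeometry(
        primary_angle_deg=float(block["primary"]),
        secondary_angle_deg=float(block["secondary"]),
        pixel_spacing_mm=float(block["pixel_spacing"]),
        sid_mm=float(block["sid"]), sod_mm=float(block["sod"]),
        image_size_px=tuple(block.get("size", (512, 512))),
        isocenter=tuple(block.get("isocenter", (0.0, 0.0, 0.0))),
    )


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 127


def save_markers(markers: MarkerPairs, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"p": markers.p.tolist(), "q": markers.q.tolist()}))


def load_markers(path: str | Path) -> MarkerPairs:
    d = json.loads(Path(path).read_text())
    return MarkerPairs(np.asarray(d["p"]), np.asarray(d["q"]))


# ---------------------------------------------------------------------------
# VTK legacy polyline (ASCII POLYDATA) for 3D trees

def tree_to_vtk(tree: VesselTree, path: str | Path) -> None:
    if tree.dim != 3:
        raise ValueError("VTK polyline export is for 3D trees")
    pts_blocks, lines, radii = [], [], []
    offset = 0
    for u, v in sorted(tree.edges()):
        c = tree.edge_centerline(u, v)
        n = len(c)
        pts_blocks.append(c.points)
        lines.append([n] + list(range(offset, offset + n)))
        radii.append(c.radius if c.radius is not None else np.zeros(n))
        offset += n
    all_pts = np.vstack(pts_blocks)
    all_r = np.concatenate(radii)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvessel tree\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(all_pts)} float\n")
        for p in all_pts:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(l) for l in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            f.write(" ".join(str(x) for x in l) + "\n")
        f.write(f"POINT_DATA {len(all_pts)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in all_r:
            f.write(f"{r:.6f}\n")


def tree_from_vtk(path: str | Path) -> VesselTree:
    """Read a legacy VTK polyline file into a 3D tree (vertices at line ends)."""
    lines = Path(path).read_text().split("\n")
    i = 0
    pts = None
    polylines = []
    radii = None
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["POINTS"]:
            n = int(tok[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            pts = np.array(vals).reshape(n, 3)
            continue
        if tok[:1] == ["LINES"]:
            n_lines = int(tok[1])
            i += 1
            for _ in range(n_lines):
                row = [int(x) for x in lines[i].split()]
                polylines.append(row[1:1 + row[0]])
                i += 1
            continue
        if tok[:1] == ["SCALARS"] and len(tok) > 1 and tok[1] == "radius":
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while i < len(lines) and len(vals) < len(pts):
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            radii = np.array(vals)
            continue
        i += 1
    tree = VesselTree(dim=3, root=0)
    key_to_vid: dict[tuple, int] = {}

    def node_for(p):
        k = tuple(np.round(p / 1e-6).astype(np.int64))
        if k not in key_to_vid:
            vid = len(key_to_vid)
            tree.add_vertex(vid, p)
            key_to_vid[k] = vid
        return key_to_vid[k]

    for idxs in polylines:
        p = pts[idxs]
        r = radii[idxs] if radii is not None and np.all(radii[idxs] > 0) else None
        u = node_for(p[0])
        v = node_for(p[-1])
        tree.add_edge(u, v, Centerline(p, r))
    return tree
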