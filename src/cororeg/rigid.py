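"""Bounded 6-DOF rigid registration of a 3D centerline tree to 2D centerlines.

The pose is a translation (Tx, Ty, Tz) in mm and Euler rotations
(Rx, Ry, Rz) in degrees applied about a rotation centre (the 3D centerline
centroid by default), composed as the z.y.x product.  The objective is the
mean Euclidean distance from the projected 3D centerline points to their
nearest 2D centerline points, minimised with Powell's direction-set method
in two stages (translation only, then all six parameters) inside a bounded
search box enforced by a quadratic penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .carm import CArmGeometry, project
from .vascular import VesselTree

__all__ = ["RigidParams", "RigidBounds", "rigid_transform", "projection_distance",
           "register_rigid", "euler_matrix"]


@dataclass
class RigidBounds:
    """Search-box half-widths: |T| <= d_max (mm), |R| <= th_R (deg)."""

    d_max: float = 30.0
    th_r: float = 10.0

    def __post_init__(self):
        if self.d_max <= 0 or self.th_r <= 0:
            raise ValueError("bounds must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([self.d_max] * 3 + [self.th_r] * 3)


@dataclass
class RigidParams:
    """6-vector pose: translation mm, rotation degrees, about ``center``."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation_deg])

    @classmethod
    def from_vector(cls, x: np.ndarray, center: np.ndarray) -> "RigidParams":
        x = np.asarray(x, dtype=float)
        return cls(x[:3].copy(), x[3:6].copy(), np.asarray(center, dtype=float))

    def within(self, bounds: RigidBounds) -> bool:
        return bool(np.all(np.abs(self.as_vector()) <= bounds.as_vector() + 1e-12))


def euler_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix R = Rz(rz) @ Ry(ry) @ Rx(rx), angles in degrees."""
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def rigid_transform(points: np.ndarray, p: RigidParams) -> np.ndarray:
    """x' = R (x - c) + c + T with R the z.y.x Euler product."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = euler_matrix(p.rotation_deg)
    return (pts - p.center) @ m.T + p.center + p.translation


def transform_tree(tree: VesselTree, p: RigidParams) -> VesselTree:
    """Apply a rigid transform to every vertex and centerline point of a 3D tree."""
    out = tree.copy()
    for vid in out.graph.nodes:
        out.graph.nodes[vid]["pos"] = rigid_transform(out.vertex_pos(vid), p)[0]
    for _, _, data in out.graph.edges(data=True):
        c = data["centerline"]
        c.points = rigid_transform(c.points, p)
    return out


def projection_distance(points3d: np.ndarray, points2d: np.ndarray,
                        geometry: CArmGeometry, params: RigidParams | None = None) -> float:
    """Mean distance of projected (transformed) 3D points to nearest 2D points."""
    pts3 = np.atleast_2d(points3d)
    pts2 = np.atleast_2d(points2d)
    if len(pts3) == 0 or len(pts2) == 0:
        raise ValueError("empty point set")
    if params is not None:
        pts3 = rigid_transform(pts3, params)
    proj = project(pts3, geometry)
    d, _ = cKDTree(pts2).query(proj)
    return float(d.mean())


def _objective(x, pts3, tree2, geometry, center, bounds_vec, penalty=100.0):
    params = RigidParams.from_vector(x, center)
    excess = np.maximum(np.abs(x) - bounds_vec, 0.0)
    pen = penalty * float(np.sum(excess ** 2))
    try:
        proj = project(rigid_transform(pts3, params), geometry)
    except ValueError:
        return 1e9 + pen
    d, _ = tree2.query(proj)
    return float(d.mean()) + pen


def register_rigid(points3d: np.ndarray, points2d: np.ndarray, geometry: CArmGeometry,
                   bounds: RigidBounds | None = None, init: RigidParams | None = None,
                   center: np.ndarray | None = None, multistart: int = 0,
                   seed: int = 0) -> tuple[RigidParams, float]:
    """Two-stage bounded Powell alignment; returns (params, final mean distance).

    Stage 1 optimises the translation only, stage 2 all six parameters from
    the stage-1 result.  ``multistart`` > 0 adds that many extra random
    starting poses inside 0.5x the bounds (deterministic in ``seed``).
    """
    pts3 = np.atleast_2d(np.asarray(points3d, dtype=float))
    pts2 = np.atleast_2d(np.asarray(points2d, dtype=float))
    if len(pts3) == 0 or len(pts2) == 0:
        raise ValueError("empty input centerlines")
    bounds = bounds or RigidBounds()
    if center is None:
        center = pts3.mean(axis=0)
    center = np.asarray(center, dtype=float)
    if init is None:
        init = RigidParams(center=center)
    if not init.within(bounds):
        raise ValueError("initial parameters outside bounds")
    tree2 = cKDTree(pts2)
    bvec = bounds.as_vector()

    def run(x0: np.ndarray) -> tuple[np.ndarray, float]:
        # stage 1: translation only
        def f_t(t):
            return _objective(np.concatenate([t, x0[3:]]), pts3, tree2, geometry, center, bvec)

        r1 = minimize(f_t, x0[:3], method="Powell",
                      options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": 2000})
        x1 = np.concatenate([r1.x, x0[3:]])
        # stage 2: full 6-DOF
        def f_all(x):
            return _objective(x, pts3, tree2, geometry, center, bvec)

        r2 = minimize(f_all, x1, method="Powell",
                      options={"xtol": 1e-5, "ftol": 1e-8, "maxiter": 5000})
        return r2.x, float(r2.fun)

    starts = [init.as_vector()]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        starts += [rng.uniform(-0.5, 0.5, 6) * bvec for _ in range(multistart)]

    best_x, best_f = None, np.inf
    for x0 in starts:
        x, f = run(x0)
        if f < best_f:
            best_x, best_f = x, f

    f0 = _objective(init.as_vector(), pts3, tree2, geometry, center, bvec)
    if best_f > f0:  # Powell should never worsen the start, but guarantee descent
        best_x, best_f = init.as_vector(), f0
    best_x = np.clip(best_x, -bvec, bvec)
    final = _objective(best_x, pts3, tree2, geometry, center, bvec)
    return RigidParams.from_vector(best_x, center), float(final)
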