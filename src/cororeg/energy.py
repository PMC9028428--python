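"""Nonrigid deformation of 3D centerlines by snake-energy gradient descent.

The total energy per branch is E = sum_i mu*E_cont + tau*E_curv +
phi*E_image.  E_cont = (dbar - |v_i - v_{i-1}|)^2 keeps point spacing at
its initial mean dbar; E_curv = |v_{i-1} - 2 v_i + v_{i+1}|^2 penalises
kinks; E_image = H(v_i) * dist(v_i, ray(u_i))^2 pulls each point onto the
back-projected source ray through its matched 2D point, leaving depth
unconstrained (the single-view setting).  Points move by explicit gradient
descent with periodic re-matching; between re-matches the correspondence
is frozen so the gradient is well defined.  Branch endpoints shared between
branches (bifurcations) receive the summed gradient and move as one point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .carm import CArmGeometry, backproject_ray, project
from .matching import match_points

__all__ = ["EnergyWeights", "DeformationState", "energy_cont", "energy_curv",
           "energy_image", "deform", "deform_branches"]


@dataclass(frozen=True)
class EnergyWeights:
    mu: float = 0.5
    tau: float = 0.4
    phi: float = 0.6

    def __post_init__(self):
        if min(self.mu, self.tau, self.phi) < 0:
            raise ValueError("energy weights must be non-negative")


@dataclass
class DeformationState:
    branches: list[np.ndarray]            # current (N_b, 3) points per branch
    iterations: int = 0
    energy_trace: list[dict] = field(default_factory=list)
    step: float = 0.05
    converged: bool = False

    @property
    def points(self) -> np.ndarray:
        return self.branches[0]


def energy_cont(points: np.ndarray, dbar: float) -> tuple[np.ndarray, float]:
    """Continuity term (dbar - |v_i - v_{i-1}|)^2; the first point contributes 0."""
    pts = np.atleast_2d(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    per = np.concatenate([[0.0], (dbar - seg) ** 2])
    return per, float(per.sum())


def energy_curv(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Curvature term |v_{i-1} - 2 v_i + v_{i+1}|^2; endpoints contribute 0."""
    pts = np.atleast_2d(points)
    per = np.zeros(len(pts))
    if len(pts) >= 3:
        lap = pts[:-2] - 2 * pts[1:-1] + pts[2:]
        per[1:-1] = np.einsum("ij,ij->i", lap, lap)
    return per, float(per.sum())


def _rays(points2d: np.ndarray, valid: np.ndarray,
          geometry: CArmGeometry) -> tuple[np.ndarray, np.ndarray]:
    origins = np.zeros((len(points2d), 3))
    dirs = np.zeros((len(points2d), 3))
    for i in np.nonzero(valid)[0]:
        o, d = backproject_ray(points2d[i], geometry)
        origins[i], dirs[i] = o, d
    return origins, dirs


def energy_image(points: np.ndarray, valid: np.ndarray, ray_origins: np.ndarray,
                 ray_dirs: np.ndarray) -> tuple[np.ndarray, float]:
    """Image term H(v_i) * (perpendicular distance of v_i to its match's ray)^2."""
    pts = np.atleast_2d(points)
    per = np.zeros(len(pts))
    if valid.any():
        w = pts[valid] - ray_origins[valid]
        t = np.einsum("ij,ij->i", w, ray_dirs[valid])
        perp = w - t[:, None] * ray_dirs[valid]
        per[valid] = np.einsum("ij,ij->i", perp, perp)
    return per, float(per.sum())


def _grad_cont(pts: np.ndarray, dbar: float) -> np.ndarray:
    g = np.zeros_like(pts)
    diff = np.diff(pts, axis=0)
    seg = np.linalg.norm(diff, axis=1)
    safe = np.maximum(seg, 1e-12)
    coef = -2.0 * (dbar - seg) / safe          # d/d|dv| of (dbar-|dv|)^2
    g[1:] += coef[:, None] * diff              # wrt v_i of term i
    g[:-1] -= coef[:, None] * diff             # wrt v_{i-1}
    return g


def _grad_curv(pts: np.ndarray) -> np.ndarray:
    g = np.zeros_like(pts)
    if len(pts) < 3:
        return g
    lap = pts[:-2] - 2 * pts[1:-1] + pts[2:]
    g[1:-1] += -4.0 * lap
    g[:-2] += 2.0 * lap
    g[2:] += 2.0 * lap
    return g


def _grad_image(pts: np.ndarray, valid: np.ndarray, origins: np.ndarray,
                dirs: np.ndarray) -> np.ndarray:
    g = np.zeros_like(pts)
    if valid.any():
        w = pts[valid] - origins[valid]
        t = np.einsum("ij,ij->i", w, dirs[valid])
        perp = w - t[:, None] * dirs[valid]
        g[valid] = 2.0 * perp
    return g


class DivergenceError(RuntimeError):
    pass


def deform_branches(branches: list[np.ndarray],
                    candilines: list[np.ndarray],
                    geometry: CArmGeometry,
                    weights: EnergyWeights = EnergyWeights(),
                    step: float = 0.05, max_iter: int = 500, tol: float = 1e-6,
                    rematch_every: int = 10, max_dist: float = 5.0,
                    n: int = 3, window: int = 3) -> DeformationState:
    """Jointly deform several branches toward their selected candi-lines.

    Branch endpoints that coincide (within 1e-6 mm) across branches are tied
    together: they receive the summed gradient of all incident branches, so
    bifurcation points stay coincident.  Correspondences are refreshed every
    ``rematch_every`` iterations.  If the total energy rises for 5
    consecutive iterations the step is halved; after 5 halvings a
    :class:`DivergenceError` is raised.
    """
    branches = [np.array(b, dtype=float) for b in branches]
    if len(branches) != len(candilines):
        raise ValueError("one candi-line per branch required")
    dbars = [float(np.linalg.norm(np.diff(b, axis=0), axis=1).mean()) for b in branches]

    # tie shared endpoints: map (branch, index) of endpoints to shared groups
    ties: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for bi, b in enumerate(branches):
        for idx in (0, len(b) - 1):
            key = tuple(np.round(b[idx] / 1e-6).astype(np.int64))
            ties.setdefault(key, []).append((bi, idx))
    shared = [v for v in ties.values() if len(v) > 1]

    state = DeformationState(branches=branches, step=step)
    match = [None] * len(branches)

    def refresh_matches():
        for bi, b in enumerate(branches):
            proj = project(b, geometry)
            cmap = match_points(proj, candilines[bi], n=n, max_dist=max_dist,
                                window=window)
            origins, dirs = _rays(cmap.points2d, cmap.valid, geometry)
            match[bi] = (cmap.valid.copy(), origins, dirs)

    def total_energy():
        e_c = e_k = e_i = 0.0
        for bi, b in enumerate(branches):
            e_c += energy_cont(b, dbars[bi])[1]
            e_k += energy_curv(b)[1]
            valid, origins, dirs = match[bi]
            e_i += energy_image(b, valid, origins, dirs)[1]
        return e_c, e_k, e_i, weights.mu * e_c + weights.tau * e_k + weights.phi * e_i

    refresh_matches()
    prev_total = total_energy()[3]
    bad_streak = 0
    halvings = 0
    cur_step = step

    for it in range(1, max_iter + 1):
        if rematch_every > 0 and it > 1 and (it - 1) % rematch_every == 0:
            refresh_matches()
            prev_total = total_energy()[3]
        grads = []
        for bi, b in enumerate(branches):
            valid, origins, dirs = match[bi]
            g = (weights.mu * _grad_cont(b, dbars[bi])
                 + weights.tau * _grad_curv(b)
                 + weights.phi * _grad_image(b, valid, origins, dirs))
            grads.append(g)
        # shared bifurcation points: summed gradient applied identically
        for group in shared:
            gsum = sum(grads[bi][idx] for bi, idx in group)
            for bi, idx in group:
                grads[bi][idx] = gsum
        for bi in range(len(branches)):
            branches[bi] -= cur_step * grads[bi]

        e_c, e_k, e_i, total = total_energy()
        state.energy_trace.append({"iter": it, "e_cont": e_c, "e_curv": e_k,
                                   "e_image": e_i, "total": total,
                                   "step": cur_step})
        state.iterations = it
        if total > prev_total + 1e-12:
            bad_streak += 1
            if bad_streak >= 5:
                halvings += 1
                if halvings > 5:
                    raise DivergenceError("energy descent diverged after 5 step halvings")
                cur_step *= 0.5
                bad_streak = 0
        else:
            bad_streak = 0
        if prev_total > 0 and abs(total - prev_total) / max(prev_total, 1e-12) < tol:
            state.converged = True
            prev_total = total
            break
        prev_total = total

    state.step = cur_step
    return state


def deform(points3d: np.ndarray, candiline_points: np.ndarray,
           geometry: CArmGeometry, weights: EnergyWeights = EnergyWeights(),
           **opts) -> DeformationState:
    """Single-branch convenience wrapper around :func:`deform_branches`."""
    return deform_branches([np.asarray(points3d, dtype=float)],
                           [np.asarray(candiline_points, dtype=float)],
                           geometry, weights, **opts)
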