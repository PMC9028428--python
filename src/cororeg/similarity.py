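"""Multi-feature similarity scoring and optimal candi-line selection.

Each surviving candi-line is scored against its 3D segment with four terms:
gradient (tangent-line) disagreement D_theta, mean matched Euclidean
distance d2, thickness difference D_Th, and relative length difference D_L.
The selected candi-line minimises SM = alpha*D_theta + beta*d2 + gamma*D_Th
+ delta*D_L.  Default weights follow the simulation-tuned values
(0.4, 0.7, 0.25, 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .carm import CArmGeometry, project_depth
from .graphrec import CandiLine
from .matching import CorrespondenceMap, match_points, matched_distance_stats, _tangent_lines
from .vascular import Centerline, centerline_length

__all__ = ["SimilarityWeights", "SimilarityScore", "gradient_term", "thickness_term",
           "length_term", "select_candiline"]

_D2_FLOOR = 0.1  # mm; per-pair normalisation floor for the gradient term


@dataclass(frozen=True)
class SimilarityWeights:
    alpha: float = 0.4
    beta: float = 0.7
    gamma: float = 0.25
    delta: float = 0.15

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("similarity weights must be non-negative")


@dataclass
class SimilarityScore:
    d_theta: float
    d2_mean: float
    d_th: float
    d_l: float
    total: float
    candiline: CandiLine | None = None


def gradient_term(proj3d: np.ndarray, cmap: CorrespondenceMap,
                  window: int = 3) -> float:
    """Mean per-pair tangent-line distance normalised by the pair's d2.

    For each valid match the distance of the 2D point to the tangent line at
    its 3D point is divided by max(d2, 0.1 mm); pairs are averaged.  +inf
    when no valid matches exist.
    """
    proj3d = np.atleast_2d(proj3d)
    if not cmap.valid.any():
        return float("inf")
    dirs = _tangent_lines(proj3d, window)
    idx = np.nonzero(cmap.valid)[0]
    vals = []
    for i in idx:
        a, d = proj3d[i], dirs[i]
        c = cmap.points2d[i]
        line_d = abs(d[0] * (c[1] - a[1]) - d[1] * (c[0] - a[0]))
        vals.append(line_d / max(cmap.d2[i], _D2_FLOOR))
    return float(np.mean(vals))


def thickness_term(th3d: np.ndarray, th2d_at_match: np.ndarray,
                   valid: np.ndarray, rms: bool = True) -> float:
    """Thickness disagreement over matched pairs.

    ``rms=True`` (default) returns sqrt(mean((Th3D - Th2D)^2)) so the term is
    in millimetres like the others; ``rms=False`` returns the raw mean of
    squares.
    """
    if not np.any(valid):
        return float("inf")
    diff = np.asarray(th3d, dtype=float)[valid] - np.asarray(th2d_at_match, dtype=float)[valid]
    ms = float(np.mean(diff ** 2))
    return float(np.sqrt(ms)) if rms else ms


def length_term(proj3d: np.ndarray, candiline_points: np.ndarray) -> float:
    """Relative length difference |s3D_L - c2D_L| / s3D_L of the projected segment."""
    s_l = centerline_length(np.atleast_2d(proj3d))
    if s_l <= 0:
        raise ValueError("zero-length 3D segment")
    c_l = centerline_length(np.atleast_2d(candiline_points))
    return float(abs(s_l - c_l) / s_l)


def projected_thickness(centerline3d: Centerline, geometry: CArmGeometry) -> np.ndarray:
    """Projected vessel diameter at each 3D point: 2 r * SID/(SOD + depth)."""
    if centerline3d.radius is None:
        raise ValueError("3D centerline carries no radius")
    depth = project_depth(centerline3d.points, geometry)
    return 2.0 * centerline3d.radius * geometry.sid_mm / (geometry.sod_mm + depth)


def score_candiline(proj3d: np.ndarray, cl: CandiLine,
                    th3d: np.ndarray | None = None,
                    weights: SimilarityWeights = SimilarityWeights(),
                    n: int = 3, max_dist: float = 5.0, window: int = 3,
                    rms_thickness: bool = True) -> tuple[SimilarityScore, CorrespondenceMap]:
    cmap = match_points(proj3d, cl.points, n=n, max_dist=max_dist, window=window)
    stats = matched_distance_stats(cmap)
    d2_mean = stats["mean_d2"] if stats["defined"] else float("inf")
    d_theta = gradient_term(proj3d, cmap, window)
    gamma = weights.gamma
    if th3d is not None and cl.radius is not None and stats["defined"]:
        th2d = np.full(len(proj3d), np.nan)
        th2d[cmap.valid] = 2.0 * cl.radius[cmap.indices[cmap.valid]]
        d_th = thickness_term(th3d, th2d, cmap.valid, rms=rms_thickness)
    else:
        d_th, gamma = 0.0, 0.0   # thickness unavailable: term skipped
    d_l = length_term(proj3d, cl.points)
    total = (weights.alpha * d_theta + weights.beta * d2_mean
             + gamma * d_th + weights.delta * d_l)
    return SimilarityScore(d_theta, d2_mean, d_th, d_l, float(total), cl), cmap


def select_candiline(proj3d: np.ndarray, candilines: list[CandiLine],
                     th3d: np.ndarray | None = None,
                     weights: SimilarityWeights = SimilarityWeights(),
                     n: int = 3, max_dist: float = 5.0, window: int = 3,
                     rms_thickness: bool = True
                     ) -> tuple[CandiLine, CorrespondenceMap, list[SimilarityScore]]:
    """Score every candi-line and return the argmin of SM.

    Ties are broken by lower mean matched distance, then by the candi-line's
    canonical edge-id key.  The full score table is returned for audit.
    """
    if not candilines:
        raise ValueError("no candi-lines to select from")
    scored = []
    for cl in candilines:
        score, cmap = score_candiline(proj3d, cl, th3d, weights, n, max_dist,
                                      window, rms_thickness)
        scored.append((score, cmap, cl))
    scored.sort(key=lambda t: (t[0].total, t[0].d2_mean, t[2].key()))
    best_score, best_cmap, best_cl = scored[0]
    return best_cl, best_cmap, [s for s, _, _ in scored]
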