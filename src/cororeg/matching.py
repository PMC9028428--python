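"""Tangent-based point matching between a projected 3D centerline and a candi-line.

Each projected 3D point is assigned the candi-line point minimising a cost
that combines the Euclidean distance with the mean distance of the
candidate to the tangent lines at the 3D point and its window of
neighbouring points.  Using the whole window of tangents stabilises the
assignment against local segmentation and registration errors that defeat
purely distance- or purely curvature-based matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vascular import tangent_direction

__all__ = ["CorrespondenceMap", "match_cost", "match_points", "matched_distance_stats"]


@dataclass
class CorrespondenceMap:
    """Per-3D-point match: index into the candi-line points, validity H, cost."""

    indices: np.ndarray          # (N,) int, -1 when unmatched
    valid: np.ndarray            # (N,) bool, H(v_i)
    cost: np.ndarray             # (N,) float
    d2: np.ndarray               # (N,) float, Euclidean distance of the match
    points2d: np.ndarray         # (N, 2) matched 2D points (NaN where invalid)

    def __len__(self) -> int:
        return len(self.indices)


def _tangent_lines(proj3d: np.ndarray, window: int = 3) -> np.ndarray:
    """Unit tangent direction at every projected 3D point, (N, 2)."""
    n = len(proj3d)
    dirs = np.empty((n, 2))
    for i in range(n):
        dirs[i] = tangent_direction(proj3d, i, window)
    return dirs


def _line_distance_matrix(anchors: np.ndarray, dirs: np.ndarray,
                          cand: np.ndarray) -> np.ndarray:
    """(N, M) distance from candidate j to the tangent line through anchor i."""
    # |cross(dir_i, c_j - a_i)| for unit dir_i == |c' x - y + b| / sqrt(c'^2+1)
    diff0 = cand[None, :, 0] - anchors[:, None, 0]
    diff1 = cand[None, :, 1] - anchors[:, None, 1]
    return np.abs(dirs[:, 0:1] * diff1 - dirs[:, 1:2] * diff0)


def match_cost(proj3d: np.ndarray, i: int, candidate: np.ndarray,
               n: int = 3, window: int = 3,
               line_weight: float = 1.0, dist_weight: float = 1.0) -> float:
    """Matching cost of one candidate 2D point against projected 3D point ``i``.

    cost = line_weight * mean_{k in [-n, n]} dist(candidate, tangent line at
    point i+k) + dist_weight * ||proj3d[i] - candidate||.  The window is
    truncated at the curve ends and the mean taken over the points present.
    """
    proj3d = np.atleast_2d(proj3d)
    candidate = np.asarray(candidate, dtype=float).reshape(2)
    npts = len(proj3d)
    lo, hi = max(0, i - n), min(npts, i + n + 1)
    dists = []
    for k in range(lo, hi):
        d = tangent_direction(proj3d, k, window)
        a = proj3d[k]
        dists.append(abs(d[0] * (candidate[1] - a[1]) - d[1] * (candidate[0] - a[0])))
    line_term = float(np.mean(dists))
    d2 = float(np.linalg.norm(proj3d[i] - candidate))
    return line_weight * line_term + dist_weight * d2


def match_points(proj3d: np.ndarray, candiline_points: np.ndarray,
                 n: int = 3, max_dist: float = 5.0, window: int = 3,
                 line_weight: float = 1.0, dist_weight: float = 1.0) -> CorrespondenceMap:
    """Assign every projected 3D point its argmin-cost candi-line point.

    Ties are broken by smaller Euclidean distance, then smaller candidate
    index.  H(v_i) = 0 when the chosen match lies farther than ``max_dist``.
    """
    proj3d = np.atleast_2d(np.asarray(proj3d, dtype=float))
    cand = np.atleast_2d(np.asarray(candiline_points, dtype=float))
    if len(cand) == 0:
        raise ValueError("empty candi-line")
    npts, m = len(proj3d), len(cand)

    dirs = _tangent_lines(proj3d, window)
    line_d = _line_distance_matrix(proj3d, dirs, cand)       # (N, M)
    d2 = np.linalg.norm(proj3d[:, None, :] - cand[None, :, :], axis=2)

    # windowed mean of line distances along the 3D index, truncated at ends
    csum = np.vstack([np.zeros((1, m)), np.cumsum(line_d, axis=0)])
    idx = np.arange(npts)
    lo = np.maximum(0, idx - n)
    hi = np.minimum(npts, idx + n + 1)
    win_mean = (csum[hi] - csum[lo]) / (hi - lo)[:, None]

    cost = line_weight * win_mean + dist_weight * d2
    # argmin with deterministic tie-breaking: cost, then d2, then index
    order = np.lexsort((np.broadcast_to(np.arange(m), cost.shape).reshape(npts, m),
                        d2, cost), axis=1)
    best = order[:, 0]
    best_cost = cost[idx, best]
    best_d2 = d2[idx, best]
    valid = best_d2 <= max_dist
    pts = cand[best].astype(float)
    pts[~valid] = np.nan
    indices = np.where(valid, best, -1)
    return CorrespondenceMap(indices=indices, valid=valid, cost=best_cost,
                             d2=best_d2, points2d=pts)


def matched_distance_stats(cmap: CorrespondenceMap) -> dict:
    """Mean Euclidean distance over valid matches and the valid fraction."""
    n = len(cmap)
    k = int(cmap.valid.sum())
    mean_d2 = float(cmap.d2[cmap.valid].mean()) if k else float("nan")
    return {"mean_d2": mean_d2, "valid_fraction": k / n if n else 0.0,
            "n_valid": k, "defined": k > 0}
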