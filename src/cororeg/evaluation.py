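"""Registration and segmentation evaluation metrics.

ADD (average of distance differences) over marker pairs, point and
bifurcation precision/recall/F1 at metric tolerances (1 mm for centerline
points, 3 mm for bifurcations), pixel-wise precision/recall/F1, and
centerline distance summaries.  The printed recall variant TP/(TP+FP+FN)
is reported alongside the standard TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .vascular import MarkerPairs

__all__ = ["MatchCounts", "add_metric", "point_prf", "pixel_prf",
           "centerline_distance_report"]


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None


def _prf(counts: MatchCounts) -> dict:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall_printed = tp / (tp + fp + fn) if tp + fp + fn else float("nan")
    recall_standard = tp / (tp + fn) if tp + fn else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"precision": precision, "recall": recall_printed,
            "recall_standard": recall_standard, "f1": f1, "counts": counts}


def add_metric(markers: MarkerPairs) -> float:
    """ADD = (1/M) sum_i ||p_i - q_i|| over the marker pairs, mm."""
    return float(np.linalg.norm(markers.p - markers.q, axis=1).mean())


def point_prf(pred: np.ndarray, gt: np.ndarray, tol_mm: float = 1.0,
              one_to_one: bool = False) -> dict:
    """Precision/recall/F1 for point sets at a metric tolerance.

    Default (many-to-one): a predicted point within ``tol_mm`` of any GT
    point is a TP, otherwise FP; a GT point with no predicted point within
    ``tol_mm`` is an FN.  ``one_to_one=True`` uses greedy nearest-pair
    one-to-one assignment (used for bifurcations, where one true branching
    must not absorb several detections).
    """
    if tol_mm <= 0:
        raise ValueError("tolerance must be positive")
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    gt = np.atleast_2d(np.asarray(gt, dtype=float))
    if pred.size == 0 and gt.size == 0:
        return {"precision": float("nan"), "recall": float("nan"),
                "recall_standard": float("nan"), "f1": float("nan"),
                "counts": MatchCounts(), "defined": False}
    if pred.size == 0:
        return {**_prf(MatchCounts(0, 0, len(gt))), "defined": True}
    if gt.size == 0:
        return {**_prf(MatchCounts(0, len(pred), 0)), "defined": True}

    if one_to_one:
        d = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=2)
        pairs = [(d[i, j], i, j) for i in range(len(pred)) for j in range(len(gt))
                 if d[i, j] <= tol_mm]
        pairs.sort()
        used_p, used_g = set(), set()
        tp = 0
        for dist, i, j in pairs:
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            tp += 1
        counts = MatchCounts(tp, len(pred) - tp, len(gt) - tp)
    else:
        kd_gt = cKDTree(gt)
        d_pred, _ = kd_gt.query(pred)
        tp = int((d_pred <= tol_mm).sum())
        fp = len(pred) - tp
        kd_pred = cKDTree(pred)
        d_gt, _ = kd_pred.query(gt)
        fn = int((d_gt > tol_mm).sum())
        counts = MatchCounts(tp, fp, fn)
    return {**_prf(counts), "defined": True}


def pixel_prf(pred_mask: np.ndarray, gt_mask: np.ndarray) -> dict:
    """Per-pixel precision/recall/F1 between binary rasters of equal shape."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    return {**_prf(MatchCounts(tp, fp, fn, tn)), "defined": True}


def centerline_distance_report(proj_pred2d: np.ndarray, gt2d: np.ndarray,
                               pred3d: np.ndarray | None = None,
                               gt3d: np.ndarray | None = None) -> dict:
    """Distance summary of a registered centerline against ground truth.

    2D: mean nearest-point distance of the projected deformed centerline to
    the ground-truth 2D centerline.  3D (simulation only, where the index
    correspondence is known): mean per-point distance between the deformed
    estimate and the true deformed points.
    """
    proj_pred2d = np.atleast_2d(proj_pred2d)
    gt2d = np.atleast_2d(gt2d)
    d2, _ = cKDTree(gt2d).query(proj_pred2d)
    report = {"mean_2d_mm": float(d2.mean()), "max_2d_mm": float(d2.max())}
    if pred3d is not None and gt3d is not None:
        pred3d = np.atleast_2d(pred3d)
        gt3d = np.atleast_2d(gt3d)
        if pred3d.shape != gt3d.shape:
            raise ValueError("3D correspondence requires equal shapes")
        d3 = np.linalg.norm(pred3d - gt3d, axis=1)
        report["mean_3d_mm"] = float(d3.mean())
        report["max_3d_mm"] = float(d3.max())
    return report
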