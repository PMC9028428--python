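"""End-to-end orchestration: simulate -> rigid -> reconstruct -> match/select
-> nonrigid -> evaluate.

Runs the full registration chain on a simulation case (or user-supplied
inputs), records per-stage results, and aggregates seeded experiments.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields

import numpy as np

from . import graphrec
from .carm import project
from .energy import EnergyWeights, deform_branches
from .evaluation import add_metric, centerline_distance_report
from .rigid import RigidBounds, RigidParams, projection_distance, register_rigid, \
    transform_tree
from .similarity import SimilarityWeights, projected_thickness, select_candiline
from .synthetic import SimConfig, SimulationCase, make_case
from .vascular import MarkerPairs, VesselTree

__all__ = ["PipelineConfig", "PipelineResult", "run_case", "run_experiment"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the registration chain."""

    bounds: RigidBounds = field(default_factory=RigidBounds)
    multistart: int = 0
    d_cand: float = 3.0                   # candidate-distance threshold, mm
    connect_tol_mm: float = 2.0           # candi-line connection tolerance, mm
    max_paths: int = 10000
    match_n: int = 3                      # matching window half-width, points
    max_dist: float = 5.0                 # H(v) gating distance, mm
    tangent_window: int = 3
    similarity: SimilarityWeights = field(default_factory=SimilarityWeights)
    energy: EnergyWeights = field(default_factory=EnergyWeights)
    step: float = 0.05
    max_iter: int = 500
    tol: float = 1e-6
    rematch_every: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "bounds" in kwargs and isinstance(kwargs["bounds"], dict):
            kwargs["bounds"] = RigidBounds(**kwargs["bounds"])
        if "similarity" in kwargs and isinstance(kwargs["similarity"], dict):
            kwargs["similarity"] = SimilarityWeights(**kwargs["similarity"])
        if "energy" in kwargs and isinstance(kwargs["energy"], dict):
            kwargs["energy"] = EnergyWeights(**kwargs["energy"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    rigid_params: RigidParams
    rigid_distance: float
    selected: dict                        # edge id -> CandiLine or None
    deformed: dict                        # edge id -> (N, 3) final points
    report: dict
    stage_seconds: dict
    energy_trace: list


def _stage(log: dict, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log[name] = t1 - t0
    return t1


def run_case(case: SimulationCase, config: PipelineConfig = PipelineConfig(),
             skip_nonrigid: bool = False, skip_rigid: bool = False) -> PipelineResult:
    """Run rigid -> graph -> match/select -> nonrigid -> evaluate on one case.

    ``skip_rigid`` keeps the model at its given pose (identity parameters),
    for stage-isolated studies of the later stages; ``skip_nonrigid`` stops
    after selection.
    """
    geometry = case.geometry
    log: dict = {}
    t = time.perf_counter()

    # -- rigid ---------------------------------------------------------
    pts3 = case.tree3d.all_points()
    pts2 = case.tree2d.all_points()
    if skip_rigid:
        params = RigidParams(center=pts3.mean(axis=0))
        rigid_dist = projection_distance(pts3, pts2, geometry, params)
        registered = case.tree3d.copy()
    else:
        params, rigid_dist = register_rigid(pts3, pts2, geometry, config.bounds,
                                            multistart=config.multistart,
                                            seed=case.seed)
        registered = transform_tree(case.tree3d, params)
    t = _stage(log, "rigid", t)

    # -- graph reconstruction -----------------------------------------
    graph2d = graphrec.build_2d_graph(case.tree2d)
    connect_tol = config.connect_tol_mm
    projected3d = {e: project(registered.edge_centerline(*e).points, geometry)
                   for e in sorted(registered.edges())}
    cands = graphrec.candidate_segments(projected3d, graph2d, config.d_cand)
    candilines = graphrec.enumerate_candilines(cands, graph2d, config.max_paths,
                                               connect_tol)
    candilines = graphrec.prune_by_parent_connectivity(candilines, registered,
                                                       connect_tol)
    t = _stage(log, "reconstruct", t)

    # -- similarity selection ------------------------------------------
    selected: dict = {}
    for e in sorted(projected3d):
        lines = candilines.get(e, [])
        if not lines:
            selected[e] = None
            continue
        th3d = projected_thickness(registered.edge_centerline(*e), geometry)
        best, cmap, scores = select_candiline(
            projected3d[e], lines, th3d, config.similarity,
            n=config.match_n, max_dist=config.max_dist, window=config.tangent_window)
        selected[e] = best
    t = _stage(log, "select", t)

    # -- nonrigid ------------------------------------------------------
    edge_order = sorted(projected3d)
    branches = [registered.edge_centerline(*e).points.copy() for e in edge_order]
    cand_pts = []
    for e, b in zip(edge_order, branches):
        if selected[e] is not None:
            cand_pts.append(selected[e].points)
        else:
            cand_pts.append(project(b, geometry))  # no hypothesis: hold in place
    if skip_nonrigid:
        deformed = {e: b for e, b in zip(edge_order, branches)}
        trace = []
    else:
        state = deform_branches(branches, cand_pts, geometry, config.energy,
                                step=config.step, max_iter=config.max_iter,
                                tol=config.tol, rematch_every=config.rematch_every,
                                max_dist=config.max_dist, n=config.match_n,
                                window=config.tangent_window)
        deformed = {e: b for e, b in zip(edge_order, state.branches)}
        trace = state.energy_trace
    t = _stage(log, "nonrigid", t)

    # -- evaluation ----------------------------------------------------
    report = evaluate_case(case, registered, deformed, params, rigid_dist)
    _stage(log, "evaluate", t)
    return PipelineResult(rigid_params=params, rigid_distance=rigid_dist,
                          selected=selected, deformed=deformed, report=report,
                          stage_seconds=log, energy_trace=trace)


def _marker_estimate(case: SimulationCase, registered: VesselTree,
                     deformed: dict) -> MarkerPairs:
    est, truth = [], []
    for kind, locator, true_pt in case.markers:
        if kind == "vertex":
            vid = locator
            # a vertex is the endpoint of some incident edge's centerline
            u, v = next(iter(sorted(e for e in deformed
                                    if vid in e)))
            pts = deformed[(u, v)]
            est.append(pts[0] if u == vid else pts[-1])
        else:
            (u, v), idx = locator
            e = (u, v) if (u, v) in deformed else (v, u)
            est.append(deformed[e][idx])
        truth.append(true_pt)
    return MarkerPairs(np.array(est), np.array(truth))


def evaluate_case(case: SimulationCase, registered: VesselTree,
                  deformed: dict, params: RigidParams, rigid_dist: float) -> dict:
    geometry = case.geometry
    gt2d = case.tree2d_clean.all_points()

    pre_pts = np.vstack([registered.edge_centerline(*e).points
                         for e in sorted(deformed)])
    post_pts = np.vstack([deformed[e] for e in sorted(deformed)])
    true_pts = np.vstack([case.true_points(e) for e in sorted(deformed)])
    pre2d = centerline_distance_report(project(pre_pts, geometry), gt2d)
    post = centerline_distance_report(project(post_pts, geometry), gt2d,
                                      pred3d=post_pts, gt3d=true_pts)
    markers = _marker_estimate(case, registered, deformed)
    # rigid recovery errors (in-plane / out-of-plane split along the view axis)
    view_dir = geometry.rotation().T @ np.array([0.0, 0.0, 1.0])
    dt = params.translation - case.true_rigid.translation
    depth_err = float(np.dot(dt, view_dir))
    inplane_err = float(np.linalg.norm(dt - depth_err * view_dir))
    rot_err = params.rotation_deg - case.true_rigid.rotation_deg
    return {
        "rigid": {
            "final_distance_mm": rigid_dist,
            "translation_error_mm": [float(x) for x in dt],
            "inplane_translation_error_mm": inplane_err,
            "depth_translation_error_mm": depth_err,
            "rotation_error_deg": [float(x) for x in rot_err],
            "max_abs_rotation_error_deg": float(np.max(np.abs(rot_err))),
        },
        "pre_deformation_2d_mm": pre2d["mean_2d_mm"],
        "post_deformation_2d_mm": post["mean_2d_mm"],
        "post_deformation_3d_mm": post["mean_3d_mm"],
        "marker_add_mm": add_metric(markers),
        # detector-plane marker error: what marker evaluation on an angiogram sees
        "marker_add_2d_mm": add_metric(MarkerPairs(project(markers.p, geometry),
                                                   project(markers.q, geometry))),
    }


def run_experiment(n_cases: int, sim_config: SimConfig = SimConfig(),
                   config: PipelineConfig = PipelineConfig(), seed: int = 0,
                   skip_nonrigid: bool = False, skip_rigid: bool = False) -> dict:
    """Run the pipeline over seeded cases and aggregate the metrics."""
    if n_cases < 1:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(seed)
    case_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, n_cases)]
    rows = []
    for cs in case_seeds:
        case = make_case(sim_config, cs)
        res = run_case(case, config, skip_nonrigid=skip_nonrigid, skip_rigid=skip_rigid)
        r = res.report
        rows.append({
            "seed": cs,
            "inplane_translation_error_mm": r["rigid"]["inplane_translation_error_mm"],
            "depth_translation_error_mm": r["rigid"]["depth_translation_error_mm"],
            "max_abs_rotation_error_deg": r["rigid"]["max_abs_rotation_error_deg"],
            "rigid_final_distance_mm": r["rigid"]["final_distance_mm"],
            "pre_deformation_2d_mm": r["pre_deformation_2d_mm"],
            "post_deformation_2d_mm": r["post_deformation_2d_mm"],
            "post_deformation_3d_mm": r["post_deformation_3d_mm"],
            "marker_add_mm": r["marker_add_mm"],
            "marker_add_2d_mm": r["marker_add_2d_mm"],
        })
    keys = [k for k in rows[0] if k != "seed"]
    summary = {f"median_{k}": float(np.median([row[k] for row in rows])) for k in keys}
    summary.update({f"mean_{k}": float(np.mean([row[k] for row in rows])) for k in keys})
    return {"cases": rows, "summary": summary, "case_seeds": case_seeds}
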