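import numpy as np
import pytest

from cororeg.graphrec import CandiLine
from cororeg.matching import match_points, matched_distance_stats
from cororeg.similarity import (SimilarityWeights, gradient_term, length_term,
                                score_candiline, select_candiline,
                                thickness_term)


def straight(n=30, y=0.0, x0=0.0, dx=1.0):
    return np.stack([x0 + dx * np.arange(n), np.full(n, y)], axis=1)


def as_candiline(points, radius=None, eid=((0, 1),)):
    return CandiLine(tuple(eid), np.asarray(points, float),
                     None if radius is None else np.asarray(radius, float))


class TestGradientTerm:
    def test_coincident_curves_zero(self):
        proj = straight()
        cmap = match_points(proj, proj, max_dist=np.inf)
        assert gradient_term(proj, cmap) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_offset_lines_give_unity(self):
        # line distance 2 mm, matched d2 2 mm -> 2/2 = 1 per pair
        proj = straight()
        cand = straight(y=2.0)
        cmap = match_points(proj, cand, n=0, line_weight=0.0, max_dist=np.inf)
        assert gradient_term(proj, cmap) == pytest.approx(1.0, rel=1e-9)

    def test_matches_per_pair_loop(self, rng):
        t = np.linspace(0, np.pi, 40)
        proj = np.stack([15 * np.cos(t), 9 * np.sin(t)], axis=1)
        cand = proj + rng.normal(scale=0.5, size=proj.shape)
        cmap = match_points(proj, cand, max_dist=np.inf)
        from cororeg.vascular import tangent_direction
        vals = []
        for i in range(len(proj)):
            d = tangent_direction(proj, i, 3)
            c = cmap.points2d[i]
            line_d = abs(d[0] * (c[1] - proj[i, 1]) - d[1] * (c[0] - proj[i, 0]))
            vals.append(line_d / max(cmap.d2[i], 0.1))
        assert gradient_term(proj, cmap) == pytest.approx(np.mean(vals), rel=1e-12)

    def test_no_valid_matches_is_inf(self):
        proj = straight()
        cmap = match_points(proj, straight(y=100.0), max_dist=1.0)
        assert gradient_term(proj, cmap) == np.inf


class TestThicknessTerm:
    def test_equal_thickness_zero(self):
        valid = np.ones(10, bool)
        assert thickness_term(np.full(10, 2.0), np.full(10, 2.0), valid) == 0.0

    def test_constant_difference_is_that_difference(self):
        valid = np.ones(10, bool)
        assert thickness_term(np.full(10, 3.0), np.full(10, 2.0), valid) == \
            pytest.approx(1.0)

    def test_rms_and_mean_square_variants(self, rng):
        th3 = rng.uniform(1, 3, 20)
        th2 = rng.uniform(1, 3, 20)
        valid = rng.random(20) > 0.3
        ms = np.mean((th3[valid] - th2[valid]) ** 2)
        assert thickness_term(th3, th2, valid, rms=False) == pytest.approx(ms)
        assert thickness_term(th3, th2, valid, rms=True) == pytest.approx(np.sqrt(ms))


class TestLengthTerm:
    def test_equal_lengths_zero(self):
        proj = straight()
        assert length_term(proj, proj.copy()) == 0.0

    def test_half_length_candiline(self):
        assert length_term(straight(21), straight(11)) == pytest.approx(0.5)

    def test_fifteen_percent(self):
        # 20 mm segment vs 23 mm candi-line -> 0.15
        assert length_term(straight(21), straight(24)) == pytest.approx(0.15)

    def test_zero_length_error(self):
        proj = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            length_term(proj, straight())


class TestSelectCandiline:
    def test_single_candidate_returned(self):
        proj = straight()
        cl = as_candiline(straight(y=1.0))
        best, cmap, scores = select_candiline(proj, [cl])
        assert best is cl
        assert len(scores) == 1

    def test_length_mismatched_decoy_loses(self):
        # same mean distance, but the decoy is half the length: delta * D_L decides
        proj = straight(30)
        true_cl = as_candiline(straight(30, y=1.0), eid=((0, 1),))
        decoy = as_candiline(straight(15, y=-1.0), eid=((2, 3),))
        best, _, scores = select_candiline(proj, [true_cl, decoy])
        assert best is true_cl
        # oracle: both have d2 = 1; decoy pays the relative-length penalty
        w = SimilarityWeights()
        assert scores[0].total < scores[1].total
        assert scores[1].d_l == pytest.approx(0.5, abs=0.02)

    def test_equals_exhaustive_scoring(self, rng):
        proj = np.cumsum(rng.normal(size=(25, 2)), axis=0)
        cls = [as_candiline(np.cumsum(rng.normal(size=(20, 2)), axis=0) + s,
                            eid=((s, s + 1),))
               for s in range(4)]
        best, _, scores = select_candiline(proj, cls, max_dist=np.inf)
        oracle = [score_candiline(proj, cl, max_dist=np.inf)[0].total for cl in cls]
        assert best.key() == cls[int(np.argmin(oracle))].key()
        assert scores[0].total == pytest.approx(min(oracle))

    def test_distance_only_weights_reduce_to_min_mean_distance(self, rng):
        proj = np.cumsum(rng.normal(size=(25, 2)), axis=0)
        cls = [as_candiline(proj + np.array([0.0, off]), eid=((int(off * 10), 0),))
               for off in (0.5, 1.5, 3.0)]
        w = SimilarityWeights(alpha=0.0, beta=1.0, gamma=0.0, delta=0.0)
        best, _, scores = select_candiline(proj, cls, weights=w, max_dist=np.inf)
        assert best.key() == cls[0].key()
        # with beta-only weights the score IS the mean matched distance
        oracle = [matched_distance_stats(
            match_points(proj, cl.points, max_dist=np.inf))["mean_d2"]
            for cl in cls]
        assert scores[0].total == pytest.approx(min(oracle), rel=1e-12)

    def test_scale_behaviour(self):
        proj = straight(30)
        cl = as_candiline(straight(30, y=1.0))
        s1, _ = score_candiline(proj, cl, max_dist=np.inf)
        s2, _ = score_candiline(proj * 2, as_candiline(straight(30, y=2.0, dx=2.0)),
                                max_dist=np.inf)
        assert s2.d2_mean == pytest.approx(2 * s1.d2_mean)
        assert s2.d_l == pytest.approx(s1.d_l, abs=1e-12)
        # the gradient term is a distance ratio: scale-invariant by design
        assert s2.d_theta == pytest.approx(s1.d_theta, abs=1e-9)

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            select_candiline(straight(), [])

    def test_true_chain_selected_on_simulator_case(self, corrupted_case):
        from cororeg.carm import project
        from cororeg.graphrec import (build_2d_graph, candidate_segments,
                                      enumerate_candilines,
                                      prune_by_parent_connectivity)
        from cororeg.similarity import projected_thickness
        case = corrupted_case
        g2 = build_2d_graph(case.tree2d)
        projected = {e: project(case.tree3d.edge_centerline(*e).points,
                                case.geometry)
                     for e in sorted(case.tree3d.edges())}
        cands = candidate_segments(projected, g2, 3.0)
        lines = enumerate_candilines(cands, g2, connect_tol=2.0)
        lines = prune_by_parent_connectivity(lines, case.tree3d, 2.0)
        chains = case.true_chains(g2, 2.0)
        hits = 0
        for e in projected:
            th3d = projected_thickness(case.tree3d.edge_centerline(*e),
                                       case.geometry)
            best, _, _ = select_candiline(projected[e], lines[e], th3d)
            hits += frozenset(best.edge_ids) == chains[e]
        assert hits >= 6  # at least 6 of 7 edges resolved exactly
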