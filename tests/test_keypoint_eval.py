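"""Verdict taxonomy, ID-switch carry-forward, scene summaries, centroids."""

import numpy as np
import pytest

from vmtrack import (EvalConfig, GroundTruthScene, IdAssignment, KeypointVerdict,
                     Verdict, classify_centroids, classify_keypoints, compute_centroid,
                     detect_id_switches, summarize_scene)

from conftest import (brute_classify, brute_id_switches, make_track, random_scene)


def identity_assignment(n):
    return IdAssignment(mapping={i: i for i in range(n)}, total_cost=0.0,
                        cost_matrix=np.zeros((n, n)))


def single_frame_scene(gt_points, pred_points):
    """Build a 1-frame scene from {(individual, bodypart): (x, y)} dicts."""
    inds = sorted({k[0] for k in gt_points})
    bps = sorted({k[1] for k in gt_points})
    gt_xy = np.full((1, len(inds), len(bps), 2), np.nan)
    pr_xy = np.full((1, len(inds), len(bps), 2), np.nan)
    for (g, b), xy in gt_points.items():
        gt_xy[0, inds.index(g), bps.index(b)] = xy
    for (g, b), xy in pred_points.items():
        pr_xy[0, inds.index(g), bps.index(b)] = xy
    gt = GroundTruthScene(track=make_track(gt_xy, individuals=inds, bodyparts=bps))
    pred = make_track(pr_xy, individuals=inds, bodyparts=bps)
    return pred, gt


class TestVerdictRules:
    """The five-way classification with corresponding-GT priority."""

    def test_corresponding_gt_priority_over_nearer_wrong_id(self):
        # prediction 5 px from its own GT but only 3 px from another animal's
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("b", "kp1"): (8, 0)},
            pred_points={("a", "kp1"): (5, 0), ("b", "kp1"): (200, 200)},
        )
        verdicts = classify_keypoints(pred, gt, identity_assignment(2))
        by = {(v.gt_individual, v.bodypart): v for v in verdicts}
        v = by[("a", "kp1")]
        assert v.verdict is Verdict.MATCH
        assert v.matched_gt == ("a", "kp1")
        assert v.distance == 5.0

    def test_id_mismatch_fp_same_bodypart_wrong_individual(self):
        # 15 px from its own GT, 6 px from the same bodypart of the other animal
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("b", "kp1"): (21, 0)},
            pred_points={("a", "kp1"): (15, 0), ("b", "kp1"): (300, 300)},
        )
        verdicts = classify_keypoints(pred, gt, identity_assignment(2))
        v = {(v.gt_individual, v.bodypart): v for v in verdicts}[("a", "kp1")]
        assert v.verdict is Verdict.ID_MISMATCH_FP
        assert v.matched_gt == ("b", "kp1")

    def test_bodypart_mismatch_fp_any_individual(self):
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("a", "kp2"): (20, 0)},
            pred_points={("a", "kp1"): (14, 0), ("a", "kp2"): (20, 0)},
        )
        verdicts = classify_keypoints(pred, gt, identity_assignment(1))
        v = {(v.gt_individual, v.bodypart): v for v in verdicts}[("a", "kp1")]
        assert v.verdict is Verdict.BODYPART_MISMATCH_FP
        assert v.matched_gt == ("a", "kp2")

    def test_deviating_fp_and_fn(self):
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("a", "kp2"): (50, 0)},
            pred_points={("a", "kp1"): (25, 0)},     # kp2 has no prediction
        )
        by = {(v.gt_individual, v.bodypart): v
              for v in classify_keypoints(pred, gt, identity_assignment(1))}
        assert by[("a", "kp1")].verdict is Verdict.DEVIATING_FP
        assert by[("a", "kp2")].verdict is Verdict.FN
        assert by[("a", "kp2")].distance is None

    def test_within_means_at_most_threshold(self):
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0)},
            pred_points={("a", "kp1"): (10, 0)},     # exactly on the boundary
        )
        verdicts = classify_keypoints(pred, gt, identity_assignment(1))
        assert verdicts[0].verdict is Verdict.MATCH

    def test_nearest_gt_decides_fp_subtype(self):
        # both a wrong-bodypart GT (4 px) and a wrong-ID same-bodypart GT (7 px)
        # are in range; the nearest (bodypart) decides
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("a", "kp2"): (24, 0),
                       ("b", "kp1"): (27, 0), ("b", "kp2"): (300, 300)},
            pred_points={("a", "kp1"): (20, 0), ("a", "kp2"): (24, 0),
                         ("b", "kp1"): (27, 0), ("b", "kp2"): (300, 300)},
        )
        v = {(v.gt_individual, v.bodypart): v
             for v in classify_keypoints(pred, gt, identity_assignment(2))}[("a", "kp1")]
        assert v.verdict is Verdict.BODYPART_MISMATCH_FP
        assert v.matched_gt == ("a", "kp2")

    def test_unannotated_gt_cells_are_excluded(self):
        pred, gt = single_frame_scene(
            gt_points={("a", "kp1"): (0, 0), ("a", "kp2"): (50, 50)},
            pred_points={("a", "kp1"): (0, 0), ("a", "kp2"): (50, 50)},
        )
        gt.track.coords[0, 0, 1] = np.nan          # kp2 unannotated
        verdicts = classify_keypoints(pred, gt, identity_assignment(1))
        assert len(verdicts) == 1
        assert verdicts[0].bodypart == "kp1"


def _series_scene(positions_a, positions_b, pred_for_a):
    """n-frame scene with two stationary animals; animal a's prediction hops
    between them (or goes missing/far) per ``pred_for_a``."""
    nf = len(pred_for_a)
    gt_xy = np.zeros((nf, 2, 1, 2))
    gt_xy[:, 0, 0] = positions_a
    gt_xy[:, 1, 0] = positions_b
    pr_xy = np.zeros((nf, 2, 1, 2))
    pr_xy[:, 1, 0] = (500.0, 500.0)
    for f, spec in enumerate(pred_for_a):
        if spec == "A":
            pr_xy[f, 0, 0] = positions_a
        elif spec == "B":
            pr_xy[f, 0, 0] = positions_b
        elif spec == "FN":
            pr_xy[f, 0, 0] = np.nan
        elif spec == "DEV":
            pr_xy[f, 0, 0] = (250.0, 250.0)
    gt = GroundTruthScene(track=make_track(gt_xy, individuals=["a", "b"],
                                           bodyparts=["kp1"]))
    pred = make_track(pr_xy, individuals=["a", "b"], bodyparts=["kp1"])
    return pred, gt


class TestIdSwitchCarryForward:
    A, B = (0.0, 0.0), (100.0, 0.0)

    def _switch_frames(self, sequence):
        pred, gt = _series_scene(self.A, self.B, sequence)
        verdicts = classify_keypoints(pred, gt, identity_assignment(2))
        return [v.frame for v in verdicts
                if v.gt_individual == "a" and v.id_switch]

    def test_plain_identity_change_flags_switch(self):
        assert self._switch_frames(["A", "A", "B"]) == [2]

    def test_carry_across_fn_no_switch(self):
        assert self._switch_frames(["A", "FN", "A"]) == []

    def test_carry_across_deviating_detects_switch(self):
        assert self._switch_frames(["A", "DEV", "B"]) == [2]

    def test_carry_across_long_gap(self):
        assert self._switch_frames(["A", "FN", "DEV", "FN", "B", "B"]) == [4]

    def test_first_matched_frame_never_a_switch(self):
        assert self._switch_frames(["FN", "B", "B"]) == []

    def test_switch_back_counts_again(self):
        assert self._switch_frames(["A", "B", "A"]) == [1, 2]


class TestSummarize:
    def _verdict(self, kind, frame=0, dist=None, switch=False):
        return KeypointVerdict(frame=frame, gt_individual="a", bodypart="kp",
                               verdict=Verdict[kind], distance=dist, id_switch=switch)

    def test_percentages_from_constructed_counts(self):
        verdicts = ([self._verdict("MATCH", dist=1.0)] * 80
                    + [self._verdict("FN")] * 10
                    + [self._verdict("DEVIATING_FP", dist=40.0)] * 4
                    + [self._verdict("ID_MISMATCH_FP", dist=30.0)] * 3
                    + [self._verdict("BODYPART_MISMATCH_FP", dist=30.0)] * 3)
        m = summarize_scene(verdicts)
        assert m.n_gt == 100 and m.n_pred == 90
        assert (m.tgt_match_pct, m.fn_pct, m.fp_pct) == (80.0, 10.0, 10.0)
        assert m.pred_match_pct == pytest.approx(100 * 80 / 90, abs=1e-9)
        assert m.bodypart_match_pct == pytest.approx(100 * 83 / 90)

    def test_all_perfect(self):
        m = summarize_scene([self._verdict("MATCH", dist=0.0)] * 10)
        assert m.tgt_match_pct == 100.0 and m.fn_pct == 0.0 and m.fp_pct == 0.0
        assert m.rmse == 0.0

    def test_zero_fn_makes_tgt_equal_pred_match(self, rng):
        pred, gt = random_scene(rng, n_frames=6)
        verdicts = classify_keypoints(pred, gt, identity_assignment(3))
        verdicts = [v for v in verdicts if v.verdict is not Verdict.FN]
        m = summarize_scene(verdicts)
        assert m.fn_pct == 0.0
        assert m.tgt_match_pct == pytest.approx(m.pred_match_pct)

    def test_rmse_covers_all_predictions_with_annotated_gt(self):
        verdicts = [self._verdict("MATCH", dist=3.0),
                    self._verdict("DEVIATING_FP", dist=4.0)]
        m = summarize_scene(verdicts)
        assert m.rmse == pytest.approx(np.sqrt((9 + 16) / 2))
        m2 = summarize_scene(verdicts, rmse_matches_only=True)
        assert m2.rmse == 3.0

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError, match="empty scene"):
            summarize_scene([])


class TestConservationProperties:
    def test_partition_and_subtype_sums(self, rng):
        for _ in range(60):
            pred, gt = random_scene(rng,
                                    n_animals=int(rng.integers(1, 6)),
                                    n_bodyparts=int(rng.integers(2, 7)),
                                    n_frames=int(rng.integers(2, 10)))
            verdicts = classify_keypoints(pred, gt,
                                          identity_assignment(gt.track.n_individuals))
            m = summarize_scene(verdicts)
            assert m.tgt_match_pct + m.fn_pct + m.fp_pct == pytest.approx(100.0)
            assert (m.deviating_fp_pct + m.id_mismatch_fp_pct
                    + m.bodypart_mismatch_fp_pct) == pytest.approx(m.fp_pct)
            assert m.pred_match_pct <= m.bodypart_match_pct + 1e-12

    def test_raising_threshold_never_decreases_tgt_match(self, rng):
        pred, gt = random_scene(rng, n_frames=10)
        asg = identity_assignment(3)
        last = -1.0
        for tau in (2.0, 5.0, 10.0, 20.0, 50.0):
            m = summarize_scene(classify_keypoints(pred, gt, asg,
                                                   EvalConfig(kp_threshold=tau)))
            assert m.tgt_match_pct >= last
            last = m.tgt_match_pct


class TestAgainstBruteForce:
    def test_verdicts_match_nested_loop_oracle(self, rng):
        for _ in range(40):
            n_animals = int(rng.integers(1, 6))
            pred, gt = random_scene(rng, n_animals=n_animals,
                                    n_bodyparts=int(rng.integers(2, 7)),
                                    n_frames=int(rng.integers(2, 12)))
            asg = identity_assignment(n_animals)
            mine = classify_keypoints(pred, gt, asg)
            oracle = brute_classify(pred, gt, dict(enumerate(range(n_animals))), 10.0)
            assert len(mine) == len(oracle)
            inds, bps = gt.track.individuals, gt.track.bodyparts
            for v in mine:
                key = (v.frame, inds.index(v.gt_individual), bps.index(v.bodypart))
                kind, matched = oracle[key]
                assert v.verdict.value == kind, (key, v.verdict, kind)
                if matched is not None:
                    assert v.matched_gt == (inds[matched[0]], bps[matched[1]])
            switch_frames = {(v.frame, inds.index(v.gt_individual),
                              bps.index(v.bodypart))
                             for v in mine if v.id_switch}
            assert switch_frames == brute_id_switches(oracle)


class TestCentroids:
    def test_mean_of_available_points(self):
        assert compute_centroid(np.array([[0.0, 0.0], [2.0, 2.0]])).tolist() == [1.0, 1.0]

    def test_single_available_point_is_the_centroid(self):
        pts = np.array([[np.nan, np.nan], [7.0, 3.0], [np.nan, np.nan]])
        assert compute_centroid(pts).tolist() == [7.0, 3.0]

    def test_no_points_gives_missing(self):
        assert np.isnan(compute_centroid(np.full((4, 2), np.nan))).all()

    def _two_animal_scene(self, pred_centroid_at):
        # animals: vertical 5-part chains at x=0 and x=200
        gt_xy = np.zeros((1, 2, 5, 2))
        gt_xy[0, 0, :, 1] = np.arange(5) * 30.0
        gt_xy[0, 1, :, 0] = 200.0
        gt_xy[0, 1, :, 1] = np.arange(5) * 30.0
        pr_xy = np.full((1, 2, 5, 2), np.nan)
        pr_xy[0, 0, :, :] = pred_centroid_at       # every part at one spot
        pr_xy[0, 1, :, 0] = 200.0
        pr_xy[0, 1, :, 1] = np.arange(5) * 30.0
        gt = GroundTruthScene(track=make_track(gt_xy))
        pred = make_track(pr_xy)
        return pred, gt

    def test_match_within_20px_of_any_mid_axis_point(self):
        pred, gt = self._two_animal_scene((5.0, 60.0))   # 5 px from mid part
        verdicts, summary = classify_centroids(pred, gt, identity_assignment(2))
        assert verdicts[0].verdict is Verdict.MATCH
        assert summary.tgt_match_pct == 100.0

    def test_deviating_when_far_from_all_axis_points(self):
        pred, gt = self._two_animal_scene((100.0, 60.0))
        verdicts, _ = classify_centroids(pred, gt, identity_assignment(2))
        assert verdicts[0].verdict is Verdict.DEVIATING_FP

    def test_id_mismatch_when_near_other_individuals_axis_only(self):
        pred, gt = self._two_animal_scene((190.0, 60.0))  # 10 px from animal 2 axis
        verdicts, summary = classify_centroids(pred, gt, identity_assignment(2))
        assert verdicts[0].verdict is Verdict.ID_MISMATCH_FP
        assert summary.id_mismatch_fp_pct == 50.0

    def test_all_parts_missing_is_centroid_fn(self):
        pred, gt = self._two_animal_scene((0.0, 0.0))
        pred.coords[0, 0, :, :] = np.nan
        verdicts, summary = classify_centroids(pred, gt, identity_assignment(2))
        assert verdicts[0].verdict is Verdict.FN
        assert summary.fn_pct == 50.0
        assert summary.tgt_match_pct + summary.fn_pct + summary.fp_pct == 100.0

    def test_axis_parts_must_exist(self):
        pred, gt = self._two_animal_scene((0.0, 0.0))
        with pytest.raises(ValueError, match="axis_parts"):
            classify_centroids(pred, gt, identity_assignment(2),
                               EvalConfig(axis_parts=["nope"]))
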