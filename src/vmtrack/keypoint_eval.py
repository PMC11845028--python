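"""Keypoint verdict taxonomy, ID-switch detection and scene summaries.

Every annotated ground-truth keypoint (one cell per GT individual, body part
and frame) receives exactly one verdict:

MATCH
    the assigned prediction lies within the threshold of its *corresponding*
    GT keypoint (same identity, same body part) — the corresponding GT takes
    priority even if other GT keypoints are nearer;
FN
    the prediction is missing;
ID_MISMATCH_FP
    the prediction is beyond threshold of its corresponding GT but within
    threshold of the nearest GT keypoint, which has the same body part under
    a different identity;
BODYPART_MISMATCH_FP
    as above but the nearest in-threshold GT keypoint has a different body
    part (any identity);
DEVIATING_FP
    the prediction is beyond threshold of every GT keypoint.

A cell whose verdict carries a matched GT identity (MATCH or either mismatch
FP) is flagged as an ID switch when that identity differs from the cell's
most recent previously matched identity — FN and DEVIATING_FP frames are
skipped when looking back, so a switch is resolved against earlier frames.

Threshold comparisons use distance <= threshold ("within").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matching import IdAssignment
from .model import GroundTruthScene, PoseTrack

__all__ = [
    "Verdict",
    "EvalConfig",
    "KeypointVerdict",
    "SceneMetrics",
    "classify_keypoints",
    "detect_id_switches",
    "summarize_scene",
    "evaluate_scene",
    "compute_centroid",
    "classify_centroids",
    "verdicts_to_frame",
]


class Verdict(str, Enum):
    MATCH = "MATCH"
    FN = "FN"
    DEVIATING_FP = "DEVIATING_FP"
    ID_MISMATCH_FP = "ID_MISMATCH_FP"
    BODYPART_MISMATCH_FP = "BODYPART_MISMATCH_FP"


_FP_VERDICTS = {Verdict.DEVIATING_FP, Verdict.ID_MISMATCH_FP, Verdict.BODYPART_MISMATCH_FP}
# verdicts that carry a matched GT identity usable for ID-switch tracking
_MATCHED_VERDICTS = {Verdict.MATCH, Verdict.ID_MISMATCH_FP, Verdict.BODYPART_MISMATCH_FP}


@dataclass
class EvalConfig:
    """Evaluation thresholds and body-part roles.

    ``kp_threshold`` (default 10 px) decides keypoint matches;
    ``centroid_threshold`` (default 20 px) decides centroid matches against
    the GT individual's ``axis_parts`` (default: the 3 central body parts of
    the chain); ``centroid_parts`` are the predicted parts averaged into the
    centroid (default: all).
    """

    kp_threshold: float = 10.0
    centroid_threshold: float = 20.0
    centroid_parts: Optional[list[str]] = None
    axis_parts: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.kp_threshold <= 0 or self.centroid_threshold <= 0:
            raise ValueError("thresholds must be > 0")

    def resolved_axis_parts(self, bodyparts: Sequence[str]) -> list[str]:
        if self.axis_parts is not None:
            missing = [p for p in self.axis_parts if p not in bodyparts]
            if missing:
                raise ValueError(f"axis_parts {missing} not in track bodyparts")
            return list(self.axis_parts)
        # default: 3 mid-axis parts of the chain
        n = len(bodyparts)
        mid = n // 2
        lo = max(0, mid - 1)
        return list(bodyparts[lo:lo + 3]) if n >= 3 else list(bodyparts)


@dataclass
class KeypointVerdict:
    """Classification record for one (GT individual, body part, frame) cell."""

    frame: int
    gt_individual: str
    bodypart: str
    verdict: Verdict
    matched_gt: Optional[tuple[str, str]] = None   # (individual, bodypart) used
    distance: Optional[float] = None               # px to corresponding GT
    id_switch: bool = False


@dataclass
class SceneMetrics:
    """Per-scene percentage summary.

    GT-denominated percentages (``tgt_match_pct``, ``fn_pct``, ``fp_pct`` and
    its subtypes, ``id_switch_pct``) use the number of annotated GT keypoints;
    prediction-denominated ones (``pred_match_pct``, ``bodypart_match_pct``)
    use the number of non-missing predictions.  ``rmse`` is over all
    non-missing predictions with an annotated corresponding GT.
    """

    tgt_match_pct: float
    fn_pct: float
    fp_pct: float
    id_switch_pct: float
    deviating_fp_pct: float
    id_mismatch_fp_pct: float
    bodypart_mismatch_fp_pct: float
    pred_match_pct: float
    bodypart_match_pct: float
    rmse: float
    n_gt: int
    n_pred: int

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in self.__dict__.items()}


def classify_keypoints(pred: PoseTrack, gt: GroundTruthScene,
                       assignment: IdAssignment, cfg: Optional[EvalConfig] = None,
                       ) -> list[KeypointVerdict]:
    """Classify every annotated GT cell; see the module docstring for rules.

    Verdicts are returned ordered by (frame, GT individual, body part) and
    already carry ID-switch flags (via :func:`detect_id_switches`) when the
    scene is consecutive.
    """
    cfg = cfg or EvalConfig()
    gtrack = gt.track
    if pred.bodyparts != gtrack.bodyparts:
        raise ValueError("prediction and ground truth must share the bodypart list")
    tau = cfg.kp_threshold
    nf, nb = gtrack.n_frames, gtrack.n_bodyparts
    gt_missing = gtrack.missing_mask()
    pred_missing = pred.missing_mask()

    # GT individual g is evaluated against predicted individual assignment⁻¹(g)
    pred_of_gt = {g: p for p, g in assignment.mapping.items()}

    verdicts: list[KeypointVerdict] = []
    for f in range(nf):
        gt_xy = gtrack.coords[f]          # (ng, nb, 2)
        annotated = ~gt_missing[f]
        for g in range(gtrack.n_individuals):
            p = pred_of_gt.get(g)
            for b in range(nb):
                if not annotated[g, b]:
                    continue               # unannotated GT cells are excluded
                cell = KeypointVerdict(frame=f, gt_individual=gtrack.individuals[g],
                                       bodypart=gtrack.bodyparts[b], verdict=Verdict.FN)
                if p is None or pred_missing[f, p, b]:
                    verdicts.append(cell)
                    continue
                pt = pred.coords[f, p, b]
                d_corr = float(np.linalg.norm(pt - gt_xy[g, b]))
                cell.distance = d_corr
                if d_corr <= tau:
                    cell.verdict = Verdict.MATCH
                    cell.matched_gt = (gtrack.individuals[g], gtrack.bodyparts[b])
                else:
                    # nearest annotated GT keypoint within threshold decides the subtype
                    d_all = np.linalg.norm(gt_xy - pt, axis=-1)     # (ng, nb)
                    d_all[~annotated] = np.inf
                    within = d_all <= tau
                    if not within.any():
                        cell.verdict = Verdict.DEVIATING_FP
                    else:
                        d_masked = np.where(within, d_all, np.inf)
                        gi, bi = np.unravel_index(np.argmin(d_masked), d_masked.shape)
                        cell.matched_gt = (gtrack.individuals[gi], gtrack.bodyparts[bi])
                        if bi == b:
                            cell.verdict = Verdict.ID_MISMATCH_FP
                        else:
                            cell.verdict = Verdict.BODYPART_MISMATCH_FP
                verdicts.append(cell)
    if gt.is_consecutive:
        detect_id_switches(verdicts)
    return verdicts


def detect_id_switches(verdicts: list[KeypointVerdict]) -> list[KeypointVerdict]:
    """Set ``id_switch`` flags in place (and return the list).

    For each (GT individual, body part) cell series in frame order, a verdict
    with a matched GT identity is a switch when that identity differs from
    the most recent earlier frame in which the cell had a matched identity;
    FN and DEVIATING_FP frames are skipped.  The first matched frame of a
    cell is never a switch.
    """
    last_identity: dict[tuple[str, str], str] = {}
    for v in sorted(verdicts, key=lambda v: v.frame):
        if v.verdict not in _MATCHED_VERDICTS:
            continue
        key = (v.gt_individual, v.bodypart)
        identity = v.matched_gt[0]
        prev = last_identity.get(key)
        v.id_switch = prev is not None and identity != prev
        last_identity[key] = identity
    return verdicts


def summarize_scene(verdicts: Sequence[KeypointVerdict],
                    n_pred: Optional[int] = None, *,
                    rmse_matches_only: bool = False) -> SceneMetrics:
    """Aggregate verdicts into :class:`SceneMetrics`.

    ``n_pred`` defaults to the number of non-FN verdicts (each corresponds to
    one non-missing prediction with annotated GT).  ``rmse_matches_only``
    restricts the RMSE set to MATCH cells instead of all non-missing
    predictions.
    """
    n_gt = len(verdicts)
    if n_gt == 0:
        raise ValueError("empty scene: no annotated GT keypoints")
    counts = {v: 0 for v in Verdict}
    switches = 0
    sq = []
    for v in verdicts:
        counts[v.verdict] += 1
        switches += v.id_switch
        if v.distance is not None and (v.verdict is Verdict.MATCH or not rmse_matches_only):
            sq.append(v.distance ** 2)
    n_match = counts[Verdict.MATCH]
    n_fn = counts[Verdict.FN]
    n_fp = sum(counts[v] for v in _FP_VERDICTS)
    if n_pred is None:
        n_pred = n_gt - n_fn
    pct = lambda c, denom: 100.0 * c / denom if denom else float("nan")
    return SceneMetrics(
        tgt_match_pct=pct(n_match, n_gt),
        fn_pct=pct(n_fn, n_gt),
        fp_pct=pct(n_fp, n_gt),
        id_switch_pct=pct(switches, n_gt),
        deviating_fp_pct=pct(counts[Verdict.DEVIATING_FP], n_gt),
        id_mismatch_fp_pct=pct(counts[Verdict.ID_MISMATCH_FP], n_gt),
        bodypart_mismatch_fp_pct=pct(counts[Verdict.BODYPART_MISMATCH_FP], n_gt),
        pred_match_pct=pct(n_match, n_pred),
        bodypart_match_pct=pct(n_match + counts[Verdict.ID_MISMATCH_FP], n_pred),
        rmse=float(np.sqrt(np.mean(sq))) if sq else float("nan"),
        n_gt=n_gt,
        n_pred=n_pred,
    )


def evaluate_scene(pred: PoseTrack, gt: GroundTruthScene,
                   cfg: Optional[EvalConfig] = None,
                   assignment: Optional[IdAssignment] = None,
                   ) -> tuple[SceneMetrics, list[KeypointVerdict], IdAssignment]:
    """Pair identities, classify keypoints and summarize in one call."""
    from .matching import pair_ids
    cfg = cfg or EvalConfig()
    if assignment is None:
        assignment = pair_ids(pred, gt)
    verdicts = classify_keypoints(pred, gt, assignment, cfg)
    return summarize_scene(verdicts), verdicts, assignment


def compute_centroid(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the non-missing keypoints in ``points`` (n, 2).

    A single available keypoint is itself the centroid; with none available
    the centroid is MISSING (NaN pair) — a centroid FN.
    """
    points = np.asarray(points, dtype=float)
    ok = ~np.isnan(points[:, 0])
    if not ok.any():
        return np.array([np.nan, np.nan])
    return points[ok].mean(axis=0)


@dataclass
class CentroidSummary:
    """Centroid-evaluation summary: no body-part categories, switches or RMSE."""

    tgt_match_pct: float
    fn_pct: float
    fp_pct: float
    deviating_fp_pct: float
    id_mismatch_fp_pct: float
    pred_match_pct: float
    n_gt: int
    n_pred: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_centroids(pred: PoseTrack, gt: GroundTruthScene,
                       assignment: IdAssignment, cfg: Optional[EvalConfig] = None,
                       ) -> tuple[list[KeypointVerdict], CentroidSummary]:
    """Evaluate per-animal centroids against GT body-axis keypoints.

    The centroid of each predicted individual's ``centroid_parts`` is a MATCH
    when within ``centroid_threshold`` of ANY ``axis_parts`` keypoint of the
    corresponding GT individual, an ID_MISMATCH_FP when only another
    individual's axis keypoints are that close, a DEVIATING_FP otherwise, and
    an FN when no centroid could be computed.
    """
    cfg = cfg or EvalConfig()
    gtrack = gt.track
    axis_parts = cfg.resolved_axis_parts(gtrack.bodyparts)
    axis_idx = [gtrack.bodypart_index(p) for p in axis_parts]
    if cfg.centroid_parts is not None:
        cent_idx = [pred.bodypart_index(p) for p in cfg.centroid_parts]
    else:
        cent_idx = list(range(pred.n_bodyparts))
    tau = cfg.centroid_threshold
    pred_of_gt = {g: p for p, g in assignment.mapping.items()}

    verdicts: list[KeypointVerdict] = []
    for f in range(gtrack.n_frames):
        gt_axis = gtrack.coords[f][:, axis_idx, :]     # (ng, n_axis, 2)
        for g in range(gtrack.n_individuals):
            own = gt_axis[g]
            if np.isnan(own[:, 0]).all():
                continue    # individual not annotated this frame
            cell = KeypointVerdict(frame=f, gt_individual=gtrack.individuals[g],
                                   bodypart="centroid", verdict=Verdict.FN)
            p = pred_of_gt.get(g)
            centroid = (compute_centroid(pred.coords[f, p, cent_idx, :])
                        if p is not None else np.array([np.nan, np.nan]))
            if np.isnan(centroid[0]):
                verdicts.append(cell)
                continue
            d = np.linalg.norm(gt_axis - centroid, axis=-1)   # (ng, n_axis)
            with np.errstate(invalid="ignore"):
                own_min = np.nanmin(d[g]) if not np.isnan(d[g]).all() else np.inf
            cell.distance = float(own_min)
            if own_min <= tau:
                cell.verdict = Verdict.MATCH
                cell.matched_gt = (gtrack.individuals[g], "centroid")
            else:
                d_other = d.copy()
                d_other[g] = np.nan
                with np.errstate(invalid="ignore"):
                    other_ok = np.nanmin(d_other) <= tau if not np.isnan(d_other).all() else False
                if other_ok:
                    gi = int(np.nanargmin(np.nanmin(np.where(np.isnan(d_other), np.inf, d_other),
                                                    axis=1)))
                    cell.verdict = Verdict.ID_MISMATCH_FP
                    cell.matched_gt = (gtrack.individuals[gi], "centroid")
                else:
                    cell.verdict = Verdict.DEVIATING_FP
            verdicts.append(cell)

    n_gt = len(verdicts)
    if n_gt == 0:
        raise ValueError("empty scene: no annotated GT individuals")
    counts = {v: 0 for v in Verdict}
    for v in verdicts:
        counts[v.verdict] += 1
    n_fp = counts[Verdict.DEVIATING_FP] + counts[Verdict.ID_MISMATCH_FP]
    n_pred = n_gt - counts[Verdict.FN]
    pct = lambda c, denom: 100.0 * c / denom if denom else float("nan")
    summary = CentroidSummary(
        tgt_match_pct=pct(counts[Verdict.MATCH], n_gt),
        fn_pct=pct(counts[Verdict.FN], n_gt),
        fp_pct=pct(n_fp, n_gt),
        deviating_fp_pct=pct(counts[Verdict.DEVIATING_FP], n_gt),
        id_mismatch_fp_pct=pct(counts[Verdict.ID_MISMATCH_FP], n_gt),
        pred_match_pct=pct(counts[Verdict.MATCH], n_pred),
        n_gt=n_gt,
        n_pred=n_pred,
    )
    return verdicts, summary


def verdicts_to_frame(verdicts: Sequence[KeypointVerdict]) -> pd.DataFrame:
    """Tidy per-cell verdict table (one row per GT cell)."""
    return pd.DataFrame([
        dict(frame=v.frame, gt_individual=v.gt_individual, bodypart=v.bodypart,
             verdict=v.verdict.value,
             matched_individual=v.matched_gt[0] if v.matched_gt else None,
             matched_bodypart=v.matched_gt[1] if v.matched_gt else None,
             distance=v.distance, id_switch=v.id_switch)
        for v in verdicts
    ])
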