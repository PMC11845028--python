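"""Virtual-marker accuracy: per-marker ID match and assignment patterns.

A virtual marker is a rendered identity cue: a keypoint of the multi-animal
tracking output drawn into the video so a single-animal tracker can follow
identities.  Its quality is scored against ground truth per animal-frame:
a marker's ID matches when it lies within a threshold (10 px) of ANY ground
truth keypoint of the same animal; a missing marker counts as a mismatch,
since it represents an identity cue that should have been present.

With two designated markers per animal, each animal-frame falls into one of
six assignment patterns (both match / one of two matches / neither matches /
single present and matching / single present and not matching / both
missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GroundTruthScene, PoseTrack

__all__ = [
    "VMStatus",
    "VMPattern",
    "VMPatternSummary",
    "vm_id_match",
    "classify_vm_pattern",
    "scene_vm_summary",
]

VM_THRESHOLD_DEFAULT = 10.0


class VMStatus(str, Enum):
    MATCHED = "MATCHED"
    MISMATCHED = "MISMATCHED"
    ABSENT = "ABSENT"


class VMPattern(str, Enum):
    MATCH_TWO_VM = "MATCH_TWO_VM"
    MATCH_ONE_VM = "MATCH_ONE_VM"
    PARTIAL_MATCH_TWO_VM = "PARTIAL_MATCH_TWO_VM"
    NO_MATCH_TWO_VM = "NO_MATCH_TWO_VM"
    NO_MATCH_ONE_VM = "NO_MATCH_ONE_VM"
    MISSING_NO_VM = "MISSING_NO_VM"


@dataclass
class VMPatternSummary:
    """Scene-level virtual-marker quality.

    ``proportions`` sum to 1 over animal-frames; ``id_matched_vm_pct`` is
    MATCHED markers over the expected-marker denominator (2 x animals x
    frames), so ABSENT markers depress it.
    """

    proportions: dict[VMPattern, float]
    id_matched_vm_pct: float
    per_animal_frame: pd.DataFrame
    n_animal_frames: int

    def to_dict(self) -> dict:
        return {
            "id_matched_vm_pct": self.id_matched_vm_pct,
            "n_animal_frames": self.n_animal_frames,
            **{p.value: self.proportions[p] for p in VMPattern},
        }


def vm_id_match(marker: np.ndarray, gt_individual_keypoints: np.ndarray,
                threshold: float = VM_THRESHOLD_DEFAULT) -> VMStatus:
    """ID-match status of one marker against its own animal's GT keypoints.

    MATCHED when within ``threshold`` of any same-animal GT keypoint,
    MISMATCHED otherwise, ABSENT when the marker itself is missing.
    """
    marker = np.asarray(marker, dtype=float)
    if np.isnan(marker).any():
        return VMStatus.ABSENT
    pts = np.asarray(gt_individual_keypoints, dtype=float).reshape(-1, 2)
    pts = pts[~np.isnan(pts[:, 0])]
    if len(pts) == 0:
        raise ValueError("ground-truth keypoint set for the animal is empty")
    d = np.linalg.norm(pts - marker, axis=1)
    return VMStatus.MATCHED if float(d.min()) <= threshold else VMStatus.MISMATCHED


def classify_vm_pattern(status_a: VMStatus, status_b: VMStatus) -> VMPattern:
    """Six-way assignment pattern of an animal-frame's two markers (symmetric)."""
    pair = sorted([status_a, status_b], key=lambda s: s.value)
    n_absent = pair.count(VMStatus.ABSENT)
    n_matched = pair.count(VMStatus.MATCHED)
    if n_absent == 2:
        return VMPattern.MISSING_NO_VM
    if n_absent == 1:
        return VMPattern.MATCH_ONE_VM if n_matched == 1 else VMPattern.NO_MATCH_ONE_VM
    if n_matched == 2:
        return VMPattern.MATCH_TWO_VM
    if n_matched == 1:
        return VMPattern.PARTIAL_MATCH_TWO_VM
    return VMPattern.NO_MATCH_TWO_VM


def scene_vm_summary(vm_track: PoseTrack, gt: GroundTruthScene,
                     marker_parts: Optional[Sequence[str]] = None,
                     threshold: float = VM_THRESHOLD_DEFAULT, *,
                     individual_map: Optional[dict[str, str]] = None,
                     ) -> VMPatternSummary:
    """Score a scene's virtual markers against ground truth.

    ``marker_parts`` names the two designated marker body parts of
    ``vm_track`` (default: its first two).  ``individual_map`` maps vm-track
    individual labels to GT labels; by default labels correspond by name if
    shared, else by position.
    """
    gtrack = gt.track
    if marker_parts is None:
        marker_parts = vm_track.bodyparts[:2]
    if len(marker_parts) != 2:
        raise ValueError("exactly two marker bodyparts are expected")
    for p in marker_parts:
        if p not in vm_track.bodyparts:
            raise ValueError(f"marker bodypart {p!r} not in vm track")
    if vm_track.n_frames != gtrack.n_frames:
        raise ValueError("vm track and ground truth must cover the same frames")

    if individual_map is None:
        if set(vm_track.individuals) == set(gtrack.individuals):
            individual_map = {s: s for s in vm_track.individuals}
        elif vm_track.n_individuals == gtrack.n_individuals:
            individual_map = dict(zip(vm_track.individuals, gtrack.individuals))
        else:
            raise ValueError("individual correspondence ambiguous; pass individual_map")

    ia, ib = (vm_track.bodypart_index(p) for p in marker_parts)
    rows = []
    counts = {p: 0 for p in VMPattern}
    n_matched_markers = 0
    for vm_label, gt_label in individual_map.items():
        vi = vm_track.individual_index(vm_label)
        gi = gtrack.individual_index(gt_label)
        for f in range(vm_track.n_frames):
            gt_pts = gtrack.coords[f, gi]
            sa = vm_id_match(vm_track.coords[f, vi, ia], gt_pts, threshold)
            sb = vm_id_match(vm_track.coords[f, vi, ib], gt_pts, threshold)
            pattern = classify_vm_pattern(sa, sb)
            counts[pattern] += 1
            n_matched_markers += (sa is VMStatus.MATCHED) + (sb is VMStatus.MATCHED)
            rows.append(dict(frame=f, individual=vm_label,
                             status_a=sa.value, status_b=sb.value,
                             pattern=pattern.value))
    n_af = len(rows)
    if n_af == 0:
        raise ValueError("no animal-frames to evaluate")
    proportions = {p: counts[p] / n_af for p in VMPattern}
    id_matched_pct = 100.0 * n_matched_markers / (2 * n_af)
    return VMPatternSummary(proportions=proportions, id_matched_vm_pct=id_matched_pct,
                            per_animal_frame=pd.DataFrame(rows), n_animal_frames=n_af)
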