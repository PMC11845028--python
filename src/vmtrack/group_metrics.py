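"""Collective-behavior and body-geometry metrics.

Fish-school metrics: the per-frame variance of adjacent body-axis keypoint
distances (equidistant keypoints ⇒ zero variance; large variance flags bad
tracking), IQR-fence outlier counts over a pooled reference, heading angles
from the two anterior keypoints, per-frame heading cosine similarity across
the school, and counts of abnormal (>90°) frame-to-frame heading flips.

Dance metrics: each individual's pose is summarized per frame as the z-scored
upper triangle of its pairwise keypoint distance matrix — invariant to
translation, rotation and uniform scaling — and pose similarity between
individuals is the RMSD between those standardized matrices.

Stray-keypoint overlap: fraction of frames in which two individuals' same-
named keypoints lie closer than a threshold.

Angles use the standard mathematical convention on raw pixel coordinates
(the image y-axis points down, but every metric here is a difference of
angles, which is flip-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PoseTrack

__all__ = [
    "adjacent_distance_variance",
    "track_adjacent_variance",
    "iqr_outlier_count",
    "heading_angle",
    "track_headings",
    "group_cos_sim",
    "heading_flip_count",
    "standardized_distance_matrix",
    "pose_rmsd",
    "frame_mean_rmsd",
    "overlap_frequency",
]


def adjacent_distance_variance(chain: np.ndarray) -> float:
    """Population variance of adjacent-keypoint distances along one body chain.

    ``chain`` is (n, 2) ordered head→tail.  Any missing keypoint (or fewer
    than 3 points) makes the statistic MISSING (NaN) for the frame.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or chain.shape[0] < 3:
        return float("nan")
    if np.isnan(chain).any():
        return float("nan")
    d = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    return float(np.var(d))          # population variance (ddof=0)


def track_adjacent_variance(track: PoseTrack,
                            chain_parts: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tidy (frame, individual, variance) table over a whole track."""
    t = track if chain_parts is None else track.select_bodyparts(chain_parts)
    rows = []
    for f in range(t.n_frames):
        for i, ind in enumerate(t.individuals):
            rows.append(dict(frame=f, individual=ind,
                             variance=adjacent_distance_variance(t.coords[f, i])))
    return pd.DataFrame(rows)


def iqr_outlier_count(values: dict[str, np.ndarray],
                      pooled_reference: np.ndarray,
                      ) -> tuple[float, dict[str, int]]:
    """Upper-fence outlier counts per individual against a pooled threshold.

    The fence is Q3 + 1.5 x IQR of ``pooled_reference`` (linear-interpolation
    quantiles); only the upper fence is used, since only large values signal
    tracking failure.  Returns ``(threshold, {individual: count})`` counting
    frames with value strictly above the fence; NaNs are ignored.
    """
    pooled = np.asarray(pooled_reference, dtype=float)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("pooled reference contains no observed values")
    q1, q3 = np.percentile(pooled, [25, 75])
    fence = float(q3 + 1.5 * (q3 - q1))
    counts = {}
    for ind, v in values.items():
        v = np.asarray(v, dtype=float)
        counts[ind] = int(np.sum(v[~np.isnan(v)] > fence))
    return fence, counts


def heading_angle(anterior: np.ndarray, second: np.ndarray) -> float:
    """Angle (radians, (-pi, pi]) of the vector from the second keypoint to
    the anterior one; NaN when either point is missing or they coincide."""
    anterior = np.asarray(anterior, dtype=float)
    second = np.asarray(second, dtype=float)
    if np.isnan(anterior).any() or np.isnan(second).any():
        return float("nan")
    v = anterior - second
    if v[0] == 0.0 and v[1] == 0.0:
        return float("nan")
    ang = float(np.arctan2(v[1], v[0]))
    return np.pi if ang == -np.pi else ang


def track_headings(track: PoseTrack, anterior_part: Optional[str] = None,
                   second_part: Optional[str] = None) -> np.ndarray:
    """(frames, individuals) heading angles from the two anterior keypoints."""
    ia = 0 if anterior_part is None else track.bodypart_index(anterior_part)
    ib = 1 if second_part is None else track.bodypart_index(second_part)
    out = np.full((track.n_frames, track.n_individuals), np.nan)
    for f in range(track.n_frames):
        for i in range(track.n_individuals):
            out[f, i] = heading_angle(track.coords[f, i, ia], track.coords[f, i, ib])
    return out


def group_cos_sim(headings: np.ndarray) -> float:
    """Mean cosine of pairwise heading differences for one frame.

    Averaged over all unordered pairs of individuals with observed headings;
    MISSING (NaN) with fewer than two observed headings.  Bounded in [-1, 1];
    1 means the whole group points the same way.
    """
    h = np.asarray(headings, dtype=float)
    h = h[~np.isnan(h)]
    n = h.size
    if n < 2:
        return float("nan")
    total = 0.0
    for a, b in combinations(range(n), 2):
        total += np.cos(h[a] - h[b])
    return float(total / (n * (n - 1) / 2))


def heading_flip_count(angles: np.ndarray, limit: float = np.pi / 2) -> int:
    """Count abnormal frame-to-frame heading changes along one sequence.

    A consecutive-frame pair flips when its absolute angular difference,
    wrapped to [0, pi], strictly exceeds ``limit`` (default 90°).  Pairs
    involving a MISSING heading are skipped (not bridged).
    """
    a = np.asarray(angles, dtype=float)
    count = 0
    for i in range(len(a) - 1):
        if np.isnan(a[i]) or np.isnan(a[i + 1]):
            continue
        diff = np.abs(np.angle(np.exp(1j * (a[i + 1] - a[i]))))
        if diff > limit:
            count += 1
    return count


def standardized_distance_matrix(keypoints: np.ndarray) -> np.ndarray:
    """Z-scored pairwise distance matrix of one individual's pose.

    All pairwise Euclidean distances are computed; the observed
    upper-triangle values are standardized to mean 0, sd 1 (population sd).
    Pairs involving a missing keypoint are NaN and excluded from the
    standardization.  Invariant to rigid motion and uniform scaling.
    """
    pts = np.asarray(keypoints, dtype=float)
    n = pts.shape[0]
    present = ~np.isnan(pts[:, 0])
    if present.sum() < 3:
        raise ValueError("need at least 3 observed keypoints for a pose matrix")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    ok = ~np.isnan(vals)
    mu = vals[ok].mean()
    sd = vals[ok].std()
    if sd <= 1e-9 * max(mu, 1.0):
        raise ValueError("degenerate pose: all pairwise distances equal")
    z = np.full((n, n), np.nan)
    z[iu] = (vals - mu) / sd
    z.T[iu] = z[iu]
    np.fill_diagonal(z, 0.0)
    return z


def pose_rmsd(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """RMS difference between two standardized pose matrices.

    Computed over upper-triangle entries present in both; MISSING when no
    entry is co-present.  Symmetric, zero on identical matrices.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must cover identical keypoint sets")
    iu = np.triu_indices(a.shape[0], k=1)
    da, db = a[iu], b[iu]
    ok = ~np.isnan(da) & ~np.isnan(db)
    if not ok.any():
        return float("nan")
    diff = da[ok] - db[ok]
    return float(np.sqrt(np.mean(diff ** 2)))


def frame_mean_rmsd(matrices: Sequence[np.ndarray]) -> float:
    """Mean pose RMSD over all unordered individual pairs in one frame."""
    vals = [pose_rmsd(a, b) for a, b in combinations(matrices, 2)]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def overlap_frequency(track: PoseTrack, id_pair: tuple[str, str], bodypart: str,
                      threshold: float = 10.0) -> float:
    """Fraction of frames where two individuals' same-named keypoint overlaps.

    Overlap means distance strictly less than ``threshold``; frames with
    either keypoint missing are excluded from numerator and denominator.
    """
    ia, ib = (track.individual_index(s) for s in id_pair)
    j = track.bodypart_index(bodypart)
    pa = track.coords[:, ia, j, :]
    pb = track.coords[:, ib, j, :]
    ok = ~np.isnan(pa[:, 0]) & ~np.isnan(pb[:, 0])
    if not ok.any():
        return float("nan")
    d = np.linalg.norm(pa[ok] - pb[ok], axis=1)
    return float(np.mean(d < threshold))
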