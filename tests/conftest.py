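"""Shared fixtures and independent oracle implementations.

The oracles here re-derive results by the most literal route available
(nested loops, exhaustive permutation search) and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from vmtrack import GroundTruthScene, PoseTrack


def make_track(coords, individuals=None, bodyparts=None, **kw) -> PoseTrack:
    coords = np.asarray(coords, dtype=float)
    nf, ni, nb, _ = coords.shape
    individuals = individuals or [f"animal{i + 1}" for i in range(ni)]
    bodyparts = bodyparts or [f"kp{j + 1}" for j in range(nb)]
    return PoseTrack(coords=coords, individuals=individuals, bodyparts=bodyparts, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_assignment(cost: np.ndarray) -> float:
    """Exhaustive minimum assignment cost over all permutations."""
    cost = np.asarray(cost, dtype=float)
    n_rows, n_cols = cost.shape
    k = min(n_rows, n_cols)
    best = math.inf
    if n_rows <= n_cols:
        for perm in itertools.permutations(range(n_cols), k):
            best = min(best, sum(cost[r, c] for r, c in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_rows), k):
            best = min(best, sum(cost[r, c] for c, r in enumerate(perm)))
    return best


def brute_classify(pred: PoseTrack, gt: GroundTruthScene, pred_of_gt: dict,
                   tau: float) -> dict:
    """Literal nested-loop verdicts: {(frame, g, b): (verdict, matched_or_None)}.

    For each annotated GT cell: missing prediction -> FN; within tau of the
    corresponding GT -> MATCH; otherwise scan every annotated GT keypoint for
    the nearest within tau (ties: lowest individual then bodypart index) and
    subtype by bodypart; none within tau -> DEVIATING_FP.
    """
    g_xy = gt.track.coords
    out = {}
    for f in range(gt.track.n_frames):
        for g in range(gt.track.n_individuals):
            for b in range(gt.track.n_bodyparts):
                if math.isnan(g_xy[f, g, b, 0]):
                    continue
                p = pred_of_gt.get(g)
                if p is None or math.isnan(pred.coords[f, p, b, 0]):
                    out[(f, g, b)] = ("FN", None)
                    continue
                px, py = pred.coords[f, p, b]
                d_corr = math.hypot(px - g_xy[f, g, b, 0], py - g_xy[f, g, b, 1])
                if d_corr <= tau:
                    out[(f, g, b)] = ("MATCH", (g, b))
                    continue
                best = None
                best_d = math.inf
                for g2 in range(gt.track.n_individuals):
                    for b2 in range(gt.track.n_bodyparts):
                        if math.isnan(g_xy[f, g2, b2, 0]):
                            continue
                        d = math.hypot(px - g_xy[f, g2, b2, 0], py - g_xy[f, g2, b2, 1])
                        if d <= tau and d < best_d:
                            best, best_d = (g2, b2), d
                if best is None:
                    out[(f, g, b)] = ("DEVIATING_FP", None)
                elif best[1] == b:
                    out[(f, g, b)] = ("ID_MISMATCH_FP", best)
                else:
                    out[(f, g, b)] = ("BODYPART_MISMATCH_FP", best)
    return out


def brute_id_switches(cells: dict) -> set:
    """Frames flagged as switches per cell, from brute_classify output."""
    switches = set()
    last = {}
    for (f, g, b) in sorted(cells):
        verdict, matched = cells[(f, g, b)]
        if matched is None:
            continue
        key = (g, b)
        if key in last and last[key] != matched[0]:
            switches.add((f, g, b))
        last[key] = matched[0]
    return switches


def random_scene(rng, n_animals=3, n_bodyparts=4, n_frames=8, size=300.0, tau=10.0):
    """Random GT plus a prediction mixing matches, near-misses, far misses
    and dropouts — exercises every verdict class."""
    gt_xy = rng.uniform(0, size, size=(n_frames, n_animals, n_bodyparts, 2))
    pred_xy = np.empty_like(gt_xy)
    for f in range(n_frames):
        for g in range(n_animals):
            for b in range(n_bodyparts):
                u = rng.random()
                if u < 0.15:
                    pred_xy[f, g, b] = np.nan            # FN
                elif u < 0.55:
                    pred_xy[f, g, b] = gt_xy[f, g, b] + rng.normal(0, 4, 2)
                elif u < 0.8:
                    # aim near some other GT keypoint
                    g2 = rng.integers(n_animals)
                    b2 = rng.integers(n_bodyparts)
                    pred_xy[f, g, b] = gt_xy[f, g2, b2] + rng.normal(0, 4, 2)
                else:
                    pred_xy[f, g, b] = rng.uniform(0, size, 2)   # anywhere
    gt = GroundTruthScene(track=make_track(gt_xy))
    pred = make_track(pred_xy)
    return pred, gt
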