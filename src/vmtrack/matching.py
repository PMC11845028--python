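"""Identity pairing between predicted and ground-truth individuals.

A scene gets ONE global predicted-to-GT identity mapping, found by
minimum-cost one-to-one assignment (the Hungarian method) on a cost matrix of
mean inter-track keypoint distances.  Scene-global pairing is deliberate:
re-pairing per frame would silently absorb the identity switches the
evaluation exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import GroundTruthScene, PoseTrack

__all__ = ["IdAssignment", "solve_assignment", "pair_ids"]


@dataclass
class IdAssignment:
    """One-to-one mapping predicted index -> GT index, total over the smaller side.

    ``mapping[p]`` is the GT column assigned to predicted row ``p``;
    unassigned predicted rows (when predictions outnumber GT) are absent.
    The cost matrix is retained for audit.
    """

    mapping: dict[int, int]
    total_cost: float
    cost_matrix: np.ndarray
    pred_labels: Optional[list[str]] = None
    gt_labels: Optional[list[str]] = None

    def gt_for(self, pred_index: int) -> Optional[int]:
        return self.mapping.get(pred_index)

    def pred_for(self, gt_index: int) -> Optional[int]:
        for p, g in self.mapping.items():
            if g == gt_index:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, g in sorted(self.mapping.items()):
            rows.append({
                "pred_index": p,
                "gt_index": g,
                "pred_label": self.pred_labels[p] if self.pred_labels else str(p),
                "gt_label": self.gt_labels[g] if self.gt_labels else str(g),
                "cost": float(self.cost_matrix[p, g]),
            })
        return pd.DataFrame(rows)


def solve_assignment(cost: np.ndarray) -> IdAssignment:
    """Minimum-total-cost one-to-one assignment of rows to columns.

    Optimal (equals the exhaustive minimum over permutations).  Among
    equally optimal assignments the lexicographically smallest one is
    returned — row 0 gets the smallest feasible column, then row 1, ... —
    so ties are deterministic.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        raise ValueError("empty cost matrix")
    if cost.ndim != 2:
        raise ValueError(f"cost must be 2-D; got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite (pre-impute missing comparisons)")
    if np.any(cost < 0):
        raise ValueError("cost matrix must be nonnegative")

    rows, cols = linear_sum_assignment(cost)
    optimum = float(cost[rows, cols].sum())
    tol = 1e-9 * (1.0 + abs(optimum))

    # lexicographic refinement: pin each assigned row in turn to the smallest
    # column that still permits an optimal completion
    n_rows, n_cols = cost.shape
    assigned_rows = sorted(rows.tolist())
    fixed: dict[int, int] = {}
    for r in assigned_rows:
        remaining = [rr for rr in assigned_rows if rr > r]
        free_cols = [c for c in range(n_cols) if c not in fixed.values()]
        base = sum(cost[rr, cc] for rr, cc in fixed.items())
        for c in free_cols:
            rest_cols = [cc for cc in free_cols if cc != c]
            if remaining:
                sub = cost[np.ix_(remaining, rest_cols)]
                sr, sc = linear_sum_assignment(sub)
                rest = float(sub[sr, sc].sum())
            else:
                rest = 0.0
            if base + cost[r, c] + rest <= optimum + tol:
                fixed[r] = c
                break
    total = float(sum(cost[r, c] for r, c in fixed.items()))
    return IdAssignment(mapping=fixed, total_cost=total, cost_matrix=cost)


def pair_ids(pred: PoseTrack, gt: GroundTruthScene) -> IdAssignment:
    """Pair predicted individuals with GT individuals for a whole scene.

    ``cost[p, g]`` is the mean Euclidean distance over every (frame, bodypart)
    cell where both tracks are observed; pairs with no co-observed cell get a
    cost larger than any observed one, so they are assigned only as a last
    resort.  The mapping is scene-global.
    """
    gtrack = gt.track
    if pred.n_frames != gtrack.n_frames:
        raise ValueError(
            f"prediction covers {pred.n_frames} frames but ground truth covers "
            f"{gtrack.n_frames}; the scenes must align"
        )
    if pred.bodyparts != gtrack.bodyparts:
        raise ValueError("prediction and ground truth must share the bodypart list")

    np_, ng = pred.n_individuals, gtrack.n_individuals
    cost = np.full((np_, ng), np.nan)
    for p in range(np_):
        d = np.linalg.norm(pred.coords[:, p, None, :, :] - gtrack.coords,
                           axis=-1)  # (frames, ng, nb)
        with np.errstate(invalid="ignore"):
            cost[p] = np.nanmean(d, axis=(0, 2))
    unobserved = np.isnan(cost)
    if unobserved.all():
        cost[:] = 1.0
    elif unobserved.any():
        cost[unobserved] = np.nanmax(cost) + 1.0
    asg = solve_assignment(cost)
    asg.pred_labels = list(pred.individuals)
    asg.gt_labels = list(gtrack.individuals)
    return asg
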