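"""Synthetic multi-animal body-axis trajectories with a logged error model.

The generator emulates the geometry the evaluation framework is built for:
each animal is a chain of equidistant keypoints along its body axis (a fish
with 5 axis points, a mouse with 6 midline points, ...) moving through a
bounded arena.  ``inject_errors`` then degrades a clean track with the error
phenomenology real trackers show — coordinate jitter, missing detections,
displaced detections, within-animal body-part swaps and identity-swap
episodes — while recording every corruption in an :class:`ErrorLog` so that
evaluation code can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PoseTrack

__all__ = [
    "SimulationConfig",
    "ErrorConfig",
    "ErrorLog",
    "simulate_ground_truth",
    "inject_errors",
    "mouse_scene_config",
    "fish_school_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the clean-trajectory generator.

    Defaults describe a mouse-like scene: 3 animals x 6 midline keypoints,
    300 consecutive frames in a 640x480 arena.
    """

    n_animals: int = 3
    n_keypoints: int = 6
    spacing: float = 15.0          # px between adjacent chain keypoints
    arena: tuple[float, float] = (640.0, 480.0)   # (width, height) px
    n_frames: int = 300
    speed_mean: float = 4.0        # px/frame
    speed_sd: float = 2.0
    turn_sd: float = 0.3           # rad/frame heading random walk
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_keypoints < 2:
            raise ValueError("n_keypoints must be >= 2")
        chain = self.spacing * (self.n_keypoints - 1)
        if min(self.arena) <= chain:
            raise ValueError(
                f"arena {self.arena} cannot contain a chain of length {chain:g} px"
            )

    @property
    def chain_length(self) -> float:
        return self.spacing * (self.n_keypoints - 1)


def mouse_scene_config(**kw) -> SimulationConfig:
    """3 mice x 6 midline keypoints, 300-frame scene."""
    return SimulationConfig(**{"n_animals": 3, "n_keypoints": 6, **kw})


def fish_school_config(**kw) -> SimulationConfig:
    """10 fish x 5 equidistant body-axis keypoints (50 keypoint series)."""
    defaults = dict(n_animals=10, n_keypoints=5, spacing=12.0, speed_mean=6.0,
                    speed_sd=2.0, turn_sd=0.15)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@dataclass
class ErrorConfig:
    """Parameters of the tracking-error model.

    ``displacement_min`` must exceed the keypoint match threshold that will be
    used to evaluate the degraded track, so displaced detections are
    guaranteed to classify as deviating rather than matching.
    """

    jitter_sd: float = 0.0            # px, isotropic Gaussian per coordinate
    fn_rate: float = 0.0              # P(keypoint deleted)
    deviating_rate: float = 0.0       # P(keypoint displaced)
    displacement_min: float = 30.0    # px, minimum deviating displacement
    displacement_max: Optional[float] = None   # default: displacement_min + 20
    bodypart_swap_rate: float = 0.0   # P per animal-frame of swapping two parts
    id_swap_events: Sequence[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    id_swap_rate: float = 0.0         # P per frame of starting an episode (alternative)
    id_swap_duration: int = 30        # frames, for rate-generated episodes
    match_threshold: float = 10.0     # threshold the degraded track will be scored at
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "deviating_rate", "bodypart_swap_rate", "id_swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if self.deviating_rate > 0 and self.displacement_min <= self.match_threshold:
            raise ValueError(
                f"displacement_min ({self.displacement_min}) must exceed the match "
                f"threshold ({self.match_threshold}); smaller displacements would be "
                "unclassifiable fixtures"
            )
        if self.displacement_max is None:
            self.displacement_max = self.displacement_min + 20.0


@dataclass
class ErrorLog:
    """Exact record of every injected discrete corruption.

    ``entries`` has one row per corrupted cell or swap event with columns
    ``kind`` (fn / deviating / bodypart_swap / id_swap), ``frame``,
    ``individual``, ``bodypart`` (or the swapped pair), and for id_swap the
    episode span.  ``true_identity[f, i]`` gives the ground-truth individual
    index whose coordinates occupy output slot ``i`` at frame ``f`` — the
    identity map evaluation results can be checked against.  Jitter is a
    global noise field set by ``config.jitter_sd``; it is not logged per cell.
    """

    entries: pd.DataFrame
    true_identity: np.ndarray          # (n_frames, n_individuals) int
    config: ErrorConfig

    def count(self, kind: str) -> int:
        if self.entries.empty:
            return 0
        return int((self.entries["kind"] == kind).sum())

    def cells(self, kind: str) -> set[tuple[int, int, int]]:
        """(frame, individual, bodypart) index triples logged under ``kind``."""
        if self.entries.empty:
            return set()
        sub = self.entries[self.entries["kind"] == kind]
        return {(int(r.frame), int(r.individual), int(r.bodypart))
                for r in sub.itertuples() if not pd.isna(r.bodypart)}

    def swap_episodes(self) -> list[tuple[int, int, tuple[int, int]]]:
        """(frame_start, duration, (individual_a, individual_b)) per episode."""
        if self.entries.empty:
            return []
        sub = self.entries[self.entries["kind"] == "id_swap"]
        return [(int(r.frame), int(r.duration), (int(r.individual), int(r.individual_b)))
                for r in sub.itertuples()]

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def simulate_ground_truth(config: SimulationConfig) -> PoseTrack:
    """Generate a clean multi-animal track.

    Each animal's head performs a heading random walk (wrapped Gaussian turn
    increments, Gaussian speed clipped at 0) inside an inner box inset by the
    chain length, with reflective boundaries; the body chain is laid out
    straight behind the head along the current heading, so adjacent-keypoint
    distances equal ``config.spacing`` exactly in every frame and the whole
    chain stays inside the arena.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.arena
    chain = config.chain_length
    lo = np.array([chain, chain])
    hi = np.array([w - chain, h - chain])
    if np.any(hi <= lo):
        raise ValueError(
            f"arena {config.arena} too small for reflective motion with chain "
            f"length {chain:g} px (needs > 2x chain length per side)"
        )

    na, nk, nf = config.n_animals, config.n_keypoints, config.n_frames
    heads = rng.uniform(lo, hi, size=(na, 2))
    headings = rng.uniform(-np.pi, np.pi, size=na)
    coords = np.empty((nf, na, nk, 2))
    offsets = np.arange(nk) * config.spacing

    for f in range(nf):
        if f > 0:
            headings = np.angle(np.exp(1j * (headings + rng.normal(0.0, config.turn_sd, na))))
            speed = np.clip(rng.normal(config.speed_mean, config.speed_sd, na), 0.0, None)
            step = np.column_stack([np.cos(headings), np.sin(headings)]) * speed[:, None]
            heads = heads + step
            # reflect into the inset box (repeat in case of large overshoot)
            for _ in range(8):
                under = heads < lo
                heads = np.where(under, 2 * lo - heads, heads)
                over = heads > hi
                heads = np.where(over, 2 * hi - heads, heads)
                if not (under.any() or over.any()):
                    break
        direction = np.column_stack([np.cos(headings), np.sin(headings)])
        coords[f] = heads[:, None, :] - direction[:, None, :] * offsets[None, :, None]

    individuals = [f"animal{i + 1}" for i in range(na)]
    bodyparts = [f"kp{j + 1}" for j in range(nk)]
    return PoseTrack(coords=coords, individuals=individuals, bodyparts=bodyparts)


def inject_errors(gt: PoseTrack, err: ErrorConfig) -> tuple[PoseTrack, ErrorLog]:
    """Degrade a clean track, returning the corrupted copy and its exact log.

    Sampling order: jitter -> bodypart swap -> deviating displacement -> FN
    deletion -> ID swap.  A cell receives at most one of {deviating, FN}
    (mutually exclusive draws from one uniform variate).  With all rates zero
    and ``jitter_sd == 0`` the output equals the input and the log is empty.
    """
    if gt.missing_mask().any():
        raise ValueError("inject_errors expects a fully observed ground-truth track")
    rng = np.random.default_rng(err.seed)
    nf, na, nk = gt.n_frames, gt.n_individuals, gt.n_bodyparts
    coords = gt.coords.copy()
    rows: list[dict] = []

    if err.jitter_sd > 0:
        coords += rng.normal(0.0, err.jitter_sd, size=coords.shape)

    if err.bodypart_swap_rate > 0:
        swap_mask = rng.random((nf, na)) < err.bodypart_swap_rate
        for f, i in zip(*np.nonzero(swap_mask)):
            a, b = rng.choice(nk, size=2, replace=False)
            coords[f, i, [a, b]] = coords[f, i, [b, a]]
            rows.append(dict(kind="bodypart_swap", frame=int(f), individual=int(i),
                             bodypart=int(a), bodypart_b=int(b)))

    # one uniform draw decides FN vs deviating vs clean, so the two are exclusive
    u = rng.random((nf, na, nk))
    fn_mask = u < err.fn_rate
    dev_mask = (u >= err.fn_rate) & (u < err.fn_rate + err.deviating_rate)

    for f, i, j in zip(*np.nonzero(dev_mask)):
        r = rng.uniform(err.displacement_min, err.displacement_max)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        coords[f, i, j] += [r * np.cos(theta), r * np.sin(theta)]
        rows.append(dict(kind="deviating", frame=int(f), individual=int(i),
                         bodypart=int(j), displacement=float(r)))

    coords[fn_mask] = np.nan
    for f, i, j in zip(*np.nonzero(fn_mask)):
        rows.append(dict(kind="fn", frame=int(f), individual=int(i), bodypart=int(j)))

    episodes = list(err.id_swap_events)
    if err.id_swap_rate > 0 and na >= 2:
        for f in range(nf):
            if rng.random() < err.id_swap_rate:
                pair = tuple(int(x) for x in rng.choice(na, size=2, replace=False))
                episodes.append((f, err.id_swap_duration, pair))

    true_identity = np.tile(np.arange(na), (nf, 1))
    for start, duration, (a, b) in episodes:
        if not (0 <= start < nf):
            raise ValueError(f"id_swap episode start {start} outside track")
        stop = min(start + duration, nf)
        coords[start:stop][:, [a, b]] = coords[start:stop][:, [b, a]]
        true_identity[start:stop][:, [a, b]] = true_identity[start:stop][:, [b, a]]
        rows.append(dict(kind="id_swap", frame=int(start), duration=int(stop - start),
                         individual=int(a), individual_b=int(b)))

    columns = ["kind", "frame", "individual", "bodypart", "bodypart_b",
               "individual_b", "duration", "displacement"]
    entries = pd.DataFrame(rows)
    entries = entries.reindex(columns=columns) if not entries.empty else pd.DataFrame(columns=columns)
    degraded = PoseTrack(coords=coords, individuals=list(gt.individuals),
                         bodyparts=list(gt.bodyparts), frame_rate=gt.frame_rate)
    return degraded, ErrorLog(entries=entries, true_identity=true_identity, config=err)
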