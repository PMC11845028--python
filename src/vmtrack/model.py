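"""Core pose-track data model.

A :class:`PoseTrack` stores multi-animal 2-D keypoint trajectories as a dense
``(n_frames, n_individuals, n_bodyparts, 2)`` float array in image-pixel
coordinates (origin top-left, x rightward, y downward, frames 0-based).
Missing keypoints are NaN in *both* coordinates — a keypoint is never
half-missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["PoseTrack", "GroundTruthScene"]


@dataclass
class PoseTrack:
    """Dense frames x individuals x bodyparts x (x, y) keypoint container.

    Parameters
    ----------
    coords
        Float array of shape ``(n_frames, n_individuals, n_bodyparts, 2)``.
        Missing keypoints are NaN in both coordinates.
    individuals
        Ordered unique identity labels, one per individual axis entry.
    bodyparts
        Ordered unique body-part labels, shared by every individual.
    confidence
        Optional per-keypoint detection confidence in [0, 1], shape
        ``(n_frames, n_individuals, n_bodyparts)``; NaN where the keypoint
        is missing.
    frame_rate
        Optional frames/second, used for time-to-frame conversion.
    """

    coords: np.ndarray
    individuals: list[str]
    bodyparts: list[str]
    confidence: Optional[np.ndarray] = None
    frame_rate: Optional[float] = None
    scorer: str = "vmtrack"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 2:
            raise ValueError(
                f"coords must have shape (frames, individuals, bodyparts, 2); "
                f"got {self.coords.shape}"
            )
        self.individuals = [str(s) for s in self.individuals]
        self.bodyparts = [str(s) for s in self.bodyparts]
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual labels must be unique")
        if len(set(self.bodyparts)) != len(self.bodyparts):
            raise ValueError("bodypart labels must be unique")
        nf, ni, nb, _ = self.coords.shape
        if ni != len(self.individuals) or nb != len(self.bodyparts):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.individuals)} individuals / {len(self.bodyparts)} bodyparts"
            )
        # enforce the never-half-missing invariant
        x_nan = np.isnan(self.coords[..., 0])
        y_nan = np.isnan(self.coords[..., 1])
        if np.any(x_nan != y_nan):
            raise ValueError("keypoints must be missing in both x and y or neither")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (nf, ni, nb):
                raise ValueError("confidence shape must be (frames, individuals, bodyparts)")

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.coords.shape[1]

    @property
    def n_bodyparts(self) -> int:
        return self.coords.shape[2]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(frames, individuals, bodyparts)`` mask of missing keypoints."""
        return np.isnan(self.coords[..., 0])

    def n_present(self) -> int:
        """Number of non-missing keypoints across the whole track."""
        return int((~self.missing_mask()).sum())

    def copy(self) -> "PoseTrack":
        return replace(
            self,
            coords=self.coords.copy(),
            individuals=list(self.individuals),
            bodyparts=list(self.bodyparts),
            confidence=None if self.confidence is None else self.confidence.copy(),
        )

    # -- indexing helpers ----------------------------------------------------

    def individual_index(self, label: str) -> int:
        try:
            return self.individuals.index(label)
        except ValueError:
            raise KeyError(f"unknown individual {label!r}") from None

    def bodypart_index(self, label: str) -> int:
        try:
            return self.bodyparts.index(label)
        except ValueError:
            raise KeyError(f"unknown bodypart {label!r}") from None

    def select_bodyparts(self, parts: Sequence[str]) -> "PoseTrack":
        """Return a track restricted to ``parts`` (order as given)."""
        idx = [self.bodypart_index(p) for p in parts]
        return replace(
            self,
            coords=self.coords[:, :, idx, :].copy(),
            bodyparts=[self.bodyparts[i] for i in idx],
            confidence=None if self.confidence is None else self.confidence[:, :, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseTrack):
            return NotImplemented
        if self.individuals != other.individuals or self.bodyparts != other.bodyparts:
            return False
        if self.coords.shape != other.coords.shape:
            return False
        same = np.array_equal(self.coords, other.coords, equal_nan=True)
        if not same:
            return False
        if (self.confidence is None) != (other.confidence is None):
            return False
        if self.confidence is not None:
            return np.array_equal(self.confidence, other.confidence, equal_nan=True)
        return True


@dataclass
class GroundTruthScene:
    """Manually annotated scene used as the evaluation reference.

    ``is_consecutive`` must be true for ID-switch evaluation (the carry-forward
    rule compares each frame with earlier frames of the same scene).
    """

    track: PoseTrack
    frame_offset: int = 0
    is_consecutive: bool = True

    @property
    def n_frames(self) -> int:
        return self.track.n_frames
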