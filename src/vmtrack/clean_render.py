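"""Data cleaning and marker/overlay rendering.

``delete_range`` rewrites selected keypoints and frame ranges to MISSING —
the NaN-rewrite step used to remove redundant stray keypoints before a video
is rendered.  ``keep_only`` blanks every body part except a designated subset
(e.g., keep only the two virtual-marker keypoints of each animal).

Rendering draws filled discs at keypoint positions onto video frames.  Frames
move as ``(n, H, W, 3)`` uint8 stacks; sources and sinks can also be
directories of numbered PNG images (lossless), read and written with imageio.
Disc centers are rounded to integer pixels and no anti-aliasing is applied,
so identical inputs yield bit-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np

from .model import PoseTrack

__all__ = [
    "MarkerSpec",
    "PALETTES",
    "delete_range",
    "keep_only",
    "time_to_frames",
    "render_markers",
    "overlay_tracking",
    "read_frames",
    "write_frames",
    "blank_canvas",
]

# Built-in palettes as explicit RGB lists (approximations of the pose-tool
# palettes, not tied to any plotting library, so tests can be bit-exact).
PALETTES: dict[str, list[tuple[int, int, int]]] = {
    "standard": [(255, 0, 0), (0, 0, 255), (0, 255, 0), (255, 255, 0),
                 (255, 0, 255), (0, 255, 255), (255, 128, 0), (128, 0, 255)],
    "alphabet": [(240, 163, 255), (0, 117, 220), (153, 63, 0), (76, 0, 92),
                 (25, 25, 25), (0, 92, 49), (43, 206, 72), (255, 204, 153),
                 (128, 128, 128), (148, 255, 181), (143, 124, 0), (157, 204, 0)],
    "gray": [(40, 40, 40), (80, 80, 80), (120, 120, 120), (160, 160, 160),
             (200, 200, 200), (240, 240, 240)],
    "rainbow": [(255, 0, 0), (255, 165, 0), (255, 255, 0), (0, 128, 0),
                (0, 0, 255), (75, 0, 130), (238, 130, 238)],
}


@dataclass
class MarkerSpec:
    """How markers are drawn: which body parts, size, colors, skeleton flag."""

    marker_parts: Optional[Sequence[str]] = None   # default: all bodyparts
    radius: int = 2
    palette: Union[str, Sequence[tuple[int, int, int]]] = "standard"
    color_by: str = "individual"                   # or "bodypart"
    draw_skeleton: bool = False

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("marker radius must be >= 1")
        if self.color_by not in {"individual", "bodypart"}:
            raise ValueError("color_by must be 'individual' or 'bodypart'")

    def colors(self, n: int) -> list[tuple[int, int, int]]:
        pal = PALETTES[self.palette] if isinstance(self.palette, str) else list(self.palette)
        if not pal:
            raise ValueError("empty palette")
        return [tuple(pal[i % len(pal)]) for i in range(n)]


def delete_range(track: PoseTrack, bodyparts: Optional[Sequence[str]] = None,
                 frames: Optional[Sequence[Union[int, range, tuple[int, int]]]] = None,
                 individuals: Optional[Sequence[str]] = None, *,
                 time_range: Optional[tuple[float, float]] = None,
                 fps: Optional[float] = None) -> PoseTrack:
    """Rewrite the selected cells to MISSING, leaving all others bit-identical.

    ``frames`` accepts ints, ``range`` objects or inclusive ``(start, stop)``
    tuples; alternatively ``time_range=(t0, t1)`` in seconds with ``fps``
    (or ``track.frame_rate``) selects frames ``floor(t0*fps) ..
    ceil(t1*fps)-1``.  Defaults select all body parts / individuals / frames.
    Idempotent; out-of-range frames raise before anything is modified.
    """
    out = track.copy()
    bp_idx = (list(range(track.n_bodyparts)) if bodyparts is None
              else [track.bodypart_index(b) for b in bodyparts])
    ind_idx = (list(range(track.n_individuals)) if individuals is None
               else [track.individual_index(s) for s in individuals])

    if time_range is not None:
        rate = fps if fps is not None else track.frame_rate
        if rate is None:
            raise ValueError("time_range requires fps (or track.frame_rate)")
        frames = [time_to_frames(time_range, rate)]
    if frames is None:
        frame_idx = np.arange(track.n_frames)
    else:
        sel: list[int] = []
        for fr in frames:
            if isinstance(fr, range):
                sel.extend(fr)
            elif isinstance(fr, tuple):
                sel.extend(range(fr[0], fr[1] + 1))
            else:
                sel.append(int(fr))
        frame_idx = np.asarray(sorted(set(sel)), dtype=int)
        if frame_idx.size and (frame_idx[0] < 0 or frame_idx[-1] >= track.n_frames):
            raise IndexError(
                f"frame selection {frame_idx[0]}..{frame_idx[-1]} outside track "
                f"of {track.n_frames} frames"
            )
    out.coords[np.ix_(frame_idx, ind_idx, bp_idx)] = np.nan
    if out.confidence is not None:
        out.confidence[np.ix_(frame_idx, ind_idx, bp_idx)] = np.nan
    return out


def time_to_frames(time_range: tuple[float, float], fps: float) -> tuple[int, int]:
    """Inclusive frame span covering ``(t_start, t_end)`` seconds at ``fps``.

    Start = floor(t_start*fps); end = ceil(t_end*fps) - 1 (conservative
    coverage of the requested interval).
    """
    t0, t1 = time_range
    if t1 < t0:
        raise ValueError("time range end precedes start")
    start = math.floor(t0 * fps)
    end = max(start, math.ceil(t1 * fps) - 1)
    return start, end


def keep_only(track: PoseTrack, bodyparts: Sequence[str]) -> PoseTrack:
    """Blank every body part except ``bodyparts`` (the virtual-marker step)."""
    if not bodyparts:
        raise ValueError("keep_only requires a non-empty bodypart subset")
    keep = {track.bodypart_index(b) for b in bodyparts}
    drop = [b for j, b in enumerate(track.bodyparts) if j not in keep]
    if not drop:
        return track.copy()
    return delete_range(track, bodyparts=drop)


# -- frame I/O ---------------------------------------------------------------

def blank_canvas(n_frames: int, height: int, width: int,
                 color: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Uniform uint8 frame stack to render onto."""
    frames = np.empty((n_frames, height, width, 3), dtype=np.uint8)
    frames[:] = np.asarray(color, dtype=np.uint8)
    return frames


def read_frames(source: Union[np.ndarray, str, Path]) -> np.ndarray:
    """Load frames from an array (passed through), an image-sequence directory
    (sorted by filename) or a single multi-frame image file."""
    if isinstance(source, np.ndarray):
        return source
    path = Path(source)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp"})
        if not files:
            raise IOError(f"no image frames found in {path}")
        return np.stack([iio.imread(p) for p in files])
    if not path.exists():
        raise IOError(f"cannot read video source {path}")
    arr = np.asarray(iio.imread(path))
    return arr if arr.ndim == 4 else arr[None]


def write_frames(frames: np.ndarray, target: Union[str, Path]) -> Path:
    """Write a frame stack as a numbered PNG sequence directory (lossless)."""
    target = Path(target)
    target.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(target / f"frame_{i:06d}.png", frame)
    return target


def _draw_disc(frame: np.ndarray, x: float, y: float, radius: int,
               color: tuple[int, int, int]) -> None:
    """Filled disc at integer-rounded center; pixels with
    (px-cx)^2 + (py-cy)^2 <= r^2 take the color. No anti-aliasing."""
    h, w = frame.shape[:2]
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(0, cx - radius), min(w - 1, cx + radius)
    y0, y1 = max(0, cy - radius), min(h - 1, cy + radius)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    frame[y0:y1 + 1, x0:x1 + 1][mask] = color


def _render(frames_in: Union[np.ndarray, str, Path], track: PoseTrack,
            spec: MarkerSpec) -> np.ndarray:
    frames = read_frames(frames_in).copy()
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W, 3) frames; got shape {frames.shape}")
    if track.n_frames > frames.shape[0]:
        raise ValueError(
            f"track has {track.n_frames} frames but video only {frames.shape[0]}"
        )
    parts = (list(track.bodyparts) if spec.marker_parts is None
             else list(spec.marker_parts))
    part_idx = [track.bodypart_index(p) for p in parts]
    if spec.color_by == "individual":
        colors = spec.colors(track.n_individuals)
    else:
        colors = spec.colors(len(part_idx))
    for f in range(track.n_frames):
        for i in range(track.n_individuals):
            pts = track.coords[f, i]
            if spec.draw_skeleton:
                _draw_skeleton(frames[f], pts[part_idx],
                               colors[i] if spec.color_by == "individual" else (255, 255, 255))
            for k, j in enumerate(part_idx):
                x, y = pts[j]
                if np.isnan(x):
                    continue
                color = colors[i] if spec.color_by == "individual" else colors[k]
                _draw_disc(frames[f], x, y, spec.radius, color)
    return frames


def _draw_skeleton(frame: np.ndarray, pts: np.ndarray,
                   color: tuple[int, int, int]) -> None:
    for a, b in zip(pts[:-1], pts[1:]):
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        n = int(max(abs(b[0] - a[0]), abs(b[1] - a[1]))) + 1
        for t in np.linspace(0.0, 1.0, n):
            x = a[0] + t * (b[0] - a[0])
            y = a[1] + t * (b[1] - a[1])
            ix, iy = int(round(x)), int(round(y))
            if 0 <= iy < frame.shape[0] and 0 <= ix < frame.shape[1]:
                frame[iy, ix] = color


def render_markers(frames_in: Union[np.ndarray, str, Path], track: PoseTrack,
                   spec: Optional[MarkerSpec] = None, *,
                   out: Optional[Union[str, Path]] = None) -> np.ndarray:
    """Draw per-individual virtual-marker discs onto frames.

    Only the designated marker body parts are drawn, one palette color per
    individual, a filled disc of ``spec.radius`` at each non-MISSING keypoint;
    MISSING keypoints draw nothing.  Returns the rendered stack and, when
    ``out`` is given, also writes it as a lossless PNG sequence.
    """
    spec = spec or MarkerSpec()
    frames = _render(frames_in, track, spec)
    if out is not None:
        write_frames(frames, out)
    return frames


def overlay_tracking(frames_in: Union[np.ndarray, str, Path], track: PoseTrack,
                     spec: Optional[MarkerSpec] = None, *,
                     out: Optional[Union[str, Path]] = None) -> np.ndarray:
    """Draw full tracking output onto frames (e.g., the markerless original).

    Same drawing rules as :func:`render_markers`; ``spec.color_by`` selects
    per-individual or per-bodypart coloring.
    """
    spec = spec or MarkerSpec(marker_parts=None, color_by="bodypart")
    frames = _render(frames_in, track, spec)
    if out is not None:
        write_frames(frames, out)
    return frames
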