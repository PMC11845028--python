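"""Readers/writers for the tabular pose formats used by the pose-tool ecosystem.

Supported dialects:

``single_flat``
    CSV with a 3-row header (scorer / bodyparts / coords) or the HDF5
    equivalent — the single-animal layout, one column pair (or triple with
    likelihood) per body part.
``multi_nested``
    CSV with a 4-row header (scorer / individuals / bodyparts / coords) or the
    HDF5 equivalent — the multi-animal layout.
``sleap_h5``
    Analysis HDF5 exported by SLEAP (datasets ``tracks`` with shape
    ``(n_tracks, 2, n_nodes, n_frames)``, ``node_names``, ``track_names``),
    read-only.

Empty cells / NaNs become MISSING; reading never invents coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .model import PoseTrack

__all__ = [
    "read_pose_table",
    "write_pose_table",
    "reshape_flat_to_multi",
    "reshape_multi_to_flat",
    "PoseFormatError",
]

_HDF_KEY = "df_with_missing"
_SINGLE_LABEL = "individual0"


class PoseFormatError(ValueError):
    """Raised when a pose table does not match the declared dialect."""


def _is_hdf(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5", ".hdf"}


def _track_from_frame(df: pd.DataFrame, dialect: str,
                      confidence_threshold: Optional[float]) -> PoseTrack:
    cols = df.columns
    if dialect == "multi_nested":
        if cols.nlevels != 4:
            raise PoseFormatError(
                f"multi_nested requires a 4-level header "
                f"(scorer/individuals/bodyparts/coords); got {cols.nlevels} levels: "
                f"{list(cols.names)}"
            )
        scorer = str(cols.get_level_values(0)[0])
        individuals = list(dict.fromkeys(cols.get_level_values(1)))
        bodyparts = list(dict.fromkeys(cols.get_level_values(2)))
    elif dialect == "single_flat":
        if cols.nlevels != 3:
            raise PoseFormatError(
                f"single_flat requires a 3-level header (scorer/bodyparts/coords); "
                f"got {cols.nlevels} levels: {list(cols.names)}"
            )
        scorer = str(cols.get_level_values(0)[0])
        individuals = [_SINGLE_LABEL]
        bodyparts = list(dict.fromkeys(cols.get_level_values(1)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    coord_names = set(cols.get_level_values(-1))
    if not {"x", "y"} <= coord_names:
        raise PoseFormatError(
            f"coords header row must contain 'x' and 'y'; found {sorted(coord_names)}"
        )
    has_likelihood = "likelihood" in coord_names

    nf = len(df)
    ni, nb = len(individuals), len(bodyparts)
    coords = np.full((nf, ni, nb, 2), np.nan)
    conf = np.full((nf, ni, nb), np.nan) if has_likelihood else None
    for i, ind in enumerate(individuals):
        for j, bp in enumerate(bodyparts):
            key = (scorer, ind, bp) if dialect == "multi_nested" else (scorer, bp)
            coords[:, i, j, 0] = pd.to_numeric(df[key + ("x",)], errors="coerce")
            coords[:, i, j, 1] = pd.to_numeric(df[key + ("y",)], errors="coerce")
            if conf is not None and key + ("likelihood",) in df.columns:
                conf[:, i, j] = pd.to_numeric(df[key + ("likelihood",)], errors="coerce")

    # half-missing cells cannot be represented: blank either coordinate → MISSING
    half = np.isnan(coords[..., 0]) != np.isnan(coords[..., 1])
    if half.any():
        coords[half] = np.nan
    missing = np.isnan(coords[..., 0])
    if conf is not None:
        conf[missing] = np.nan
    if confidence_threshold is not None and conf is not None:
        low = conf < confidence_threshold
        coords[low] = np.nan
        conf[low] = np.nan
    return PoseTrack(coords=coords, individuals=individuals, bodyparts=bodyparts,
                     confidence=conf, scorer=scorer)


def read_pose_table(path: Union[str, Path], dialect: str = "multi_nested", *,
                    confidence_threshold: Optional[float] = None) -> PoseTrack:
    """Read a pose coordinate table into a :class:`PoseTrack`.

    Parameters
    ----------
    path
        CSV or HDF5 file.
    dialect
        ``single_flat``, ``multi_nested`` or ``sleap_h5``.
    confidence_threshold
        Optional likelihood cutoff: keypoints below it become MISSING.
        Default off — no filtering is applied on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "sleap_h5":
        return _read_sleap_h5(path)
    if dialect not in {"single_flat", "multi_nested"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    n_header = 4 if dialect == "multi_nested" else 3
    if _is_hdf(path):
        df = pd.read_hdf(path)
        if not isinstance(df, pd.DataFrame):
            raise PoseFormatError(f"{path} does not hold a pose DataFrame")
    else:
        try:
            df = pd.read_csv(path, header=list(range(n_header)), index_col=0,
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            m = re.search(r"line (\d+)", str(exc))
            row = m.group(1) if m else "?"
            raise PoseFormatError(f"ragged/mixed row at line {row} in {path}") from exc
    return _track_from_frame(df, dialect, confidence_threshold)


def _read_sleap_h5(path: Path) -> PoseTrack:
    with h5py.File(path, "r") as f:
        if "tracks" not in f or "node_names" not in f:
            raise PoseFormatError(
                f"{path} lacks the 'tracks'/'node_names' datasets of a SLEAP analysis file"
            )
        tracks = np.asarray(f["tracks"], dtype=float)  # (n_tracks, 2, n_nodes, n_frames)
        nodes = [n.decode() if isinstance(n, bytes) else str(n) for n in f["node_names"][:]]
        if "track_names" in f:
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in f["track_names"][:]]
        else:
            names = [f"track_{i}" for i in range(tracks.shape[0])]
    if tracks.ndim != 4 or tracks.shape[1] != 2:
        raise PoseFormatError(f"SLEAP tracks dataset has shape {tracks.shape}; "
                              "expected (n_tracks, 2, n_nodes, n_frames)")
    coords = np.moveaxis(tracks, (0, 1, 2, 3), (1, 3, 2, 0))  # → (frames, tracks, nodes, 2)
    half = np.isnan(coords[..., 0]) != np.isnan(coords[..., 1])
    coords[half] = np.nan
    return PoseTrack(coords=coords, individuals=names, bodyparts=nodes, scorer="sleap")


def _to_dataframe(track: PoseTrack, dialect: str) -> pd.DataFrame:
    with_conf = track.confidence is not None
    coord_lvls = ["x", "y", "likelihood"] if with_conf else ["x", "y"]
    columns, data = [], []
    for i, ind in enumerate(track.individuals):
        for j, bp in enumerate(track.bodyparts):
            for c in coord_lvls:
                if dialect == "multi_nested":
                    columns.append((track.scorer, ind, bp, c))
                else:
                    columns.append((track.scorer, bp, c))
                if c == "likelihood":
                    data.append(track.confidence[:, i, j])
                else:
                    data.append(track.coords[:, i, j, 0 if c == "x" else 1])
    names = (["scorer", "individuals", "bodyparts", "coords"] if dialect == "multi_nested"
             else ["scorer", "bodyparts", "coords"])
    idx = pd.MultiIndex.from_tuples(columns, names=names)
    return pd.DataFrame(np.column_stack(data), columns=idx)


def write_pose_table(track: PoseTrack, path: Union[str, Path],
                     dialect: str = "multi_nested") -> Path:
    """Write ``track`` so that :func:`read_pose_table` round-trips it exactly.

    MISSING keypoints become empty CSV cells / NaN in HDF5.
    """
    path = Path(path)
    if dialect == "sleap_h5":
        raise ValueError("sleap_h5 is read-only")
    if dialect == "single_flat" and track.n_individuals != 1:
        raise ValueError(
            f"single_flat holds one individual; track has {track.n_individuals} "
            "(use reshape_multi_to_flat first)"
        )
    df = _to_dataframe(track, dialect)
    if _is_hdf(path):
        df.to_hdf(path, key=_HDF_KEY, mode="w")
    else:
        df.to_csv(path)
    return path


def reshape_flat_to_multi(track: PoseTrack, n_individuals: int,
                          parts_per_individual: Optional[int] = None, *,
                          individuals: Optional[list[str]] = None,
                          bodyparts: Optional[list[str]] = None) -> PoseTrack:
    """Reinterpret an individual-major flat single-animal track as multi-animal.

    A flat track whose body parts are ordered ``m1_nose ... m1_tail, m2_nose,
    ...`` (individual-major) is split into ``n_individuals`` tracks of
    ``parts_per_individual`` parts each.  ``reshape_multi_to_flat`` inverts it.
    """
    if track.n_individuals != 1:
        raise ValueError("reshape_flat_to_multi expects a single-individual track")
    nb = track.n_bodyparts
    if parts_per_individual is None:
        if nb % n_individuals:
            raise ValueError(f"{nb} bodyparts not divisible by {n_individuals} individuals")
        parts_per_individual = nb // n_individuals
    if n_individuals * parts_per_individual != nb:
        raise ValueError(
            f"expected {n_individuals} x {parts_per_individual} = "
            f"{n_individuals * parts_per_individual} flat bodyparts, got {nb}"
        )
    nf = track.n_frames
    coords = track.coords.reshape(nf, 1, n_individuals, parts_per_individual, 2)[:, 0]
    conf = (None if track.confidence is None
            else track.confidence.reshape(nf, n_individuals, parts_per_individual))
    if individuals is None:
        individuals = [f"individual{i + 1}" for i in range(n_individuals)]
    if bodyparts is None:
        # strip a common "<ind>_" prefix when the flat names encode individuals
        first = track.bodyparts[:parts_per_individual]
        bodyparts = [re.sub(r"^[^_]+_", "", b) if "_" in b else b for b in first]
        if len(set(bodyparts)) != parts_per_individual:
            bodyparts = [f"bodypart{j + 1}" for j in range(parts_per_individual)]
    return PoseTrack(coords=coords.copy(), individuals=individuals, bodyparts=bodyparts,
                     confidence=None if conf is None else conf.copy(),
                     frame_rate=track.frame_rate, scorer=track.scorer)


def reshape_multi_to_flat(track: PoseTrack, *,
                          name_pattern: str = "{individual}_{bodypart}") -> PoseTrack:
    """Flatten a multi-animal track into a single-individual, individual-major track."""
    nf = track.n_frames
    nb = track.n_individuals * track.n_bodyparts
    coords = track.coords.reshape(nf, 1, nb, 2)
    conf = None if track.confidence is None else track.confidence.reshape(nf, 1, nb)
    flat_parts = [name_pattern.format(individual=ind, bodypart=bp)
                  for ind in track.individuals for bp in track.bodyparts]
    return PoseTrack(coords=coords.copy(), individuals=[_SINGLE_LABEL],
                     bodyparts=flat_parts,
                     confidence=None if conf is None else conf.copy(),
                     frame_rate=track.frame_rate, scorer=track.scorer)
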