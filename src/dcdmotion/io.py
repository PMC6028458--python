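"""Reading, validation, nuclear-frame alignment and writing of particle tracks.

Tracks are delimited text tables with one record per (track, frame):
``track_id,frame,time_s,x_um,y_um[,extra...]``. Positions are micrometers,
times seconds, frames 0-based integers. All trajectories in a file must be
uniformly sampled at a shared period tau; the downstream coarse-graining
and MSD formulas assume positions at integer multiples of tau, so missing
frames are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrackSet",
    "ReferenceSeries",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks",
    "read_reference",
    "align_to_reference",
    "write_tracks",
]

#: relative tolerance on inter-frame interval uniformity
TAU_RTOL = 1e-6

REQUIRED_COLUMNS = ("track_id", "frame", "time_s", "x_um", "y_um")


class TrackFormatError(ValueError):
    """Raised when a track table is structurally malformed (missing columns)."""


class TrackValidationError(ValueError):
    """Raised when track contents violate an invariant (sampling, finiteness)."""


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered 2-D positions of one tracked particle.

    Parameters
    ----------
    track_id : str
        Opaque identifier of the track.
    tau : float
        Sampling period in seconds.
    times : ndarray, shape (M,)
        Sample times in seconds, strictly increasing, spaced by ``tau``.
    positions : ndarray, shape (M, 2)
        Particle positions (x, y) in micrometers.
    meta : mapping
        Free-form annotations (condition, cell id, genotype, ...).
    """

    track_id: str
    tau: float
    times: np.ndarray
    positions: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or len(times) < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: need >= 2 samples, got {len(times)}"
            )
        if positions.shape != (len(times), 2):
            raise TrackValidationError(
                f"track {self.track_id!r}: positions shape {positions.shape} "
                f"does not match {len(times)} times"
            )
        if not np.all(np.isfinite(positions)) or not np.all(np.isfinite(times)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time or position values"
            )
        dt = np.diff(times)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            raise TrackValidationError(
                f"track {self.track_id!r}: times not strictly increasing at "
                f"sample {k + 1}"
            )
        bad = np.abs(dt - self.tau) > TAU_RTOL * self.tau
        if np.any(bad):
            k = int(np.argmax(bad))
            raise TrackValidationError(
                f"track {self.track_id!r}: non-uniform sampling at frame "
                f"{k + 1}: interval {dt[k]:g} s != tau {self.tau:g} s"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrackSet:
    """Collection of trajectories sharing one sampling period."""

    trajectories: tuple[Trajectory, ...]
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        ids = [t.track_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise TrackValidationError("duplicate track_ids in TrackSet")
        for t in self.trajectories:
            if abs(t.tau - self.tau) > TAU_RTOL * self.tau:
                raise TrackValidationError(
                    f"track {t.track_id!r} has tau {t.tau:g} != set tau {self.tau:g}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)


@dataclass(frozen=True)
class ReferenceSeries:
    """Reference-channel anchor positions for nuclear-frame alignment.

    The reference channel (e.g. a nuclear-pore marker) is imaged only on a
    subset of frames; positions between anchors are linearly interpolated.
    """

    anchor_frames: np.ndarray
    anchor_positions: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.anchor_frames, dtype=int)
        pos = np.asarray(self.anchor_positions, dtype=float)
        object.__setattr__(self, "anchor_frames", frames)
        object.__setattr__(self, "anchor_positions", pos)
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError("anchor frames must be strictly increasing")
        if pos.shape != (len(frames), 2):
            raise TrackValidationError("anchor positions must be (n, 2)")


def _frames_of(traj: Trajectory) -> np.ndarray:
    """0-based integer frame indices implied by times and tau."""
    return np.rint(traj.times / traj.tau).astype(int)


def read_tracks(path: str | Path, dialect: str = "csv") -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    Columns beyond the required five are preserved per track in
    ``Trajectory.meta['extra']`` (a DataFrame) and round-trip through
    :func:`write_tracks`.

    Raises
    ------
    TrackFormatError
        If a required column is missing.
    TrackValidationError
        If the file is empty or sampling is non-uniform.
    """
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrackValidationError(f"{path}: empty track file") from None
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise TrackFormatError(f"{path}: missing required column {col!r}")
    if len(table) == 0:
        raise TrackValidationError(f"{path}: track file has a header but no records")

    extra_cols = [c for c in table.columns if c not in REQUIRED_COLUMNS]

    # tau = modal inter-frame interval across all tracks
    diffs: list[np.ndarray] = []
    for _, group in table.groupby("track_id", sort=False):
        t = np.sort(group["time_s"].to_numpy(dtype=float))
        if len(t) >= 2:
            diffs.append(np.diff(t))
    if not diffs:
        raise TrackValidationError(f"{path}: no track has >= 2 records")
    all_diffs = np.concatenate(diffs)
    rounded = np.round(all_diffs, 9)
    values, counts = np.unique(rounded, return_counts=True)
    tau = float(values[np.argmax(counts)])

    trajectories = []
    for track_id, group in table.groupby("track_id", sort=False):
        group = group.sort_values("time_s")
        meta: dict[str, object] = {}
        if extra_cols:
            meta["extra"] = group[extra_cols].reset_index(drop=True)
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                tau=tau,
                times=group["time_s"].to_numpy(dtype=float),
                positions=group[["x_um", "y_um"]].to_numpy(dtype=float),
                meta=meta,
            )
        )
    return TrackSet(trajectories=tuple(trajectories), tau=tau)


def read_reference(path: str | Path) -> ReferenceSeries:
    """Read a reference-channel anchor table ``frame,ref_x_um,ref_y_um``."""
    table = pd.read_csv(path)
    for col in ("frame", "ref_x_um", "ref_y_um"):
        if col not in table.columns:
            raise TrackFormatError(f"{path}: missing required column {col!r}")
    table = table.sort_values("frame")
    return ReferenceSeries(
        anchor_frames=table["frame"].to_numpy(dtype=int),
        anchor_positions=table[["ref_x_um", "ref_y_um"]].to_numpy(dtype=float),
    )


def align_to_reference(
    tracks: TrackSet, ref: ReferenceSeries, extrapolate: bool = False
) -> TrackSet:
    """Subtract the interpolated reference-channel translation from each track.

    The reference position at each track frame is obtained by piecewise-linear
    interpolation between anchors, and subtracted, expressing motion relative
    to the nuclear frame. Alignment is translation-only: rotation of the
    nucleus between anchors (a few seconds apart) is assumed negligible.

    Raises
    ------
    TrackValidationError
        If a track frame falls outside the anchor span and ``extrapolate``
        is False.
    """
    fmin, fmax = int(ref.anchor_frames[0]), int(ref.anchor_frames[-1])
    aligned = []
    for traj in tracks:
        frames = _frames_of(traj)
        if not extrapolate and (frames[0] < fmin or frames[-1] > fmax):
            raise TrackValidationError(
                f"track {traj.track_id!r}: frames [{frames[0]}, {frames[-1]}] "
                f"outside reference anchor span [{fmin}, {fmax}] "
                "(pass extrapolate=True to allow)"
            )
        offset = np.column_stack(
            [
                np.interp(frames, ref.anchor_frames, ref.anchor_positions[:, 0]),
                np.interp(frames, ref.anchor_frames, ref.anchor_positions[:, 1]),
            ]
        )
        aligned.append(
            Trajectory(
                track_id=traj.track_id,
                tau=traj.tau,
                times=traj.times,
                positions=traj.positions - offset,
                meta=dict(traj.meta),
            )
        )
    return TrackSet(trajectories=tuple(aligned), tau=tracks.tau)


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as a delimited track table.

    Round-trip guarantee: ``read_tracks(write_tracks(T))`` reproduces ``T``
    positionally to 1e-9 micrometers. Extra metadata columns stored under
    ``meta['extra']`` are written back verbatim.
    """
    path = Path(path)
    rows = []
    for traj in tracks:
        frames = _frames_of(traj)
        df = pd.DataFrame(
            {
                "track_id": traj.track_id,
                "frame": frames,
                "time_s": traj.times,
                "x_um": traj.positions[:, 0],
                "y_um": traj.positions[:, 1],
            }
        )
        extra = traj.meta.get("extra")
        if isinstance(extra, pd.DataFrame):
            df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
        rows.append(df)
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    out.to_csv(path, index=False, float_format="%.12g")


def trackset_from_arrays(
    positions_per_track: Sequence[np.ndarray],
    tau: float,
    ids: Sequence[str] | None = None,
) -> TrackSet:
    """Build a TrackSet from raw per-track (M, 2) position arrays."""
    trajectories = []
    for i, pos in enumerate(positions_per_track):
        pos = np.asarray(pos, dtype=float)
        tid = str(ids[i]) if ids is not None else f"track{i:04d}"
        times = np.arange(len(pos)) * tau
        trajectories.append(
            Trajectory(track_id=tid, tau=tau, times=times, positions=pos)
        )
    return TrackSet(trajectories=tuple(trajectories), tau=tau)
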