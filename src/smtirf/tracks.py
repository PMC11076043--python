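"""Trajectory containers and TrackMate-dialect CSV I/O.

The shared currency of the tracking, dwell, and diffusion stages is the
:class:`TrackSet`: a list of particle trajectories with positions in µm
plus the acquisition metadata needed to convert frames to seconds.
Positions live in a continuous coordinate frame with the origin at the
top-left pixel center (0-based pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .params import AcquisitionParams

#: Column names of the TrackMate export dialect subset we read/write.
TRACKMATE_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]


@dataclass(frozen=True)
class Spot:
    """A single detected particle in one frame (position in µm)."""

    frame: int
    x: float
    y: float
    intensity: float = 0.0
    quality: float = 0.0

    def __post_init__(self):
        if self.frame < 0:
            raise ParameterError("frame must be >= 0")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ParameterError("spot coordinates must be finite")


@dataclass
class Track:
    """One particle trajectory: strictly increasing frames, positions in µm."""

    track_id: int
    frames: np.ndarray          # int, strictly increasing
    x: np.ndarray               # µm
    y: np.ndarray               # µm

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise InputError("frames/x/y length mismatch")
        if len(self.frames) == 0:
            raise InputError("empty track")
        if np.any(np.diff(self.frames) <= 0):
            raise InputError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames_observed(self) -> int:
        """Number of frames in which the particle was actually seen."""
        return len(self.frames)

    @property
    def duration_frames(self) -> int:
        """Span from first to last observed frame, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def total_displacement_um(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


@dataclass
class TrackSet:
    """A collection of trajectories plus acquisition metadata."""

    tracks: List[Track] = field(default_factory=list)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self):
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise InputError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, xx, yy in zip(t.frames, t.x, t.y):
                rows.append((t.track_id, int(f), float(xx), float(yy)))
        return pd.DataFrame(rows, columns=TRACKMATE_COLUMNS)

    def to_csv(self, path) -> None:
        """Write the TrackMate-dialect CSV (TRACK_ID, FRAME, POSITION_X, POSITION_Y)."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, acquisition: Optional[AcquisitionParams] = None
    ) -> "TrackSet":
        missing = [c for c in TRACKMATE_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"missing columns: {missing}")
        tracks = []
        for tid, grp in df.groupby("TRACK_ID", sort=True):
            grp = grp.sort_values("FRAME")
            tracks.append(
                Track(
                    track_id=int(tid),
                    frames=grp["FRAME"].to_numpy(),
                    x=grp["POSITION_X"].to_numpy(),
                    y=grp["POSITION_Y"].to_numpy(),
                )
            )
        return cls(tracks=tracks, acquisition=acquisition or AcquisitionParams())

    @classmethod
    def from_csv(cls, path, acquisition: Optional[AcquisitionParams] = None) -> "TrackSet":
        """Read a TrackMate-style CSV export (subset of columns)."""
        return cls.from_dataframe(pd.read_csv(path), acquisition=acquisition)


@dataclass(frozen=True)
class FilterRules:
    """Trajectory filters mirroring the standard single-molecule cleanup.

    Tracks already present in the first movie frame or still present in
    the last one have censored dwell times and are dropped; tracks
    observed in fewer than ``min_frames`` frames (default 2) are dropped;
    optional total-displacement and field-edge filters complete the set.
    """

    drop_present_at_start: bool = True
    drop_present_at_end: bool = True
    min_frames: int = 2
    max_displacement_um: Optional[float] = None
    edge_margin_um: Optional[float] = None

    def __post_init__(self):
        if self.min_frames < 1:
            raise ParameterError("min_frames must be >= 1")
        if self.max_displacement_um is not None and self.max_displacement_um < 0:
            raise ParameterError("max_displacement_um must be >= 0")
        if self.edge_margin_um is not None and self.edge_margin_um < 0:
            raise ParameterError("edge_margin_um must be >= 0")


def replace_acquisition(ts: TrackSet, acq: AcquisitionParams) -> TrackSet:
    return TrackSet(tracks=list(ts.tracks), acquisition=acq)
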