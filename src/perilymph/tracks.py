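"""Migration-track readouts: velocity, directionality, path distances.

Directionality is the Euclidean displacement divided by the accumulated
path length (1 for a perfectly straight track); velocity is the mean path
speed (accumulated distance over elapsed time) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Track",
    "TrackMetrics",
    "trim_frames",
    "filter_gaps",
    "compute_metrics",
    "origin_normalize",
    "metrics_table",
]


@dataclass
class Track:
    """Ordered (t, x, y) samples of one cell, with optional 1-based frames."""

    track_id: str
    t: np.ndarray  # seconds
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    frames: np.ndarray | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValidationError(f"track {self.track_id}: ragged sample arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"track {self.track_id}: timestamps must be strictly increasing"
            )
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=np.int64)
            if self.frames.shape != self.t.shape:
                raise ValidationError(f"track {self.track_id}: frames length mismatch")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrackMetrics:
    track_id: str
    velocity: float  # µm/s, accumulated / elapsed
    accumulated_distance: float  # µm
    euclidean_distance: float  # µm
    directionality: float  # [0, 1]
    group: str = ""


def trim_frames(
    tracks: Sequence[Track], first_frame: int, last_frame: int
) -> tuple[list[Track], int]:
    """Keep only samples in the 1-based inclusive window [first, last].

    Tracks left with fewer than 2 samples are dropped; returns the kept
    tracks and the number dropped.
    """
    if first_frame < 1 or last_frame < first_frame:
        raise ValidationError(
            f"invalid frame window [{first_frame}, {last_frame}]"
        )
    kept: list[Track] = []
    dropped = 0
    for tr in tracks:
        if tr.frames is None:
            raise ValidationError(f"track {tr.track_id} has no frame indices to trim")
        sel = (tr.frames >= first_frame) & (tr.frames <= last_frame)
        if sel.sum() < 2:
            dropped += 1
            continue
        kept.append(
            Track(
                track_id=tr.track_id,
                t=tr.t[sel],
                x=tr.x[sel],
                y=tr.y[sel],
                frames=tr.frames[sel],
                group=tr.group,
            )
        )
    return kept, dropped


def filter_gaps(tracks: Sequence[Track], max_gap: int = 2) -> tuple[list[Track], int]:
    """Drop tracks with more than ``max_gap`` consecutive missed frames.

    Gaps that pass are bridged implicitly: metrics treat the samples as
    joined by straight segments.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    kept, dropped = [], 0
    for tr in tracks:
        if tr.frames is not None and tr.frames.size >= 2:
            worst = int(np.max(np.diff(tr.frames))) - 1
            if worst > max_gap:
                dropped += 1
                continue
        kept.append(tr)
    return kept, dropped


def compute_metrics(
    track: Track, velocity_mode: Literal["path", "instantaneous"] = "path"
) -> TrackMetrics:
    """Accumulated/Euclidean distance, directionality and mean velocity.

    ``velocity_mode="path"`` (default) is accumulated distance over elapsed
    time; ``"instantaneous"`` averages per-step speeds.
    """
    if track.n_samples < 2:
        raise ValidationError(f"track {track.track_id}: need >=2 samples")
    steps = np.diff(track.points(), axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    accumulated = float(step_len.sum())
    euclid = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    directionality = euclid / accumulated if accumulated > 0 else 0.0
    elapsed = float(track.t[-1] - track.t[0])
    if velocity_mode == "path":
        velocity = accumulated / elapsed
    elif velocity_mode == "instantaneous":
        velocity = float(np.mean(step_len / np.diff(track.t)))
    else:
        raise ValidationError(f"unknown velocity mode {velocity_mode!r}")
    return TrackMetrics(
        track_id=track.track_id,
        velocity=velocity,
        accumulated_distance=accumulated,
        euclidean_distance=euclid,
        directionality=directionality,
        group=track.group,
    )


def origin_normalize(tracks: Sequence[Track]) -> list[Track]:
    """Translate each track so its first sample sits at (0, 0)."""
    if not tracks:
        raise ValidationError("no tracks to normalize")
    return [
        Track(
            track_id=tr.track_id,
            t=tr.t,
            x=tr.x - tr.x[0],
            y=tr.y - tr.y[0],
            frames=tr.frames,
            group=tr.group,
        )
        for tr in tracks
    ]


def metrics_table(
    tracks: Sequence[Track],
    velocity_mode: Literal["path", "instantaneous"] = "path",
) -> pd.DataFrame:
    """One row of metrics per track."""
    rows = [compute_metrics(tr, velocity_mode) for tr in tracks]
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in rows],
            "group": [m.group for m in rows],
            "velocity_um_per_s": [m.velocity for m in rows],
            "accumulated_um": [m.accumulated_distance for m in rows],
            "euclidean_um": [m.euclidean_distance for m in rows],
            "directionality": [m.directionality for m in rows],
        }
    )
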