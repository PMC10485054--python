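"""Trajectory containers, I/O, and derivation of step/angle series.

Overhead (UAV) footage of a swimming shark reduces, after pose tracking, to a
planar coordinate track: one (x, y) position per video frame, plus a binary
flag recording whether a human swimmer shares the frame.  Everything
downstream — the per-video behavioural metrics and the hidden Markov model —
consumes the derivative structure of that track: a *step length* (distance
moved between consecutive frames) and a *turning angle* (change of heading
between consecutive steps, wrapped to (-pi, pi]).

This module provides the two containers (:class:`TrackTable`,
:class:`StepSeries`), CSV reading/writing, body-size normalisation,
Savitzky-Golay smoothing, gap repair, and the step/angle derivation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "TrackTable",
    "StepSeries",
    "TrackFormatError",
    "TrackDataError",
    "wrap_angle",
    "read_tracks",
    "write_tracks",
    "body_size_correct",
    "smooth",
    "steps_and_angles",
    "repair_gaps",
]

DEFAULT_FRAME_RATE = 30.0


class TrackFormatError(ValueError):
    """A required column or field is missing from an input file."""


class TrackDataError(ValueError):
    """Track content violates an invariant (e.g. non-monotone frames)."""


def wrap_angle(a):
    """Wrap angle(s) into the half-open interval (-pi, pi].

    Idempotent: ``wrap_angle(wrap_angle(a)) == wrap_angle(a)``.
    """
    a = np.asarray(a, dtype=float)
    out = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps the seam to -pi; the convention here is (-pi, pi].
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.ndim else float(out)


@dataclass
class TrackTable:
    """Per-frame planar positions of one shark in one video.

    Parameters
    ----------
    video_id : str
        Identifier of the source video; one table per video.
    frames : ndarray of int
        Strictly increasing frame indices.  Gaps denote missing detections.
    x, y : ndarray of float
        Planar coordinates, in pixels or (after :func:`body_size_correct`)
        in body lengths.
    human_present : int
        1 if a human swimmer is present in this video, else 0.  Constant per
        video: with/without-swimmer videos are separate recordings.
    body_length : float or None
        Shark body length in the same units as ``x``/``y``; used by
        :func:`body_size_correct`.
    frame_rate : float
        Frames per second (default 30).
    states : ndarray of int or None
        Hidden behavioural state per step transition, when the track was
        simulated and the truth is known.  ``None`` for field data.
    meta : dict
        Free-form processing flags (e.g. ``body_size_corrected``).
    """

    video_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    human_present: int = 0
    body_length: float | None = None
    frame_rate: float = DEFAULT_FRAME_RATE
    states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise TrackDataError(
                f"{self.video_id}: frames/x/y lengths differ "
                f"({len(self.frames)}/{len(self.x)}/{len(self.y)})"
            )
        if len(self.frames) < 3:
            raise TrackDataError(
                f"{self.video_id}: need at least 3 frames, got {len(self.frames)}"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise TrackDataError(
                f"{self.video_id}: frame indices must be strictly increasing"
            )
        if self.body_length is not None and not self.body_length > 0:
            raise TrackDataError(
                f"{self.video_id}: body_length must be positive, got {self.body_length}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))


@dataclass
class StepSeries:
    """Step lengths and turning angles derived from one track.

    A track of T positions yields T-1 steps and T-2 turning angles; the angle
    of the first step is undefined (no previous heading) and stored as NaN at
    index 0, so ``step`` and ``angle`` stay index-aligned per transition.

    ``heading`` is the absolute direction of motion of each step (radians),
    carried forward unchanged through zero-length steps.
    """

    video_id: str
    step: np.ndarray
    angle: np.ndarray
    heading: np.ndarray
    covariate: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    smoothed: bool = False

    def __post_init__(self):
        self.step = np.asarray(self.step, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=np.int64)
        n = len(self.step)
        if not (len(self.angle) == len(self.heading) == len(self.covariate) == n):
            raise TrackDataError(f"{self.video_id}: misaligned step series arrays")
        if np.any(self.step < 0):
            raise TrackDataError(f"{self.video_id}: negative step length")
        finite = self.angle[np.isfinite(self.angle)]
        if np.any((finite <= -np.pi) | (finite > np.pi)):
            raise TrackDataError(f"{self.video_id}: angle outside (-pi, pi]")

    def __len__(self) -> int:
        return len(self.step)

    @property
    def observed_angles(self) -> np.ndarray:
        """Angles with the leading undefined entry dropped."""
        return self.angle[np.isfinite(self.angle)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PLAIN_REQUIRED = ["video_id", "frame", "x", "y", "human_present"]
_SLEAP_REQUIRED = ["track", "frame_idx", "x", "y"]


def read_tracks(
    path,
    dialect: str = "plain_csv",
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> list[TrackTable]:
    """Read coordinate tracks from CSV, one :class:`TrackTable` per video.

    Two dialects are supported:

    ``plain_csv``
        Columns ``video_id, frame, x, y, human_present[, body_length]``.
    ``sleap_csv``
        Single-point-instance export from a pose tracker: columns
        ``track, frame_idx, x, y``; the track name becomes the video id and
        ``human_present`` defaults to 0 (it is not part of that export).

    Rows are sorted by frame within each video; gaps in the frame index are
    preserved (see :func:`repair_gaps`).  A duplicated frame index raises
    :class:`TrackDataError`.
    """
    df = pd.read_csv(path)
    if dialect == "plain_csv":
        required = _PLAIN_REQUIRED
    elif dialect == "sleap_csv":
        required = _SLEAP_REQUIRED
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing column(s) {', '.join(missing)}")

    if dialect == "sleap_csv":
        df = df.rename(columns={"track": "video_id", "frame_idx": "frame"})
        if "human_present" not in df.columns:
            df["human_present"] = 0

    tracks = []
    for vid, sub in df.groupby("video_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) == 0):
            raise TrackDataError(f"{vid}: duplicated frame index")
        body_length = None
        if "body_length" in sub.columns:
            bl = sub["body_length"].dropna()
            if len(bl):
                body_length = float(bl.iloc[0])
        tracks.append(
            TrackTable(
                video_id=str(vid),
                frames=frames,
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                human_present=int(round(float(sub["human_present"].iloc[0]))),
                body_length=body_length,
                frame_rate=frame_rate,
            )
        )
    return tracks


def write_tracks(tracks: Iterable[TrackTable], path) -> None:
    """Write tracks to a plain-dialect CSV (inverse of :func:`read_tracks`)."""
    parts = []
    for t in tracks:
        part = pd.DataFrame(
            {
                "video_id": t.video_id,
                "frame": t.frames,
                "x": t.x,
                "y": t.y,
                "human_present": t.human_present,
            }
        )
        if t.body_length is not None:
            part["body_length"] = t.body_length
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def body_size_correct(track: TrackTable) -> TrackTable:
    """Normalise coordinates by body length.

    Larger sharks swim faster in absolute terms; dividing coordinates by the
    animal's body length expresses all subsequent step lengths in
    body-lengths per frame, making videos of different-sized individuals
    comparable.  If ``body_length`` is missing the track is returned
    unchanged with ``meta['body_size_corrected'] = False`` and a warning.
    """
    if track.body_length is None:
        import warnings

        warnings.warn(
            f"{track.video_id}: no body_length; skipping body-size correction",
            stacklevel=2,
        )
        return replace(track, meta={**track.meta, "body_size_corrected": False})
    bl = float(track.body_length)
    return replace(
        track,
        x=track.x / bl,
        y=track.y / bl,
        body_length=1.0,
        meta={**track.meta, "body_size_corrected": True},
    )


def smooth(track: TrackTable, window: int = 21, order: int = 3) -> TrackTable:
    """Savitzky-Golay smooth the x and y coordinate series independently.

    The defaults (window 21 frames, cubic) suppress the lateral head-yaw
    oscillation of an undulating swimmer, which otherwise inflates
    direction-change statistics, while reproducing any polynomial of degree
    <= ``order`` exactly.  The frame count is unchanged and the output is
    flagged ``meta['smoothed'] = True``.

    Raises
    ------
    ValueError
        If the track is shorter than ``window`` (skip smoothing for such
        tracks), the window is even, or ``order >= window``.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    if len(track) < window:
        raise ValueError(
            f"{track.video_id}: track length {len(track)} < window {window}; "
            "skip smoothing for this track"
        )
    return replace(
        track,
        x=savgol_filter(track.x, window, order),
        y=savgol_filter(track.y, window, order),
        meta={**track.meta, "smoothed": True},
    )


def repair_gaps(track: TrackTable, max_gap: int = 5) -> list[TrackTable]:
    """Fill short detection gaps; split the track at long ones.

    Missing frames of span <= ``max_gap`` are filled by linear interpolation
    of x and y (the hidden-state machinery needs contiguous series).  A
    longer gap splits the video into independent sub-tracks, suffixed
    ``/0``, ``/1``, ...; pieces shorter than 3 frames are dropped.
    """
    if not track.has_gaps:
        return [track]
    diffs = np.diff(track.frames)
    cut_after = np.flatnonzero(diffs > max_gap + 1)
    segments = np.split(np.arange(len(track)), cut_after + 1)
    out: list[TrackTable] = []
    multi = len(segments) > 1
    for k, idx in enumerate(segments):
        if len(idx) < 3:
            continue
        frames = track.frames[idx]
        full = np.arange(frames[0], frames[-1] + 1)
        x = np.interp(full, frames, track.x[idx])
        y = np.interp(full, frames, track.y[idx])
        out.append(
            replace(
                track,
                video_id=f"{track.video_id}/{k}" if multi else track.video_id,
                frames=full,
                x=x,
                y=y,
                states=None,
                meta={**track.meta, "gap_filled": True},
            )
        )
    if not out:
        raise TrackDataError(
            f"{track.video_id}: no segment of >=3 frames after gap splitting"
        )
    return out


def steps_and_angles(track: TrackTable, smoothed: bool | None = None) -> StepSeries:
    """Derive the step-length / turning-angle series from positions.

    step_t  = ||p_{t+1} - p_t||                       (T-1 values)
    heading_t = atan2(dy_t, dx_t), carried forward unchanged through
                zero-length steps (a stationary animal keeps its heading)
    angle_t = wrap(heading_t - heading_{t-1})          (first entry NaN)

    A zero-length step has no direction, so its turning angle is recorded
    as missing (NaN) — the zero-mass emission model evaluates only the step
    part there.  The step out of a stationary run gets the full turn
    relative to the carried heading, keeping the series index-aligned.
    """
    if len(track) < 3:
        raise TrackDataError(f"{track.video_id}: need >=3 positions for one angle")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step = np.hypot(dx, dy)

    heading = np.arctan2(dy, dx)
    nonzero = step > 0
    if nonzero.any():
        # carry last defined heading through zero-length steps
        idx = np.where(nonzero, np.arange(len(step)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(nonzero)
        idx[idx < 0] = first  # leading zeros inherit the first real heading
        heading = heading[idx]
    else:
        heading = np.zeros_like(step)

    angle = np.full(len(step), np.nan)
    if len(step) > 1:
        angle[1:] = wrap_angle(np.diff(heading))
    angle[step == 0.0] = np.nan

    smoothed_flag = (
        bool(track.meta.get("smoothed", False)) if smoothed is None else smoothed
    )
    return StepSeries(
        video_id=track.video_id,
        step=step,
        angle=angle,
        heading=heading,
        covariate=np.full(len(step), int(track.human_present), dtype=np.int64),
        frame_rate=track.frame_rate,
        smoothed=smoothed_flag,
    )
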