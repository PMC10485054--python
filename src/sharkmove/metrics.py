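"""Per-video behavioural summary metrics.

Sixteen scalar indices summarise one video's trajectory: min/max/mean/SD of
speed, of acceleration, and of turning-angle magnitude, plus four indices of
path geometry — mean directional autocorrelation, the straightness indices
eMaxA and eMaxB, and the corrected sinuosity.  All are computed from the
smoothed step series in body-length units, and all are invariant under rigid
motions of the coordinate frame.

Angle summaries use |angle| by default: signed turning angles are symmetric
about zero for an undulating swimmer, so their min/mean carry no information,
whereas magnitudes quantify angularity.  Signed summaries are available via
``signed_angles=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import StepSeries, TrackTable, body_size_correct, smooth, steps_and_angles

__all__ = [
    "METRIC_NAMES",
    "speed_accel_stats",
    "directional_autocorrelation",
    "emax",
    "sinuosity2",
    "metric_vector",
    "metric_table",
]

METRIC_NAMES = [
    "mean_speed",
    "min_speed",
    "max_speed",
    "speed_sd",
    "mean_accel",
    "min_accel",
    "max_accel",
    "accel_sd",
    "mean_angle",
    "min_angle",
    "max_angle",
    "angle_sd",
    "directional_autocorrelation",
    "emax_a",
    "emax_b",
    "sinuosity2",
]


def _four_stats(v: np.ndarray) -> tuple[float, float, float, float]:
    return float(np.mean(v)), float(np.min(v)), float(np.max(v)), float(np.std(v, ddof=1))


def speed_accel_stats(
    series: StepSeries, frame_rate: float | None = None, signed_angles: bool = False
) -> dict:
    """Min/max/mean/SD of speed, acceleration, and turning angle.

    speed_t = step_t * fps (body-lengths/s); accel_t = (speed_{t+1} -
    speed_t) * fps (body-lengths/s^2); angle statistics are over |angle|
    (or signed angles when requested), excluding the undefined first entry.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 steps for acceleration statistics")
    fps = series.frame_rate if frame_rate is None else frame_rate
    speed = series.step * fps
    accel = np.diff(speed) * fps
    ang = series.observed_angles
    if len(ang) == 0:
        raise ValueError("need at least one turning angle")
    if not signed_angles:
        ang = np.abs(ang)
    out = {}
    for prefix, v in (("speed", speed), ("accel", accel), ("angle", ang)):
        mean, mn, mx, sd = _four_stats(v)
        out[f"mean_{prefix}"] = mean
        out[f"min_{prefix}"] = mn
        out[f"max_{prefix}"] = mx
        out[f"{prefix}_sd"] = sd
    return out


def directional_autocorrelation(
    series: StepSeries, max_lag: int | None = None, mode: str = "mean"
) -> float:
    """Mean directional autocorrelation of the heading series.

    C(d) = mean_t cos(heading_{t+d} - heading_t) for lags d = 1..max_lag.
    ``mode='mean'`` returns the mean of C over lags; ``mode='first_min'``
    returns C at its first local minimum (the other convention in use for
    this index).  ``max_lag`` defaults to floor(n/4) of the heading count.
    """
    h = series.heading
    n = len(h)
    if max_lag is None:
        max_lag = max(1, n // 4)
    if max_lag >= n:
        raise ValueError(f"max_lag ({max_lag}) must be < number of headings ({n})")
    c = np.array([np.mean(np.cos(h[d:] - h[:-d])) for d in range(1, max_lag + 1)])
    if mode == "mean":
        return float(np.mean(c))
    if mode == "first_min":
        interior = np.flatnonzero((c[1:-1] < c[:-2]) & (c[1:-1] < c[2:]))
        return float(c[interior[0] + 1]) if len(interior) else float(c[-1])
    raise ValueError(f"unknown mode {mode!r}")


def emax(series: StepSeries, eps: float = 1e-12) -> tuple[float, float]:
    """Straightness indices (eMaxA, eMaxB).

    With b the mean cosine of turning angles, eMaxA = b / (1 - b): the
    expected maximum displacement of the correlated random walk in units of
    step count.  eMaxB = eMaxA * mean step length converts it to
    body-lengths.  A perfectly straight path (b -> 1) returns +inf.
    """
    ang = series.observed_angles
    if len(ang) == 0:
        raise ValueError("need at least one turning angle")
    b = float(np.mean(np.cos(ang)))
    if b >= 1.0 - eps:
        return float("inf"), float("inf")
    a = b / (1.0 - b)
    return a, a * float(np.mean(series.step))


def sinuosity2(series: StepSeries) -> float:
    """Corrected sinuosity of the path.

    S = 2 * [p * ((1 + c) / (1 - c) + b^2)]^(-1/2), with p the mean step
    length, c the mean cosine of turning angles, and b the coefficient of
    variation of step length.  S -> 0 for a straight path and grows with
    angularity; units radians * body-length^(-1/2).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 steps")
    ang = series.observed_angles
    if len(ang) == 0:
        raise ValueError("need at least one turning angle")
    p = float(np.mean(series.step))
    if p <= 0:
        raise ValueError("mean step length is zero (stationary track)")
    c = float(np.mean(np.cos(ang)))
    b = float(np.std(series.step, ddof=1)) / p
    if c >= 1.0:
        return 0.0
    return 2.0 / np.sqrt(p * ((1.0 + c) / (1.0 - c) + b * b))


@dataclass
class MetricConfig:
    """Knobs of the per-video metric battery."""

    smooth_window: int = 21
    smooth_order: int = 3
    apply_smoothing: bool = True
    apply_body_size_correction: bool = True
    max_lag: int | None = None
    autocorr_mode: str = "mean"
    signed_angles: bool = False


def metric_vector(track: TrackTable, config: MetricConfig | None = None) -> dict:
    """The full 16-entry behavioural summary of one video.

    Pipeline: body-size correction -> Savitzky-Golay smoothing -> step/angle
    derivation -> all metric operations.  Returns a dict keyed by
    :data:`METRIC_NAMES`.
    """
    cfg = config or MetricConfig()
    t = track
    if cfg.apply_body_size_correction and t.body_length is not None:
        t = body_size_correct(t)
    if cfg.apply_smoothing:
        t = smooth(t, cfg.smooth_window, cfg.smooth_order)
    series = steps_and_angles(t)
    out = speed_accel_stats(series, signed_angles=cfg.signed_angles)
    out["directional_autocorrelation"] = directional_autocorrelation(
        series, cfg.max_lag, cfg.autocorr_mode
    )
    out["emax_a"], out["emax_b"] = emax(series)
    out["sinuosity2"] = sinuosity2(series)
    return {name: out[name] for name in METRIC_NAMES}


def metric_table(tracks, config: MetricConfig | None = None):
    """Metric vectors for many tracks as a DataFrame (one row per video)."""
    import pandas as pd

    rows = []
    for t in tracks:
        row = {"video_id": t.video_id, "human_present": t.human_present}
        row.update(metric_vector(t, config))
        rows.append(row)
    return pd.DataFrame(rows).set_index("video_id")
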