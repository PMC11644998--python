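"""Minute-level wrist-tracker features derived from a raw acceleration stream.

Consumer trackers export per-minute activity metrics rather than raw
signals; this module defines the five features the load models consume the
way a minute-epoch actigraphy pipeline would compute them from the
acceleration magnitude:

* activity time  — seconds per minute with |a - 1 g| strictly above 50 mG
* activity level — proportional-integration area: trapezoidal integral of
  the rectified deviation |a - 1 g| over the minute (g*s)
* step count     — supplied externally (device counter / generator truth)
* scaled steps / scaled activity — step count and activity time multiplied
  by the same minute's activity level

The deviation signal |‖a‖ - 1 g| is zero for a stationary wrist regardless
of orientation, which is the property the 50 mG gate relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .datatypes import MINUTE_S, TrackerMinuteTable
from .errors import IncompleteSeriesError, ValidationError

#: activity-time gate on the deviation signal, in g
DEFAULT_ACTIVITY_THRESHOLD_G = 0.050


@dataclass
class WristAccelSeries:
    """Uniformly sampled wrist acceleration magnitude in g (gravity included)."""

    t: np.ndarray
    a_mag: np.ndarray
    sample_rate: float = 25.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_mag = np.asarray(self.a_mag, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.a_mag):
            raise ValidationError("t and a_mag must be equal-length 1-D arrays")
        if np.any(self.a_mag < 0):
            raise ValidationError("a_mag must be nonnegative")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(np.abs(steps - 1.0 / self.sample_rate) > 1e-6 / self.sample_rate):
                raise ValidationError("t must be uniformly spaced at 1/sample_rate")

    def __len__(self) -> int:
        return len(self.t)


def _minute_slice(accel: WristAccelSeries, minute_start: float) -> Tuple[slice, slice]:
    """(half-open, endpoint-inclusive) index ranges for one minute.

    Raises if the half-open interval is not fully sampled.
    """
    lo = np.searchsorted(accel.t, minute_start, side="left")
    hi_open = np.searchsorted(accel.t, minute_start + MINUTE_S, side="left")
    hi_closed = np.searchsorted(accel.t, minute_start + MINUTE_S, side="right")
    expected = int(round(accel.sample_rate * MINUTE_S))
    if hi_open - lo != expected:
        raise IncompleteSeriesError(
            f"minute at t={minute_start:.0f} s is only partially covered "
            f"({hi_open - lo} of {expected} samples)"
        )
    return slice(lo, hi_open), slice(lo, hi_closed)


def deviation(accel: WristAccelSeries) -> np.ndarray:
    """Rectified gravity-subtracted magnitude |a_mag - 1 g|."""
    return np.abs(accel.a_mag - 1.0)


def activity_time(
    accel: WristAccelSeries,
    minute_start: float,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD_G,
) -> float:
    """Seconds within the minute where the deviation strictly exceeds the gate."""
    half_open, _ = _minute_slice(accel, minute_start)
    dev = deviation(accel)[half_open]
    return float(np.count_nonzero(dev > threshold)) / accel.sample_rate


def activity_level(accel: WristAccelSeries, minute_start: float) -> float:
    """Proportional-integration activity level: trapezoidal area of the
    deviation over the minute (g*s).  Includes the sample at the right
    minute boundary when present so adjacent minutes tile the stream."""
    _, closed = _minute_slice(accel, minute_start)
    dev = deviation(accel)[closed]
    return float(np.trapezoid(dev, accel.t[closed]))


def scale_features(step_count: float, activity_time_s: float, activity_level_gs: float):
    """Scaled features: each base signal multiplied by the activity level."""
    if step_count < 0 or activity_time_s < 0 or activity_level_gs < 0:
        raise ValidationError("scale_features inputs must be nonnegative")
    return step_count * activity_level_gs, activity_time_s * activity_level_gs


def build_minute_table(
    accel: WristAccelSeries,
    step_counts: np.ndarray,
    minute_starts: Optional[np.ndarray] = None,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD_G,
) -> TrackerMinuteTable:
    """Assemble the five-feature minute table for a full day.

    ``minute_starts`` defaults to the whole minutes covered by the stream;
    ``step_counts`` must align with that grid one-to-one.
    """
    if minute_starts is None:
        start = np.ceil(accel.t[0] / MINUTE_S) * MINUTE_S
        n_minutes = int((accel.t[-1] + 1.0 / accel.sample_rate - start) // MINUTE_S)
        minute_starts = start + MINUTE_S * np.arange(n_minutes)
    minute_starts = np.asarray(minute_starts, dtype=float)
    step_counts = np.asarray(step_counts)
    if len(step_counts) != len(minute_starts):
        raise ValidationError(
            f"step_counts length {len(step_counts)} does not match "
            f"{len(minute_starts)} minutes"
        )
    # one pass over the stream, then per-minute slices on the shared deviation
    dev = deviation(accel)
    expected = int(round(accel.sample_rate * MINUTE_S))
    lo = np.searchsorted(accel.t, minute_starts, side="left")
    hi_open = np.searchsorted(accel.t, minute_starts + MINUTE_S, side="left")
    hi_closed = np.searchsorted(accel.t, minute_starts + MINUTE_S, side="right")
    if np.any(hi_open - lo != expected):
        bad = int(np.argmax(hi_open - lo != expected))
        raise IncompleteSeriesError(
            f"minute at t={minute_starts[bad]:.0f} s is only partially covered "
            f"({hi_open[bad] - lo[bad]} of {expected} samples)"
        )
    at = np.array(
        [np.count_nonzero(dev[a:b] > threshold) for a, b in zip(lo, hi_open)]
    ) / accel.sample_rate
    al = np.array(
        [np.trapezoid(dev[a:b], accel.t[a:b]) for a, b in zip(lo, hi_closed)]
    )
    return TrackerMinuteTable(
        minute_start=minute_starts,
        activity_time=at,
        step_count=step_counts,
        activity_level=al,
        scaled_steps=np.asarray(step_counts, dtype=float) * al,
        scaled_activity=at * al,
    )
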