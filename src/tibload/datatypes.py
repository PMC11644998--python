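"""Core data containers shared across the pipeline.

The containers are thin dataclasses around numpy arrays with eager invariant
checking: every constructor validates, so any object that exists is valid.
Units follow the package conventions: time in seconds since the local day
start, force in newtons (or bodyweights after normalization), center of
pressure in meters from the back of the insole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: seconds per minute epoch; minutes are half-open intervals [t, t + 60)
MINUTE_S = 60.0

#: provenance tags for per-minute loading-stimulus values
SOURCE_INSOLE = "insole"
SOURCE_GENERIC = "tracker_generic"
SOURCE_CALIBRATED = "tracker_calibrated"
LS_SOURCES = (SOURCE_INSOLE, SOURCE_GENERIC, SOURCE_CALIBRATED)

# tolerance for "t lies on the sample grid", in units of one sample period
_GRID_TOL = 1e-6


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ParticipantMeta:
    """Per-participant anthropometrics and insole geometry.

    ``ankle_offset_x`` is the horizontal distance from the back of the insole
    to the ankle joint center (meters); ``achilles_moment_arm_r`` is the
    Achilles tendon moment arm about the ankle, treated as a constant 5 cm.
    """

    participant_id: str
    body_mass: float
    ankle_offset_x: float
    achilles_moment_arm_r: float = 0.05
    insole_length: float = 0.26

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValidationError(f"body_mass must be > 0, got {self.body_mass}")
        if self.achilles_moment_arm_r <= 0:
            raise ValidationError(
                f"achilles_moment_arm_r must be > 0, got {self.achilles_moment_arm_r}"
            )
        if self.insole_length <= 0:
            raise ValidationError(f"insole_length must be > 0, got {self.insole_length}")
        if not 0 < self.ankle_offset_x < self.insole_length:
            raise ValidationError(
                "ankle_offset_x must lie strictly inside (0, insole_length): "
                f"got {self.ankle_offset_x} with insole_length {self.insole_length}"
            )

    @property
    def body_weight_n(self) -> float:
        """Body weight in newtons (g = 9.81 m/s^2)."""
        return 9.81 * self.body_mass


@dataclass
class InsoleSeries:
    """Plantar force and longitudinal center of pressure sampled at 25 Hz.

    Rows lie on a uniform 1/sample_rate grid but may have gaps (periods
    where the insole was not worn are simply absent).  ``cop`` is finite
    everywhere after reading: during unloaded periods it carries the last
    loaded value forward.
    """

    t: np.ndarray
    force: np.ndarray
    cop: np.ndarray
    sample_rate: float = 25.0

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.force = _as_float_array(self.force, "force")
        self.cop = _as_float_array(self.cop, "cop")
        if not (len(self.t) == len(self.force) == len(self.cop)):
            raise ValidationError("t, force and cop must have equal length")
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            idx = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise ValidationError(f"t must be strictly increasing; first violation at row {idx}")
        k = self.t * self.sample_rate
        off_grid = np.abs(k - np.round(k)) > _GRID_TOL
        if np.any(off_grid):
            idx = int(np.argmax(off_grid))
            raise ValidationError(
                f"t must lie on the 1/{self.sample_rate} s sample grid; row {idx} (t={self.t[idx]}) does not"
            )
        if np.any(self.force < 0):
            idx = int(np.argmax(self.force < 0))
            raise ValidationError(f"force must be nonnegative; row {idx} is {self.force[idx]}")
        loaded = self.force > 0
        if np.any(~np.isfinite(self.cop[loaded])):
            raise ValidationError("cop must be finite wherever force > 0")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrackerMinuteTable:
    """One row per minute of the five wrist-tracker features.

    Columns: activity time (s in [0, 60]), step count, activity level
    (g*s, proportional-integration area), and the two scaled features
    (step count x activity level, activity time x activity level).
    """

    minute_start: np.ndarray
    activity_time: np.ndarray
    step_count: np.ndarray
    activity_level: np.ndarray
    scaled_steps: np.ndarray
    scaled_activity: np.ndarray

    FEATURES = ("activity_time", "step_count", "activity_level", "scaled_steps", "scaled_activity")

    def __post_init__(self) -> None:
        self.minute_start = _as_float_array(self.minute_start, "minute_start")
        self.activity_time = _as_float_array(self.activity_time, "activity_time")
        self.step_count = np.asarray(self.step_count)
        self.activity_level = _as_float_array(self.activity_level, "activity_level")
        self.scaled_steps = _as_float_array(self.scaled_steps, "scaled_steps")
        self.scaled_activity = _as_float_array(self.scaled_activity, "scaled_activity")
        n = len(self.minute_start)
        for name in self.FEATURES:
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name} has length != minute_start")
        if n > 1 and not np.allclose(np.diff(self.minute_start), MINUTE_S, atol=1e-9, rtol=0):
            raise ValidationError("minute_start must increase in steps of exactly 60 s")
        if np.any(np.abs(self.minute_start / MINUTE_S - np.round(self.minute_start / MINUTE_S)) > 1e-9):
            raise ValidationError("minute_start values must be multiples of 60 s")
        if np.any((self.activity_time < -1e-9) | (self.activity_time > MINUTE_S + 1e-9)):
            raise ValidationError("activity_time must lie in [0, 60] s")
        steps_f = np.asarray(self.step_count, dtype=float)
        if np.any(steps_f < 0) or np.any(np.abs(steps_f - np.round(steps_f)) > 1e-9):
            raise ValidationError("step_count must be nonnegative integers")
        self.step_count = np.round(steps_f).astype(int)
        if np.any(self.activity_level < 0):
            raise ValidationError("activity_level must be nonnegative")
        if not np.allclose(self.scaled_steps, self.step_count * self.activity_level, atol=1e-9, rtol=1e-9):
            raise ValidationError("scaled_steps must equal step_count * activity_level")
        if not np.allclose(
            self.scaled_activity, self.activity_time * self.activity_level, atol=1e-9, rtol=1e-9
        ):
            raise ValidationError("scaled_activity must equal activity_time * activity_level")

    def __len__(self) -> int:
        return len(self.minute_start)

    def feature_matrix(self, minute_starts: Optional[np.ndarray] = None) -> np.ndarray:
        """Return the (n, 5) feature matrix, optionally for a subset of minutes.

        ``minute_starts`` must be a subset of this table's minute grid.
        """
        cols = np.column_stack([np.asarray(getattr(self, f), dtype=float) for f in self.FEATURES])
        if minute_starts is None:
            return cols
        idx = np.searchsorted(self.minute_start, minute_starts)
        if np.any(idx >= len(self)) or np.any(self.minute_start[np.minimum(idx, len(self) - 1)] != minute_starts):
            raise ValidationError("requested minutes are not all present in the tracker table")
        return cols[idx]


@dataclass
class LoadStimulusSeries:
    """Per-minute loading stimulus (BW^m * s) with a provenance tag per minute."""

    minute_start: np.ndarray
    ls: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start = _as_float_array(self.minute_start, "minute_start")
        self.ls = _as_float_array(self.ls, "ls")
        self.source = np.asarray(self.source, dtype=object)
        if not (len(self.minute_start) == len(self.ls) == len(self.source)):
            raise ValidationError("minute_start, ls and source must have equal length")
        if len(self.minute_start) > 1 and np.any(np.diff(self.minute_start) <= 0):
            raise ValidationError("minute_start must be strictly increasing")
        if np.any(np.abs(self.minute_start / MINUTE_S - np.round(self.minute_start / MINUTE_S)) > 1e-9):
            raise ValidationError("minute_start values must be multiples of 60 s")
        if np.any(~np.isfinite(self.ls)) or np.any(self.ls < 0):
            raise ValidationError("ls must be finite and nonnegative")
        bad = [s for s in self.source if s not in LS_SOURCES]
        if bad:
            raise ValidationError(f"unknown ls source tag(s): {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.minute_start)

    def subset(self, minute_starts: np.ndarray) -> "LoadStimulusSeries":
        """Rows for the requested minutes (all must be present)."""
        idx = np.searchsorted(self.minute_start, minute_starts)
        if np.any(idx >= len(self)) or np.any(
            self.minute_start[np.minimum(idx, len(self) - 1)] != minute_starts
        ):
            raise ValidationError("requested minutes are not all present in the series")
        return LoadStimulusSeries(self.minute_start[idx], self.ls[idx], self.source[idx])


@dataclass
class TibiaForceSeries:
    """Tibia compression force on the insole's sample grid.

    ``in_bodyweights`` records whether the series was normalized by body
    weight (the package default) or left in newtons.
    """

    t: np.ndarray
    f_tibia: np.ndarray
    sample_rate: float = 25.0
    in_bodyweights: bool = True

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.f_tibia = _as_float_array(self.f_tibia, "f_tibia")
        if len(self.t) != len(self.f_tibia):
            raise ValidationError("t and f_tibia must have equal length")
        if np.any(self.f_tibia < 0):
            raise ValidationError("f_tibia must be nonnegative (clamped at zero)")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DlsValue:
    """Daily load stimulus: (sum of minute LS)^(1/(2m))."""

    dls: float
    m: float
    n_minutes: int

    def __post_init__(self) -> None:
        if self.dls < 0:
            raise ValidationError("dls must be nonnegative")
        if self.n_minutes < 0:
            raise ValidationError("n_minutes must be nonnegative")


@dataclass
class ParticipantDay:
    """One participant's recording day: insole + tracker + metadata.

    ``ground_truth`` is present only for synthetic days; it carries the
    generator's true per-minute LS, true step counts, the bout schedule and
    the profile that produced the day.
    """

    meta: ParticipantMeta
    insole: InsoleSeries
    tracker: TrackerMinuteTable
    ground_truth: Optional[object] = None

    def __post_init__(self) -> None:
        if len(self.tracker) == 0:
            raise ValidationError("tracker table must cover the day")
        if len(self.insole):
            day_start = self.tracker.minute_start[0]
            day_end = self.tracker.minute_start[-1] + MINUTE_S
            if self.insole.t[0] < day_start - 1e-9 or self.insole.t[-1] > day_end + 1e-9:
                raise ValidationError("insole span must lie within the tracker day span")

    @property
    def participant_id(self) -> str:
        return self.meta.participant_id

    @property
    def minute_starts(self) -> np.ndarray:
        return self.tracker.minute_start
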