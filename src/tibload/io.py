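"""Delimited-text readers and writers for the package's file dialects.

Dialects (all plain CSV, written by pandas with default float formatting so
that a write/read/write cycle is byte-stable):

* insole:        ``t_s,force_n,cop_m`` — one row per 25 Hz sample
* tracker:       ``minute_start_s,activity_time_s,step_count,activity_level,scaled_steps,scaled_activity``
* load stimulus: ``minute_start_s,ls,source``
* metadata:      YAML document with keys ``participant_id, body_mass_kg,
  ankle_offset_x_m, achilles_moment_arm_r_m, insole_length_m``
* run config:    YAML document mirroring :class:`tibload.config.RunConfig`
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig, config_from_dict
from .datatypes import (
    InsoleSeries,
    LoadStimulusSeries,
    ParticipantMeta,
    TrackerMinuteTable,
)
from .errors import ConfigError, FormatError, ValidationError

PathLike = Union[str, os.PathLike]

INSOLE_COLUMNS = ["t_s", "force_n", "cop_m"]
TRACKER_COLUMNS = [
    "minute_start_s",
    "activity_time_s",
    "step_count",
    "activity_level",
    "scaled_steps",
    "scaled_activity",
]
LS_COLUMNS = ["minute_start_s", "ls", "source"]


def _read_csv(path: PathLike, expected_columns: list) -> pd.DataFrame:
    try:
        # round_trip float parsing: shortest-repr values survive bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: cannot parse delimited text ({exc})") from exc
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in expected_columns]
    if extra:
        raise FormatError(f"{path}: unexpected column(s): {', '.join(extra)}")
    return df[expected_columns]


def carry_forward_cop(force: np.ndarray, cop: np.ndarray, noise_floor: float) -> np.ndarray:
    """Replace the center of pressure of unloaded samples.

    Samples with force below ``noise_floor`` take the CoP of the last loaded
    sample; leading unloaded samples take the first loaded value.  If no
    sample is loaded the CoP is left as provided.
    """
    out = np.array(cop, dtype=float, copy=True)
    loaded = force >= noise_floor
    if not np.any(loaded):
        return out
    idx = np.where(loaded, np.arange(len(force)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(loaded)
    idx[idx < 0] = first  # backfill before the first loaded sample
    return out[idx]


def read_insole(
    path: PathLike,
    meta: ParticipantMeta,
    noise_floor_n: float = 1.0,
    sample_rate: float = 25.0,
) -> InsoleSeries:
    """Read and validate an insole recording.

    Unloaded samples (force below ``noise_floor_n``) get their CoP carried
    forward from the last loaded sample, so downstream code never sees the
    meaningless CoP values an unloaded pressure insole reports.
    """
    df = _read_csv(path, INSOLE_COLUMNS)
    t = df["t_s"].to_numpy(dtype=float)
    force = df["force_n"].to_numpy(dtype=float)
    cop = df["cop_m"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.diff(t) <= 0
        if np.any(bad):
            raise ValidationError(
                f"{path}: time not strictly increasing; first offending row {int(np.argmax(bad)) + 1}"
            )
    cop = carry_forward_cop(force, cop, noise_floor_n)
    series = InsoleSeries(t=t, force=force, cop=cop, sample_rate=sample_rate)
    loaded = force >= noise_floor_n
    if np.any(loaded):
        c = cop[loaded]
        if np.any((c < -1e-9) | (c > meta.insole_length + 1e-9)):
            raise ValidationError(f"{path}: cop outside [0, insole_length={meta.insole_length}]")
    return series


def _float_strings(arr: np.ndarray) -> list:
    # shortest repr that parses back to the identical double, so a
    # write/read/write cycle is byte-stable
    return [repr(float(v)) for v in arr]


def write_insole(series: InsoleSeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "t_s": _float_strings(series.t),
            "force_n": _float_strings(series.force),
            "cop_m": _float_strings(series.cop),
        }
    ).to_csv(path, index=False)


def read_tracker(path: PathLike) -> TrackerMinuteTable:
    df = _read_csv(path, TRACKER_COLUMNS)
    return TrackerMinuteTable(
        minute_start=df["minute_start_s"].to_numpy(dtype=float),
        activity_time=df["activity_time_s"].to_numpy(dtype=float),
        step_count=df["step_count"].to_numpy(),
        activity_level=df["activity_level"].to_numpy(dtype=float),
        scaled_steps=df["scaled_steps"].to_numpy(dtype=float),
        scaled_activity=df["scaled_activity"].to_numpy(dtype=float),
    )


def write_tracker(table: TrackerMinuteTable, path: PathLike) -> None:
    pd.DataFrame(
        {
            "minute_start_s": _float_strings(table.minute_start),
            "activity_time_s": _float_strings(table.activity_time),
            "step_count": table.step_count,
            "activity_level": _float_strings(table.activity_level),
            "scaled_steps": _float_strings(table.scaled_steps),
            "scaled_activity": _float_strings(table.scaled_activity),
        }
    ).to_csv(path, index=False)


def read_ls(path: PathLike) -> LoadStimulusSeries:
    df = _read_csv(path, LS_COLUMNS)
    return LoadStimulusSeries(
        minute_start=df["minute_start_s"].to_numpy(dtype=float),
        ls=df["ls"].to_numpy(dtype=float),
        source=df["source"].to_numpy(dtype=object),
    )


def write_ls(series: LoadStimulusSeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "minute_start_s": _float_strings(series.minute_start),
            "ls": _float_strings(series.ls),
            "source": series.source,
        }
    ).to_csv(path, index=False)


_META_KEYS = {
    "participant_id",
    "body_mass_kg",
    "ankle_offset_x_m",
    "achilles_moment_arm_r_m",
    "insole_length_m",
}


def read_meta(path: PathLike) -> ParticipantMeta:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: metadata document must be a mapping")
    missing = sorted(_META_KEYS - set(raw))
    if missing:
        raise FormatError(f"{path}: missing metadata key(s): {', '.join(missing)}")
    unknown = sorted(set(raw) - _META_KEYS)
    if unknown:
        raise FormatError(f"{path}: unknown metadata key(s): {', '.join(unknown)}")
    return ParticipantMeta(
        participant_id=str(raw["participant_id"]),
        body_mass=float(raw["body_mass_kg"]),
        ankle_offset_x=float(raw["ankle_offset_x_m"]),
        achilles_moment_arm_r=float(raw["achilles_moment_arm_r_m"]),
        insole_length=float(raw["insole_length_m"]),
    )


def write_meta(meta: ParticipantMeta, path: PathLike) -> None:
    doc = {
        "participant_id": meta.participant_id,
        "body_mass_kg": float(meta.body_mass),
        "ankle_offset_x_m": float(meta.ankle_offset_x),
        "achilles_moment_arm_r_m": float(meta.achilles_moment_arm_r),
        "insole_length_m": float(meta.insole_length),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path: Optional[PathLike] = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` or an empty file give defaults."""
    if path is None:
        cfg = config_from_dict({})
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    return config_from_dict(raw)


# --- participant directories --------------------------------------------------

INSOLE_FILE = "insole.csv"
TRACKER_FILE = "tracker.csv"
META_FILE = "meta.yaml"
GROUND_TRUTH_FILE = "ground_truth.csv"
SCHEDULE_FILE = "schedule.csv"


def write_participant_dir(day, dir_path: PathLike) -> None:
    """Write one participant's day as a directory of delimited-text files.

    Ground truth and bout schedule are written only for synthetic days.
    """
    os.makedirs(dir_path, exist_ok=True)
    write_insole(day.insole, os.path.join(dir_path, INSOLE_FILE))
    write_tracker(day.tracker, os.path.join(dir_path, TRACKER_FILE))
    write_meta(day.meta, os.path.join(dir_path, META_FILE))
    gt = day.ground_truth
    if gt is not None:
        pd.DataFrame(
            {
                "minute_start_s": gt.minute_start,
                "ls_true": gt.ls_true,
                "steps_true": gt.steps_true,
            }
        ).to_csv(os.path.join(dir_path, GROUND_TRUTH_FILE), index=False)
        pd.DataFrame(
            {
                "bout_type": [b.bout_type for b in gt.schedule],
                "start_min": [b.start_min for b in gt.schedule],
                "duration_min": [b.duration_min for b in gt.schedule],
            }
        ).to_csv(os.path.join(dir_path, SCHEDULE_FILE), index=False)


def read_participant_dir(dir_path: PathLike, noise_floor_n: float = 1.0, sample_rate: float = 25.0):
    """Read a participant directory back into a :class:`ParticipantDay`.

    Ground truth files, if present, are not reloaded; modeling needs only
    the streams and metadata.
    """
    from .datatypes import ParticipantDay

    meta = read_meta(os.path.join(dir_path, META_FILE))
    insole = read_insole(
        os.path.join(dir_path, INSOLE_FILE), meta,
        noise_floor_n=noise_floor_n, sample_rate=sample_rate,
    )
    tracker = read_tracker(os.path.join(dir_path, TRACKER_FILE))
    return ParticipantDay(meta=meta, insole=insole, tracker=tracker)


def read_cohort_dir(dir_path: PathLike, noise_floor_n: float = 1.0, sample_rate: float = 25.0):
    """Read every participant subdirectory of a cohort directory (sorted)."""
    subdirs = sorted(
        d for d in os.listdir(dir_path) if os.path.isdir(os.path.join(dir_path, d))
    )
    if not subdirs:
        raise FormatError(f"{dir_path}: no participant subdirectories found")
    return [
        read_participant_dir(os.path.join(dir_path, d), noise_floor_n, sample_rate)
        for d in subdirs
    ]
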