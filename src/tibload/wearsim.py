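"""Sliding-window wear-time simulation.

Each simulated day re-uses one recorded (or generated) day: a contiguous
window of minutes plays the role of the period the insoles were worn; a
calibration model is fitted inside the window and fills the rest of the day
from the tracker.  The combined daily load stimulus is compared with the
all-insole reference, and absolute percent errors are summarized in 5%
insole-coverage bins (per-participant means first, then cross-participant
mean and sample standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomech import compute_dls, day_insole_ls
from .config import RunConfig
from .datatypes import LoadStimulusSeries, ParticipantDay
from .errors import ParameterError, ValidationError
from .models import (
    GenericModelSet,
    fit_calibration,
    predict_calibration,
    predict_generic,
)


@dataclass(frozen=True)
class Window:
    """A contiguous block of minutes: start index and length, in minutes."""

    start_min: int
    length_min: int


@dataclass
class SimulatedDay:
    """Outcome of one simulated wear-time day."""

    participant_id: str
    window_start_min: int
    window_length_min: int
    insole_fraction_pct: float
    dls_combined: float
    dls_reference: float
    ape_pct: float
    fallback_flag: bool = False
    low_information_flag: bool = False


@dataclass
class BinnedSummary:
    """APE summaries in coverage bins (left-open, right-closed).

    ``per_participant`` has one row per (participant, bin); ``overall``
    aggregates the per-participant bin means across participants.  Bins
    with no simulated days are simply absent.
    """

    bin_width_pct: float
    per_participant: pd.DataFrame
    overall: pd.DataFrame


def window_schedule(
    day_length_min: int,
    start_length_min: int = 30,
    increment_min: int = 5,
    stride_min: Optional[int] = None,
    target_days: Tuple[int, int] = (300, 400),
) -> List[Window]:
    """All simulated-day windows for a recording of ``day_length_min`` minutes.

    Window lengths grow from ``start_length_min`` in ``increment_min`` steps
    up to the full day; each length slides across the day in ``stride_min``
    steps.  The full-day window is always included.  When ``stride_min`` is
    None it is auto-chosen as the largest stride landing the total number of
    simulated days inside ``target_days``.
    """
    if day_length_min < start_length_min:
        raise ParameterError("day is shorter than the starting window length")
    if increment_min <= 0:
        raise ParameterError("increment_min must be > 0")
    if stride_min is None:
        stride_min = auto_stride(day_length_min, start_length_min, increment_min, target_days)
    if stride_min <= 0:
        raise ParameterError("stride_min must be > 0")
    lengths = list(range(start_length_min, day_length_min + 1, increment_min))
    windows = [
        Window(start, length)
        for length in lengths
        for start in range(0, day_length_min - length + 1, stride_min)
    ]
    if Window(0, day_length_min) not in windows:
        windows.append(Window(0, day_length_min))
    return windows


def _schedule_size(day_length: int, start_length: int, increment: int, stride: int) -> int:
    lengths = range(start_length, day_length + 1, increment)
    n = sum((day_length - length) // stride + 1 for length in lengths)
    if (day_length - start_length) % increment != 0:
        n += 1  # explicit full-day window
    return n


def auto_stride(
    day_length_min: int,
    start_length_min: int = 30,
    increment_min: int = 5,
    target_days: Tuple[int, int] = (300, 400),
) -> int:
    """Largest stride whose schedule size reaches ``target_days[0]`` days."""
    lo, hi = target_days
    for stride in range(day_length_min, 0, -1):
        n = _schedule_size(day_length_min, start_length_min, increment_min, stride)
        if n >= lo:
            return stride
    return 1


def simulate_day(
    day: ParticipantDay,
    model_set: GenericModelSet,
    window: Window,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    gap_fill: str = "calibrated",
    insole_ls: Optional[LoadStimulusSeries] = None,
    generic_ls: Optional[LoadStimulusSeries] = None,
) -> SimulatedDay:
    """One simulated wear-time day.

    Minutes inside the window take the insole LS; minutes outside take the
    gap-fill estimate ("calibrated": window-trained calibration model;
    "generic": the uncalibrated generic model).  If the calibration cannot
    be fitted (fewer than two usable window minutes) the day falls back to
    generic gap-filling and is flagged.
    """
    config = config or RunConfig()
    if gap_fill not in ("calibrated", "generic"):
        raise ParameterError(f"unknown gap_fill mode {gap_fill!r}")
    minutes = day.minute_starts
    n_minutes = len(minutes)
    if window.start_min < 0 or window.length_min <= 0 or window.start_min + window.length_min > n_minutes:
        raise ParameterError(f"window {window} does not fit in a {n_minutes}-minute day")

    ls = insole_ls if insole_ls is not None else day_insole_ls(day, config)
    if len(ls) != n_minutes:
        raise ValidationError(
            "wear-time simulation requires full insole coverage of the day "
            f"({len(ls)} of {n_minutes} minutes covered)"
        )
    gen = generic_ls if generic_ls is not None else predict_generic(model_set, day)

    window_minutes = minutes[window.start_min : window.start_min + window.length_min]
    outside = minutes[~np.isin(minutes, window_minutes)]

    fallback = False
    low_info = False
    if len(outside) == 0:
        combined = ls
    else:
        if gap_fill == "calibrated":
            try:
                cal = fit_calibration(
                    day, gen, window_minutes, config=config, seed=seed, insole_ls=ls
                )
                low_info = cal.low_information_flag
                fill = predict_calibration(cal, day, gen, outside)
            except ValidationError:
                fallback = True
                fill = gen.subset(outside)
        else:
            fill = gen.subset(outside)
        inside = ls.subset(window_minutes)
        order = np.argsort(np.concatenate([inside.minute_start, fill.minute_start]))
        combined = LoadStimulusSeries(
            minute_start=np.concatenate([inside.minute_start, fill.minute_start])[order],
            ls=np.concatenate([inside.ls, fill.ls])[order],
            source=np.concatenate([inside.source, fill.source])[order],
        )

    reference = compute_dls(ls, m=config.m)
    dls_combined = compute_dls(combined, m=config.m)
    if reference.dls < 1e-9:
        ape = float("nan")
    else:
        ape = abs(dls_combined.dls - reference.dls) / reference.dls * 100.0
    return SimulatedDay(
        participant_id=day.participant_id,
        window_start_min=window.start_min,
        window_length_min=window.length_min,
        insole_fraction_pct=100.0 * window.length_min / n_minutes,
        dls_combined=dls_combined.dls,
        dls_reference=reference.dls,
        ape_pct=ape,
        fallback_flag=fallback,
        low_information_flag=low_info,
    )


def run_wear_time(
    day: ParticipantDay,
    model_set: GenericModelSet,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    gap_fill: str = "calibrated",
    schedule: Optional[Sequence[Window]] = None,
) -> List[SimulatedDay]:
    """Run the full window schedule for one day."""
    config = config or RunConfig()
    if schedule is None:
        schedule = window_schedule(
            len(day.minute_starts),
            start_length_min=config.window_start_min,
            increment_min=config.window_increment_min,
            stride_min=config.stride_min,
            target_days=(config.target_days_min, config.target_days_max),
        )
    ls = day_insole_ls(day, config)
    gen = predict_generic(model_set, day)
    return [
        simulate_day(
            day,
            model_set,
            window,
            config=config,
            seed=seed,
            gap_fill=gap_fill,
            insole_ls=ls,
            generic_ls=gen,
        )
        for window in schedule
    ]


def sim_days_frame(sim_days: Sequence[SimulatedDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in sim_days],
            "window_start_min": [d.window_start_min for d in sim_days],
            "window_len_min": [d.window_length_min for d in sim_days],
            "insole_fraction_pct": [d.insole_fraction_pct for d in sim_days],
            "dls_combined": [d.dls_combined for d in sim_days],
            "dls_reference": [d.dls_reference for d in sim_days],
            "ape_pct": [d.ape_pct for d in sim_days],
            "fallback_flag": [d.fallback_flag for d in sim_days],
            "low_information_flag": [d.low_information_flag for d in sim_days],
        }
    )


def summarize(sim_days: Sequence[SimulatedDay], bin_width_pct: float = 5.0) -> BinnedSummary:
    """Bin simulated days by insole coverage and summarize APE.

    Bins are left-open right-closed: a fraction of exactly 5% falls in the
    (0, 5] bin.  Per-participant bin means are computed first; the overall
    rows average those means across participants (sample SD, n-1).
    """
    if not sim_days:
        raise ValidationError("no simulated days to summarize")
    df = sim_days_frame(sim_days)
    dropped = df["ape_pct"].isna()
    if dropped.any():
        warnings.warn(
            f"excluding {int(dropped.sum())} simulated day(s) with near-zero reference DLS",
            stacklevel=2,
        )
        df = df[~dropped]
    frac = df["insole_fraction_pct"].to_numpy()
    bin_idx = np.ceil(frac / bin_width_pct).astype(int) - 1
    df = df.assign(
        bin_left=bin_idx * bin_width_pct, bin_right=(bin_idx + 1) * bin_width_pct
    )
    per = (
        df.groupby(["participant_id", "bin_left", "bin_right"], as_index=False)
        .agg(mean_ape_pct=("ape_pct", "mean"), n_days=("ape_pct", "size"))
        .sort_values(["participant_id", "bin_left"], ignore_index=True)
    )
    overall = (
        per.groupby(["bin_left", "bin_right"], as_index=False)
        .agg(
            mean_ape_pct=("mean_ape_pct", "mean"),
            sd_ape_pct=("mean_ape_pct", lambda s: s.std(ddof=1)),
            n_participants=("mean_ape_pct", "size"),
        )
        .sort_values("bin_left", ignore_index=True)
    )
    return BinnedSummary(bin_width_pct=bin_width_pct, per_participant=per, overall=overall)
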