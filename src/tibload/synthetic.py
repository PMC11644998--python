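"""Synthetic study-like cohorts: day-long insole and wrist streams with truth.

The generator emulates the statistical structure the load models assume and
the between-participant variability that defeats a generic wrist model:

* days of 9-10 h built from non-overlapping activity bouts (sedentary,
  standing, walking, vigorous) plus two ~20-min mixed-intensity exercise
  sessions (morning and afternoon);
* plantar loading as half-sine vertical force pulses at the participant's
  cadence, peak ``peak_vgrf`` bodyweights (times ``run_multiplier`` during
  vigorous work), with the center of pressure progressing heel-to-toe
  within each stance;
* wrist acceleration whose oscillation amplitude during locomotion scales
  with a participant-specific ``wrist_gain`` (smaller arm swing -> lower
  activity level at identical tibia load), and sedentary hand-gesture
  bursts that inflate activity metrics while the tibia is unloaded.

Ground truth stores the analytically integrated per-minute loading
stimulus (exact up to the stated quadrature), the true step counts and the
bout schedule, so pipeline output can be checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .config import CohortConfig, RunConfig
from .datatypes import (
    MINUTE_S,
    InsoleSeries,
    ParticipantDay,
    ParticipantMeta,
)
from .errors import ConfigError
from .tracker import WristAccelSeries, build_minute_table

LOCOMOTOR_TYPES = ("walking", "vigorous", "exercise")
BOUT_TYPES = ("sedentary", "standing", "walking", "vigorous", "exercise")


@dataclass(frozen=True)
class Bout:
    bout_type: str
    start_min: int
    duration_min: int


@dataclass
class ParticipantProfile:
    """Gait and wrist-behavior parameters of one synthetic participant."""

    participant_id: str
    body_mass: float
    ankle_offset_x: float
    cadence: float  # steps/min of the generated (single-leg equivalent) stream
    peak_vgrf: float  # bodyweights at preferred walking speed
    run_multiplier: float  # amplitude scaling in vigorous bouts
    wrist_gain: float  # multiplicative arm-swing amplitude factor
    gesture_rate: float  # sedentary gesture events per minute


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic day."""

    minute_start: np.ndarray
    ls_true: np.ndarray  # BW^m * s, analytic per-minute integral
    steps_true: np.ndarray
    schedule: List[Bout]
    profile: ParticipantProfile


def draw_profile(cfg: CohortConfig, participant_id: str, rng: np.random.Generator) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id=participant_id,
        body_mass=float(np.clip(rng.normal(cfg.body_mass_mean, cfg.body_mass_sd), 45.0, 110.0)),
        ankle_offset_x=float(rng.uniform(cfg.ankle_offset_min, cfg.ankle_offset_max)),
        cadence=float(np.clip(rng.normal(cfg.cadence_mean, cfg.cadence_sd), 80.0, 140.0)),
        peak_vgrf=float(np.clip(rng.normal(cfg.peak_vgrf_mean, cfg.peak_vgrf_sd), 0.9, 1.5)),
        run_multiplier=float(rng.uniform(cfg.run_multiplier_min, cfg.run_multiplier_max)),
        wrist_gain=float(rng.lognormal(0.0, cfg.wrist_gain_sigma)),
        gesture_rate=float(rng.uniform(cfg.gesture_rate_min, cfg.gesture_rate_max)),
    )


def generate_schedule(
    cfg: CohortConfig, day_minutes: int, rng: np.random.Generator
) -> List[Bout]:
    """Randomized bout sequence covering exactly ``day_minutes`` minutes."""
    if cfg.schedule_style == "alternating":
        bouts: List[Bout] = []
        cur = 0
        pattern = (
            ("sedentary", cfg.alternating_sedentary_minutes),
            ("walking", cfg.alternating_walking_minutes),
        )
        k = 0
        while cur < day_minutes:
            btype, dur = pattern[k % 2]
            dur = min(dur, day_minutes - cur)
            bouts.append(Bout(btype, cur, dur))
            cur += dur
            k += 1
        return bouts

    exercise_starts: List[int] = []
    if cfg.exercise_bouts:
        if 2 * cfg.exercise_minutes + 60 > day_minutes:
            raise ConfigError("mandatory exercise bouts do not fit in the day")
        morning = int(rng.integers(20, 61))
        lo = max(day_minutes // 2, morning + cfg.exercise_minutes + 30)
        hi = day_minutes - cfg.exercise_minutes - 10
        if lo >= hi:
            raise ConfigError("mandatory exercise bouts do not fit in the day")
        afternoon = int(rng.integers(lo, hi + 1))
        exercise_starts = [morning, afternoon]

    types = np.array(["sedentary", "standing", "walking", "vigorous"])
    probs = np.array([cfg.p_sedentary, cfg.p_standing, cfg.p_walking, cfg.p_vigorous])
    probs = probs / probs.sum()
    ranges = {
        "sedentary": (cfg.sedentary_minutes_min, cfg.sedentary_minutes_max),
        "standing": (cfg.standing_minutes_min, cfg.standing_minutes_max),
        "walking": (cfg.walking_minutes_min, cfg.walking_minutes_max),
        "vigorous": (cfg.vigorous_minutes_min, cfg.vigorous_minutes_max),
    }
    bouts = []
    cur = 0
    pending = list(exercise_starts)
    while cur < day_minutes:
        if pending and cur == pending[0]:
            pending.pop(0)
            bouts.append(Bout("exercise", cur, cfg.exercise_minutes))
            cur += cfg.exercise_minutes
            continue
        btype = str(rng.choice(types, p=probs))
        lo, hi = ranges[btype]
        dur = int(rng.integers(lo, hi + 1))
        limit = pending[0] if pending else day_minutes
        dur = min(dur, limit - cur, day_minutes - cur)
        if dur <= 0:  # stuck against a mandatory bout
            dur = max(1, min(limit - cur, day_minutes - cur))
        bouts.append(Bout(btype, cur, dur))
        cur += dur
    return bouts


def _loading_segments(
    schedule: List[Bout], profile: ParticipantProfile
) -> List[Tuple[float, float, float]]:
    """(start_s, end_s, amplitude in BW) for every loaded stretch of the day.

    Exercise bouts alternate moderate and vigorous minutes, a generic stand-in
    for a mixed rehabilitation battery.
    """
    segments = []
    walk_amp = profile.peak_vgrf
    vig_amp = profile.peak_vgrf * profile.run_multiplier
    for bout in schedule:
        start_s = bout.start_min * MINUTE_S
        end_s = (bout.start_min + bout.duration_min) * MINUTE_S
        if bout.bout_type == "walking":
            segments.append((start_s, end_s, walk_amp))
        elif bout.bout_type == "vigorous":
            segments.append((start_s, end_s, vig_amp))
        elif bout.bout_type == "exercise":
            for k in range(bout.duration_min):
                amp = walk_amp if k % 2 == 0 else vig_amp
                segments.append((start_s + k * MINUTE_S, start_s + (k + 1) * MINUTE_S, amp))
    return segments


def _ffill(values: np.ndarray, fallback: float) -> np.ndarray:
    """Forward-fill NaNs; leading NaNs take the first finite value (or fallback)."""
    out = values.copy()
    mask = np.isfinite(out)
    if not mask.any():
        out[:] = fallback
        return out
    idx = np.where(mask, np.arange(len(out)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.argmax(mask))
    idx[idx < 0] = first
    return out[idx]


def generate_insole(
    schedule: List[Bout],
    profile: ParticipantProfile,
    cfg: CohortConfig,
    rng: np.random.Generator,
    day_minutes: int,
    m: float = 4.0,
    achilles_r: float = 0.05,
) -> Tuple[InsoleSeries, np.ndarray, np.ndarray]:
    """Synthesize the 25 Hz insole stream plus analytic ground truth.

    Returns ``(series, ls_true, steps_true)`` where ``ls_true`` is the
    per-minute integral of the bodyweight-normalized tibia force to the
    power ``m``, computed from the pulse parameters on a fine quadrature
    grid and split exactly at minute boundaries.
    """
    rate = cfg.sample_rate
    n_samples = int(round(day_minutes * MINUTE_S * rate))
    t = np.arange(n_samples) / rate
    force = np.zeros(n_samples)
    cop = np.full(n_samples, np.nan)
    ls_true = np.zeros(day_minutes)
    steps_true = np.zeros(day_minutes, dtype=int)

    period = MINUTE_S / profile.cadence
    ns = min(int(cfg.stance_s * rate), int(period * rate) - 1)
    if ns < 2:
        raise ConfigError("cadence/stance/sample_rate combination leaves < 2 stance samples")
    stance = ns / rate
    offs = np.arange(ns + 1)
    pulse_shape = np.clip(np.sin(np.pi * offs / ns), 0.0, None)
    pulse_shape[0] = pulse_shape[-1] = 0.0
    cop_shape = cfg.cop_heel + (cfg.cop_toe - cfg.cop_heel) * offs / ns

    # fine-grid quadrature of the unit-amplitude tibia-force integrand,
    # clamped where the CoP falls behind the effective ankle pivot
    tau = np.linspace(0.0, stance, 601)
    unit = np.sin(np.pi * tau / stance)
    lever = 1.0 + (cfg.cop_heel + (cfg.cop_toe - cfg.cop_heel) * tau / stance - profile.ankle_offset_x) / achilles_r
    integrand = np.clip(unit * lever, 0.0, None) ** m
    cum = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(tau))])
    pulse_integral = cum[-1]

    bw_n = 9.81 * profile.body_mass
    for start_s, end_s, amp in _loading_segments(schedule, profile):
        span = end_s - start_s - stance
        if span < 0:
            continue
        n_pulses = int(span / period) + 1
        starts = start_s + period * np.arange(n_pulses)
        i0 = np.round(starts * rate).astype(int)
        keep = i0 + ns <= n_samples - 1
        i0, n_pulses = i0[keep], int(keep.sum())
        if n_pulses == 0:
            continue
        if cfg.step_amp_noise_sd > 0:
            amps = amp * np.clip(1.0 + rng.normal(0.0, cfg.step_amp_noise_sd, n_pulses), 0.05, None)
        else:
            amps = np.full(n_pulses, amp)
        idx = i0[:, None] + offs[None, :]
        force[idx] = amps[:, None] * pulse_shape[None, :] * bw_n
        cop[idx] = np.broadcast_to(cop_shape, (n_pulses, ns + 1))

        snapped = i0 / rate
        minute0 = (snapped / MINUTE_S).astype(int)
        minute_end = ((snapped + stance) / MINUTE_S).astype(int)
        contrib = amps**m * pulse_integral
        same = minute0 == minute_end
        np.add.at(ls_true, minute0[same], contrib[same])
        split = ~same
        if np.any(split):
            boundary = (minute0[split] + 1) * MINUTE_S
            part1 = amps[split] ** m * np.interp(boundary - snapped[split], tau, cum)
            np.add.at(ls_true, minute0[split], part1)
            np.add.at(ls_true, np.minimum(minute0[split] + 1, day_minutes - 1), contrib[split] - part1)
        np.add.at(steps_true, minute0, 1)

    cop = _ffill(cop, profile.ankle_offset_x)
    series = InsoleSeries(t=t, force=force, cop=cop, sample_rate=rate)
    return series, ls_true, steps_true


def generate_wrist(
    schedule: List[Bout],
    profile: ParticipantProfile,
    cfg: CohortConfig,
    rng: np.random.Generator,
    day_minutes: int,
) -> WristAccelSeries:
    """Synthesize the wrist acceleration-magnitude stream (in g).

    Locomotor bouts produce an arm-swing oscillation with amplitude
    proportional to ``wrist_gain``; sedentary bouts produce gesture bursts
    at ``gesture_rate`` whose amplitude exceeds the 50 mG activity gate even
    though the tibia is unloaded; background noise stays below the gate.
    """
    rate = cfg.sample_rate
    n_samples = int(round(day_minutes * MINUTE_S * rate))
    t = np.arange(n_samples) / rate
    dev = np.zeros(n_samples)
    f_arm = profile.cadence / 120.0  # one swing cycle per stride

    for bout in schedule:
        start_s = bout.start_min * MINUTE_S
        end_s = (bout.start_min + bout.duration_min) * MINUTE_S
        lo = int(round(start_s * rate))
        hi = min(int(round(end_s * rate)), n_samples)
        if bout.bout_type in ("walking", "vigorous"):
            base = cfg.walking_arm_amp if bout.bout_type == "walking" else cfg.vigorous_arm_amp
            amp = profile.wrist_gain * base
            dev[lo:hi] = amp * (0.5 + 0.5 * np.sin(2 * np.pi * f_arm * (t[lo:hi] - start_s)))
        elif bout.bout_type == "exercise":
            for k in range(bout.duration_min):
                base = cfg.walking_arm_amp if k % 2 == 0 else cfg.vigorous_arm_amp
                amp = profile.wrist_gain * base
                mlo = lo + int(round(k * MINUTE_S * rate))
                mhi = min(lo + int(round((k + 1) * MINUTE_S * rate)), n_samples)
                dev[mlo:mhi] = amp * (
                    0.5 + 0.5 * np.sin(2 * np.pi * f_arm * (t[mlo:mhi] - start_s))
                )
        elif bout.bout_type == "standing":
            dev[lo:hi] = profile.wrist_gain * cfg.standing_arm_amp
        else:  # sedentary: gesture bursts
            if profile.gesture_rate > 0:
                n_events = rng.poisson(profile.gesture_rate * bout.duration_min)
                dur = cfg.gesture_duration_s
                if n_events > 0 and end_s - start_s > dur:
                    times = rng.uniform(start_s, end_s - dur, n_events)
                    for t0 in times:
                        glo = int(round(t0 * rate))
                        ghi = min(int(round((t0 + dur) * rate)) + 1, n_samples)
                        dev[glo:ghi] += cfg.gesture_amp * np.sin(
                            np.pi * (t[glo:ghi] - t0) / dur
                        ) ** 2

    a = 1.0 + dev
    if cfg.wrist_noise_sd > 0:
        a = a + rng.normal(0.0, cfg.wrist_noise_sd, n_samples)
    a = np.clip(a, 0.0, None)
    return WristAccelSeries(t=t, a_mag=a, sample_rate=rate)


def generate_participant_day(
    config: RunConfig,
    participant_id: str,
    rng: np.random.Generator,
) -> ParticipantDay:
    """Generate one full synthetic day (profile, schedule, streams, truth)."""
    cfg = config.cohort
    profile = draw_profile(cfg, participant_id, rng)
    day_minutes = int(rng.integers(cfg.day_minutes_min, cfg.day_minutes_max + 1))
    schedule = generate_schedule(cfg, day_minutes, rng)
    insole, ls_true, steps_true = generate_insole(
        schedule, profile, cfg, rng, day_minutes,
        m=config.m, achilles_r=config.achilles_moment_arm_r,
    )
    accel = generate_wrist(schedule, profile, cfg, rng, day_minutes)
    if cfg.step_miss_rate > 0:
        steps_tracker = rng.binomial(steps_true, 1.0 - cfg.step_miss_rate)
    else:
        steps_tracker = steps_true.copy()
    table = build_minute_table(
        accel, steps_tracker, threshold=config.activity_threshold_g
    )
    meta = ParticipantMeta(
        participant_id=participant_id,
        body_mass=profile.body_mass,
        ankle_offset_x=profile.ankle_offset_x,
        achilles_moment_arm_r=config.achilles_moment_arm_r,
        insole_length=cfg.insole_length,
    )
    gt = GroundTruth(
        minute_start=table.minute_start.copy(),
        ls_true=ls_true,
        steps_true=steps_true,
        schedule=schedule,
        profile=profile,
    )
    return ParticipantDay(meta=meta, insole=insole, tracker=table, ground_truth=gt)


def generate_cohort(config: Optional[RunConfig] = None, seed: int = 0) -> List[ParticipantDay]:
    """Generate the full synthetic cohort, one day per participant.

    Each participant gets an independent, reproducible random stream spawned
    from ``seed``; regenerating with the same seed is bit-identical.
    """
    config = config or RunConfig()
    cfg = config.cohort
    if cfg.n_participants < 2:
        raise ConfigError("a cohort needs at least 2 participants")
    children = np.random.SeedSequence(seed).spawn(cfg.n_participants)
    return [
        generate_participant_day(config, f"P{i + 1:02d}", np.random.default_rng(children[i]))
        for i in range(cfg.n_participants)
    ]
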