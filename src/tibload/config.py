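"""Run configuration: the tunable knobs of the pipeline and their defaults.

Defaults encode the package's documented choices: damage exponent m = 4,
Achilles moment arm 5 cm, 25 Hz insole sampling, 30-min starting wear
window growing in 5-min increments, 5% coverage bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError


@dataclass
class CohortConfig:
    """Parameters of the synthetic study cohort.

    Distributions emulate the study conditions: 8 participants, 9-10 h
    recording days with bout-structured activity including two ~20-min
    exercise sessions, participant-specific wrist-motion gains (lognormal
    across the cohort) and sedentary hand-gesture noise.
    """

    n_participants: int = 8
    day_minutes_min: int = 540
    day_minutes_max: int = 600
    sample_rate: float = 25.0

    # bout schedule
    schedule_style: str = "random"  # "random" or "alternating"
    exercise_bouts: bool = True
    exercise_minutes: int = 20
    p_sedentary: float = 0.50
    p_standing: float = 0.15
    p_walking: float = 0.25
    p_vigorous: float = 0.10
    sedentary_minutes_min: int = 15
    sedentary_minutes_max: int = 45
    standing_minutes_min: int = 5
    standing_minutes_max: int = 15
    walking_minutes_min: int = 5
    walking_minutes_max: int = 20
    vigorous_minutes_min: int = 4
    vigorous_minutes_max: int = 8
    alternating_sedentary_minutes: int = 20
    alternating_walking_minutes: int = 10

    # gait / loading profile distributions
    body_mass_mean: float = 70.0
    body_mass_sd: float = 10.0
    ankle_offset_min: float = 0.10
    ankle_offset_max: float = 0.14
    insole_length: float = 0.26
    cadence_mean: float = 105.0
    cadence_sd: float = 8.0
    peak_vgrf_mean: float = 1.15
    peak_vgrf_sd: float = 0.08
    run_multiplier_min: float = 1.3
    run_multiplier_max: float = 1.7
    stance_s: float = 0.6
    cop_heel: float = 0.05
    cop_toe: float = 0.25

    # wrist-motion profile distributions (the between-participant confound)
    wrist_gain_sigma: float = 0.5
    gesture_rate_min: float = 0.5
    gesture_rate_max: float = 6.0
    walking_arm_amp: float = 0.12
    vigorous_arm_amp: float = 0.30
    standing_arm_amp: float = 0.02
    gesture_amp: float = 0.15
    gesture_duration_s: float = 2.0

    # noise levels
    step_amp_noise_sd: float = 0.05
    step_miss_rate: float = 0.03
    wrist_noise_sd: float = 0.01

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0 < self.day_minutes_min <= self.day_minutes_max:
            raise ConfigError("day_minutes_min/max must satisfy 0 < min <= max")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be > 0")
        if self.schedule_style not in ("random", "alternating"):
            raise ConfigError(f"unknown schedule_style {self.schedule_style!r}")
        probs = (self.p_sedentary, self.p_standing, self.p_walking, self.p_vigorous)
        if any(p < 0 for p in probs) or sum(probs) <= 0:
            raise ConfigError("bout-type probabilities must be nonnegative with positive sum")
        for name in ("wrist_gain_sigma", "step_amp_noise_sd", "wrist_noise_sd", "step_miss_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.step_miss_rate >= 1:
            raise ConfigError("step_miss_rate must be < 1")
        if not 0 <= self.cop_heel < self.cop_toe <= self.insole_length:
            raise ConfigError("cop_heel/cop_toe must satisfy 0 <= heel < toe <= insole_length")

    @classmethod
    def noise_free_linear(cls, n_participants: int = 2) -> "CohortConfig":
        """A deterministic, noise-free cohort whose LS is exactly linear in
        the tracker step count: alternating sedentary/walking bouts, cadence
        100 steps/min (step period divides the minute), no vigorous bouts,
        no gestures, no measurement noise, identical profiles.

        Used for parameter-recovery experiments where the calibrated model
        should reach the exact-fit limit.
        """
        return cls(
            n_participants=n_participants,
            day_minutes_min=600,
            day_minutes_max=600,
            schedule_style="alternating",
            exercise_bouts=False,
            p_vigorous=0.0,
            cadence_mean=100.0,
            cadence_sd=0.0,
            body_mass_sd=0.0,
            peak_vgrf_sd=0.0,
            ankle_offset_min=0.12,
            ankle_offset_max=0.12,
            wrist_gain_sigma=0.0,
            gesture_rate_min=0.0,
            gesture_rate_max=0.0,
            step_amp_noise_sd=0.0,
            step_miss_rate=0.0,
            wrist_noise_sd=0.0,
        )


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    # biomechanics
    m: float = 4.0
    achilles_moment_arm_r: float = 0.05
    sample_rate: float = 25.0
    minute_s: float = 60.0
    noise_floor_n: float = 1.0
    normalize_bw: bool = True
    coverage_threshold: float = 0.9
    activity_threshold_g: float = 0.050

    # models
    lambda_grid: Optional[Sequence[float]] = None
    lambda_num: int = 9
    lambda_min_ratio: float = 1e-4
    include_zero_lambda: bool = True
    n_folds: int = 5
    log1p_target: bool = False
    low_information_minutes: int = 10

    # wear-time simulation
    window_start_min: int = 30
    window_increment_min: int = 5
    stride_min: Optional[int] = None  # None: auto-chosen to land in target_days
    target_days_min: int = 300
    target_days_max: int = 400
    bin_width_pct: float = 5.0

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if self.m <= 0:
            raise ConfigError("m must be > 0")
        if self.achilles_moment_arm_r <= 0:
            raise ConfigError("achilles_moment_arm_r must be > 0")
        if self.sample_rate <= 0 or self.minute_s <= 0:
            raise ConfigError("sample_rate and minute_s must be > 0")
        if not 0 < self.coverage_threshold <= 1:
            raise ConfigError("coverage_threshold must lie in (0, 1]")
        if self.noise_floor_n < 0:
            raise ConfigError("noise_floor_n must be >= 0")
        if self.activity_threshold_g < 0:
            raise ConfigError("activity_threshold_g must be >= 0")
        if self.lambda_grid is not None and any(l < 0 for l in self.lambda_grid):
            raise ConfigError("lambda_grid entries must be >= 0")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.window_start_min <= 0:
            raise ConfigError("window_start_min must be > 0")
        if self.window_increment_min <= 0:
            raise ConfigError("window_increment_min must be > 0")
        if self.stride_min is not None and self.stride_min <= 0:
            raise ConfigError("stride_min must be > 0")
        if not 0 < self.target_days_min <= self.target_days_max:
            raise ConfigError("target_days_min/max must satisfy 0 < min <= max")
        if self.bin_width_pct <= 0 or self.bin_width_pct > 100:
            raise ConfigError("bin_width_pct must lie in (0, 100]")
        if self.low_information_minutes < 0:
            raise ConfigError("low_information_minutes must be >= 0")
        self.cohort.validate()


def _build_dataclass(cls, raw: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - names)
    if unknown:
        raise ConfigError(f"unknown {context} key(s): {', '.join(unknown)}")
    return cls(**raw)


def config_from_dict(raw: Optional[dict]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a (possibly empty) mapping.

    Unknown keys, at the top level or under ``cohort``, raise
    :class:`~tibload.errors.ConfigError` listing them.
    """
    raw = dict(raw or {})
    cohort_raw = raw.pop("cohort", None)
    if cohort_raw is not None and not isinstance(cohort_raw, dict):
        raise ConfigError("cohort section must be a mapping")
    cfg = _build_dataclass(RunConfig, raw, "config")
    if cohort_raw is not None:
        cfg.cohort = _build_dataclass(CohortConfig, cohort_raw, "cohort config")
    cfg.validate()
    return cfg
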