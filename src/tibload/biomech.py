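"""Tibia-load biomechanics: force model, loading stimulus, daily load stimulus.

The tibia compression force is estimated from the insole's total plantar
force F(t) and longitudinal center of pressure CoP(t) by a sagittal-plane
moment balance about the ankle.  The plantar force acting at a lever arm
(CoP - x) about the ankle joint center must be balanced by Achilles tendon
tension acting at moment arm r, and that tension adds to the bone's axial
compression:

    F_tibia(t) = F(t) + (CoP(t) - x) * F(t) / r

negative values (CoP behind the ankle) are clamped at zero since the bone
cannot be loaded in tension by this mechanism.

The per-minute loading stimulus weights load magnitude by a damage exponent
m (default 4, from animal and cadaver bone-damage work):

    LS_j = integral over minute j of F_tibia(t)^m dt        [BW^m * s]

and the daily load stimulus treats every minute as one discrete loading
task and summarizes the whole day on the stress-like scale

    DLS = (sum_j LS_j)^(1 / (2m))                            [BW^(1/2) * s^(1/(2m))]
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import RunConfig
from .datatypes import (
    MINUTE_S,
    SOURCE_INSOLE,
    DlsValue,
    InsoleSeries,
    LoadStimulusSeries,
    ParticipantDay,
    ParticipantMeta,
    TibiaForceSeries,
)
from .errors import IncompleteSeriesError, ParameterError


def compute_tibia_force(
    insole: InsoleSeries,
    meta: ParticipantMeta,
    normalize_bw: bool = True,
) -> TibiaForceSeries:
    """Per-sample tibia compression force from plantar force and CoP.

    With ``normalize_bw`` (the default) the output is in bodyweights, the
    scale on which all LS/DLS values in this package are expressed.
    """
    lever = (insole.cop - meta.ankle_offset_x) / meta.achilles_moment_arm_r
    f = insole.force * (1.0 + lever)
    f = np.maximum(f, 0.0)
    if normalize_bw:
        f = f / meta.body_weight_n
    return TibiaForceSeries(
        t=insole.t, f_tibia=f, sample_rate=insole.sample_rate, in_bodyweights=normalize_bw
    )


def compute_ls(
    tibia: TibiaForceSeries,
    minute_starts: np.ndarray,
    m: float = 4.0,
    coverage_threshold: float = 0.9,
) -> LoadStimulusSeries:
    """Trapezoidal per-minute integral of ``f_tibia ** m``.

    A minute is integrated only if at least ``coverage_threshold`` of its
    expected samples are present (>= 1350 of 1500 at 25 Hz by default);
    minutes failing the rule are omitted from the output.  The integral for
    minute [t, t+60) includes the sample at t+60 when present, so adjacent
    minutes tile the day without losing the boundary segment.
    """
    if m <= 0:
        raise ParameterError(f"exponent m must be > 0, got {m}")
    minute_starts = np.asarray(minute_starts, dtype=float)
    t = tibia.t
    fm = tibia.f_tibia**m
    expected = int(round(tibia.sample_rate * MINUTE_S))
    min_count = int(np.ceil(coverage_threshold * expected))

    out_minutes, out_ls = [], []
    left = np.searchsorted(t, minute_starts, side="left")
    right_open = np.searchsorted(t, minute_starts + MINUTE_S, side="left")
    right_closed = np.searchsorted(t, minute_starts + MINUTE_S, side="right")
    for ms, lo, hi_o, hi_c in zip(minute_starts, left, right_open, right_closed):
        if hi_o - lo < min_count:
            continue
        seg = slice(lo, hi_c)
        out_minutes.append(ms)
        out_ls.append(np.trapezoid(fm[seg], t[seg]))
    n = len(out_minutes)
    return LoadStimulusSeries(
        minute_start=np.asarray(out_minutes, dtype=float),
        ls=np.asarray(out_ls, dtype=float),
        source=np.asarray([SOURCE_INSOLE] * n, dtype=object),
    )


def compute_dls(ls: LoadStimulusSeries, m: float = 4.0) -> DlsValue:
    """Daily load stimulus ``(sum LS)^(1/(2m))`` over a complete minute series.

    The series must have no missing minutes in its span; gap-fill first.
    """
    if m <= 0:
        raise ParameterError(f"exponent m must be > 0, got {m}")
    if len(ls) == 0:
        return DlsValue(dls=0.0, m=m, n_minutes=0)
    diffs = np.diff(ls.minute_start)
    if np.any(np.abs(diffs - MINUTE_S) > 1e-9):
        first = int(np.argmax(np.abs(diffs - MINUTE_S) > 1e-9))
        raise IncompleteSeriesError(
            "minute series has a gap after "
            f"t={ls.minute_start[first]:.0f} s; gap-fill before computing DLS"
        )
    total = float(np.sum(ls.ls))
    return DlsValue(dls=total ** (1.0 / (2.0 * m)), m=m, n_minutes=len(ls))


def day_insole_ls(day: ParticipantDay, config: Optional[RunConfig] = None) -> LoadStimulusSeries:
    """Insole-derived LS for every sufficiently covered minute of a day."""
    config = config or RunConfig()
    tibia = compute_tibia_force(day.insole, day.meta, normalize_bw=config.normalize_bw)
    return compute_ls(
        tibia,
        day.minute_starts,
        m=config.m,
        coverage_threshold=config.coverage_threshold,
    )
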