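"""Evaluation statistics and the study orchestration pipeline.

``run_study`` reproduces the package's three headline analyses on a
synthetic cohort: (1) leave-one-participant-out accuracy of the generic
tracker model, (2) pooled held-out accuracy of quarter-wise participant
calibration, and (3) the sliding-window wear-time simulation with both
calibrated and generic gap-filling, summarized in coverage bins.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .biomech import day_insole_ls
from .config import RunConfig
from .datatypes import LoadStimulusSeries, ParticipantDay
from .errors import TibloadError, ValidationError
from .models import (
    GenericModelSet,
    evaluate_quarter_calibration,
    fit_generic,
    predict_generic,
)
from .synthetic import generate_cohort
from .wearsim import BinnedSummary, SimulatedDay, run_wear_time, sim_days_frame, summarize


def r_squared(target: np.ndarray, estimate: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    May be negative (the estimate fits worse than the target's mean);
    equals 1 only for a perfect fit.  A constant target has no defined
    R^2 and raises :class:`~tibload.errors.ValidationError`.
    """
    target = np.asarray(target, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if len(target) != len(estimate):
        raise ValidationError("target and estimate must have equal length")
    if len(target) < 2:
        raise ValidationError("need at least 2 values to compute R^2")
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot <= 0:
        raise ValidationError("R^2 is undefined for a zero-variance target")
    ss_res = float(np.sum((target - estimate) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationReport:
    """All quantities the study pipeline computes, plus provenance."""

    seed: int
    config_hash: str
    package_version: str
    r2_table: pd.DataFrame  # participant_id, generic_r2, calibrated_r2
    generic_r2_mean: float
    generic_r2_sd: float
    calibrated_r2_mean: float
    calibrated_r2_sd: float
    wear_days_calibrated: pd.DataFrame
    wear_days_generic: pd.DataFrame
    wear_bins_calibrated: BinnedSummary
    wear_bins_generic: BinnedSummary
    stage_rows: Dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        """Persist every table plus a run log (so each reported mean can be
        recomputed from its constituents)."""
        os.makedirs(out_dir, exist_ok=True)
        self.r2_table.to_csv(os.path.join(out_dir, "r2_table.csv"), index=False)
        self.wear_days_calibrated.to_csv(
            os.path.join(out_dir, "wear_days_calibrated.csv"), index=False
        )
        self.wear_days_generic.to_csv(
            os.path.join(out_dir, "wear_days_generic.csv"), index=False
        )
        self.wear_bins_calibrated.overall.to_csv(
            os.path.join(out_dir, "wear_bins_calibrated.csv"), index=False
        )
        self.wear_bins_calibrated.per_participant.to_csv(
            os.path.join(out_dir, "wear_bins_calibrated_per_participant.csv"), index=False
        )
        self.wear_bins_generic.overall.to_csv(
            os.path.join(out_dir, "wear_bins_generic.csv"), index=False
        )
        self.wear_bins_generic.per_participant.to_csv(
            os.path.join(out_dir, "wear_bins_generic_per_participant.csv"), index=False
        )
        log = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "generic_r2_mean": self.generic_r2_mean,
            "generic_r2_sd": self.generic_r2_sd,
            "calibrated_r2_mean": self.calibrated_r2_mean,
            "calibrated_r2_sd": self.calibrated_r2_sd,
            "stage_rows": self.stage_rows,
        }
        with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(
    config: Optional[RunConfig] = None,
    seed: int = 0,
    out_dir: Optional[str] = None,
) -> EvaluationReport:
    """Run the full synthetic study pipeline.

    Stages: generate cohort -> insole LS -> generic leave-one-out models ->
    per-participant generic and quarter-calibrated R^2 -> wear-time
    simulation with calibrated and generic gap filling -> binned summaries.
    Identical (config, seed) pairs produce identical reports.
    """
    config = config or RunConfig()
    stage = "generate_cohort"
    try:
        days = generate_cohort(config, seed=seed)
        stage = "insole_ls"
        insole_ls: Dict[str, LoadStimulusSeries] = {
            d.participant_id: day_insole_ls(d, config) for d in days
        }
        stage = "fit_generic"
        model_set = fit_generic(days, config=config, seed=seed, insole_ls=insole_ls)
        stage = "evaluate_r2"
        rows = []
        generic_preds: Dict[str, LoadStimulusSeries] = {}
        for day in days:
            pid = day.participant_id
            ls = insole_ls[pid]
            gen = predict_generic(model_set, day)
            generic_preds[pid] = gen
            generic_r2 = r_squared(ls.ls, gen.subset(ls.minute_start).ls)
            calibrated_r2 = evaluate_quarter_calibration(
                day, model_set, config=config, seed=seed, insole_ls=ls, generic_ls=gen
            )
            rows.append(
                {"participant_id": pid, "generic_r2": generic_r2, "calibrated_r2": calibrated_r2}
            )
        r2_table = pd.DataFrame(rows)
        stage = "wear_time_simulation"
        sims_cal: List[SimulatedDay] = []
        sims_gen: List[SimulatedDay] = []
        for day in days:
            sims_cal.extend(
                run_wear_time(day, model_set, config=config, seed=seed, gap_fill="calibrated")
            )
            sims_gen.extend(
                run_wear_time(day, model_set, config=config, seed=seed, gap_fill="generic")
            )
        stage = "summarize"
        bins_cal = summarize(sims_cal, bin_width_pct=config.bin_width_pct)
        bins_gen = summarize(sims_gen, bin_width_pct=config.bin_width_pct)
    except TibloadError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    report = EvaluationReport(
        seed=int(seed),
        config_hash=config_hash(config),
        package_version=__version__,
        r2_table=r2_table,
        generic_r2_mean=float(r2_table["generic_r2"].mean()),
        generic_r2_sd=float(r2_table["generic_r2"].std(ddof=1)),
        calibrated_r2_mean=float(r2_table["calibrated_r2"].mean()),
        calibrated_r2_sd=float(r2_table["calibrated_r2"].std(ddof=1)),
        wear_days_calibrated=sim_days_frame(sims_cal),
        wear_days_generic=sim_days_frame(sims_gen),
        wear_bins_calibrated=bins_cal,
        wear_bins_generic=bins_gen,
        stage_rows={
            "participants": len(days),
            "insole_ls_minutes": int(sum(len(v) for v in insole_ls.values())),
            "simulated_days_calibrated": len(sims_cal),
            "simulated_days_generic": len(sims_gen),
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
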