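"""tibload: tibia bone-load monitoring from pressure insoles and wrist trackers.

Estimates tibia compression force from insole force and center-of-pressure
signals, summarizes it as a per-minute loading stimulus and a daily load
stimulus, trains generic and participant-calibrated models that estimate
the loading stimulus from wrist-tracker minute metrics, and simulates how
daily-load accuracy degrades with reduced insole wear time.
"""

__version__ = "0.1.0"

from .biomech import compute_dls, compute_ls, compute_tibia_force, day_insole_ls
from .config import CohortConfig, RunConfig, config_from_dict
from .datatypes import (
    DlsValue,
    InsoleSeries,
    LoadStimulusSeries,
    ParticipantDay,
    ParticipantMeta,
    TibiaForceSeries,
    TrackerMinuteTable,
)
from .errors import (
    ConfigError,
    FormatError,
    IncompleteSeriesError,
    ParameterError,
    TibloadError,
    ValidationError,
)
from .models import (
    CalibrationModel,
    GenericModelSet,
    LinearModel,
    evaluate_quarter_calibration,
    fit_calibration,
    fit_generic,
    fit_lasso,
    predict_calibration,
    predict_generic,
)
from .synthetic import generate_cohort
from .wearsim import Window, simulate_day, summarize, window_schedule

__all__ = [
    "__version__",
    "CohortConfig",
    "RunConfig",
    "config_from_dict",
    "DlsValue",
    "InsoleSeries",
    "LoadStimulusSeries",
    "ParticipantDay",
    "ParticipantMeta",
    "TibiaForceSeries",
    "TrackerMinuteTable",
    "TibloadError",
    "FormatError",
    "ValidationError",
    "ParameterError",
    "ConfigError",
    "IncompleteSeriesError",
    "compute_tibia_force",
    "compute_ls",
    "compute_dls",
    "day_insole_ls",
    "LinearModel",
    "GenericModelSet",
    "CalibrationModel",
    "fit_lasso",
    "fit_generic",
    "predict_generic",
    "fit_calibration",
    "predict_calibration",
    "evaluate_quarter_calibration",
    "generate_cohort",
    "Window",
    "window_schedule",
    "simulate_day",
    "summarize",
]


def r_squared(target, estimate):
    """Coefficient of determination; see :func:`tibload.evaluation.r_squared`."""
    from .evaluation import r_squared as _r2

    return _r2(target, estimate)
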