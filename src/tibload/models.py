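"""Two-stage estimation of loading stimulus from tracker minute features.

Stage one is a *generic* L1-regularized linear model (LASSO) mapping the
five tracker features to insole-derived LS, trained on a pooled cohort and
evaluated leave-one-participant-out.  Stage two is a *calibration* LASSO
per participant whose inputs are the generic LS estimate plus the same five
features, trained only on minutes where insole and tracker data coexist.

Fitting details
---------------
Features are standardized to zero mean / unit variance on the training rows
(constant features keep scale 1 and end up with coefficient 0), the
intercept is unpenalized, and the penalty weight is chosen by seeded k-fold
cross-validation over a data-driven logarithmic grid that also contains
lambda = 0 (plain least squares), with ties resolved toward the sparser,
larger-lambda model.  Coefficient paths for positive penalties come from
coordinate descent (:func:`sklearn.linear_model.lasso_path`); the
lambda = 0 solution is the minimum-norm least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .biomech import day_insole_ls
from .config import RunConfig
from .datatypes import (
    SOURCE_CALIBRATED,
    SOURCE_GENERIC,
    LoadStimulusSeries,
    ParticipantDay,
    TrackerMinuteTable,
)
from .errors import ParameterError, ValidationError

TRACKER_FEATURES: Tuple[str, ...] = TrackerMinuteTable.FEATURES
CALIBRATION_FEATURES: Tuple[str, ...] = ("generic_ls",) + TRACKER_FEATURES


@dataclass
class LinearModel:
    """A fitted standardized linear model y = intercept + Z @ coef.

    ``coef`` applies to standardized features Z = (X - means) / scales.
    ``target_transform`` is "identity" or "log1p"; predictions are returned
    on the original target scale (clamping to zero is the caller's job).
    """

    feature_names: Tuple[str, ...]
    coef: np.ndarray
    intercept: float
    means: np.ndarray
    scales: np.ndarray
    penalty: float
    seed: int
    target_transform: str = "identity"

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        p = len(self.feature_names)
        if not (len(self.coef) == len(self.means) == len(self.scales) == p):
            raise ValidationError("coef/means/scales must align with feature_names")
        if np.any(self.scales <= 0):
            raise ValidationError("standardization scales must be > 0")
        if self.target_transform not in ("identity", "log1p"):
            raise ValidationError(f"unknown target_transform {self.target_transform!r}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        z = (X - self.means) / self.scales
        raw = self.intercept + z @ self.coef
        if self.target_transform == "log1p":
            raw = np.expm1(raw)
        return raw

    # --- plain-text serialization -------------------------------------------------
    def to_text(self) -> str:
        def fmt(a):
            return ",".join(repr(float(v)) for v in np.atleast_1d(a))

        lines = [
            "tibload-linear-model v1",
            f"feature_names={','.join(self.feature_names)}",
            f"means={fmt(self.means)}",
            f"scales={fmt(self.scales)}",
            f"coefficients={fmt(self.coef)}",
            f"intercept={float(self.intercept)!r}",
            f"penalty={float(self.penalty)!r}",
            f"seed={int(self.seed)}",
            f"target_transform={self.target_transform}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0] != "tibload-linear-model v1":
            raise ValidationError("not a tibload linear-model document")
        kv = dict(ln.split("=", 1) for ln in lines[1:])
        names = tuple(kv["feature_names"].split(","))
        parse = lambda s: np.array([float(v) for v in s.split(",")]) if s else np.array([])
        return cls(
            feature_names=names,
            coef=parse(kv["coefficients"]),
            intercept=float(kv["intercept"]),
            means=parse(kv["means"]),
            scales=parse(kv["scales"]),
            penalty=float(kv["penalty"]),
            seed=int(kv["seed"]),
            target_transform=kv.get("target_transform", "identity"),
        )


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 1e-12, scales, 1.0)
    return (X - means) / scales, means, scales


def _path_coefficients(Z: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coefficients for every penalty in ``lambdas`` on centered data.

    Positive penalties share one coordinate-descent path; lambda = 0 is the
    minimum-norm least-squares solution.
    """
    coefs = np.zeros((len(lambdas), Z.shape[1]))
    pos_vals = np.unique(lambdas[lambdas > 0])[::-1]
    if len(pos_vals):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alphas_out, path, _ = lasso_path(
                Z, yc, alphas=pos_vals, max_iter=10000, tol=1e-8
            )
        lookup = {float(a): path[:, i] for i, a in enumerate(alphas_out)}
        for i, lam in enumerate(lambdas):
            if lam > 0:
                coefs[i] = lookup[float(lam)]
    if np.any(lambdas == 0):
        w, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        coefs[lambdas == 0] = w
    return coefs


def default_lambda_grid(
    Z: np.ndarray,
    yc: np.ndarray,
    num: int = 9,
    min_ratio: float = 1e-4,
    include_zero: bool = True,
) -> np.ndarray:
    """Logarithmic grid from the smallest penalty that zeroes all coefficients."""
    n = len(yc)
    alpha_max = float(np.max(np.abs(Z.T @ yc))) / max(n, 1)
    if alpha_max <= 0:
        return np.array([0.0])
    grid = alpha_max * np.logspace(0, np.log10(min_ratio), num)
    if include_zero:
        grid = np.append(grid, 0.0)
    return grid


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_folds: int = 5,
    target_transform: str = "identity",
) -> LinearModel:
    """Fit a LASSO with internal cross-validated penalty selection.

    The penalty minimizing pooled out-of-fold mean squared error wins; exact
    ties go to the largest (sparsest) penalty.  With fewer rows than folds
    the fold count is reduced (with a warning); fewer than two rows is an
    error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n == 0 or len(y) == 0:
        raise ValidationError("cannot fit on empty input")
    if len(y) != n:
        raise ValidationError("X and y must have the same number of rows")
    if n < 2:
        raise ValidationError("need at least 2 rows to fit")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValidationError("X and y must be finite (no missing values)")
    if target_transform == "log1p":
        y = np.log1p(y)
    elif target_transform != "identity":
        raise ParameterError(f"unknown target_transform {target_transform!r}")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(p)
    )

    Zall, means, scales = _standardize(X)
    ycall = y - y.mean()
    if lambda_grid is None:
        grid = default_lambda_grid(Zall, ycall)
    else:
        grid = np.asarray(lambda_grid, dtype=float)
        if len(grid) == 0:
            raise ParameterError("lambda_grid must be non-empty")
        if np.any(grid < 0):
            raise ParameterError("lambda_grid entries must be >= 0")

    if len(grid) == 1:
        best_lambda = float(grid[0])
    else:
        folds = n_folds
        if n < folds:
            warnings.warn(
                f"only {n} rows; reducing cross-validation folds from {folds} to {n}",
                stacklevel=2,
            )
            folds = n
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
        sq_err = np.zeros(len(grid))
        for train_idx, val_idx in kf.split(X):
            Ztr, mtr, str_ = _standardize(X[train_idx])
            ytr = y[train_idx]
            coefs = _path_coefficients(Ztr, ytr - ytr.mean(), grid)
            Zval = (X[val_idx] - mtr) / str_
            preds = ytr.mean() + Zval @ coefs.T  # (n_val, n_lambda)
            sq_err += np.sum((preds - y[val_idx][:, None]) ** 2, axis=0)
        mse = sq_err / n
        winners = np.flatnonzero(mse <= mse.min())
        best_lambda = float(grid[winners][np.argmax(grid[winners])])

    coef = _path_coefficients(Zall, ycall, np.array([best_lambda]))[0]
    return LinearModel(
        feature_names=names,
        coef=coef,
        intercept=float(y.mean()),
        means=means,
        scales=scales,
        penalty=best_lambda,
        seed=int(seed),
        target_transform=target_transform,
    )


@dataclass
class GenericModelSet:
    """Leave-one-participant-out generic models: held-out id -> model
    trained on every *other* participant's minutes."""

    models: Dict[str, LinearModel]
    feature_names: Tuple[str, ...] = TRACKER_FEATURES
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, model in self.models.items():
            if tuple(model.feature_names) != tuple(self.feature_names):
                raise ValidationError(f"model for {pid!r} has mismatched features")

    def participants(self) -> List[str]:
        return list(self.models)


def _day_training_rows(day: ParticipantDay, ls: LoadStimulusSeries):
    X = day.tracker.feature_matrix(ls.minute_start)
    return X, ls.ls.copy()


def fit_generic(
    days: Sequence[ParticipantDay],
    config: Optional[RunConfig] = None,
    seed: int = 0,
    insole_ls: Optional[Dict[str, LoadStimulusSeries]] = None,
) -> GenericModelSet:
    """Fit one generic model per held-out participant.

    For each participant the model is trained on the pooled insole-covered
    minutes of every *other* participant (unweighted pooling).
    """
    config = config or RunConfig()
    ids = [d.participant_id for d in days]
    if len(ids) != len(set(ids)):
        raise ValidationError("participant ids must be unique")
    if len(days) < 2:
        raise ValidationError("need at least 2 participants for leave-one-out training")
    rows = {}
    for day in days:
        ls = (insole_ls or {}).get(day.participant_id) or day_insole_ls(day, config)
        if len(ls) == 0:
            raise ValidationError(
                f"participant {day.participant_id!r} has no insole-covered minutes"
            )
        rows[day.participant_id] = _day_training_rows(day, ls)
    models = {}
    transform = "log1p" if config.log1p_target else "identity"
    for held_out in ids:
        X = np.vstack([rows[pid][0] for pid in ids if pid != held_out])
        y = np.concatenate([rows[pid][1] for pid in ids if pid != held_out])
        models[held_out] = fit_lasso(
            X,
            y,
            feature_names=TRACKER_FEATURES,
            lambda_grid=config.lambda_grid,
            seed=seed,
            n_folds=config.n_folds,
            target_transform=transform,
        )
    return GenericModelSet(models=models, feature_names=TRACKER_FEATURES, seed=int(seed))


def predict_generic(
    model_set: GenericModelSet,
    day: ParticipantDay,
    minute_starts: Optional[np.ndarray] = None,
) -> LoadStimulusSeries:
    """Generic LS estimate for a day, clamped at zero."""
    pid = day.participant_id
    if pid not in model_set.models:
        raise ValidationError(f"no generic model for participant {pid!r}")
    if minute_starts is None:
        minute_starts = day.minute_starts
    X = day.tracker.feature_matrix(minute_starts)
    pred = np.maximum(model_set.models[pid].predict(X), 0.0)
    return LoadStimulusSeries(
        minute_start=np.asarray(minute_starts, dtype=float),
        ls=pred,
        source=np.asarray([SOURCE_GENERIC] * len(pred), dtype=object),
    )


@dataclass
class CalibrationModel:
    """Participant-specific second-stage model.

    Features are the generic LS estimate plus the five tracker features;
    the model is trained only on minutes that are insole-covered and inside
    the training window.  ``low_information_flag`` marks windows with fewer
    than the configured number of nonzero-LS training minutes.
    """

    model: LinearModel
    participant_id: str
    window_minutes: np.ndarray
    low_information_flag: bool


def _calibration_matrix(
    day: ParticipantDay, generic_ls: LoadStimulusSeries, minute_starts: np.ndarray
) -> np.ndarray:
    gen = generic_ls.subset(minute_starts).ls
    feats = day.tracker.feature_matrix(minute_starts)
    return np.column_stack([gen, feats])


def fit_calibration(
    day: ParticipantDay,
    generic_ls: LoadStimulusSeries,
    window_minutes: np.ndarray,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    insole_ls: Optional[LoadStimulusSeries] = None,
) -> CalibrationModel:
    """Fit the calibration model on the insole-covered minutes of a window."""
    config = config or RunConfig()
    window_minutes = np.asarray(window_minutes, dtype=float)
    ls = insole_ls if insole_ls is not None else day_insole_ls(day, config)
    usable = window_minutes[np.isin(window_minutes, ls.minute_start)]
    if len(usable) < 2:
        raise ValidationError(
            f"window has {len(usable)} insole-covered minute(s); need at least 2"
        )
    y = ls.subset(usable).ls
    X = _calibration_matrix(day, generic_ls, usable)
    transform = "log1p" if config.log1p_target else "identity"
    model = fit_lasso(
        X,
        y,
        feature_names=CALIBRATION_FEATURES,
        lambda_grid=config.lambda_grid,
        seed=seed,
        n_folds=config.n_folds,
        target_transform=transform,
    )
    low_info = int(np.count_nonzero(y > 0)) < config.low_information_minutes
    return CalibrationModel(
        model=model,
        participant_id=day.participant_id,
        window_minutes=usable,
        low_information_flag=low_info,
    )


def predict_calibration(
    cal: CalibrationModel,
    day: ParticipantDay,
    generic_ls: LoadStimulusSeries,
    minute_starts: np.ndarray,
) -> LoadStimulusSeries:
    """Calibrated LS estimate for the requested minutes, clamped at zero."""
    minute_starts = np.asarray(minute_starts, dtype=float)
    X = _calibration_matrix(day, generic_ls, minute_starts)
    pred = np.maximum(cal.model.predict(X), 0.0)
    return LoadStimulusSeries(
        minute_start=minute_starts,
        ls=pred,
        source=np.asarray([SOURCE_CALIBRATED] * len(pred), dtype=object),
    )


def evaluate_quarter_calibration(
    day: ParticipantDay,
    model_set: GenericModelSet,
    config: Optional[RunConfig] = None,
    seed: int = 0,
    insole_ls: Optional[LoadStimulusSeries] = None,
    generic_ls: Optional[LoadStimulusSeries] = None,
    min_minutes: int = 240,
) -> float:
    """Pooled held-out R^2 of quarter-wise calibration for one day.

    The day's insole-covered minutes are split into four contiguous
    quarters; each quarter in turn trains a calibration model that predicts
    the other three.  All held-out (prediction, target) pairs are pooled and
    scored with the coefficient of determination.
    """
    from .evaluation import r_squared  # local import to avoid a cycle

    config = config or RunConfig()
    ls = insole_ls if insole_ls is not None else day_insole_ls(day, config)
    if len(ls) < min_minutes:
        raise ValidationError(
            f"day has {len(ls)} insole-covered minutes; need >= {min_minutes}"
        )
    gen = generic_ls if generic_ls is not None else predict_generic(model_set, day)
    quarters = np.array_split(ls.minute_start, 4)
    preds, targets = [], []
    for q in quarters:
        cal = fit_calibration(day, gen, q, config=config, seed=seed, insole_ls=ls)
        held_out = ls.minute_start[~np.isin(ls.minute_start, q)]
        pred = predict_calibration(cal, day, gen, held_out)
        preds.append(pred.ls)
        targets.append(ls.subset(held_out).ls)
    return r_squared(np.concatenate(targets), np.concatenate(preds))
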