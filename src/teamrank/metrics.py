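"""Standard fit/evaluate adapters and calibration/discrimination metrics.

Provides ready-made :class:`~teamrank.data_model.ModelAdapter` implementations
for the three outcome families — ordinary least squares with mean squared
error for continuous outcomes, logistic regression with AUROC or calibration
metrics for binary outcomes, and a Cox proportional-hazards model with
concordance or fixed-horizon calibration for right-censored survival — plus
the calibration-curve machinery (lowess-smoothed observed vs. predicted
probabilities) behind the integrated calibration index (ICI) and its
percentile companions E50/E90/Emax, and hold-out / cross-validation /
bootstrap metric estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import FIT_FAILURE, Dataset, FeatureSet, ModelAdapter, make_split

__all__ = [
    "CalibrationCurve",
    "CalibrationIndices",
    "regression_adapter",
    "binary_adapter",
    "survival_adapter",
    "calibration_curve",
    "calibration_indices",
    "resample_evaluate",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# calibration curves and indices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Predicted probabilities paired with smoother-estimated observed ones."""

    predicted: np.ndarray
    observed_smooth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.observed_smooth):
            raise ValueError("predicted and observed_smooth must have equal length")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"predicted": self.predicted, "observed_smooth": self.observed_smooth}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationIndices:
    """ICI (mean), E50/E90 (percentiles) and Emax of |predicted - observed|."""

    ici: float
    e50: float
    e90: float
    emax: float


def calibration_curve(
    predicted: np.ndarray, outcomes: np.ndarray, frac: float = 0.75
) -> CalibrationCurve:
    """Estimate observed event probability at each predicted value by lowess.

    The smoother regresses the 0/1 outcome on the predicted probability and is
    evaluated at every predicted value; results are clipped to [0, 1].  With
    (near-)constant predictions the smoother degenerates to the event rate.
    """
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if predicted.shape != outcomes.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if np.ptp(predicted) < 1e-12:
        observed = np.full_like(predicted, outcomes.mean())
    else:
        observed = lowess(
            outcomes, predicted, frac=frac, it=0, xvals=predicted, return_sorted=False
        )
        observed = np.asarray(observed, dtype=float)
        if np.isnan(observed).any():  # sparse regions: fall back to the event rate
            observed = np.where(np.isnan(observed), outcomes.mean(), observed)
    return CalibrationCurve(predicted, np.clip(observed, 0.0, 1.0))


def calibration_indices(curve: CalibrationCurve) -> CalibrationIndices:
    """Summaries of the absolute calibration error d = |predicted - observed|.

    ICI is the mean of d; E50 and E90 are its 50th and 90th percentiles under
    the linear-interpolation quantile convention; Emax is the maximum.
    """
    d = np.abs(curve.predicted - curve.observed_smooth)
    e50, e90 = np.percentile(d, [50, 90])
    return CalibrationIndices(
        ici=float(d.mean()), e50=float(e50), e90=float(e90), emax=float(d.max())
    )


def ici_from_predictions(predicted: np.ndarray, outcomes: np.ndarray, frac: float = 0.75) -> float:
    return calibration_indices(calibration_curve(predicted, outcomes, frac=frac)).ici


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------


def _feature_matrix(dataset: Dataset, features: FeatureSet) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix with constant columns dropped (logged, not fatal)."""
    X = dataset.features(features).to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [name for j, name in enumerate(features) if j not in keep]
    if dropped:
        logger.info("dropping constant feature column(s): %s", dropped)
    return X[:, keep], [list(features)[j] for j in keep]


@dataclass(frozen=True)
class _OLSHandle:
    features: tuple[str, ...]
    used: tuple[str, ...]
    coef: np.ndarray  # intercept first


def regression_adapter() -> ModelAdapter:
    """OLS fit, mean-squared-error evaluation (minimize).

    Constant feature columns are dropped before fitting; a design matrix that
    is rank-deficient even after dropping them yields FIT_FAILURE.
    """

    def fit(train: Dataset, features: FeatureSet):
        X, used = _feature_matrix(train, features)
        if not used:
            return FIT_FAILURE
        y = train.outcome_values()
        design = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            return FIT_FAILURE
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return _OLSHandle(tuple(features), tuple(used), coef)

    def evaluate(handle: _OLSHandle, validation: Dataset) -> float:
        X = validation.features(FeatureSet(handle.used)).to_numpy(dtype=float)
        y = validation.outcome_values()
        pred = np.column_stack([np.ones(len(y)), X]) @ handle.coef
        return float(np.mean((y - pred) ** 2))

    return ModelAdapter(fit, evaluate, "minimize", name="ols_mse")


@dataclass(frozen=True)
class _LogitHandle:
    features: tuple[str, ...]
    used: tuple[str, ...]
    model: LogisticRegression


def _logit_probabilities(handle: _LogitHandle, dataset: Dataset) -> np.ndarray:
    X = dataset.features(FeatureSet(handle.used)).to_numpy(dtype=float)
    return handle.model.predict_proba(X)[:, 1]


def binary_adapter(
    metric: Literal["auroc", "ici", "composite"] = "auroc",
    lowess_frac: float = 0.75,
) -> ModelAdapter:
    """Logistic-regression adapter for binary outcomes.

    metrics: ``auroc`` (maximize), ``ici`` (minimize), or ``composite`` —
    discrimination with a calibration adjustment, AUROC - ICI (maximize), a
    concrete arbitration between the two goals.  The logistic fit carries a
    weak L2 ridge so separated data still yields a finite, usable model;
    FIT_FAILURE is reserved for single-class training outcomes or solver
    failure.
    """
    if metric not in ("auroc", "ici", "composite"):
        raise ValueError(f"unknown metric {metric!r}")

    def fit(train: Dataset, features: FeatureSet):
        X, used = _feature_matrix(train, features)
        if not used:
            return FIT_FAILURE
        y = train.outcome_values().astype(int)
        if len(np.unique(y)) < 2:
            return FIT_FAILURE
        model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=200)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, y)
        except Exception:
            return FIT_FAILURE
        return _LogitHandle(tuple(features), tuple(used), model)

    def evaluate(handle: _LogitHandle, validation: Dataset) -> float:
        prob = _logit_probabilities(handle, validation)
        y = validation.outcome_values().astype(int)
        if metric == "ici":
            return ici_from_predictions(prob, y, frac=lowess_frac)
        if len(np.unique(y)) < 2:
            return np.nan  # AUROC undefined on a single-class validation half
        auroc = float(roc_auc_score(y, prob))
        if metric == "auroc":
            return auroc
        return auroc - ici_from_predictions(prob, y, frac=lowess_frac)

    direction = "minimize" if metric == "ici" else "maximize"
    return ModelAdapter(fit, evaluate, direction, name=f"logistic_{metric}")


@dataclass(frozen=True)
class _CoxHandle:
    features: tuple[str, ...]
    used: tuple[str, ...]
    fitter: CoxPHFitter
    horizon: float | None


def survival_adapter(
    metric: Literal["concordance", "ici"] = "concordance",
    horizon: float | None = None,
    lowess_frac: float = 0.75,
) -> ModelAdapter:
    """Cox proportional-hazards adapter for right-censored outcomes.

    ``concordance`` (maximize) scores discrimination via Harrell's C on the
    validation half.  ``ici`` (minimize) scores calibration of the predicted
    event probability by a fixed horizon tau (default: median observed
    training time) against the lowess-smoothed observed status among subjects
    whose status at tau is known (event by tau, or still at risk past tau).
    Training halves without any event yield FIT_FAILURE.
    """
    if metric not in ("concordance", "ici"):
        raise ValueError(f"unknown metric {metric!r}")

    def fit(train: Dataset, features: FeatureSet):
        spec = train.outcome_spec
        X, used = _feature_matrix(train, features)
        if not used:
            return FIT_FAILURE
        frame = pd.DataFrame(X, columns=used)
        frame["__time"] = train.frame[spec.time].to_numpy(dtype=float)
        frame["__event"] = train.frame[spec.event].to_numpy(dtype=float)
        if frame["__event"].sum() == 0:
            return FIT_FAILURE
        fitter = CoxPHFitter(penalizer=1e-4)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(frame, duration_col="__time", event_col="__event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            return FIT_FAILURE
        tau = horizon
        if metric == "ici" and tau is None:
            tau = float(np.median(frame["__time"]))
        if tau is not None and tau > float(frame["__time"].max()):
            raise ValueError("calibration horizon lies beyond the last observed time")
        return _CoxHandle(tuple(features), tuple(used), fitter, tau)

    def evaluate(handle: _CoxHandle, validation: Dataset) -> float:
        spec = validation.outcome_spec
        X = validation.features(FeatureSet(handle.used)).to_numpy(dtype=float)
        frame = pd.DataFrame(X, columns=handle.used)
        times = validation.frame[spec.time].to_numpy(dtype=float)
        events = validation.frame[spec.event].to_numpy(dtype=float)
        partial_hazard = handle.fitter.predict_partial_hazard(frame).to_numpy()
        if metric == "concordance":
            return float(concordance_index(times, -partial_hazard, events))
        tau = handle.horizon
        surv = handle.fitter.predict_survival_function(frame, times=[tau]).to_numpy().ravel()
        prob_event = 1.0 - surv
        known = (events == 1) & (times <= tau) | (times > tau)
        if known.sum() < 10:
            return np.nan
        status = ((events == 1) & (times <= tau)).astype(float)[known]
        return ici_from_predictions(prob_event[known], status, frac=lowess_frac)

    direction = "maximize" if metric == "concordance" else "minimize"
    return ModelAdapter(fit, evaluate, direction, name=f"cox_{metric}")


# ---------------------------------------------------------------------------
# resampled metric estimation
# ---------------------------------------------------------------------------


def resample_evaluate(
    dataset: Dataset,
    adapter: ModelAdapter,
    features: FeatureSet,
    scheme: Literal["holdout", "cv", "bootstrap"] = "holdout",
    k: int = 5,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Estimate the adapter's metric by resampling; returns (mean, sd).

    holdout: one 50:50 split (sd = 0).  cv: k-fold cross-validation (k = n
    gives leave-one-out).  bootstrap: fit on a bootstrap resample, evaluate on
    the out-of-bag rows, repeated ``n_boot`` times.
    """
    data = dataset.complete_cases(features)
    n = data.n_rows
    rng = np.random.default_rng(seed)
    values: list[float] = []
    if scheme == "holdout":
        split = make_split(data, fraction=0.5, seed=seed)
        value = _fit_eval(data, adapter, features, split.train_indices, split.validation_indices)
        if value is None:
            raise RuntimeError("hold-out fit failed")
        return float(value), 0.0
    if scheme == "cv":
        if not 2 <= k <= n:
            raise ValueError("k must be in [2, n]")
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            value = _fit_eval(data, adapter, features, train, fold)
            if value is not None:
                values.append(value)
    elif scheme == "bootstrap":
        for _ in range(n_boot):
            sample = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), np.unique(sample))
            if len(oob) == 0:
                continue
            value = _fit_eval(data, adapter, features, sample, oob)
            if value is not None:
                values.append(value)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not values:
        raise RuntimeError("every resample fit failed")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def _fit_eval(data: Dataset, adapter: ModelAdapter, features: FeatureSet, train_idx, val_idx):
    handle = adapter.fit(data.subset_rows(np.asarray(train_idx)), features)
    if handle is FIT_FAILURE:
        return None
    value = float(adapter.evaluate(handle, data.subset_rows(np.asarray(val_idx))))
    return value if np.isfinite(value) else None
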