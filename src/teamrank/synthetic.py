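"""Synthetic clinical-style tabular datasets with known ground truth.

Emulates the structure of clinical model-building data: a handful of truly
informative features with stated effect sizes, many noise features, optional
skewed (lognormal) or multimodal feature distributions, and all three outcome
families (continuous, binary, right-censored survival).  Every generator is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import Dataset, FeatureSet, OutcomeSpec

__all__ = ["GroundTruth", "make_dataset", "make_multimodal_feature"]


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters for a synthetic dataset with planted signal.

    ``n_informative`` features carry the listed ``coefficients`` (linear
    predictor scale); ``n_noise`` features are pure standard-normal noise.
    ``skew_informative`` replaces informative features with lognormal draws
    (standardized), mirroring the heavy skew common in clinical variables.
    Survival outcomes follow a Weibull proportional-hazards model with
    independent uniform censoring calibrated to ``censoring_rate``.
    """

    family: str = "binary"
    n: int = 500
    coefficients: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    n_noise: int = 45
    noise_sd: float = 1.0
    intercept: float = 0.0
    censoring_rate: float = 0.3
    weibull_shape: float = 1.5
    baseline_scale: float = 1.0
    skew_informative: bool = False
    seed: int = 0

    @property
    def n_informative(self) -> int:
        return len(self.coefficients)

    @property
    def informative(self) -> FeatureSet:
        return FeatureSet(f"x{i + 1:03d}" for i in range(self.n_informative))

    @property
    def feature_names(self) -> list[str]:
        p = self.n_informative + self.n_noise
        return [f"x{i + 1:03d}" for i in range(p)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family": self.family,
            "n": self.n,
            "coefficients": list(self.coefficients),
            "n_noise": self.n_noise,
            "noise_sd": self.noise_sd,
            "intercept": self.intercept,
            "censoring_rate": self.censoring_rate,
            "weibull_shape": self.weibull_shape,
            "baseline_scale": self.baseline_scale,
            "skew_informative": self.skew_informative,
            "seed": self.seed,
            "informative": list(self.informative),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _design_matrix(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    p = truth.n_informative + truth.n_noise
    X = rng.standard_normal((truth.n, p))
    if truth.skew_informative:
        for j in range(truth.n_informative):
            z = np.exp(rng.standard_normal(truth.n))
            X[:, j] = (z - z.mean()) / z.std()
    return X


def _censoring_horizon(event_times: np.ndarray, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the requested rate.

    Solves E[fraction censored] = rate on the realized event times; with
    C ~ U(0, c), P(censored | T=t) = P(C < t) = min(t, c)/c, which decreases
    monotonically in c.
    """

    def censored_fraction(c: float) -> float:
        return float(np.mean(np.minimum(event_times, c) / c))

    lo, hi = 1e-8, float(event_times.max()) * 2
    while censored_fraction(hi) > rate:
        hi *= 2
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda c: censored_fraction(c) - rate, lo, hi))


def make_dataset(truth: GroundTruth) -> Dataset:
    """Generate a :class:`Dataset` from the stated ground truth.

    regression: y = X beta + intercept + Normal(0, noise_sd)
    binary:     y ~ Bernoulli(logistic(X beta + intercept))
    survival:   Weibull PH, h(t|x) = shape/scale * (t/scale)^(shape-1) * exp(x beta),
                with independent Uniform(0, c) censoring, c calibrated so the
                censored fraction matches ``censoring_rate``.
    """
    rng = np.random.default_rng(truth.seed)
    X = _design_matrix(truth, rng)
    beta = np.zeros(X.shape[1])
    beta[: truth.n_informative] = truth.coefficients
    lp = X @ beta + truth.intercept
    frame = pd.DataFrame(X, columns=truth.feature_names)

    if truth.family == "regression":
        frame["y"] = lp + truth.noise_sd * rng.standard_normal(truth.n)
        spec = OutcomeSpec("regression", outcome="y")
    elif truth.family == "binary":
        prob = 1.0 / (1.0 + np.exp(-lp))
        frame["y"] = rng.binomial(1, prob)
        spec = OutcomeSpec("binary", outcome="y")
    elif truth.family == "survival":
        # inverse-CDF draw: T = scale * (-log U / exp(lp))^(1/shape)
        u = rng.uniform(size=truth.n)
        times = truth.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / truth.weibull_shape)
        if truth.censoring_rate > 0:
            horizon = _censoring_horizon(times, truth.censoring_rate)
            censor = rng.uniform(0, horizon, size=truth.n)
            observed = np.minimum(times, censor)
            event = (times <= censor).astype(int)
        else:
            observed, event = times, np.ones(truth.n, dtype=int)
        frame["time"] = np.maximum(observed, 1e-9)
        frame["event"] = event
        spec = OutcomeSpec("survival", time="time", event="event")
    else:
        raise ValueError(f"unknown family {truth.family!r}")
    return Dataset(frame, spec, truth.feature_names)


def make_multimodal_feature(
    n: int,
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a univariate Gaussian-mixture feature.

    Returns ``(values, component_labels)``; labels are kept so cut-point
    recovery can be checked against the generating component.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(means) == len(sds) == len(weights)):
        raise ValueError("means, sds and weights must have equal length")
    if (weights < 0).any():
        raise ValueError("mixture weights must be nonnegative")
    if (sds <= 0).any():
        raise ValueError("mixture sds must be positive")
    total = weights.sum()
    if total <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / total
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(means), size=n, p=weights)
    values = rng.normal(means[labels], sds[labels])
    return values, labels


def write_fixture(dataset: Dataset, truth: GroundTruth, csv_path: str | Path) -> None:
    """Write a CSV fixture plus a ground-truth JSON sidecar next to it."""
    csv_path = Path(csv_path)
    dataset.to_csv(csv_path)
    truth.to_json(csv_path.with_suffix(".truth.json"))
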