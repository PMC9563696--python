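"""Pre-selection variable review: transformations, Box-Cox, mixtures, cut points.

Clinical variables are frequently skewed or multimodal, and reviewing each
candidate before any selection step pays off.  This module screens the usual
normalizing transforms (sqrt, cube root, log, Box-Cox) by the Shapiro-Wilk
statistic, fits an outcome-guided Box-Cox exponent by profile likelihood,
detects multimodality with univariate Gaussian mixtures selected by AIC, and
turns a multimodal fit into categorical variables via equal-posterior cut
points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "TransformReport",
    "MixtureFit",
    "screen_transformations",
    "boxcox_fit",
    "fit_mixture",
    "derive_cutpoints",
    "categorize",
    "apply_transform",
]

_SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class TransformCandidate:
    tag: str
    normality: float  # Shapiro-Wilk W; NaN when not applicable
    applicable: bool


@dataclass(frozen=True)
class TransformReport:
    variable: str
    candidates: tuple[TransformCandidate, ...]
    recommended: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable": self.variable,
            "recommended": self.recommended,
            "candidates": [
                {"transform": c.tag, "normality": None if np.isnan(c.normality) else c.normality,
                 "applicable": c.applicable}
                for c in self.candidates
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _shapiro_w(x: np.ndarray, seed: int = 0) -> float:
    if len(x) > _SHAPIRO_MAX_N:  # Shapiro-Wilk is defined for n <= 5000
        x = np.random.default_rng(seed).choice(x, size=_SHAPIRO_MAX_N, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).statistic)


def apply_transform(x: np.ndarray, tag: str) -> np.ndarray:
    """Apply a transform tag from :func:`screen_transformations` to new data."""
    if tag == "identity":
        return np.asarray(x, dtype=float)
    if tag == "sqrt":
        return np.sqrt(x)
    if tag == "cbrt":
        return np.cbrt(x)
    if tag == "log":
        return np.log(x)
    if tag.startswith("boxcox("):
        lam = float(tag[len("boxcox(") : -1])
        return special.boxcox(np.asarray(x, dtype=float), lam)
    raise ValueError(f"unknown transform tag {tag!r}")


def screen_transformations(
    x: Sequence[float] | np.ndarray,
    variable: str = "x",
    allow_shift: bool = False,
    include_boxcox: bool = False,
) -> TransformReport:
    """Score candidate transforms by Shapiro-Wilk normality; recommend the best.

    Default candidates are the basic normalizing transforms identity, sqrt,
    cbrt and log; ``include_boxcox`` adds a Box-Cox candidate at its
    normality-maximizing exponent (a continuous family that nearly always
    edges out log by construction, hence opt-in).  sqrt needs x >= 0 and
    log/Box-Cox x > 0; with ``allow_shift`` the data are shifted to
    x - min(x) + 1e-6*range first, otherwise domain-violating transforms are
    marked inapplicable.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 20:
        raise ValueError("need at least 20 non-missing values")
    if np.ptp(x) < 1e-12:
        raise ValueError("variable is constant")

    shift = 0.0
    if allow_shift and x.min() <= 0:
        shift = -x.min() + 1e-6 * np.ptp(x)
    xs = x + shift  # shifted copy used by domain-restricted transforms

    candidates: list[TransformCandidate] = []
    candidates.append(TransformCandidate("identity", _shapiro_w(x), True))
    candidates.append(TransformCandidate("cbrt", _shapiro_w(np.cbrt(x)), True))
    if xs.min() >= 0:
        candidates.append(TransformCandidate("sqrt", _shapiro_w(np.sqrt(xs)), True))
    else:
        candidates.append(TransformCandidate("sqrt", np.nan, False))
    if xs.min() > 0:
        candidates.append(TransformCandidate("log", _shapiro_w(np.log(xs)), True))
        if include_boxcox:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lam = float(stats.boxcox_normmax(xs, method="mle"))
            candidates.append(
                TransformCandidate(f"boxcox({lam:.4f})", _shapiro_w(special.boxcox(xs, lam)), True)
            )
    else:
        candidates.append(TransformCandidate("log", np.nan, False))
        if include_boxcox:
            candidates.append(TransformCandidate("boxcox(nan)", np.nan, False))

    applicable = [c for c in candidates if c.applicable]
    recommended = max(applicable, key=lambda c: c.normality).tag
    return TransformReport(variable, tuple(candidates), recommended)


# ---------------------------------------------------------------------------
# outcome-guided Box-Cox
# ---------------------------------------------------------------------------


def _outcome_loglik(lam: float, x: np.ndarray, y: np.ndarray, family: str) -> float:
    z = special.boxcox(x, lam)
    design = np.column_stack([np.ones(len(z)), z])
    if family == "regression":
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        n = len(y)
        return -0.5 * n * np.log(max(rss, 1e-300) / n)
    # binary: logistic log-likelihood at the MLE
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            return float(fit.llf)
        except Exception:
            return -np.inf


def boxcox_fit(
    x: Sequence[float] | np.ndarray,
    outcome: Sequence[float] | np.ndarray,
    family: Literal["regression", "binary"] = "regression",
    grid: tuple[float, float] = (-3.0, 3.0),
    n_grid: int = 61,
) -> float:
    """Box-Cox exponent for a positive covariate, chosen by profile likelihood.

    Maximizes the outcome-model likelihood (least squares for regression,
    logistic for binary) of y on boxcox(x, lambda) over a grid on ``grid``
    followed by bounded golden-section refinement around the grid optimum.
    lambda = 0 corresponds to the log transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and outcome must have equal length")
    if (x <= 0).any():
        raise ValueError("Box-Cox requires strictly positive x; shift the variable first")
    if np.ptp(x) < 1e-12:
        raise ValueError("variable is constant")
    if family not in ("regression", "binary"):
        raise ValueError(f"unsupported family {family!r}")
    lams = np.linspace(grid[0], grid[1], n_grid)
    lls = np.array([_outcome_loglik(lam, x, y, family) for lam in lams])
    best = int(np.argmax(lls))
    lo = lams[max(best - 1, 0)]
    hi = lams[min(best + 1, n_grid - 1)]
    result = optimize.minimize_scalar(
        lambda lam: -_outcome_loglik(lam, x, y, family),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(result.x)


# ---------------------------------------------------------------------------
# Gaussian mixtures and cut points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureFit:
    """AIC-selected univariate Gaussian mixture, components sorted by mean."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    aic: float
    cutpoints: np.ndarray
    aic_by_k: dict[int, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "aic": self.aic,
            "cutpoints": self.cutpoints.tolist(),
            "aic_by_k": {str(k): v for k, v in self.aic_by_k.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_mixture(
    x: Sequence[float] | np.ndarray,
    max_components: int = 3,
    seed: int = 0,
    variance_floor_frac: float = 0.01,
) -> MixtureFit:
    """Fit 1..max_components univariate Gaussian mixtures; keep the AIC minimizer.

    Each component count is fitted by a single EM run initialized with
    component means at the (j+1/2)/k sample quantiles, equal weights and
    equal variances Var(x).  The mixture likelihood with free variances is
    unbounded, so a likelihood-maximizing multistart chases spurious
    near-degenerate roots that derail AIC order selection; the well-dispersed
    deterministic start targets the consistent root instead, and a variance
    floor of ``variance_floor_frac * Var(x)`` rejects spike components
    outright (a component narrower than 1% of the marginal variance is noise,
    not a category worth constructing).  When n < 5 * max_components the
    component range is capped accordingly.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if np.ptp(x) < 1e-12:
        raise ValueError("variable is constant")
    n = len(x)
    max_components = max(1, min(max_components, n // 5))
    X = x.reshape(-1, 1)
    var = float(np.var(x))
    floor = max(variance_floor_frac * var, 1e-10)
    best_model, best_aic, best_k = None, np.inf, 1
    aic_by_k: dict[int, float] = {}
    for k in range(1, max_components + 1):
        model = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=1,
            weights_init=np.full(k, 1.0 / k),
            means_init=np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1),
            precisions_init=np.full((k, 1, 1), 1.0 / var),
            reg_covar=floor,
            tol=1e-6,
            max_iter=500,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
        aic = float(model.aic(X))
        aic_by_k[k] = aic
        if aic < best_aic:
            best_model, best_aic, best_k = model, aic, k
    order = np.argsort(best_model.means_.ravel())
    weights = best_model.weights_[order]
    means = best_model.means_.ravel()[order]
    variances = best_model.covariances_.ravel()[order]
    fit = MixtureFit(best_k, weights, means, variances, best_aic, np.empty(0), aic_by_k)
    cuts = derive_cutpoints(fit)
    return MixtureFit(best_k, weights, means, variances, best_aic, cuts, aic_by_k)


def derive_cutpoints(fit: MixtureFit) -> np.ndarray:
    """Equal-posterior boundaries between adjacent mixture components.

    Between each pair of adjacent-by-mean components the cut point solves
    w_a N(c; mu_a, s_a) = w_b N(c; mu_b, s_b) on (mu_a, mu_b); when no
    crossing exists in that interval the midpoint of the means is used.
    """
    cuts: list[float] = []
    for a in range(fit.n_components - 1):
        wa, ma, va = fit.weights[a], fit.means[a], fit.variances[a]
        wb, mb, vb = fit.weights[a + 1], fit.means[a + 1], fit.variances[a + 1]

        def diff(c: float) -> float:
            return (np.log(wa) + stats.norm.logpdf(c, ma, np.sqrt(va))) - (
                np.log(wb) + stats.norm.logpdf(c, mb, np.sqrt(vb))
            )

        lo, hi = ma + 1e-9 * max(1.0, abs(ma)), mb - 1e-9 * max(1.0, abs(mb))
        if lo >= hi or diff(lo) * diff(hi) > 0:
            cuts.append(0.5 * (ma + mb))
        else:
            cuts.append(float(optimize.brentq(diff, lo, hi)))
    return np.asarray(sorted(cuts))


def categorize(
    x: Sequence[float] | np.ndarray, cutpoints: Sequence[float] | np.ndarray
) -> pd.Categorical:
    """Assign each value to its right-closed interval level "(lo, hi]".

    Level j collects x in (c_{j-1}, c_j]; a value exactly at a cut point
    falls in the lower interval.  Missing values stay missing.  Empty
    cutpoints yield a single level.
    """
    x = np.asarray(x, dtype=float)
    cutpoints = np.asarray(cutpoints, dtype=float)
    if len(cutpoints) and (np.diff(cutpoints) <= 0).any():
        raise ValueError("cutpoints must be strictly increasing")
    edges = np.concatenate([[-np.inf], cutpoints, [np.inf]])
    return pd.cut(x, bins=edges, right=True)
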