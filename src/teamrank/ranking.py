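"""Match-based feature ranking via a maximum-likelihood Bradley-Terry team model.

The algorithm explores the feature search space by playing "matches" between
randomly drawn, disjoint feature teams of fixed size t.  Each match consists
of r rounds; each round draws a fresh random 50:50 split of the data, fits the
adapter's model for both teams on one half, evaluates the metric on the other
half, and credits a win to the better team.  A model can win either on the
objective value or by being the only one of the pair that fits at all.  Match
generation stops once every feature has appeared in at least k matches, or
after a maximum number of matches.

The resulting ledger of team rosters and win counts (n_i+, n_i-) is the
*feature-learning dataset*.  Feature strengths v are estimated by minimizing
the negative log-likelihood of the team-generalized Bradley-Terry model,

    - sum_i [ n_i+ log( e^{T_i+} / (e^{T_i+} + e^{T_i-}) )
            + n_i- log( e^{T_i-} / (e^{T_i+} + e^{T_i-}) ) ],

where T_i+- is the sum of member scores of each team.  The ML framing yields
standard errors and Wald confidence intervals per feature from the observed
information, and delta-method intervals for the strength of any feature set.
The estimate is asymptotically consistent: the larger the ledger, the better
the ranking.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import FIT_FAILURE, Dataset, FeatureSet, ModelAdapter, make_split
from .wrapper import SelectionResult

__all__ = [
    "MatchRecord",
    "MatchLedger",
    "RankingEstimate",
    "play_match",
    "generate_matches",
    "negative_log_likelihood",
    "fit_ranking",
    "set_strength_ci",
    "select_top",
]

DEFAULT_RIDGE = 1e-4


@dataclass(frozen=True)
class MatchRecord:
    """One pairing of two disjoint, equal-size feature teams.

    ``wins_plus``/``wins_minus`` are the win tallies n+ and n- (fractional:
    a tied round credits 0.5 to each side).  Rounds in which both fits fail
    are discarded, so ``wins_plus + wins_minus <= rounds_played``.
    """

    team_plus: FeatureSet
    team_minus: FeatureSet
    wins_plus: float
    wins_minus: float
    rounds_played: int

    def __post_init__(self) -> None:
        if len(self.team_plus) != len(self.team_minus):
            raise ValueError("teams must have equal size")
        if not self.team_plus.isdisjoint(self.team_minus):
            raise ValueError("teams within a match must be disjoint")
        if self.wins_plus < 0 or self.wins_minus < 0:
            raise ValueError("win counts must be nonnegative")
        if self.wins_plus + self.wins_minus > self.rounds_played + 1e-9:
            raise ValueError("wins cannot exceed rounds played")


@dataclass
class MatchLedger:
    """The feature-learning dataset: matches, win counts and coverage counts."""

    matches: list[MatchRecord]
    feature_universe: tuple[str, ...]
    eval_counts: dict[str, int]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.feature_universe)
        for match in self.matches:
            for name in list(match.team_plus) + list(match.team_minus):
                if name not in universe:
                    raise ValueError(f"feature {name!r} not in the universe")

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def total_wins(self) -> float:
        return sum(m.wins_plus + m.wins_minus for m in self.matches)

    def recount(self) -> dict[str, int]:
        counts = {name: 0 for name in self.feature_universe}
        for match in self.matches:
            for name in list(match.team_plus) + list(match.team_minus):
                counts[name] += 1
        return counts

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["team_plus", "team_minus", "n_plus", "n_minus", "rounds"])
            for m in self.matches:
                writer.writerow(
                    [
                        ";".join(m.team_plus),
                        ";".join(m.team_minus),
                        m.wins_plus,
                        m.wins_minus,
                        m.rounds_played,
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path, feature_universe: Sequence[str] | None = None) -> "MatchLedger":
        matches = []
        seen: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                plus = FeatureSet(row["team_plus"].split(";"))
                minus = FeatureSet(row["team_minus"].split(";"))
                matches.append(
                    MatchRecord(plus, minus, float(row["n_plus"]), float(row["n_minus"]), int(row["rounds"]))
                )
                for name in list(plus) + list(minus):
                    if name not in seen:
                        seen.append(name)
        universe = tuple(feature_universe) if feature_universe is not None else tuple(seen)
        ledger = cls(matches, universe, {})
        ledger.eval_counts = ledger.recount()
        return ledger

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_universe": list(self.feature_universe),
            "config": self.config,
            "matches": [
                {
                    "team_plus": list(m.team_plus),
                    "team_minus": list(m.team_minus),
                    "n_plus": m.wins_plus,
                    "n_minus": m.wins_minus,
                    "rounds": m.rounds_played,
                }
                for m in self.matches
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class RankingEstimate:
    """ML ranking scores with standard errors and Wald confidence intervals.

    Scores satisfy the sum-zero identifiability constraint; ``covariance`` is
    the full (constraint-projected) covariance of the score vector, used by
    :func:`set_strength_ci` for delta-method intervals on set strengths.
    """

    feature_universe: tuple[str, ...]
    scores: np.ndarray
    standard_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    covariance: np.ndarray
    ci_level: float
    constraint: str = "sum_zero"
    converged: bool = True
    nll_at_optimum: float = np.nan
    excluded: tuple[str, ...] = ()

    def score_of(self, name: str) -> float:
        return float(self.scores[self.feature_universe.index(name)])

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_universe,
                "score": self.scores,
                "se": self.standard_errors,
                "ci_lo": self.ci_lower,
                "ci_hi": self.ci_upper,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.as_table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# match play
# ---------------------------------------------------------------------------


def _round_metric(dataset: Dataset, adapter: ModelAdapter, team: FeatureSet, split) -> float | None:
    """Fit on the train half, evaluate on the validation half; None on failure."""
    data = dataset.complete_cases(team)
    if data.n_rows < 4:
        return None
    # the split indices refer to the complete-case rows of this team
    train = data.subset_rows(split.train_indices)
    validation = data.subset_rows(split.validation_indices)
    handle = adapter.fit(train, team)
    if handle is FIT_FAILURE:
        return None
    value = float(adapter.evaluate(handle, validation))
    if not np.isfinite(value):
        return None
    return value


def play_match(
    team_plus: FeatureSet,
    team_minus: FeatureSet,
    dataset: Dataset,
    adapter: ModelAdapter,
    rounds: int = 30,
    rng: np.random.Generator | None = None,
) -> MatchRecord:
    """Play ``rounds`` rounds between two teams, one fresh 50:50 split each.

    Win rules per round: better metric (per adapter direction) wins; a team
    whose fit fails or returns a non-finite metric loses the round; a tie
    credits 0.5 wins to each side; if both fits fail the round is discarded.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not team_plus.isdisjoint(team_minus):
        raise ValueError("teams must be disjoint")
    if len(team_plus) != len(team_minus):
        raise ValueError("teams must have equal size")
    rng = rng if rng is not None else np.random.default_rng(0)
    wins_plus = wins_minus = 0.0
    both = team_plus.union(team_minus)
    data = dataset.complete_cases(both)
    for _ in range(rounds):
        split_seed = int(rng.integers(0, 2**31 - 1))
        split = make_split(data, fraction=0.5, seed=split_seed)
        try:
            metric_plus = _round_metric(data, adapter, team_plus, split)
            metric_minus = _round_metric(data, adapter, team_minus, split)
        except Exception as exc:  # adapter contract violation
            raise RuntimeError(
                f"adapter raised during match {tuple(team_plus)} vs {tuple(team_minus)}: {exc}"
            ) from exc
        if metric_plus is None and metric_minus is None:
            continue  # no information about relative strength
        if metric_minus is None:
            wins_plus += 1.0
        elif metric_plus is None:
            wins_minus += 1.0
        elif adapter.better(metric_plus, metric_minus):
            wins_plus += 1.0
        elif adapter.better(metric_minus, metric_plus):
            wins_minus += 1.0
        else:
            wins_plus += 0.5
            wins_minus += 0.5
    return MatchRecord(team_plus, team_minus, wins_plus, wins_minus, rounds)


def generate_matches(
    dataset: Dataset,
    adapter: ModelAdapter,
    team_size: int = 10,
    rounds: int = 30,
    min_evals: int = 5,
    max_matches: int = 1000,
    seed: int = 0,
) -> MatchLedger:
    """Generate the feature-learning dataset of random team matches.

    Each match draws 2*team_size distinct features uniformly at random and
    splits them into two disjoint teams.  Matches are appended until every
    feature has appeared in at least ``min_evals`` matches or ``max_matches``
    is reached.
    """
    features = tuple(dataset.feature_names)
    p = len(features)
    if 2 * team_size > p:
        raise ValueError(f"2*team_size = {2 * team_size} exceeds feature count {p}")
    if min_evals < 1:
        raise ValueError("min_evals must be >= 1")
    if max_matches < 1:
        raise ValueError("max_matches must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in features}
    matches: list[MatchRecord] = []
    while len(matches) < max_matches and min(counts.values()) < min_evals:
        drawn = rng.choice(p, size=2 * team_size, replace=False)
        team_plus = FeatureSet(features[i] for i in drawn[:team_size])
        team_minus = FeatureSet(features[i] for i in drawn[team_size:])
        match = play_match(team_plus, team_minus, dataset, adapter, rounds=rounds, rng=rng)
        matches.append(match)
        for name in list(team_plus) + list(team_minus):
            counts[name] += 1
    return MatchLedger(
        matches,
        features,
        counts,
        config={
            "team_size": team_size,
            "rounds": rounds,
            "min_evals": min_evals,
            "max_matches": max_matches,
            "seed": seed,
            "adapter": adapter.name,
        },
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _design(ledger: MatchLedger) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed team-membership matrix A (m x p) and win-count vectors.

    Row i of A is +1 on team_plus members and -1 on team_minus members, so
    the score difference T_i+ - T_i- equals (A v)_i.
    """
    index = {name: j for j, name in enumerate(ledger.feature_universe)}
    m, p = len(ledger.matches), len(ledger.feature_universe)
    A = np.zeros((m, p))
    n_plus = np.zeros(m)
    n_minus = np.zeros(m)
    for i, match in enumerate(ledger.matches):
        for name in match.team_plus:
            A[i, index[name]] = 1.0
        for name in match.team_minus:
            A[i, index[name]] = -1.0
        n_plus[i] = match.wins_plus
        n_minus[i] = match.wins_minus
    return A, n_plus, n_minus


def _nll_grad(v: np.ndarray, A: np.ndarray, n_plus: np.ndarray, n_minus: np.ndarray, ridge: float):
    d = A @ v  # T+ - T-
    # log(1 + e^{-d}) and log(1 + e^{d}) via the stable softplus
    log_p_plus = -np.logaddexp(0.0, -d)
    log_p_minus = -np.logaddexp(0.0, d)
    nll = -(n_plus @ log_p_plus + n_minus @ log_p_minus) + ridge * float(v @ v)
    p_plus = np.exp(log_p_plus)
    resid = n_plus - (n_plus + n_minus) * p_plus
    grad = -(A.T @ resid) + 2.0 * ridge * v
    return float(nll), grad


def _hessian(v: np.ndarray, A: np.ndarray, n_plus: np.ndarray, n_minus: np.ndarray, ridge: float) -> np.ndarray:
    d = A @ v
    p = 1.0 / (1.0 + np.exp(-np.clip(d, -700, 700)))
    w = (n_plus + n_minus) * p * (1.0 - p)
    return (A * w[:, None]).T @ A + 2.0 * ridge * np.eye(A.shape[1])


def negative_log_likelihood(
    scores: Sequence[float] | np.ndarray,
    ledger: MatchLedger,
    ridge: float = 0.0,
) -> float:
    """Penalized negative log-likelihood of the team Bradley-Terry model.

    Computed with numerically stable softplus terms: no overflow for score
    sums up to |T| ~ 700.  ``scores`` is indexed by ``ledger.feature_universe``.
    """
    v = np.asarray(scores, dtype=float)
    if v.shape != (len(ledger.feature_universe),):
        raise ValueError(
            f"expected {len(ledger.feature_universe)} scores, got shape {v.shape}"
        )
    A, n_plus, n_minus = _design(ledger)
    nll, _ = _nll_grad(v, A, n_plus, n_minus, ridge)
    return nll


def fit_ranking(
    ledger: MatchLedger,
    ridge: float = DEFAULT_RIDGE,
    tol: float = 1e-8,
    ci_level: float = 0.95,
    x0: np.ndarray | None = None,
) -> RankingEstimate:
    """Maximum-likelihood feature ranking from a match ledger.

    Minimizes the (ridge-penalized) negative log-likelihood under the
    sum-zero identifiability constraint, via L-BFGS warm start plus Newton
    polishing with the analytic Hessian.  Standard errors come from the
    inverse observed information projected onto the sum-zero subspace; Wald
    CIs at ``ci_level``.  Features never appearing in any match carry no
    information: they are excluded from the fit and flagged.

    The default small ridge guards against divergent scores when a feature
    wins every match it plays (the ML estimate would be infinite); the
    resulting bias is tiny and documented.
    """
    if not ledger.matches:
        raise ValueError("ledger is empty")
    counts = ledger.recount()
    excluded = tuple(name for name in ledger.feature_universe if counts[name] == 0)
    if excluded:
        warnings.warn(
            f"{len(excluded)} feature(s) never appeared in a match and are excluded: {excluded}",
            stacklevel=2,
        )
    universe = tuple(n for n in ledger.feature_universe if counts[n] > 0)
    sub = MatchLedger(ledger.matches, universe, {}, config=ledger.config)
    A, n_plus, n_minus = _design(sub)
    p = len(universe)

    v0 = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float).copy()
    result = optimize.minimize(
        _nll_grad,
        v0,
        args=(A, n_plus, n_minus, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "gtol": 1e-10, "ftol": 1e-15},
    )
    v = result.x
    # Newton polish in the sum-zero subspace (the NLL is shift-invariant, so
    # projecting the step keeps the iteration well conditioned at ridge=0).
    P = np.eye(p) - np.full((p, p), 1.0 / p)
    for _ in range(100):
        _, grad = _nll_grad(v, A, n_plus, n_minus, ridge)
        pg = P @ grad
        if np.linalg.norm(pg) < tol:
            break
        H = _hessian(v, A, n_plus, n_minus, ridge)
        Hp = P @ H @ P + (np.max(np.diag(H)) + 1.0) * 1e-12 * np.eye(p)
        try:
            step = np.linalg.lstsq(Hp, pg, rcond=None)[0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        step = P @ step
        # backtracking to keep the NLL monotone
        nll0, _ = _nll_grad(v, A, n_plus, n_minus, ridge)
        alpha = 1.0
        for _ in range(40):
            trial = v - alpha * step
            nll1, _ = _nll_grad(trial, A, n_plus, n_minus, ridge)
            if nll1 <= nll0:
                v = trial
                break
            alpha *= 0.5
        else:
            break
    v = v - v.mean()  # NLL is shift-invariant; pin the sum-zero representative
    nll_opt, grad = _nll_grad(v, A, n_plus, n_minus, ridge)
    converged = bool(np.linalg.norm(P @ grad) < max(tol, 1e-7))

    H = _hessian(v, A, n_plus, n_minus, ridge)
    Hp = P @ H @ P
    if ridge == 0.0:
        rank = np.linalg.matrix_rank(Hp, tol=1e-10 * max(1.0, float(np.abs(Hp).max())))
        if rank < p - 1:
            raise np.linalg.LinAlgError(
                "observed information is singular at the optimum with ridge=0; "
                f"retry with the default ridge={DEFAULT_RIDGE}"
            )
    cov = np.linalg.pinv(Hp, hermitian=True)
    cov = P @ cov @ P
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return RankingEstimate(
        feature_universe=universe,
        scores=v,
        standard_errors=se,
        ci_lower=v - z * se,
        ci_upper=v + z * se,
        covariance=cov,
        ci_level=ci_level,
        converged=converged,
        nll_at_optimum=nll_opt,
        excluded=excluded,
    )


def set_strength_ci(
    estimate: RankingEstimate,
    feature_set: FeatureSet,
    ci_level: float | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Delta-method strength interval for an arbitrary feature set.

    The set strength g(v) = sum_{j in S} v_j is linear, so the delta method is
    exact to first order: se^2 = 1_S' Cov 1_S using the full covariance of the
    fitted scores.  Returns (strength, se, (lo, hi)).
    """
    level = estimate.ci_level if ci_level is None else ci_level
    try:
        idx = [estimate.feature_universe.index(name) for name in feature_set]
    except ValueError as exc:
        raise KeyError(f"feature not in the ranking estimate: {exc}") from exc
    indicator = np.zeros(len(estimate.feature_universe))
    indicator[idx] = 1.0
    strength = float(indicator @ estimate.scores)
    se = float(np.sqrt(max(indicator @ estimate.covariance @ indicator, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return strength, se, (strength - z * se, strength + z * se)


def select_top(estimate: RankingEstimate, m: int) -> SelectionResult:
    """The m features with the highest ranking scores.

    Ties are broken by smaller standard error, then lexicographic name.
    """
    p = len(estimate.feature_universe)
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}]")
    order = sorted(
        range(p),
        key=lambda j: (-estimate.scores[j], estimate.standard_errors[j], estimate.feature_universe[j]),
    )
    selected = FeatureSet(estimate.feature_universe[j] for j in order[:m])
    strength, _, _ = set_strength_ci(estimate, selected)
    return SelectionResult(
        selected=selected,
        trajectory=[(selected, strength)],
        evaluations_used=0,
        seed=0,
    )
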