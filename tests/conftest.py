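"""Shared fixtures: tiny datasets, oracle adapters, and ledger builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teamrank.data_model import (
    FIT_FAILURE,
    Dataset,
    FeatureSet,
    ModelAdapter,
    OutcomeSpec,
)
from teamrank.ranking import MatchLedger, MatchRecord


@pytest.fixture
def regression_dataset() -> Dataset:
    rng = np.random.default_rng(42)
    n = 80
    frame = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(1, 7)})
    frame["y"] = 2.0 * frame["x1"] - frame["x2"] + 0.3 * rng.standard_normal(n)
    return Dataset(frame, OutcomeSpec("regression", outcome="y"))


@pytest.fixture
def binary_dataset() -> Dataset:
    rng = np.random.default_rng(7)
    n = 200
    frame = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(1, 7)})
    lp = 2.0 * frame["x1"] + 1.0 * frame["x2"]
    frame["y"] = rng.binomial(1, 1 / (1 + np.exp(-lp)))
    return Dataset(frame, OutcomeSpec("binary", outcome="y"))


def oracle_adapter(informative: set[str]) -> ModelAdapter:
    """Deterministic metric = number of informative features in the team."""

    def fit(train: Dataset, features: FeatureSet):
        return tuple(features)

    def evaluate(handle, validation: Dataset) -> float:
        return float(len(set(handle) & informative))

    return ModelAdapter(fit, evaluate, "maximize", name="oracle")


def constant_adapter(value: float = 1.0) -> ModelAdapter:
    def fit(train, features):
        return tuple(features)

    def evaluate(handle, validation) -> float:
        return value

    return ModelAdapter(fit, evaluate, "maximize", name="constant")


def failing_adapter(failing_teams: set[frozenset[str]]) -> ModelAdapter:
    """Fails every fit whose feature set matches one of ``failing_teams``."""

    def fit(train, features: FeatureSet):
        if features.as_frozenset() in failing_teams:
            return FIT_FAILURE
        return tuple(features)

    def evaluate(handle, validation) -> float:
        return float(len(handle))

    return ModelAdapter(fit, evaluate, "maximize", name="failing")


class CountingAdapter:
    """Wraps an adapter, counting fit/evaluate calls (adapter-only access check)."""

    def __init__(self, inner: ModelAdapter):
        self.inner = inner
        self.fit_calls = 0
        self.evaluate_calls = 0

    def adapter(self) -> ModelAdapter:
        def fit(train, features):
            self.fit_calls += 1
            return self.inner.fit(train, features)

        def evaluate(handle, validation):
            self.evaluate_calls += 1
            return self.inner.evaluate(handle, validation)

        return ModelAdapter(fit, evaluate, self.inner.direction, name="counting")


def single_match_ledger(n_plus: float = 3.0, n_minus: float = 1.0) -> MatchLedger:
    """Two single-feature teams, one match: the textbook two-player comparison."""
    match = MatchRecord(
        FeatureSet(["a"]), FeatureSet(["b"]), n_plus, n_minus, int(n_plus + n_minus)
    )
    ledger = MatchLedger([match], ("a", "b"), {})
    ledger.eval_counts = ledger.recount()
    return ledger


def random_singles_ledger(
    n_features: int, n_matches: int, seed: int, true_scores: np.ndarray | None = None,
    rounds: int = 8,
) -> MatchLedger:
    """Random t=1 ledger; wins drawn from the Bradley-Terry model when
    ``true_scores`` is given, else uniformly."""
    rng = np.random.default_rng(seed)
    names = tuple(f"f{i}" for i in range(n_features))
    matches = []
    for _ in range(n_matches):
        i, j = rng.choice(n_features, size=2, replace=False)
        if true_scores is not None:
            p = 1.0 / (1.0 + np.exp(-(true_scores[i] - true_scores[j])))
        else:
            p = rng.uniform(0.2, 0.8)
        wins = rng.binomial(rounds, p)
        matches.append(
            MatchRecord(FeatureSet([names[i]]), FeatureSet([names[j]]), float(wins),
                        float(rounds - wins), rounds)
        )
    ledger = MatchLedger(matches, names, {})
    ledger.eval_counts = ledger.recount()
    return ledger
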