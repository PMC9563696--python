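"""Baseline combinatorial wrapper searches: forward, backward, bidirectional, random.

All four algorithms see the data only through the :class:`~teamrank.data_model.ModelAdapter`
contract and a fixed train/validation :class:`~teamrank.data_model.SplitPlan`,
so their selections are metric-for-metric comparable with the match-based
ranking.  Greedy ties are broken lexicographically for reproducibility.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .data_model import FIT_FAILURE, Dataset, FeatureSet, ModelAdapter, SplitPlan

__all__ = [
    "SelectionResult",
    "forward_select",
    "backward_select",
    "bidirectional_select",
    "random_search",
]


@dataclass
class SelectionResult:
    """A chosen feature set plus the trajectory of candidates that produced it."""

    selected: FeatureSet
    trajectory: list[tuple[FeatureSet, float]]
    evaluations_used: int
    seed: int = 0

    @property
    def best_metric(self) -> float:
        for fs, value in self.trajectory:
            if fs.as_frozenset() == self.selected.as_frozenset():
                return value
        raise ValueError("selected set not found in trajectory")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected": list(self.selected),
            "evaluations_used": self.evaluations_used,
            "seed": self.seed,
            "trajectory": [
                {"features": list(fs), "metric": value} for fs, value in self.trajectory
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            selected=FeatureSet(payload["selected"]),
            trajectory=[
                (FeatureSet(e["features"]), float(e["metric"])) for e in payload["trajectory"]
            ],
            evaluations_used=int(payload["evaluations_used"]),
            seed=int(payload.get("seed", 0)),
        )


def _eval_on_split(
    dataset: Dataset, adapter: ModelAdapter, features: FeatureSet, split: SplitPlan
) -> float | None:
    """Fit on the train half, evaluate on the validation half; None on failure.

    Rows with missing values in the active feature subset (or outcome) are
    dropped from both halves (complete-case within the candidate set).
    """
    cols = list(features) + list(dataset.outcome_spec.columns)
    mask = dataset.frame[cols].notna().all(axis=1).to_numpy()
    train = dataset.subset_rows([i for i in split.train_indices if mask[i]])
    validation = dataset.subset_rows([i for i in split.validation_indices if mask[i]])
    handle = adapter.fit(train, features)
    if handle is FIT_FAILURE:
        return None
    value = float(adapter.evaluate(handle, validation))
    return value if math.isfinite(value) else None


class _Evaluator:
    """Memoizing evaluator shared by the greedy searches."""

    def __init__(self, dataset: Dataset, adapter: ModelAdapter, split: SplitPlan):
        self.dataset = dataset
        self.adapter = adapter
        self.split = split
        self.cache: dict[frozenset[str], float | None] = {}
        self.evaluations = 0
        self.trajectory: list[tuple[FeatureSet, float]] = []

    def __call__(self, features: FeatureSet) -> float | None:
        key = features.as_frozenset()
        if key not in self.cache:
            value = _eval_on_split(self.dataset, self.adapter, features, self.split)
            self.cache[key] = value
            self.evaluations += 1
            if value is not None:
                self.trajectory.append((features, value))
        return self.cache[key]


def _best_candidate(
    candidates: list[FeatureSet], evaluator: _Evaluator, adapter: ModelAdapter
) -> tuple[FeatureSet | None, float | None]:
    """Best candidate by metric; ties broken by lexicographic member tuple."""
    best_fs, best_val = None, None
    for fs in sorted(candidates, key=lambda f: tuple(sorted(f))):
        value = evaluator(fs)
        if value is None:
            continue
        if best_val is None or adapter.better(value, best_val):
            best_fs, best_val = fs, value
    return best_fs, best_val


def forward_select(
    dataset: Dataset, adapter: ModelAdapter, m: int, split: SplitPlan
) -> SelectionResult:
    """Greedy forward selection: add the best-improving feature until size m.

    Stops early when no addition strictly improves the validation metric.
    Under a constant metric the first step still accepts the lexicographically
    first feature (there is no baseline to improve on), then stops at size 1.
    """
    names = dataset.feature_names
    if m > len(names):
        raise ValueError("m exceeds the feature count")
    evaluator = _Evaluator(dataset, adapter, split)
    current = FeatureSet(())
    current_value: float | None = None
    while len(current) < m:
        candidates = [current.union([name]) for name in names if name not in current]
        best_fs, best_val = _best_candidate(candidates, evaluator, adapter)
        if best_fs is None:
            warnings.warn("all candidate fits failed; stopping with best-so-far", stacklevel=2)
            break
        if current_value is not None and not adapter.better(best_val, current_value):
            break
        current, current_value = best_fs, best_val
    return SelectionResult(current, evaluator.trajectory, evaluator.evaluations, split.seed)


def backward_select(
    dataset: Dataset, adapter: ModelAdapter, m: int, split: SplitPlan
) -> SelectionResult:
    """Greedy backward elimination from the full set down to size m.

    Each step removes the feature whose removal leaves the best (or least
    harmed) validation metric.
    """
    names = dataset.feature_names
    if m > len(names):
        raise ValueError("m exceeds the feature count")
    evaluator = _Evaluator(dataset, adapter, split)
    current = FeatureSet(names)
    current_value = evaluator(current)
    if current_value is None:
        raise RuntimeError(
            "the full-set fit failed; reduce the candidate feature count before backward selection"
        )
    while len(current) > m:
        candidates = [current.without(name) for name in current]
        best_fs, best_val = _best_candidate(candidates, evaluator, adapter)
        if best_fs is None:
            warnings.warn("all candidate fits failed; stopping with best-so-far", stacklevel=2)
            break
        current, current_value = best_fs, best_val
    return SelectionResult(current, evaluator.trajectory, evaluator.evaluations, split.seed)


def bidirectional_select(
    dataset: Dataset,
    adapter: ModelAdapter,
    m: int,
    split: SplitPlan,
    move_budget: int | None = None,
) -> SelectionResult:
    """Stepwise search alternating best-add and best-drop moves.

    At each step the best add (while below size m) and the best drop (above
    size 1) are compared and the better move is accepted if it strictly
    improves the current validation metric.  A visited-set memo prevents
    cycling; the move budget (default 10*p) guarantees termination.
    """
    names = dataset.feature_names
    if m > len(names):
        raise ValueError("m exceeds the feature count")
    budget = move_budget if move_budget is not None else 10 * len(names)
    evaluator = _Evaluator(dataset, adapter, split)
    visited: set[frozenset[str]] = set()
    current = FeatureSet(())
    current_value: float | None = None
    for _ in range(budget):
        visited.add(current.as_frozenset())
        candidates: list[FeatureSet] = []
        if len(current) < m:
            candidates += [current.union([n]) for n in names if n not in current]
        if len(current) > 1:
            candidates += [current.without(n) for n in current]
        candidates = [c for c in candidates if c.as_frozenset() not in visited]
        if not candidates:
            break
        best_fs, best_val = _best_candidate(candidates, evaluator, adapter)
        if best_fs is None:
            break
        if current_value is not None and not adapter.better(best_val, current_value):
            break
        current, current_value = best_fs, best_val
    return SelectionResult(current, evaluator.trajectory, evaluator.evaluations, split.seed)


def random_search(
    dataset: Dataset,
    adapter: ModelAdapter,
    m: int,
    n_candidates: int,
    split: SplitPlan,
    seed: int = 0,
) -> SelectionResult:
    """Evaluate uniformly sampled distinct size-m feature sets; keep the best.

    When ``n_candidates`` covers all C(p, m) subsets the search is exhaustive
    (deterministic enumeration), so it returns the global optimum of the
    validation metric.
    """
    names = dataset.feature_names
    p = len(names)
    if m > p:
        raise ValueError("m exceeds the feature count")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    total = math.comb(p, m)
    rng = np.random.default_rng(seed)
    if n_candidates >= total:
        candidate_sets = [FeatureSet(c) for c in combinations(names, m)]
    else:
        seen: set[frozenset[str]] = set()
        candidate_sets = []
        while len(candidate_sets) < n_candidates:
            drawn = rng.choice(p, size=m, replace=False)
            fs = FeatureSet(names[i] for i in sorted(drawn))
            if fs.as_frozenset() not in seen:
                seen.add(fs.as_frozenset())
                candidate_sets.append(fs)
    evaluator = _Evaluator(dataset, adapter, split)
    best_fs, best_val = None, None
    for fs in candidate_sets:
        value = evaluator(fs)
        if value is None:
            continue
        if best_val is None or adapter.better(value, best_val):
            best_fs, best_val = fs, value
    if best_fs is None:
        raise RuntimeError("every candidate fit failed")
    return SelectionResult(best_fs, evaluator.trajectory, evaluator.evaluations, seed)
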