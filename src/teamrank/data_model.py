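"""Tabular dataset abstraction, feature bookkeeping and the fit/evaluate contract.

Every selection algorithm in this package — the match-based ranking as well as
the greedy and random wrapper baselines — sees data only through :class:`Dataset`
and a :class:`ModelAdapter`.  The adapter pairs a ``fit`` procedure (training
rows + feature subset -> fitted-model handle, or the :data:`FIT_FAILURE`
sentinel) with an ``evaluate`` procedure (handle + validation rows -> a real
metric value) and declares whether the metric is minimized or maximized.
Keeping model fitting behind this contract makes the ranking algorithm and the
baselines metric-for-metric comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FIT_FAILURE",
    "OutcomeSpec",
    "Dataset",
    "FeatureSet",
    "SplitPlan",
    "ModelAdapter",
    "load_dataset",
    "make_split",
]


class _FitFailure:
    """Sentinel returned by adapters when a model cannot be fitted.

    A failed fit is a first-class value, never an exception escaping the
    search loop: a team whose model cannot be fitted simply loses the round.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "FIT_FAILURE"

    def __bool__(self) -> bool:
        return False


FIT_FAILURE = _FitFailure()

Family = Literal["regression", "binary", "survival"]


@dataclass(frozen=True)
class OutcomeSpec:
    """Declares the outcome family and which column(s) hold the outcome.

    For ``regression`` and ``binary`` outcomes, ``outcome`` names the single
    outcome column.  For ``survival``, ``time`` names the (strictly positive)
    follow-up time column and ``event`` the 0/1 event indicator.
    """

    family: Family
    outcome: str | None = None
    time: str | None = None
    event: str | None = None

    def __post_init__(self) -> None:
        if self.family in ("regression", "binary"):
            if not self.outcome:
                raise ValueError(f"family={self.family!r} requires an outcome column name")
        elif self.family == "survival":
            if not (self.time and self.event):
                raise ValueError("family='survival' requires time and event column names")
        else:
            raise ValueError(f"unknown outcome family {self.family!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        if self.family == "survival":
            return (self.time, self.event)  # type: ignore[return-value]
        return (self.outcome,)  # type: ignore[return-value]


@dataclass(frozen=True)
class FeatureSet:
    """An ordered subset of a dataset's feature names (a "team")."""

    members: tuple[str, ...]

    def __init__(self, members: Iterable[str]):
        members = tuple(members)
        if len(set(members)) != len(members):
            raise ValueError("FeatureSet members must be unique")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def union(self, other: "FeatureSet | Iterable[str]") -> "FeatureSet":
        extra = [m for m in other if m not in self.members]
        return FeatureSet(self.members + tuple(extra))

    def without(self, name: str) -> "FeatureSet":
        return FeatureSet(m for m in self.members if m != name)

    def isdisjoint(self, other: "FeatureSet") -> bool:
        return set(self.members).isdisjoint(other.members)

    def as_frozenset(self) -> frozenset[str]:
        return frozenset(self.members)


class Dataset:
    """A rectangular table of subjects x (features + outcome columns).

    Feature columns are numeric; non-numeric columns are label-encoded at load
    time with the mapping recorded in ``encodings``.  The outcome columns are
    excluded from ``feature_names``.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        outcome_spec: OutcomeSpec,
        feature_names: Sequence[str] | None = None,
        encodings: dict[str, dict[Any, int]] | None = None,
        check_levels: bool = True,
    ):
        self.outcome_spec = outcome_spec
        for col in outcome_spec.columns:
            if col not in frame.columns:
                raise ValueError(f"outcome column {col!r} not in data")
        if feature_names is None:
            feature_names = [c for c in frame.columns if c not in outcome_spec.columns]
        feature_names = list(feature_names)
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("feature names must be unique")
        for col in outcome_spec.columns:
            if col in feature_names:
                raise ValueError(f"outcome column {col!r} cannot be a feature")
        missing = [c for c in feature_names if c not in frame.columns]
        if missing:
            raise ValueError(f"feature columns not in data: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.feature_names = feature_names
        self.encodings = encodings or {}
        self._validate_outcome(check_levels)

    # -- validation ---------------------------------------------------------

    def _validate_outcome(self, check_levels: bool = True) -> None:
        # a row subset (e.g. a bootstrap resample or training half) may
        # legitimately lose an outcome level, so the two-level check applies
        # only to freshly constructed/loaded datasets
        spec = self.outcome_spec
        if spec.family == "binary" and check_levels:
            levels = pd.unique(self.frame[spec.outcome].dropna())
            if len(levels) != 2:
                raise ValueError(
                    f"binary outcome {spec.outcome!r} has {len(levels)} observed levels, expected 2"
                )
        elif spec.family == "survival":
            times = self.frame[spec.time]
            if (times <= 0).any():
                raise ValueError("survival times must be strictly positive")
            events = pd.unique(self.frame[spec.event].dropna())
            if not set(events) <= {0, 1}:
                raise ValueError("event indicator must be 0/1")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self, feature_set: FeatureSet | Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(feature_set) if feature_set is not None else self.feature_names
        unknown = [c for c in cols if c not in self.feature_names]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        return self.frame[cols]

    def outcome(self) -> pd.DataFrame:
        return self.frame[list(self.outcome_spec.columns)]

    def outcome_values(self) -> np.ndarray:
        """Outcome as an array: 1-d for regression/binary, (n, 2) [time, event] for survival."""
        spec = self.outcome_spec
        if spec.family == "survival":
            return self.frame[[spec.time, spec.event]].to_numpy(dtype=float)
        return self.frame[spec.outcome].to_numpy(dtype=float)

    def subset_rows(self, indices: Sequence[int] | np.ndarray) -> "Dataset":
        return Dataset(
            self.frame.iloc[np.asarray(indices, dtype=int)],
            self.outcome_spec,
            self.feature_names,
            self.encodings,
            check_levels=False,
        )

    def restrict_features(self, feature_set: FeatureSet) -> "Dataset":
        cols = list(feature_set) + list(self.outcome_spec.columns)
        return Dataset(
            self.frame[cols], self.outcome_spec, list(feature_set), self.encodings,
            check_levels=False,
        )

    def complete_cases(self, feature_set: FeatureSet) -> "Dataset":
        """Rows without missing values in the active feature subset or outcome."""
        cols = list(feature_set) + list(self.outcome_spec.columns)
        mask = self.frame[cols].notna().all(axis=1)
        return self.subset_rows(np.flatnonzero(mask.to_numpy()))

    def feature_set(self) -> FeatureSet:
        return FeatureSet(self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        """Write the table; %.17g keeps float64 values bit-exact on re-read."""
        sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
        self.frame.to_csv(path, index=False, sep=sep, float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.outcome_spec == other.outcome_spec
            and self.feature_names == other.feature_names
            and self.frame.equals(other.frame)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Dataset(n={self.n_rows}, p={len(self.feature_names)}, "
            f"family={self.outcome_spec.family!r})"
        )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation row-index sets produced by :func:`make_split`."""

    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    seed: int
    stratified: bool = False

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.validation_indices):
            raise ValueError("train and validation indices must be disjoint")


@dataclass(frozen=True)
class ModelAdapter:
    """Paired fit/evaluate procedures plus the optimization direction.

    ``fit(train_dataset, feature_set)`` returns a fitted-model handle or
    :data:`FIT_FAILURE`.  ``evaluate(handle, validation_dataset)`` returns a
    real metric value and must be deterministic given the handle and rows.
    """

    fit: Callable[[Dataset, FeatureSet], Any]
    evaluate: Callable[[Any, Dataset], float]
    direction: Literal["minimize", "maximize"]
    name: str = "adapter"

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")

    def better(self, a: float, b: float) -> bool:
        """True iff metric value ``a`` is strictly better than ``b``."""
        return a < b if self.direction == "minimize" else a > b

    def worst_value(self) -> float:
        return np.inf if self.direction == "minimize" else -np.inf


# ---------------------------------------------------------------------------
# loading and splitting
# ---------------------------------------------------------------------------


def load_dataset(
    path: str | Path,
    outcome_spec: OutcomeSpec,
    feature_names: Sequence[str] | None = None,
) -> Dataset:
    """Read a CSV/TSV file (header row required) into a validated :class:`Dataset`.

    Non-numeric feature columns are label-encoded (levels sorted by string
    value) and the mapping is recorded in ``Dataset.encodings``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in outcome_spec.columns:
        if col not in frame.columns:
            raise ValueError(f"outcome column {col!r} missing from {path.name}")
    candidates = feature_names or [c for c in frame.columns if c not in outcome_spec.columns]
    encodings: dict[str, dict[Any, int]] = {}
    for col in candidates:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            levels = sorted(frame[col].dropna().astype(str).unique())
            mapping = {level: code for code, level in enumerate(levels)}
            encodings[col] = mapping
            frame[col] = frame[col].astype(str).map(mapping).astype(float)
    return Dataset(frame, outcome_spec, candidates, encodings)


def _allocate_train_sizes(stratum_sizes: Sequence[int], fraction: float) -> list[int]:
    """Largest-remainder allocation of the train quota across strata.

    Guarantees the total train size equals ``round(fraction * n)`` while each
    stratum's train share differs from ``fraction * n_s`` by less than 1.
    """
    quotas = [fraction * n for n in stratum_sizes]
    base = [int(np.floor(q)) for q in quotas]
    total_target = int(round(fraction * sum(stratum_sizes)))
    shortfall = total_target - sum(base)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    sizes = list(base)
    for i in remainders[: max(shortfall, 0)]:
        sizes[i] += 1
    return sizes


def make_split(
    dataset: Dataset,
    fraction: float = 0.5,
    seed: int = 0,
    stratify: bool | None = None,
) -> SplitPlan:
    """Draw a reproducible train/validation split of the dataset rows.

    ``fraction`` is the train share.  For binary outcomes stratification (on
    the outcome) is on by default, and for survival outcomes on the event
    indicator, so that event prevalence differs between the halves by at most
    one subject per level.  Row order carries no information: the assignment
    is a pure function of (row count, outcome, fraction, seed, stratify).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = dataset.n_rows
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    spec = dataset.outcome_spec
    if stratify is None:
        stratify = spec.family in ("binary", "survival")
    rng = np.random.default_rng(seed)
    if stratify and spec.family in ("binary", "survival"):
        col = spec.outcome if spec.family == "binary" else spec.event
        labels = dataset.frame[col].to_numpy()
        strata = [np.flatnonzero(labels == level) for level in np.unique(labels)]
    else:
        stratify = False
        strata = [np.arange(n)]
    if any(len(s) < 2 for s in strata):
        raise ValueError("too few rows in a stratum to split")
    train_sizes = _allocate_train_sizes([len(s) for s in strata], fraction)
    train: list[int] = []
    validation: list[int] = []
    for idx, n_train in zip(strata, train_sizes):
        perm = rng.permutation(idx)
        train.extend(perm[:n_train].tolist())
        validation.extend(perm[n_train:].tolist())
    return SplitPlan(
        train_indices=tuple(sorted(train)),
        validation_indices=tuple(sorted(validation)),
        seed=seed,
        stratified=bool(stratify),
    )
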