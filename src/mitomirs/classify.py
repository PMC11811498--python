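"""Repeated random-forest classification of mitomiR vs other miRNAs.

The classifier separates the two classes on five criteria — PAI plus the
four binary flags (circulating, confident, has_target, has_disease) — and
the quantity of interest is not the classifier itself but the ranking of
criterion importances and the train/test error levels, aggregated over
repeated runs.

Each run: purify the dataset by homolog groups (a fresh random
representative per group), split uniformly at random into train (2/3) and
test (1/3), fit a bagged randomized-tree ensemble, record misclassification
fractions and per-criterion importances. Runs are repeated (default 100)
and summarized as mean ± SD errors and per-criterion importance
distributions (mean, SD, quartiles) with a ranking by mean importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from mitomirs._rng import substream
from mitomirs.annotation import CLASSIFIER_FEATURES
from mitomirs.enrichment import purify_by_homology

__all__ = [
    "ClassifierConfig",
    "ClassifierRunResult",
    "ImportanceSummary",
    "run_classification",
    "summarize_errors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    n_runs: int = 100
    test_fraction: float = 1.0 / 3.0
    n_trees: int = 500
    importance_kind: str = "impurity"  # or "permutation"
    stratify: bool = False
    max_retries: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_trees < 1 or self.n_runs < 1:
            raise ValueError("n_trees and n_runs must be positive")
        if self.importance_kind not in {"impurity", "permutation"}:
            raise ValueError("importance_kind must be 'impurity' or 'permutation'")


@dataclass(frozen=True)
class ClassifierRunResult:
    train_error: float
    test_error: float
    importances: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ImportanceSummary:
    """Per-criterion importance distribution over runs and the mean ranking."""

    stats: pd.DataFrame  # rows: criterion; columns: mean, sd, q25, median, q75
    ranking: tuple[str, ...]  # criteria by decreasing mean importance


def _split_indices(
    n: int, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return perm[n_test:], perm[:n_test]


def run_classification(
    criterion_table: pd.DataFrame,
    groups: Sequence,
    config: ClassifierConfig | None = None,
    features: Sequence[str] = tuple(CLASSIFIER_FEATURES),
) -> tuple[list[ClassifierRunResult], ImportanceSummary]:
    """Repeated purified random-forest runs with importance aggregation.

    A run whose purified train or test part lacks one of the classes is
    retried on the next random substream (logged); after ``max_retries``
    consecutive failures the run errors out.
    """
    if config is None:
        config = ClassifierConfig()
    features = list(features)
    missing = [f for f in features if f not in criterion_table.columns]
    if missing:
        raise KeyError(f"criterion table lacks feature columns: {missing}")

    results: list[ClassifierRunResult] = []
    attempt = 0
    run = 0
    while run < config.n_runs:
        rng = substream(config.seed, "classifier", f"run-{run}-attempt-{attempt}")
        rows = purify_by_homology(criterion_table, groups, rng)
        y = (rows["label"] == "mitomiR").to_numpy()
        X = rows[features].to_numpy(dtype=float)
        if config.stratify:
            train_idx, test_idx = _stratified_split(y, config.test_fraction, rng)
        else:
            train_idx, test_idx = _split_indices(len(rows), config.test_fraction, rng)
        if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
            attempt += 1
            logger.warning("run %d: a class is absent after purification/split; retrying", run)
            if attempt > config.max_retries:
                raise RuntimeError(f"run {run}: could not obtain both classes after retries")
            continue

        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[train_idx], y[train_idx])
        train_error = float(np.mean(forest.predict(X[train_idx]) != y[train_idx]))
        test_error = float(np.mean(forest.predict(X[test_idx]) != y[test_idx]))

        if config.importance_kind == "impurity":
            imp = forest.feature_importances_
            total = imp.sum()
            if total > 0:
                imp = imp / total
        else:
            perm = permutation_importance(
                forest,
                X[test_idx],
                y[test_idx],
                n_repeats=10,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            imp = perm.importances_mean

        results.append(
            ClassifierRunResult(
                train_error=train_error,
                test_error=test_error,
                importances={f: float(v) for f, v in zip(features, imp)},
            )
        )
        run += 1
        attempt = 0
    return results, summarize_importances(results, features)


def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(len(idx) * test_fraction)))
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def summarize_importances(
    results: Sequence[ClassifierRunResult], features: Sequence[str]
) -> ImportanceSummary:
    mat = pd.DataFrame([r.importances for r in results])[list(features)]
    stats = pd.DataFrame(
        {
            "mean": mat.mean(),
            "sd": mat.std(ddof=0),
            "q25": mat.quantile(0.25),
            "median": mat.quantile(0.5),
            "q75": mat.quantile(0.75),
        }
    )
    ranking = tuple(stats["mean"].sort_values(ascending=False).index)
    return ImportanceSummary(stats=stats, ranking=ranking)


def summarize_errors(results: Sequence[ClassifierRunResult]) -> dict[str, float]:
    """Mean ± SD of train and test misclassification fractions over runs."""
    if len(results) < 2:
        raise ValueError("at least two runs are required to summarize errors")
    train = np.array([r.train_error for r in results])
    test = np.array([r.test_error for r in results])
    return {
        "train_mean": float(train.mean()),
        "train_sd": float(train.std(ddof=0)),
        "test_mean": float(test.mean()),
        "test_sd": float(test.std(ddof=0)),
    }


def runs_table(results: Sequence[ClassifierRunResult]) -> pd.DataFrame:
    """Per-run table: errors plus one importance column per criterion."""
    rows = []
    for i, r in enumerate(results):
        row = {"run": i, "train_error": r.train_error, "test_error": r.test_error}
        row.update({f"imp_{k}": v for k, v in r.importances.items()})
        rows.append(row)
    return pd.DataFrame(rows)
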