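"""Entity-level leave-one-out evaluation and the speed-rate (SR) procedure.

Every evaluation run holds out one entity per class (all of its epochs) and
trains on the rest, so no epoch of a test entity can leak into tuning,
normalization or training.  With the full cohort (13 no-particle, 15 mock,
15 HST6, 10 polystyrene entities) the Cartesian product yields
13 x 15 x 15 x 10 = 29,250 runs, each spending k_folds x |grid| CV fits on
hyperparameter tuning.  A seeded uniform subsample of the run plan supports
desk-scale execution.

The SR procedure estimates how many 2-s portions a trained classifier needs
before first identifying a held-out entity correctly: per repetition, test
epochs are drawn uniformly without replacement until one is classified
correctly (or the epochs are exhausted, a flagged failure), 500 repetitions
per entity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .model import RFGrid, TrainedModel, predict, split_xy, train, tune_cv
from .synthgen import CLASS_ORDER

DESK_SCALE = {
    "entities_per_class": 3,
    "duration": 8.0,
    "n_runs": 50,
    "k_folds": 5,
}
"""Desk-scale study conditions (used with the 12-combination desk grid)."""


@dataclass(frozen=True)
class RunPlan:
    """The combinational LOO run plan and its exact fit accounting."""

    counts: dict
    runs: tuple
    cv_fits_per_run: int
    subsampled_from: Optional[int] = None
    subsample_seed: Optional[int] = None

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def total_cv_fits(self) -> int:
        return self.n_runs * self.cv_fits_per_run


def enumerate_runs(
    entities_by_class: dict,
    grid_size: int = 180,
    k_folds: int = 5,
    subsample: Optional[int] = None,
    seed: Optional[int] = None,
) -> RunPlan:
    """Cartesian product of one held-out entity per class.

    ``entities_by_class`` maps each class label to its entity ids (or to an
    integer count, in which case placeholder ids are generated).  With
    ``subsample``, a seeded uniform subset of the full plan is drawn.
    """
    ids = {}
    for label in CLASS_ORDER:
        if label not in entities_by_class:
            raise ValueError(f"class {label!r} missing from entity roster")
        v = entities_by_class[label]
        ids[label] = [f"{label}_{i:02d}" for i in range(v)] if isinstance(v, int) else list(v)
        if len(ids[label]) == 0:
            raise ValueError(f"class {label!r} has zero entities")
    runs = tuple(itertools.product(*(ids[label] for label in CLASS_ORDER)))
    counts = {label: len(ids[label]) for label in CLASS_ORDER}
    cv_fits = k_folds * grid_size
    if subsample is not None and subsample < len(runs):
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(runs), size=subsample, replace=False))
        return RunPlan(counts, tuple(runs[i] for i in pick), cv_fits, len(runs), seed)
    return RunPlan(counts, runs, cv_fits)


def run_accounting(plan: RunPlan) -> dict:
    """Exact integer totals of the evaluation workload."""
    full = int(np.prod([plan.counts[c] for c in CLASS_ORDER]))
    return {
        "n_runs": full,
        "n_executed_runs": plan.n_runs,
        "cv_fits_per_run": plan.cv_fits_per_run,
        "total_cv_fits": full * plan.cv_fits_per_run,
    }


@dataclass
class EvaluationRun:
    """Metrics of one LOO run (one held-out entity per class)."""

    test_entities: tuple[str, ...]
    accuracy: float
    f_measure: float
    per_class_accuracy: dict
    confusion: np.ndarray  # 4x4 epoch counts, CLASS_ORDER x CLASS_ORDER
    entity_accuracy: float  # majority-vote accuracy over the 4 test entities
    params: tuple[int, int, int]
    seed: int
    correct_by_entity: dict = field(default_factory=dict, repr=False)
    model: Optional[TrainedModel] = field(default=None, repr=False)


class LeakageError(RuntimeError):
    """A test entity's epochs were found in the training set."""


def execute_run(
    table: pd.DataFrame,
    test_entities: Sequence[str],
    grid: RFGrid,
    seed: int,
    k_folds: int = 5,
    keep_model: bool = False,
) -> EvaluationRun:
    """Tune, train and test one LOO run with a hard entity-leakage guard."""
    test_set = set(test_entities)
    known = set(table["entity_id"])
    missing = test_set - known
    if missing:
        raise ValueError(f"unknown test entities: {sorted(missing)}")
    is_test = table["entity_id"].isin(test_set).to_numpy()
    train_tbl, test_tbl = table[~is_test], table[is_test]
    if set(train_tbl["entity_id"]) & test_set:
        raise LeakageError(f"entities shared across train/test: {test_set}")
    X_tr, y_tr = split_xy(train_tbl)
    params, score = tune_cv(X_tr, y_tr, grid, k_folds=k_folds, seed=seed)
    model = train(X_tr, y_tr, params, seed=seed, cv_f_measure=score)
    X_te, y_te = split_xy(test_tbl)
    pred, _ = predict(model, X_te)
    correct = pred == y_te

    from sklearn.metrics import confusion_matrix, f1_score

    labels = list(CLASS_ORDER)
    conf = confusion_matrix(y_te, pred, labels=labels)
    per_class = {}
    for i, lab in enumerate(labels):
        n_lab = conf[i].sum()
        per_class[lab] = float(conf[i, i] / n_lab) if n_lab else float("nan")
    entity_ids = test_tbl["entity_id"].to_numpy()
    correct_by_entity = {e: correct[entity_ids == e] for e in test_entities}
    ent_correct = []
    for e in test_entities:
        true_lab = test_tbl.loc[test_tbl["entity_id"] == e, "class_label"].iloc[0]
        votes = pd.Series(pred[entity_ids == e]).value_counts()
        ent_correct.append(votes.idxmax() == true_lab)
    return EvaluationRun(
        test_entities=tuple(test_entities),
        accuracy=float(np.mean(correct)),
        f_measure=float(f1_score(y_te, pred, labels=labels, average="macro", zero_division=0)),
        per_class_accuracy=per_class,
        confusion=conf,
        entity_accuracy=float(np.mean(ent_correct)),
        params=params,
        seed=int(seed),
        correct_by_entity=correct_by_entity,
        model=model if keep_model else None,
    )


def aggregate(runs: Sequence[EvaluationRun]) -> dict:
    """Unweighted mean +/- sample SD across runs, plus the pooled confusion."""
    if not runs:
        raise ValueError("no runs to aggregate")
    acc = np.array([r.accuracy for r in runs])
    f = np.array([r.f_measure for r in runs])
    ent = np.array([r.entity_accuracy for r in runs])
    pooled = np.sum([r.confusion for r in runs], axis=0)
    per_class = {}
    for lab in CLASS_ORDER:
        vals = np.array([r.per_class_accuracy[lab] for r in runs], dtype=float)
        per_class[lab] = float(np.nanmean(vals))
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return {
        "n_runs": len(runs),
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": sd(acc),
        "f_measure_mean": float(f.mean()),
        "f_measure_sd": sd(f),
        "entity_accuracy_mean": float(ent.mean()),
        "per_class_accuracy": per_class,
        "pooled_confusion": pooled,
        "pooled_accuracy": float(np.trace(pooled) / pooled.sum()),
    }


def _run_seed(master_seed: int, index: int) -> int:
    """Deterministic per-run seed derived from (master seed, run index)."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def evaluate_loo(
    table: pd.DataFrame,
    grid: RFGrid,
    runs: int | str = "all",
    seed: int = 0,
    k_folds: int = 5,
    keep_correct: bool = True,
) -> tuple[RunPlan, list[EvaluationRun], dict]:
    """Execute the (optionally subsampled) LOO plan over a feature table.

    Each run is independent and seeded from (master seed, run index), so the
    results do not depend on execution order.
    """
    roster = {
        label: sorted(table.loc[table["class_label"] == label, "entity_id"].unique())
        for label in CLASS_ORDER
    }
    sub = None if runs == "all" else int(runs)
    plan = enumerate_runs(roster, grid_size=grid.size, k_folds=k_folds, subsample=sub, seed=seed)
    results = [
        execute_run(table, combo, grid, seed=_run_seed(seed, i), k_folds=k_folds)
        for i, combo in enumerate(plan.runs)
    ]
    return plan, results, aggregate(results)


# ---------------------------------------------------------------------------
# Speed rate
# ---------------------------------------------------------------------------


@dataclass
class SRResult:
    """Speed-rate statistics: portions (and seconds = 2 x portions) needed for
    the first correct identification."""

    counts: np.ndarray  # all repetition counts, pooled over entities/runs
    epoch_seconds: float
    n_failures: int

    @property
    def mean_portions(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd_portions(self) -> float:
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0

    @property
    def mean_seconds(self) -> float:
        return self.epoch_seconds * self.mean_portions

    @property
    def sd_seconds(self) -> float:
        return self.epoch_seconds * self.sd_portions

    @property
    def fraction_single_portion(self) -> float:
        return float(np.mean(self.counts == 1))


def speed_rate_from_flags(
    correct_flags: np.ndarray, repetitions: int = 500, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Portion counts for one entity given per-epoch correctness flags.

    Each repetition draws epochs uniformly without replacement; the count is
    the position of the first correctly classified epoch, or the number of
    available epochs when none is correct (a failure).
    """
    flags = np.asarray(correct_flags, dtype=bool)
    n = len(flags)
    if n == 0:
        raise ValueError("entity has no accepted epochs")
    rng = np.random.default_rng(seed)
    counts = np.empty(repetitions, dtype=int)
    failures = 0
    for rep in range(repetitions):
        order = rng.permutation(n)
        hit = np.nonzero(flags[order])[0]
        if len(hit):
            counts[rep] = hit[0] + 1
        else:
            counts[rep] = n
            failures += 1
    return counts, failures


def speed_rate(
    model: TrainedModel,
    test_table: pd.DataFrame,
    repetitions: int = 500,
    seed: int = 0,
    epoch_seconds: float = 2.0,
) -> SRResult:
    """SR of a trained model over the entities of a held-out feature table."""
    X, y = split_xy(test_table)
    pred, _ = predict(model, X)
    correct = pred == y
    ids = test_table["entity_id"].to_numpy()
    all_counts, failures = [], 0
    for i, e in enumerate(sorted(set(ids))):
        c, f = speed_rate_from_flags(
            correct[ids == e], repetitions=repetitions, seed=_run_seed(seed, i)
        )
        all_counts.append(c)
        failures += f
    return SRResult(np.concatenate(all_counts), epoch_seconds, failures)


def speed_rate_over_runs(
    runs: Sequence[EvaluationRun],
    repetitions: int = 500,
    seed: int = 0,
    epoch_seconds: float = 2.0,
) -> SRResult:
    """SR pooled over the test entities of many LOO runs, reusing each run's
    per-epoch correctness (epoch predictions are deterministic given the
    trained model, so only the sampling order is re-randomized)."""
    all_counts, failures = [], 0
    i = 0
    for run in runs:
        for e in run.test_entities:
            c, f = speed_rate_from_flags(
                run.correct_by_entity[e], repetitions=repetitions, seed=_run_seed(seed, i)
            )
            all_counts.append(c)
            failures += f
            i += 1
    return SRResult(np.concatenate(all_counts), epoch_seconds, failures)
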