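"""Entity-level LOO plan, run execution, aggregation, speed rate."""

import numpy as np
import pandas as pd
import pytest

from ilof.evaluation import (
    EvaluationRun,
    LeakageError,
    RunPlan,
    aggregate,
    enumerate_runs,
    execute_run,
    run_accounting,
    speed_rate,
    speed_rate_from_flags,
    speed_rate_over_runs,
)
from ilof.features import FEATURE_NAMES
from ilof.model import RFGrid, train
from ilof.synthgen import CLASS_ORDER

FULL_COUNTS = {"no_particle": 13, "mock": 15, "hst6": 15, "ps": 10}


def toy_table(entities_per_class=3, epochs_per_entity=5, sep=5.0, seed=0):
    """Feature table with class-separated Gaussian features."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, label in enumerate(CLASS_ORDER):
        for e in range(entities_per_class):
            eid = f"{label}_{e:02d}"
            for k in range(epochs_per_entity):
                vec = rng.normal(0, 1, 54)
                vec[ci] += sep
                rows.append((eid, label, k, *vec))
    return pd.DataFrame(rows, columns=["entity_id", "class_label", "epoch_index",
                                       *FEATURE_NAMES])


class TestEnumerateRuns:
    def test_full_study_plan(self):
        plan = enumerate_runs(FULL_COUNTS)
        assert plan.n_runs == 29_250
        assert plan.cv_fits_per_run == 900

    @pytest.mark.parametrize("n, expected", [(1, 1), (2, 16)])
    def test_small_products(self, n, expected):
        plan = enumerate_runs({c: n for c in CLASS_ORDER})
        assert plan.n_runs == expected
        # brute-force: each run holds exactly one entity per class
        for combo in plan.runs:
            assert [eid.rsplit("_", 1)[0] for eid in combo] == list(CLASS_ORDER)

    def test_subsample_reproducible_and_subset(self):
        full = enumerate_runs({c: 3 for c in CLASS_ORDER})
        a = enumerate_runs({c: 3 for c in CLASS_ORDER}, subsample=10, seed=5)
        b = enumerate_runs({c: 3 for c in CLASS_ORDER}, subsample=10, seed=5)
        assert a.runs == b.runs and len(a.runs) == 10
        assert set(a.runs) <= set(full.runs)
        assert a.subsampled_from == 81

    def test_zero_entities_rejected(self):
        with pytest.raises(ValueError):
            enumerate_runs({"no_particle": 0, "mock": 1, "hst6": 1, "ps": 1})


class TestRunAccounting:
    def test_paper_scale_totals(self):
        plan = enumerate_runs(FULL_COUNTS, grid_size=180, k_folds=5)
        acct = run_accounting(plan)
        assert acct["n_runs"] == 29_250
        assert acct["cv_fits_per_run"] == 5 * 180 == 900
        assert acct["total_cv_fits"] == 29_250 * 900 == 26_325_000

    def test_minimal_plan(self):
        plan = enumerate_runs({c: 1 for c in CLASS_ORDER}, grid_size=1, k_folds=5)
        assert run_accounting(plan)["total_cv_fits"] == 5


class TestExecuteRun:
    GRID = RFGrid(n_trees=(10,), n_predictors=(4,), min_leaf=(1,))

    def test_training_set_excludes_test_entities(self):
        table = toy_table(entities_per_class=3, epochs_per_entity=5)
        combo = ("no_particle_00", "mock_00", "hst6_00", "ps_00")
        run = execute_run(table, combo, self.GRID, seed=0, k_folds=2)
        assert run.test_entities == combo
        assert run.confusion.sum() == 4 * 5  # all test epochs counted

    def test_full_cohort_training_size(self):
        # one epoch per entity keeps this cheap; 53 entities -> 49 in training
        table = toy_table(entities_per_class=1, epochs_per_entity=1)
        # rebuild with the paper's per-class counts
        rows = []
        rng = np.random.default_rng(1)
        for ci, label in enumerate(CLASS_ORDER):
            for e in range(FULL_COUNTS[label]):
                vec = rng.normal(0, 1, 54)
                vec[ci] += 5.0
                rows.append((f"{label}_{e:02d}", label, 0, *vec))
        table = pd.DataFrame(rows, columns=list(table.columns))
        combo = ("no_particle_00", "mock_00", "hst6_00", "ps_00")
        seen = {}

        import ilof.evaluation as ev
        orig = ev.tune_cv

        def spy(X, y, *a, **kw):
            seen["n_train"] = len(X)
            return orig(X, y, *a, **kw)

        ev.tune_cv, cleanup = spy, orig
        try:
            execute_run(table, combo, self.GRID, seed=0, k_folds=2)
        finally:
            ev.tune_cv = cleanup
        assert seen["n_train"] == 49  # 53 - 4 entities, one epoch each

    def test_unknown_test_entity_rejected(self):
        table = toy_table()
        with pytest.raises(ValueError):
            execute_run(table, ("nope", "mock_00", "hst6_00", "ps_00"), self.GRID, seed=0)

    def test_separated_cohort_run_accuracy(self, separated_table):
        combo = tuple(f"{c}_00" for c in CLASS_ORDER)
        run = execute_run(separated_table, combo, RFGrid((20,), (7,), (1,)), seed=0)
        assert run.accuracy >= 0.9


class TestAggregate:
    def _mk_run(self, acc, f=0.8, conf=None):
        conf = np.eye(4, dtype=int) * 5 if conf is None else conf
        return EvaluationRun(
            test_entities=("a", "b", "c", "d"), accuracy=acc, f_measure=f,
            per_class_accuracy={c: acc for c in CLASS_ORDER}, confusion=conf,
            entity_accuracy=acc, params=(10, 4, 1), seed=0,
        )

    def test_identical_runs_sd_zero(self):
        summary = aggregate([self._mk_run(0.9)] * 3)
        assert summary["accuracy_mean"] == 0.9
        assert summary["accuracy_sd"] == 0.0

    def test_hand_arithmetic(self):
        summary = aggregate([self._mk_run(0.8), self._mk_run(1.0)])
        assert summary["accuracy_mean"] == pytest.approx(0.9)
        assert summary["accuracy_sd"] == pytest.approx(np.sqrt(0.02), rel=1e-9)

    def test_pooled_confusion_matches_epoch_weighted_accuracy(self):
        c1 = np.array([[3, 2, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
        c2 = np.eye(4, dtype=int) * 5
        runs = [self._mk_run(18 / 20, conf=c1), self._mk_run(1.0, conf=c2)]
        summary = aggregate(runs)
        total = c1.sum() + c2.sum()
        assert summary["pooled_accuracy"] == pytest.approx(
            (np.trace(c1) + np.trace(c2)) / total
        )


class TestSpeedRate:
    def test_oracle_classifier_needs_exactly_one(self):
        counts, failures = speed_rate_from_flags(np.ones(40, dtype=bool), 500, seed=0)
        assert np.all(counts == 1) and failures == 0

    def test_always_wrong_exhausts_epochs(self):
        counts, failures = speed_rate_from_flags(np.zeros(40, dtype=bool), 200, seed=0)
        assert np.all(counts == 40) and failures == 200

    def test_half_correct_matches_negative_hypergeometric(self):
        # 20 correct among 40 epochs, drawing without replacement: the first
        # success arrives at position (n+1)/(k+1) = 41/21 in expectation
        flags = np.zeros(40, dtype=bool)
        flags[:20] = True
        counts, failures = speed_rate_from_flags(flags, 5000, seed=1)
        expected = 41 / 21
        assert failures == 0
        assert counts.mean() == pytest.approx(expected, abs=0.06)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            speed_rate_from_flags(np.array([], dtype=bool), 10, seed=0)

    def test_speed_rate_over_runs_pools_entities(self):
        run = EvaluationRun(
            test_entities=("x", "y"), accuracy=1.0, f_measure=1.0,
            per_class_accuracy={}, confusion=np.eye(4, dtype=int),
            entity_accuracy=1.0, params=(10, 4, 1), seed=0,
            correct_by_entity={"x": np.ones(5, dtype=bool),
                               "y": np.zeros(3, dtype=bool)},
        )
        sr = speed_rate_over_runs([run], repetitions=100, seed=0)
        assert len(sr.counts) == 200
        assert sr.n_failures == 100
        assert sr.mean_seconds == 2.0 * sr.mean_portions

    def test_model_based_speed_rate(self):
        table = toy_table(entities_per_class=2, epochs_per_entity=6, sep=8.0)
        from ilof.model import split_xy
        X, y = split_xy(table)
        model = train(X, y, (20, 7, 1), seed=0)
        sr = speed_rate(model, table, repetitions=50, seed=0)
        assert sr.fraction_single_portion == 1.0  # training data, separable


class TestLeakageGuard:
    GRID = RFGrid(n_trees=(5,), n_predictors=(4,), min_leaf=(1,))

    def test_test_entity_rows_never_reach_tuning_or_training(self, monkeypatch):
        # poison every test entity's rows with a sentinel value and assert no
        # sentinel row is ever seen by tune_cv or train across all runs
        table = toy_table(entities_per_class=2, epochs_per_entity=4)
        sentinel = 777.0
        combo = ("no_particle_01", "mock_01", "hst6_01", "ps_01")
        mask = table["entity_id"].isin(combo)
        table.loc[mask, FEATURE_NAMES[0]] = sentinel

        import ilof.evaluation as ev
        seen = []
        orig_tune, orig_train = ev.tune_cv, ev.train
        monkeypatch.setattr(ev, "tune_cv", lambda X, y, *a, **kw: (
            seen.append(np.asarray(X)[:, 0]), orig_tune(X, y, *a, **kw))[1])
        monkeypatch.setattr(ev, "train", lambda X, y, *a, **kw: (
            seen.append(np.asarray(X)[:, 0]), orig_train(X, y, *a, **kw))[1])
        execute_run(table, combo, self.GRID, seed=0, k_folds=2)
        assert seen and all(not np.any(col == sentinel) for col in seen)

    def test_leakage_error_is_exported(self):
        assert issubclass(LeakageError, RuntimeError)
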