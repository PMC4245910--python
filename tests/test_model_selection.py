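"""Split plans, the leakage guard, and nested grid selection."""

import numpy as np
import pytest

import eegstates as es
from eegstates.features import FeatureCache, ParameterSet
from eegstates.model_selection import (
    SCHEME1,
    SCHEME2,
    LeakageError,
    SplitPlan,
    assert_no_window_leakage,
    plan_scheme1,
    plan_scheme2,
    run_grid_selection,
)

from conftest import make_annotations


@pytest.fixture(scope="module")
def annotations():
    return make_annotations()


class TestScheme1Plans:
    def test_holdout_and_fold_composition(self, annotations):
        plan = plan_scheme1(annotations, repetition=0, seed=0)
        conds = [annotations[i].condition for i in plan.holdout]
        assert sorted(conds) == ["MEC", "MER", "SPN", "SPN"]
        assert len(plan.folds) == 7
        for train, test in plan.folds:
            test_conds = sorted(annotations[i].condition for i in test)
            train_conds = [annotations[i].condition for i in train]
            assert test_conds == ["MEC", "MER", "SPN", "SPN"]
            assert train_conds.count("MEC") == 6
            assert train_conds.count("MER") == 6
            assert train_conds.count("SPN") == 14

    def test_holdout_disjoint_from_folds(self, annotations):
        plan = plan_scheme1(annotations, 2, seed=3)
        for train, test in plan.folds:
            assert not set(plan.holdout) & (set(train) | set(test))

    def test_seven_repetitions_draw_disjoint_holdouts(self, annotations):
        holdouts = [set(plan_scheme1(annotations, r, seed=1).holdout) for r in range(7)]
        for i in range(7):
            for j in range(i + 1, 7):
                assert not holdouts[i] & holdouts[j]

    def test_reproducible_and_seed_sensitive(self, annotations):
        assert plan_scheme1(annotations, 1, seed=5) == plan_scheme1(annotations, 1, seed=5)
        assert plan_scheme1(annotations, 1, seed=5) != plan_scheme1(annotations, 1, seed=6)

    def test_incompatible_counts_rejected(self):
        with pytest.raises(ValueError):
            plan_scheme1(make_annotations(n_spn=6, n_mec=8, n_mer=8))
        with pytest.raises(ValueError):
            plan_scheme1(make_annotations(n_spn=18, n_mec=8, n_mer=6))


class TestScheme2Plans:
    def test_pool_and_fold_composition(self, annotations):
        plan = plan_scheme2(annotations, seed=0)
        workload = {i: a.workload for i, a in enumerate(annotations)}
        hold_wl = sorted(workload[i] for i in plan.holdout)
        assert hold_wl == ["HW", "HW", "LW", "LW"]
        # one LW and one HW per session
        hold_sessions = sorted(
            (annotations[i].session, workload[i]) for i in plan.holdout
        )
        assert hold_sessions == [(1, "HW"), (1, "LW"), (2, "HW"), (2, "LW")]
        pool = plan.inner_pool
        assert sum(workload[i] == "LW" for i in pool) == 16
        assert sum(workload[i] == "HW" for i in pool) == 14
        assert len(plan.folds) == 11
        for train, test in plan.folds:
            assert sorted(workload[i] for i in test) == ["HW", "HW", "LW", "LW"]
            assert sum(workload[i] == "LW" for i in train) == 14
            assert sum(workload[i] == "HW" for i in train) == 12

    def test_coverage_every_pool_block_tested(self, annotations):
        plan = plan_scheme2(annotations, seed=4)
        tested = set()
        for _, test in plan.folds:
            tested.update(test)
        assert tested == set(plan.inner_pool)  # 11*4 = 44 draws cover all 30

    def test_reproducible(self, annotations):
        assert plan_scheme2(annotations, seed=2) == plan_scheme2(annotations, seed=2)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            plan_scheme2(make_annotations(n_spn=2, n_mec=1, n_mer=1))


class TestLeakageGuard:
    def test_window_guard_raises_on_overlap(self):
        with pytest.raises(LeakageError):
            assert_no_window_leakage(np.array([1, 2, 3]), [3, 9])
        assert_no_window_leakage(np.array([1, 2]), [3, 9])  # clean: no raise

    def test_corrupted_plan_rejected(self, annotations):
        plan = plan_scheme1(annotations, 0, seed=0)
        train0, test0 = plan.folds[0]
        bad = SplitPlan(
            plan.scheme,
            plan.repetition,
            plan.seed,
            plan.holdout,
            ((train0 + (plan.holdout[0],), test0),) + plan.folds[1:],
        )
        with pytest.raises(LeakageError):
            bad.validate()


@pytest.fixture(scope="module")
def tiny_cache(tiny_design):
    rec, ann = es.generate_experiment(tiny_design, es.default_signature(), seed=9)
    return FeatureCache(rec, ann), ann


class TestGridSelection:
    def test_singleton_grid_returns_that_point(self, tiny_cache):
        cache, ann = tiny_cache
        params = ParameterSet(subset="S1", spatial_filter="none", band=(3, 10), window_length=2.0)
        plan = plan_scheme1(ann, 0, seed=0)
        result = run_grid_selection(cache, plan, [params], "lda")
        assert result.selected == params
        assert result.inner_accuracies.shape == (1,)

    def test_report_confusion_shape_matches_scheme(self, tiny_cache):
        cache, ann = tiny_cache
        grid = [ParameterSet(subset="S1", spatial_filter="none", band=(3, 15), window_length=2.0)]
        r1 = run_grid_selection(cache, plan_scheme1(ann, 0, seed=1), grid, "lda")
        r2 = run_grid_selection(cache, plan_scheme2(ann, seed=1), grid, "lda")
        assert r1.confusion.shape == (3, 3) and r1.classes == ("SPN", "MER", "MEC")
        assert r2.confusion.shape == (2, 2) and r2.classes == ("LW", "HW")
        assert r1.confusion.sum() == sum(
            1 for w in cache.base(2.0, "none")[2] if w.block_id in r1.plan.holdout
        )

    def test_identical_seed_identical_report(self, tiny_cache):
        cache, ann = tiny_cache
        grid = [
            ParameterSet(subset="S1", spatial_filter="none", band=b, window_length=2.0)
            for b in ((3, 10), (7, 15))
        ]
        a = run_grid_selection(cache, plan_scheme2(ann, seed=7), grid, "lda")
        b = run_grid_selection(cache, plan_scheme2(ann, seed=7), grid, "lda")
        assert a.selected == b.selected
        assert a.outer_accuracy == b.outer_accuracy
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_empty_grid_rejected(self, tiny_cache):
        cache, ann = tiny_cache
        with pytest.raises(ValueError):
            run_grid_selection(cache, plan_scheme1(ann, 0, 0), [], "lda")

    def test_nested_cv_aggregates_repetitions(self, tiny_design):
        rec, ann = es.generate_experiment(tiny_design, es.default_signature(), seed=10)
        grid = [ParameterSet(subset="S1", spatial_filter="none", band=(3, 15), window_length=2.0)]
        report = es.nested_cv(rec, ann, SCHEME1, "lda", grid, seed=2, n_repetitions=2)
        assert len(report.repetitions) == 2
        accs = [r.outer_accuracy for r in report.repetitions]
        assert report.mean_accuracy == pytest.approx(np.mean(accs))
        assert len(report.selected_parameters) == 2
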