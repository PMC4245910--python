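"""Nested, strictly block-wise cross-validation for continuous decoding.

Windows shifted every 200 ms overlap by ~96%, so any split that puts
windows of one block on both sides of a train/test boundary leaks almost
the entire test signal into training.  Every split here therefore operates
on whole blocks, and a structural leakage guard re-checks each fitted
model's window assignment at run time.

Two schemes are implemented:

* **scheme 1** (3-class SPN/MER/MEC): 1 MEC + 1 MER + 2 SPN blocks are held
  out; the remaining blocks enter an inner CV (7 folds at the default
  counts, each fold testing 1 MEC + 1 MER + 2 SPN and training on
  6 MEC + 6 MER + 14 SPN) that selects the best parameter-grid point by
  mean window accuracy; the winner is refit on the whole inner pool and
  scored on the holdout.  The procedure repeats (7 repetitions by default)
  with disjoint holdouts and the outer scores are averaged.
* **scheme 2** (high vs low workload): blocks are relabelled HW = MER+MEC,
  LW = SPN; 1 LW + 1 HW block per session are held out, the remaining
  16 LW + 14 HW enter an 11-fold inner CV whose folds each test 2 LW +
  2 HW (drawn with coverage balancing — the block counts cannot tile 11
  disjoint folds of 4) and train on 14 LW + 12 HW.

Holdout draws are seeded uniform draws without replacement, stratified per
class; identical seeds reproduce identical plans and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classification import (
    SVMConfig,
    accuracy as _accuracy,
    confusion_matrix,
    mcc as _mcc,
    train_lda,
    train_svm_rbf,
)
from .data import BlockAnnotation, Montage
from .features import FeatureCache, ParameterSet, WindowFeatureSet, default_grid

SCHEME1 = "scheme1_3class"
SCHEME2 = "scheme2_workload"


class LeakageError(AssertionError):
    """A training set touched a test or holdout block."""


@dataclass(frozen=True)
class SplitPlan:
    """Outer holdout block ids plus inner-fold (train, test) block ids."""

    scheme: str
    repetition: int
    seed: int
    holdout: tuple[int, ...]
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    @property
    def inner_pool(self) -> tuple[int, ...]:
        pool: set[int] = set()
        for train, test in self.folds:
            pool.update(train)
            pool.update(test)
        return tuple(sorted(pool))

    def validate(self) -> None:
        hold = set(self.holdout)
        for train, test in self.folds:
            if hold & (set(train) | set(test)):
                raise LeakageError("holdout block inside an inner fold")
            if set(train) & set(test):
                raise LeakageError("block in both train and test of a fold")


def _ids_by_condition(annotations: Sequence[BlockAnnotation]) -> dict[str, list[int]]:
    ids: dict[str, list[int]] = {"SPN": [], "MER": [], "MEC": []}
    for i, a in enumerate(annotations):
        ids[a.condition].append(i)
    return ids


def plan_scheme1(
    annotations: Sequence[BlockAnnotation], repetition: int = 0, seed: int = 0
) -> SplitPlan:
    """Plan one repetition of the 3-class scheme.

    Needs equal MEC/MER counts n and at least 2n + 2 SPN blocks (the
    default 8/8/18); the inner CV has n - 1 folds.  Repetitions draw
    disjoint holdouts from seeded per-class permutations while counts
    permit, then wrap.
    """
    ids = _ids_by_condition(annotations)
    n_mec, n_mer, n_spn = len(ids["MEC"]), len(ids["MER"]), len(ids["SPN"])
    if n_mec != n_mer or n_mec < 2:
        raise ValueError(f"scheme 1 needs equal MEC/MER counts >= 2, got {n_mec}/{n_mer}")
    n_folds = n_mec - 1
    if n_spn < 2 * n_folds + 2:
        raise ValueError(
            f"scheme 1 needs >= {2 * n_folds + 2} SPN blocks for {n_folds} folds, got {n_spn}"
        )

    rng_hold = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    perm = {c: rng_hold.permutation(ids[c]) for c in ("MEC", "MER", "SPN")}
    r = repetition
    holdout = (
        int(perm["MEC"][r % n_mec]),
        int(perm["MER"][r % n_mer]),
        int(perm["SPN"][(2 * r) % n_spn]),
        int(perm["SPN"][(2 * r + 1) % n_spn]),
    )

    pool = {c: [i for i in ids[c] if i not in holdout] for c in ("MEC", "MER", "SPN")}
    rng_folds = np.random.default_rng(np.random.SeedSequence([seed, 1, repetition, 2]))
    shuffled = {c: list(rng_folds.permutation(pool[c])) for c in pool}
    folds = []
    all_pool = {i for c in pool for i in pool[c]}
    for f in range(n_folds):
        test = {
            int(shuffled["MEC"][f]),
            int(shuffled["MER"][f]),
            int(shuffled["SPN"][2 * f]),
            int(shuffled["SPN"][2 * f + 1]),
        }
        train = tuple(sorted(all_pool - test))
        folds.append((train, tuple(sorted(test))))
    plan = SplitPlan(SCHEME1, repetition, seed, tuple(sorted(holdout)), tuple(folds))
    plan.validate()
    return plan


def plan_scheme2(
    annotations: Sequence[BlockAnnotation], seed: int = 0, n_folds: int = 11
) -> SplitPlan:
    """Plan the workload scheme on the merged MEC+MER datasets.

    Holds out 1 LW + 1 HW block from each session's dataset (4 blocks).
    The remaining blocks (16 LW + 14 HW at the default counts) enter
    ``n_folds`` inner folds whose test sets are seeded draws of 2 LW +
    2 HW with coverage balancing: blocks tested least so far are drawn
    first, so every block is tested at least once when counts permit.
    """
    lw = {1: [], 2: []}
    hw = {1: [], 2: []}
    for i, a in enumerate(annotations):
        (lw if a.workload == "LW" else hw)[a.session].append(i)
    for session in (1, 2):
        if len(lw[session]) < 2 or len(hw[session]) < 2:
            raise ValueError(
                f"scheme 2 needs >= 2 LW and >= 2 HW blocks in session {session}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    holdout = tuple(
        sorted(
            int(rng.choice(group[session]))
            for session in (1, 2)
            for group in (lw, hw)
        )
    )
    pool_lw = [i for s in (1, 2) for i in lw[s] if i not in holdout]
    pool_hw = [i for s in (1, 2) for i in hw[s] if i not in holdout]
    all_pool = set(pool_lw) | set(pool_hw)

    times_tested = {i: 0 for i in all_pool}

    def draw(pool: list[int], k: int) -> list[int]:
        # least-tested first; ties broken by a fresh random permutation
        order = rng.permutation(pool)
        order = sorted(order, key=lambda i: times_tested[int(i)])
        chosen = [int(i) for i in order[:k]]
        for i in chosen:
            times_tested[i] += 1
        return chosen

    folds = []
    for _ in range(n_folds):
        test = set(draw(pool_lw, 2)) | set(draw(pool_hw, 2))
        train = tuple(sorted(all_pool - test))
        folds.append((train, tuple(sorted(test))))
    plan = SplitPlan(SCHEME2, 0, seed, holdout, tuple(folds))
    plan.validate()
    return plan


def assert_no_window_leakage(
    train_block_ids: np.ndarray, forbidden_blocks: Sequence[int]
) -> None:
    """Structural guard: no training window may come from a test/holdout block."""
    if np.isin(train_block_ids, list(forbidden_blocks)).any():
        raise LeakageError("training windows drawn from test or holdout blocks")


def _labels_for(fset: WindowFeatureSet, scheme: str) -> np.ndarray:
    if scheme == SCHEME1:
        return fset.labels
    if scheme == SCHEME2:
        return np.where(fset.labels == "SPN", "LW", "HW")
    raise ValueError(f"unknown scheme {scheme!r}")


def _fit(classifier: str, x: np.ndarray, y: np.ndarray, svm_config: SVMConfig | None):
    if classifier == "lda":
        return train_lda(x, y)
    if classifier == "svm":
        return train_svm_rbf(x, y, svm_config)
    raise ValueError(f"unknown classifier {classifier!r}")


@dataclass
class RepetitionResult:
    """Selection and holdout evaluation for one outer repetition."""

    plan: SplitPlan
    selected: ParameterSet
    inner_accuracies: np.ndarray  # one mean inner-CV accuracy per grid point
    outer_accuracy: float
    outer_mcc: float
    confusion: np.ndarray
    classes: tuple[str, ...]


@dataclass
class CVReport:
    """Per-repetition results plus the averaged final scores."""

    scheme: str
    classifier: str
    grid: tuple[ParameterSet, ...]
    repetitions: list[RepetitionResult] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.outer_accuracy for r in self.repetitions]))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.outer_mcc for r in self.repetitions]))

    @property
    def selected_parameters(self) -> list[ParameterSet]:
        return [r.selected for r in self.repetitions]


def run_grid_selection(
    cache: FeatureCache,
    plan: SplitPlan,
    grid: Sequence[ParameterSet] | None = None,
    classifier: str = "lda",
    rejected_channels: Sequence[str] = (),
    svm_config: SVMConfig | None = None,
) -> RepetitionResult:
    """Select the best grid point on the inner folds, refit, score the holdout.

    Inner selection criterion is the mean over folds of window-level test
    accuracy; ties go to the first grid point in canonical order.  The
    winning parameters are refit on every inner-pool block and evaluated on
    the holdout blocks (window accuracy, MCC, confusion matrix).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    plan.validate()

    inner_acc = np.empty(len(grid))
    for g, params in enumerate(grid):
        fset = cache.features_for(params, rejected_channels)
        labels = _labels_for(fset, plan.scheme)
        block_ids = fset.block_ids
        fold_scores = []
        for train_blocks, test_blocks in plan.folds:
            train_mask = np.isin(block_ids, train_blocks)
            test_mask = np.isin(block_ids, test_blocks)
            if not train_mask.any() or not test_mask.any():
                raise ValueError(
                    "a fold has no windows (blocks shorter than the window?)"
                )
            assert_no_window_leakage(
                block_ids[train_mask], tuple(test_blocks) + plan.holdout
            )
            model = _fit(classifier, fset.features[train_mask], labels[train_mask], svm_config)
            pred = model.predict(fset.features[test_mask])
            fold_scores.append(float(np.mean(pred == labels[test_mask])))
        inner_acc[g] = np.mean(fold_scores)

    best = int(np.argmax(inner_acc))  # first maximiser wins ties
    selected = grid[best]

    fset = cache.features_for(selected, rejected_channels)
    labels = _labels_for(fset, plan.scheme)
    block_ids = fset.block_ids
    pool_mask = np.isin(block_ids, plan.inner_pool)
    hold_mask = np.isin(block_ids, plan.holdout)
    if not hold_mask.any():
        raise ValueError("holdout blocks produced no windows")
    assert_no_window_leakage(block_ids[pool_mask], plan.holdout)
    model = _fit(classifier, fset.features[pool_mask], labels[pool_mask], svm_config)
    pred = model.predict(fset.features[hold_mask])
    classes = ("SPN", "MER", "MEC") if plan.scheme == SCHEME1 else ("LW", "HW")
    conf, _ = confusion_matrix(labels[hold_mask], pred, classes)
    return RepetitionResult(
        plan=plan,
        selected=selected,
        inner_accuracies=inner_acc,
        outer_accuracy=_accuracy(conf),
        outer_mcc=_mcc(conf),
        confusion=conf,
        classes=classes,
    )


def nested_cv(
    recording,
    annotations: Sequence[BlockAnnotation],
    scheme: str,
    classifier: str = "lda",
    grid: Sequence[ParameterSet] | None = None,
    seed: int = 0,
    n_repetitions: int | None = None,
    rejected_channels: Sequence[str] = (),
    montage: Montage | None = None,
    svm_config: SVMConfig | None = None,
    cache: FeatureCache | None = None,
) -> CVReport:
    """Run a full nested-CV scheme and average over repetitions.

    Scheme 1 defaults to 7 repetitions with disjoint holdouts; scheme 2 is
    a single repetition (its inner folds already resample the pool).
    """
    if cache is None:
        cache = FeatureCache(recording, annotations, montage)
    grid = list(grid) if grid is not None else default_grid()
    if scheme == SCHEME1:
        n_rep = n_repetitions if n_repetitions is not None else 7
        plans = [plan_scheme1(annotations, r, seed) for r in range(n_rep)]
    elif scheme == SCHEME2:
        n_rep = n_repetitions if n_repetitions is not None else 1
        plans = [plan_scheme2(annotations, seed + r) for r in range(n_rep)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    report = CVReport(scheme, classifier, tuple(grid))
    for plan in plans:
        report.repetitions.append(
            run_grid_selection(cache, plan, grid, classifier, rejected_channels, svm_config)
        )
    return report
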