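"""Stratified cross-validation, cross-validation consistency, and model
selection across interaction orders.

For each fold the classifier is fitted (cells labeled at the training
case/control ratio) on the other F-1 folds and scored on the held-out fold.
The fold winner is the combination with the highest training balanced
accuracy; a combination's cross-validation consistency (CVC) is the number
of folds it wins.  Within a fold, winner comparison uses the exact integer
score ``tp_cells * train_controls + tn_cells * train_cases`` (a strictly
monotone transform of training balanced accuracy), so ties break
deterministically to the lexicographically smallest combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import CaseControlDataset, DatasetError
from .mdr import (
    EmptyCellPolicy,
    FactorCombination,
    TieRule,
    enumerate_combinations,
    joint_codes,
)


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified partition of subjects into F folds (labels 0..F-1)."""

    fold_of_subject: np.ndarray
    n_folds: int
    seed: int


@dataclass
class ModelEvaluation:
    """Cross-validated scores for one factor combination."""

    combination: FactorCombination
    names: tuple[str, ...]
    train_ba: float  # mean over folds
    test_ba: float  # mean over folds
    cvc: int
    per_fold: list[tuple[float, float, bool]]  # (train_ba, test_ba, winner)

    @property
    def order(self) -> int:
        return self.combination.order

    def label(self) -> str:
        return ", ".join(self.names)


@dataclass
class OrderSummary:
    """Best model and ranked list for one interaction order.

    ``prediction_ba`` is the cross-validated prediction estimate of the MDR
    procedure at this order: for each fold, the testing balanced accuracy of
    that fold's winner (chosen on training data only), averaged over folds.
    Unlike the best model's own ``test_ba`` — which inherits winner's-curse
    selection bias because the model's identity depends on the whole sample
    — this estimate is unbiased and centres on 0.5 for null data.
    """

    order: int
    best_model: ModelEvaluation
    top_n: list[ModelEvaluation]
    prediction_ba: float = float("nan")


@dataclass
class CrossOrderSummary:
    per_order: list[ModelEvaluation]
    selected: ModelEvaluation


def stratified_fold_labels(
    phenotype: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified fold labels for a raw 0/1 phenotype vector.

    Cases and controls are shuffled separately and dealt round-robin, so
    per-fold class counts differ from perfect stratification by at most 1.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    folds = np.empty(len(phenotype), dtype=np.int64)
    for cls in (1, 0):
        members = np.flatnonzero(phenotype == cls)
        if len(members) < n_folds:
            raise DatasetError(
                f"class {cls} has {len(members)} subjects, fewer than {n_folds} folds"
            )
        perm = rng.permutation(members)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


def make_folds(
    ds: CaseControlDataset, n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Stratified fold assignment reproducible from the seed."""
    rng = np.random.default_rng(seed)
    return FoldAssignment(
        stratified_fold_labels(ds.phenotype, n_folds, rng), n_folds, seed
    )


def _combo_fold_scores(
    codes: np.ndarray,
    size: int,
    pheno: np.ndarray,
    folds: FoldAssignment,
    tie_rule: TieRule,
    empty_cell_policy: EmptyCellPolicy,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fold (train_ba, test_ba, integer winner score) for one combination.

    All quantities derive from per-cell case/control counts: training
    sensitivity is the case mass in high cells over training cases, and the
    held-out fold is scored with the training labels.
    """
    F = folds.n_folds
    case_fold = np.zeros((F, size), dtype=np.int64)
    ctrl_fold = np.zeros((F, size), dtype=np.int64)
    for f in range(F):
        in_f = folds.fold_of_subject == f
        case_fold[f] = np.bincount(codes[in_f & (pheno == 1)], minlength=size)
        ctrl_fold[f] = np.bincount(codes[in_f & (pheno == 0)], minlength=size)
    case_total = case_fold.sum(axis=0)
    ctrl_total = ctrl_fold.sum(axis=0)

    train_ba = np.empty(F)
    test_ba = np.empty(F)
    win_score = np.empty(F, dtype=np.int64)
    for f in range(F):
        case_tr = case_total - case_fold[f]
        ctrl_tr = ctrl_total - ctrl_fold[f]
        cas, ctr = int(case_tr.sum()), int(ctrl_tr.sum())
        if cas == 0 or ctr == 0:
            raise DatasetError("a training split lost an entire phenotype class")
        # high iff cell ratio > (or >=) training case/control ratio, exactly
        lhs = case_tr * ctr
        rhs = ctrl_tr * cas
        high = lhs > rhs if tie_rule == "strict" else lhs >= rhs
        realized = (case_tr + ctrl_tr) > 0
        high &= realized  # empty training cells are never high
        tp_tr = int(case_tr[high].sum())
        tn_tr = int(ctrl_tr[~high].sum())
        train_ba[f] = 0.5 * (tp_tr / cas + tn_tr / ctr)
        win_score[f] = tp_tr * ctr + tn_tr * cas

        included = realized if empty_cell_policy == "exclude" else np.ones(size, bool)
        case_te = case_fold[f]
        ctrl_te = ctrl_fold[f]
        cas_te = int(case_te[included].sum())
        ctr_te = int(ctrl_te[included].sum())
        if cas_te == 0 or ctr_te == 0:
            test_ba[f] = np.nan
        else:
            sens = case_te[high & included].sum() / cas_te
            spec = ctrl_te[~high & included].sum() / ctr_te
            test_ba[f] = 0.5 * (sens + spec)
    return train_ba, test_ba, win_score


def _evaluate_all(
    ds: CaseControlDataset,
    order: int,
    folds: FoldAssignment,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
    combinations: Sequence[FactorCombination] | None = None,
) -> list[ModelEvaluation]:
    """Evaluate every combination of one order over all folds."""
    combos = (
        list(combinations)
        if combinations is not None
        else list(enumerate_combinations(ds.n_attributes, order))
    )
    F = folds.n_folds
    n = len(combos)
    train = np.empty((n, F))
    test = np.empty((n, F))
    score = np.empty((n, F), dtype=np.int64)
    for i, combo in enumerate(combos):
        codes, size = joint_codes(ds, combo)
        train[i], test[i], score[i] = _combo_fold_scores(
            codes, size, ds.phenotype, folds, tie_rule, empty_cell_policy
        )
    # one winner per fold; argmax returns the first (lexicographically
    # smallest combination) among exact integer ties
    winners = score.argmax(axis=0)
    evaluations = []
    for i, combo in enumerate(combos):
        won = winners == i
        evaluations.append(
            ModelEvaluation(
                combination=combo,
                names=tuple(ds.specs[a].name for a in combo.attribute_indices),
                train_ba=float(np.mean(train[i])),
                test_ba=float(np.mean(test[i])),
                cvc=int(won.sum()),
                per_fold=[
                    (float(train[i, f]), float(test[i, f]), bool(won[f]))
                    for f in range(F)
                ],
            )
        )
    return evaluations


def _best_of(evaluations: list[ModelEvaluation]) -> ModelEvaluation:
    # highest CVC, ties by mean testing BA, then lexicographic combination
    return min(
        evaluations,
        key=lambda e: (-e.cvc, -e.test_ba, e.combination.attribute_indices),
    )


def evaluate_order(
    ds: CaseControlDataset,
    order: int,
    folds: FoldAssignment,
    top_n: int = 10,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> OrderSummary:
    """Exhaustive search at one order: fold winners, CVC, and the best model
    (highest CVC, testing balanced accuracy as tie-break)."""
    evaluations = _evaluate_all(ds, order, folds, tie_rule, empty_cell_policy)
    ranked = sorted(
        evaluations, key=lambda e: (-e.train_ba, e.combination.attribute_indices)
    )
    prediction = float(
        np.mean(
            [
                next(e.per_fold[f][1] for e in evaluations if e.per_fold[f][2])
                for f in range(folds.n_folds)
            ]
        )
    )
    return OrderSummary(order, _best_of(evaluations), ranked[:top_n], prediction)


def rank_models(
    ds: CaseControlDataset,
    order: int,
    folds: FoldAssignment,
    top_n: int = 10,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> list[ModelEvaluation]:
    """Top combinations of one order by mean training balanced accuracy."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    evaluations = _evaluate_all(ds, order, folds, tie_rule, empty_cell_policy)
    ranked = sorted(
        evaluations, key=lambda e: (-e.train_ba, e.combination.attribute_indices)
    )
    return ranked[:top_n]


def summary_across_orders(summaries: Sequence[OrderSummary]) -> CrossOrderSummary:
    """Per-order best models plus the overall selection.

    The overall model maximises testing balanced accuracy; exact ties break
    by CVC, then by the smaller order (parsimony).
    """
    if not summaries:
        raise ValueError("need at least one evaluated order")
    per_order = [s.best_model for s in summaries]
    selected = min(per_order, key=lambda e: (-e.test_ba, -e.cvc, e.order))
    return CrossOrderSummary(per_order, selected)
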