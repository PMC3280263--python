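"""The MDR kernel: multifactor cells, high/low risk labeling, and scoring.

Multifactor dimensionality reduction pools the joint cells of a k-attribute
combination into two classes.  A cell is high risk when its case/control
ratio exceeds the case/control ratio of the fitting sample (threshold T);
the k-dimensional attribute space thereby collapses to a one-dimensional
binary classifier whose positive prediction is "high risk".

Cell ratio comparisons use exact integer cross-multiplication
(``cases_in_cell * total_controls > T_num * controls_in_cell`` with
T = total_cases / total_controls), so labeling never depends on floating
point and ties are resolved exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .dataset import MISSING, CaseControlDataset, DatasetError

HIGH = "high"
LOW = "low"
EXCLUDED = "excluded"

TieRule = Literal["strict", "gte"]
EmptyCellPolicy = Literal["low", "exclude"]


@dataclass(frozen=True)
class FactorCombination:
    """An ordered tuple of distinct attribute column indices."""

    attribute_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.attribute_indices
        if not idx:
            raise ValueError("combination must contain at least one attribute")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("attribute indices must be strictly increasing")

    @property
    def order(self) -> int:
        return len(self.attribute_indices)


def enumerate_combinations(n_attributes: int, order: int) -> Iterator[FactorCombination]:
    """All C(n, k) attribute combinations of the given order, lexicographic."""
    if not (1 <= order <= n_attributes):
        raise ValueError(f"order must be in [1, {n_attributes}], got {order}")
    for idx in itertools.combinations(range(n_attributes), order):
        yield FactorCombination(idx)


@dataclass
class CellTable:
    """Per-cell (case, control) counts for one factor combination."""

    combination: FactorCombination
    cells: dict[tuple[int, ...], tuple[int, int]]
    n_levels: tuple[int, ...]

    @property
    def n_cases(self) -> int:
        return sum(c for c, _ in self.cells.values())

    @property
    def n_controls(self) -> int:
        return sum(c for _, c in self.cells.values())


@dataclass
class RiskModel:
    """A fitted MDR classifier: per-cell high/low labels at threshold T.

    ``threshold`` is stored as the integer pair (cases, controls) of the
    fitting sample so that the comparison stays exact; ``labels`` covers
    every possible level tuple, with cells unseen during fitting labeled per
    ``empty_cell_policy`` ("low" keeps the classifier total, "exclude" drops
    such subjects from scoring).
    """

    combination: FactorCombination
    threshold: tuple[int, int]
    labels: dict[tuple[int, ...], str]
    n_levels: tuple[int, ...]
    empty_cell_policy: EmptyCellPolicy = "low"
    tie_rule: TieRule = "strict"
    cells: dict[tuple[int, ...], tuple[int, int]] = field(default_factory=dict)

    @property
    def threshold_ratio(self) -> float:
        return self.threshold[0] / self.threshold[1]

    def to_json(self, attribute_names: Sequence[str] | None = None) -> str:
        doc = {
            "attributes": list(attribute_names)
            if attribute_names is not None
            else list(self.combination.attribute_indices),
            "threshold_cases": self.threshold[0],
            "threshold_controls": self.threshold[1],
            "tie_rule": self.tie_rule,
            "empty_cell_policy": self.empty_cell_policy,
            "cells": [
                {
                    "levels": list(k),
                    "label": self.labels[k],
                    "cases": self.cells.get(k, (0, 0))[0],
                    "controls": self.cells.get(k, (0, 0))[1],
                }
                for k in sorted(self.labels)
            ],
        }
        return json.dumps(doc, indent=2)


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts; a case predicted high risk is a true positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# cell construction and labeling
# ---------------------------------------------------------------------------

def joint_codes(
    ds: CaseControlDataset, combo: FactorCombination
) -> tuple[np.ndarray, int]:
    """Mixed-radix cell index per subject for the combo's attributes.

    Cell 0 is the all-first-level cell; the code enumerates level tuples in
    lexicographic order, so it doubles as the grid cell order for rendering.
    Raises if any subject has a missing value on a combo attribute.
    """
    idx = combo.attribute_indices
    sub = ds.values[:, list(idx)]
    if (sub == MISSING).any():
        raise DatasetError(
            "missing values on combination attributes; run listwise_delete first"
        )
    codes = sub[:, 0].astype(np.int64)
    size = int(ds.specs[idx[0]].n_levels)
    for j, a in enumerate(idx[1:], start=1):
        L = ds.specs[a].n_levels
        codes = codes * L + sub[:, j]
        size *= L
    return codes, size


def cell_counts(
    ds: CaseControlDataset,
    combo: FactorCombination,
    subject_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised (case, control) counts per joint cell."""
    codes, size = joint_codes(ds, combo)
    pheno = ds.phenotype
    if subject_subset is not None:
        codes = codes[subject_subset]
        pheno = pheno[subject_subset]
    case = np.bincount(codes[pheno == 1], minlength=size)
    ctrl = np.bincount(codes[pheno == 0], minlength=size)
    return case, ctrl, size


def _code_to_levels(code: int, n_levels: tuple[int, ...]) -> tuple[int, ...]:
    out = []
    for L in reversed(n_levels):
        out.append(code % L)
        code //= L
    return tuple(reversed(out))


def build_cell_table(
    ds: CaseControlDataset,
    combo: FactorCombination,
    subject_subset: np.ndarray | None = None,
) -> CellTable:
    """Tabulate case/control counts over the combo's joint cells.

    Cells not realised in the data are absent from the map; labeling decides
    their fate downstream via the empty-cell policy.
    """
    case, ctrl, _ = cell_counts(ds, combo, subject_subset)
    n_levels = tuple(int(ds.specs[a].n_levels) for a in combo.attribute_indices)
    cells = {}
    for code in np.flatnonzero(case + ctrl):
        cells[_code_to_levels(int(code), n_levels)] = (int(case[code]), int(ctrl[code]))
    return CellTable(combo, cells, n_levels)


def label_cells(
    table: CellTable,
    threshold: tuple[int, int] | float,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> RiskModel:
    """Assign each joint cell a high/low risk label against threshold T.

    High iff case_count / control_count > T (">=" under the ``gte`` tie
    rule).  A cell with cases but no controls has ratio +inf and is high; a
    realised cell exactly at T is low under the default strict rule.  Cells
    with no subjects get the empty-cell policy's label.
    """
    if isinstance(threshold, float):
        # tolerate a float T by scaling to a rational with fixed denominator
        t_num, t_den = int(round(threshold * 10**9)), 10**9
    else:
        t_num, t_den = threshold
    if t_num <= 0 or t_den <= 0:
        raise ValueError("threshold must be a positive ratio")

    labels: dict[tuple[int, ...], str] = {}
    for levels in itertools.product(*(range(L) for L in table.n_levels)):
        if levels in table.cells:
            case, ctrl = table.cells[levels]
            lhs, rhs = case * t_den, t_num * ctrl
            high = lhs > rhs if tie_rule == "strict" else lhs >= rhs
            labels[levels] = HIGH if high else LOW
        else:
            labels[levels] = LOW if empty_cell_policy == "low" else EXCLUDED
    return RiskModel(
        table.combination,
        (t_num, t_den),
        labels,
        table.n_levels,
        empty_cell_policy,
        tie_rule,
        dict(table.cells),
    )


def classify(model: RiskModel, subject_levels: Sequence[int]) -> str:
    """Predicted risk class for one subject's level tuple."""
    key = tuple(int(v) for v in subject_levels)
    if len(key) != len(model.n_levels):
        raise ValueError("level tuple arity does not match model order")
    for v, L in zip(key, model.n_levels):
        if not (0 <= v < L):
            raise ValueError(f"level code {v} outside declared levels (0..{L - 1})")
    return model.labels[key]


def confusion(
    model: RiskModel, ds: CaseControlDataset, subject_subset: np.ndarray | None = None
) -> ConfusionSummary:
    """Cross-classify predicted risk against phenotype."""
    case, ctrl, size = cell_counts(ds, model.combination, subject_subset)
    high = np.zeros(size, dtype=bool)
    included = np.ones(size, dtype=bool)
    for code in range(size):
        lab = model.labels[_code_to_levels(code, model.n_levels)]
        if lab == HIGH:
            high[code] = True
        elif lab == EXCLUDED:
            included[code] = False
    tp = int(case[high & included].sum())
    fn = int(case[~high & included].sum())
    fp = int(ctrl[high & included].sum())
    tn = int(ctrl[~high & included].sum())
    return ConfusionSummary(tp, fp, tn, fn)


def balanced_accuracy(c: ConfusionSummary) -> float:
    """(sensitivity + specificity) / 2; requires both classes present."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("balanced accuracy undefined: a phenotype class is absent")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def accuracy(c: ConfusionSummary) -> float:
    """Plain classification accuracy, reported as a secondary metric."""
    if c.n == 0:
        raise ValueError("no classified subjects")
    return (c.tp + c.tn) / c.n


def fit_risk_model(
    ds: CaseControlDataset,
    combo: FactorCombination,
    subject_subset: np.ndarray | None = None,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> RiskModel:
    """Build the cell table on the fitting subjects and label it at their
    case/control ratio (the threshold never sees held-out data)."""
    table = build_cell_table(ds, combo, subject_subset)
    n_cases, n_controls = table.n_cases, table.n_controls
    if n_cases == 0 or n_controls == 0:
        raise DatasetError("fitting subset must contain both cases and controls")
    return label_cells(table, (n_cases, n_controls), tie_rule, empty_cell_policy)


def write_risk_model_json(
    model: RiskModel, ds: CaseControlDataset, path: str | Path
) -> None:
    names = [ds.specs[a].name for a in model.combination.attribute_indices]
    Path(path).write_text(model.to_json(names) + "\n")
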