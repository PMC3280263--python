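"""Validation of candidate interaction models.

Four complementary checks:

* **Permutation test** — phenotype labels permuted; destroys every
  attribute-phenotype association, so it rejects for main effects and
  interactions alike.
* **Explicit test of epistasis** — each attribute column is shuffled
  independently *within cases and within controls*.  Every single-attribute
  contingency table with the phenotype is preserved exactly while the joint
  structure is destroyed, so rejection evidences interaction specifically.
* **Likelihood-ratio test** — logistic regression with categorical main
  effects (reduced) against main effects plus all interaction terms among
  the combination's attributes (full, i.e. saturated on the joint cells).
* **Chi-square test** — Pearson 1-df test of the reduced high/low risk
  classification against case status.

Resampling p-values use the add-one convention p = (r + 1) / (B + 1).
All randomness derives from one master seed via ``numpy`` seed-sequence
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .dataset import CaseControlDataset, DatasetError
from .crossval import stratified_fold_labels
from .mdr import (
    EXCLUDED,
    HIGH,
    EmptyCellPolicy,
    FactorCombination,
    RiskModel,
    TieRule,
    _code_to_levels,
    cell_counts,
)

Statistic = Literal["test_ba", "train_ba"]


@dataclass
class PermutationResult:
    """Observed statistic, resampled null, and the add-one p-value."""

    observed: float
    null_values: np.ndarray
    p: float
    n_replicates: int
    seed: int
    scheme: str  # "permutation" or "explicit"
    statistic: Statistic


@dataclass
class LrtResult:
    """Deviance comparison of the saturated interaction model against the
    main-effects-only logistic model."""

    deviance_full: float
    deviance_reduced: float
    statistic: float
    df: int
    p: float
    converged: bool = True


def _resampling_p(observed: float, null_values: np.ndarray) -> float:
    r = int((null_values >= observed).sum())
    return (r + 1) / (len(null_values) + 1)


def _cv_statistic(
    values: np.ndarray,
    n_levels: np.ndarray,
    phenotype: np.ndarray,
    combo: FactorCombination,
    n_folds: int,
    rng: np.random.Generator,
    statistic: Statistic,
    tie_rule: TieRule,
    empty_cell_policy: EmptyCellPolicy,
) -> float:
    """Mean training or testing balanced accuracy of one combination under a
    fresh stratified F-fold split."""
    from .crossval import FoldAssignment, _combo_fold_scores

    idx = list(combo.attribute_indices)
    codes = values[:, idx[0]].astype(np.int64)
    size = int(n_levels[idx[0]])
    for a in idx[1:]:
        codes = codes * int(n_levels[a]) + values[:, a]
        size *= int(n_levels[a])
    folds = FoldAssignment(
        stratified_fold_labels(phenotype, n_folds, rng), n_folds, -1
    )
    train, test, _ = _combo_fold_scores(
        codes, size, phenotype, folds, tie_rule, empty_cell_policy
    )
    return float(np.mean(train if statistic == "train_ba" else test))


def permutation_test(
    ds: CaseControlDataset,
    combo: FactorCombination,
    n_replicates: int = 1000,
    statistic: Statistic = "test_ba",
    seed: int = 0,
    n_folds: int = 10,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> PermutationResult:
    """Label-permutation null for one combination's cross-validated score.

    Each replicate permutes the phenotype vector, re-draws stratified folds,
    and recomputes the full cross-validated statistic for the fixed
    combination.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    n_levels = ds.n_levels()
    children = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    rng0 = np.random.default_rng(children[0])
    observed = _cv_statistic(
        ds.values, n_levels, ds.phenotype, combo, n_folds, rng0,
        statistic, tie_rule, empty_cell_policy,
    )
    null = np.empty(n_replicates)
    for b in range(n_replicates):
        rng = np.random.default_rng(children[b + 1])
        perm_pheno = rng.permutation(ds.phenotype)
        null[b] = _cv_statistic(
            ds.values, n_levels, perm_pheno, combo, n_folds, rng,
            statistic, tie_rule, empty_cell_policy,
        )
    return PermutationResult(
        observed, null, _resampling_p(observed, null), n_replicates, seed,
        "permutation", statistic,
    )


def explicit_test(
    ds: CaseControlDataset,
    combo: FactorCombination,
    n_replicates: int = 1000,
    statistic: Statistic = "test_ba",
    seed: int = 0,
    n_folds: int = 10,
    tie_rule: TieRule = "strict",
    empty_cell_policy: EmptyCellPolicy = "low",
) -> PermutationResult:
    """Explicit test of epistasis: a main-effect-preserving null.

    Each replicate shuffles every combination attribute's column
    independently within cases and within controls.  Marginal
    attribute-phenotype tables are invariant by construction, so the null
    retains all main effects and the test has power only against joint
    (interaction) structure.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    n_levels = ds.n_levels()
    children = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    rng0 = np.random.default_rng(children[0])
    observed = _cv_statistic(
        ds.values, n_levels, ds.phenotype, combo, n_folds, rng0,
        statistic, tie_rule, empty_cell_policy,
    )
    case_idx = np.flatnonzero(ds.phenotype == 1)
    ctrl_idx = np.flatnonzero(ds.phenotype == 0)
    null = np.empty(n_replicates)
    for b in range(n_replicates):
        rng = np.random.default_rng(children[b + 1])
        shuffled = ds.values.copy()
        for a in combo.attribute_indices:
            for idx in (case_idx, ctrl_idx):
                shuffled[idx, a] = shuffled[rng.permutation(idx), a]
        null[b] = _cv_statistic(
            shuffled, n_levels, ds.phenotype, combo, n_folds, rng,
            statistic, tie_rule, empty_cell_policy,
        )
    return PermutationResult(
        observed, null, _resampling_p(observed, null), n_replicates, seed,
        "explicit", statistic,
    )


# ---------------------------------------------------------------------------
# likelihood ratio test for interaction
# ---------------------------------------------------------------------------

def _main_effects_design(
    ds: CaseControlDataset, combo: FactorCombination, cell_codes: np.ndarray
) -> np.ndarray:
    """Intercept + treatment-coded dummies per attribute, one row per cell.

    The reference level of each attribute is its most frequent level in the
    dataset (deterministic coding; the deviance is invariant to it).
    """
    n_levels = [int(ds.specs[a].n_levels) for a in combo.attribute_indices]
    cols = [np.ones(len(cell_codes))]
    for pos, a in enumerate(combo.attribute_indices):
        level_of_cell = np.array(
            [_code_to_levels(int(c), tuple(n_levels))[pos] for c in cell_codes]
        )
        col_counts = np.bincount(
            ds.values[:, a], minlength=ds.specs[a].n_levels
        )
        ref = int(col_counts.argmax())
        for lvl in range(ds.specs[a].n_levels):
            if lvl == ref:
                continue
            cols.append((level_of_cell == lvl).astype(float))
    return np.column_stack(cols)


def lrt_interaction(
    ds: CaseControlDataset, combo: FactorCombination
) -> LrtResult:
    """Deviance LRT of all interaction terms among the combination.

    Fitted on grouped (per-cell) binomial data.  The full model — main
    effects plus every interaction term among the combination's attributes —
    is saturated on the realised joint cells, so its deviance is exactly 0
    and the statistic reduces to the residual deviance of the main-effects
    model.  Degrees of freedom = realised cells minus the rank of the
    main-effects design.
    """
    import statsmodels.api as sm

    if combo.order < 2:
        raise ValueError("interaction LRT needs at least two attributes")
    case, ctrl, _ = cell_counts(ds, combo)
    realized = np.flatnonzero(case + ctrl)
    endog = np.column_stack([case[realized], ctrl[realized]]).astype(float)
    exog = _main_effects_design(ds, combo, realized)
    rank_reduced = int(np.linalg.matrix_rank(exog))
    df = len(realized) - rank_reduced
    if df < 1:
        raise DatasetError("no interaction degrees of freedom in realised cells")
    import warnings

    try:
        with warnings.catch_warnings():
            # a deviance-0 fit on balanced cells trips the separation
            # heuristic although the MLE is finite; judge by the estimates
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
        converged = bool(fit.converged) and bool(np.abs(fit.params).max() < 30)
        deviance_reduced = float(fit.deviance)
    except Exception:
        return LrtResult(0.0, np.nan, np.nan, df, np.nan, converged=False)
    statistic = max(deviance_reduced, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if converged else np.nan
    return LrtResult(0.0, deviance_reduced, statistic, df, p, converged)


def chi_square_high_low(
    ds: CaseControlDataset, model: RiskModel
) -> tuple[float, float, np.ndarray]:
    """Pearson 1-df chi-square of predicted risk class against phenotype.

    Subjects are cross-classified as (high, low) x (case, control); excluded
    cells (empty-cell policy "exclude") are left out.  No continuity
    correction.  Returns (chi_square, p, 2x2 table) with rows (high, low)
    and columns (case, control).
    """
    case, ctrl, size = cell_counts(ds, model.combination)
    table = np.zeros((2, 2), dtype=np.int64)
    for code in range(size):
        lab = model.labels[_code_to_levels(code, model.n_levels)]
        if lab == EXCLUDED:
            continue
        row = 0 if lab == HIGH else 1
        table[row, 0] += case[code]
        table[row, 1] += ctrl[code]
    if table.sum(axis=1).min() == 0:
        raise DatasetError("a risk group is empty; chi-square undefined")
    if table.sum(axis=0).min() == 0:
        raise DatasetError("a phenotype class is empty; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table
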