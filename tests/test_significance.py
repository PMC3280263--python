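"""Permutation/explicit resampling tests, interaction LRT, and the
high/low-risk chi-square validation."""

import numpy as np
import pytest
from scipy import stats

from mdrkit.dataset import DatasetError
from mdrkit.mdr import FactorCombination
from mdrkit.significance import (
    _resampling_p,
    chi_square_high_low,
    explicit_test,
    lrt_interaction,
    permutation_test,
)
from mdrkit.simulate import (
    SimulationRecipe,
    simulate_case_control,
    snp_attribute,
    xor_penetrance,
)
from conftest import make_dataset
from oracles import newton_logistic, pearson_2x2


def test_resampling_p_rank_formula():
    # observed exceeds all 19 null values -> p = 1/20
    assert _resampling_p(1.0, np.zeros(19)) == pytest.approx(0.05)
    # 4 of 19 null values >= observed -> p = 5/20
    null = np.concatenate([np.full(4, 2.0), np.zeros(15)])
    assert _resampling_p(1.0, null) == pytest.approx(0.25)
    # p can never be 0 or exceed 1
    assert _resampling_p(-np.inf, np.zeros(9)) == 1.0
    assert _resampling_p(np.inf, np.zeros(9)) == pytest.approx(0.1)


def _xor_dataset(seed, n=200, noise_attrs=1):
    model = xor_penetrance(
        snp_attribute("a", 0.5), snp_attribute("b", 0.5), baseline=0.1, effect=0.8
    )
    noise = [snp_attribute(f"n{i}", 0.3) for i in range(noise_attrs)]
    return simulate_case_control(
        SimulationRecipe(n // 2, n // 2, model, noise, seed=seed)
    )


def test_permutation_test_rejects_strong_interaction():
    ds = _xor_dataset(seed=0, n=400)
    res = permutation_test(ds, FactorCombination((0, 1)), n_replicates=19, seed=1)
    assert res.p == pytest.approx(1 / 20)
    assert res.observed > max(res.null_values)
    assert len(res.null_values) == 19


def test_explicit_test_has_power_against_pure_interaction():
    """XOR epistasis has no main effects, so the main-effect-preserving null
    still detects it."""
    hits = 0
    for seed in range(10):
        ds = _xor_dataset(seed=seed, n=400)
        res = explicit_test(ds, FactorCombination((0, 1)), n_replicates=39, seed=seed)
        hits += res.p <= 0.05
    assert hits >= 9


def test_explicit_resampling_preserves_marginal_tables():
    """Each resample must leave every attribute-phenotype contingency table
    exactly unchanged (the defining invariant of the explicit test)."""
    rng = np.random.default_rng(2)
    ds = _xor_dataset(seed=3, n=100)
    combo = FactorCombination((0, 1))
    case_idx = np.flatnonzero(ds.phenotype == 1)
    ctrl_idx = np.flatnonzero(ds.phenotype == 0)
    for _ in range(20):
        shuffled = ds.values.copy()
        for a in combo.attribute_indices:
            for idx in (case_idx, ctrl_idx):
                shuffled[idx, a] = shuffled[rng.permutation(idx), a]
        for a in combo.attribute_indices:
            for cls_idx in (case_idx, ctrl_idx):
                before = np.bincount(ds.values[cls_idx, a], minlength=3)
                after = np.bincount(shuffled[cls_idx, a], minlength=3)
                assert np.array_equal(before, after)


# ---------------------------------------------------------------------------
# likelihood ratio test
# ---------------------------------------------------------------------------

def _dataset_from_cell_counts(counts):
    """counts: dict (a, b) -> (cases, controls) over two binary factors."""
    rows, pheno = [], []
    for (a, b), (case, ctrl) in counts.items():
        rows += [[a, b]] * (case + ctrl)
        pheno += [1] * case + [0] * ctrl
    return make_dataset(
        np.array(rows, dtype=np.int16), np.array(pheno, dtype=np.int8), n_levels=[2, 2]
    )


def test_lrt_degrees_of_freedom_two_three_level_factors():
    rng = np.random.default_rng(4)
    values = rng.integers(0, 3, size=(300, 2)).astype(np.int16)
    pheno = (rng.random(300) < 0.4).astype(np.int8)
    ds = make_dataset(values, pheno, n_levels=[3, 3])
    res = lrt_interaction(ds, FactorCombination((0, 1)))
    # reduced: 1 + 2 + 2 parameters; full (saturated) adds 4
    assert res.df == 4
    assert res.statistic >= -1e-8


def test_lrt_null_identity_on_balanced_table():
    """Phenotype independent of both factors: statistic 0, p 1."""
    counts = {(a, b): (2, 3) for a in range(2) for b in range(2)}
    ds = _dataset_from_cell_counts(counts)
    res = lrt_interaction(ds, FactorCombination((0, 1)))
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p == pytest.approx(1.0, abs=1e-6)


def test_lrt_matches_newton_oracle_on_fixture():
    """Deviance difference agrees to 1e-6 with an independently written
    Newton-Raphson logistic fit on subject-level data."""
    counts = {(0, 0): (10, 20), (0, 1): (5, 25), (1, 0): (8, 22), (1, 1): (20, 10)}
    ds = _dataset_from_cell_counts(counts)
    res = lrt_interaction(ds, FactorCombination((0, 1)))

    a = ds.values[:, 0].astype(float)
    b = ds.values[:, 1].astype(float)
    y = ds.phenotype.astype(float)
    X_red = np.column_stack([np.ones_like(a), a, b])
    X_full = np.column_stack([np.ones_like(a), a, b, a * b])
    stat_oracle = 2 * (newton_logistic(X_full, y) - newton_logistic(X_red, y))
    assert res.statistic == pytest.approx(stat_oracle, abs=1e-6)
    assert res.df == 1
    assert res.p == pytest.approx(stats.chi2.sf(stat_oracle, 1), abs=1e-6)


def test_lrt_requires_two_attributes():
    ds = _dataset_from_cell_counts({(0, 0): (2, 3), (1, 1): (3, 2), (0, 1): (1, 1), (1, 0): (1, 1)})
    with pytest.raises(ValueError):
        lrt_interaction(ds, FactorCombination((0,)))


# ---------------------------------------------------------------------------
# chi-square validation of the high/low classification
# ---------------------------------------------------------------------------

def _risk_dataset(a, b, c, d):
    """Single binary attribute; level 1 plays 'high risk'.
    Table: high (a cases, b controls), low (c cases, d controls)."""
    rows = [[1]] * (a + b) + [[0]] * (c + d)
    pheno = [1] * a + [0] * b + [1] * c + [0] * d
    ds = make_dataset(
        np.array(rows, dtype=np.int16), np.array(pheno, dtype=np.int8), n_levels=[2]
    )
    return ds


def _manual_model(ds):
    from mdrkit.mdr import label_cells, build_cell_table

    table = build_cell_table(ds, FactorCombination((0,)))
    # threshold chosen so level 1 labels high, level 0 low
    model = label_cells(table, (1, 10**6))
    model.labels[(1,)] = "high"
    model.labels[(0,)] = "low"
    return model


def test_chi_square_matches_textbook_oracle():
    ds = _risk_dataset(50, 50, 50, 150)
    chi2, p, table = chi_square_high_low(ds, _manual_model(ds))
    assert chi2 == pytest.approx(pearson_2x2(50, 50, 50, 150), abs=1e-9)
    assert chi2 > 0
    assert table.tolist() == [[50, 50], [50, 150]]


def test_chi_square_zero_under_equal_ratios_and_scaling():
    ds = _risk_dataset(10, 20, 30, 60)  # identical 1:2 ratio in both groups
    chi2, p, _ = chi_square_high_low(ds, _manual_model(ds))
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)
    small = _risk_dataset(5, 10, 15, 20)
    big = _risk_dataset(10, 20, 30, 40)
    c_small, _, _ = chi_square_high_low(small, _manual_model(small))
    c_big, _, _ = chi_square_high_low(big, _manual_model(big))
    assert c_big == pytest.approx(2 * c_small, abs=1e-9)


def test_chi_square_random_tables_against_oracle():
    rng = np.random.default_rng(9)
    for _ in range(1000):
        a, b, c, d = (int(rng.integers(1, 40)) for _ in range(4))
        assert pearson_2x2(a, b, c, d) >= 0
        # spot-check the implementation on a subsample to keep runtime low
    for _ in range(50):
        a, b, c, d = (int(rng.integers(1, 40)) for _ in range(4))
        ds = _risk_dataset(a, b, c, d)
        chi2, _, _ = chi_square_high_low(ds, _manual_model(ds))
        assert chi2 == pytest.approx(pearson_2x2(a, b, c, d), abs=1e-9)


def test_chi_square_degenerate_classification_errors():
    ds = _risk_dataset(5, 5, 5, 5)
    model = _manual_model(ds)
    model.labels[(0,)] = "high"  # both levels high -> low group empty
    with pytest.raises(DatasetError):
        chi_square_high_low(ds, model)
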