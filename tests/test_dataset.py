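"""Reading, validation, QC filtering, and derived attributes."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mdrkit.dataset import (
    MISSING,
    AttributeSpec,
    DatasetError,
    GenotypeCounts,
    bmi_quartiles,
    call_rate_filter,
    derive_dampness,
    hwe_test,
    listwise_delete,
    read_dataset,
    run_qc,
    write_dataset_tsv,
)
from conftest import make_dataset


TSV = """subject_id\tphenotype\tsnp1\tsnp2
s1\t1\tAA\tAa
s2\t0\tAa\taa
s3\t0\taa\tAA
s4\t1\tAA\tNA
s5\t0\tAa\tAa
"""


def test_read_tsv_basic(tmp_path):
    path = tmp_path / "d.tsv"
    path.write_text(TSV)
    ds = read_dataset(path)
    assert ds.n_subjects == 5
    assert ds.n_attributes == 2
    assert ds.attribute_names == ["snp1", "snp2"]
    assert ds.n_cases == 2 and ds.n_controls == 3
    # "NA" normalised to the missing sentinel
    assert ds.values[3, 1] == MISSING
    # level codes follow the declared (sorted) level order
    assert ds.specs[0].levels == ("AA", "Aa", "aa")
    assert ds.values[0, 0] == 0 and ds.values[1, 0] == 1 and ds.values[2, 0] == 2


def test_read_tsv_errors(tmp_path):
    bad_row = tmp_path / "bad.tsv"
    bad_row.write_text("subject_id\tphenotype\ta\ns1\t1\t0\t9\ns2\t0\t1\n")
    with pytest.raises(DatasetError, match="line 2"):
        read_dataset(bad_row)

    bad_level = tmp_path / "lvl.tsv"
    bad_level.write_text("subject_id\tphenotype\ta\ns1\t1\t0\ns2\t0\t1\n")
    spec = AttributeSpec("a", "environment", ("0", "2"))
    with pytest.raises(DatasetError, match="unknown level"):
        read_dataset(bad_level, specs=[spec])


def test_read_ped_map_against_hand_parse(tmp_path):
    """4-subject ped with 3 markers, compared to a hand-derived coding."""
    (tmp_path / "toy.map").write_text(
        "1 rs1 0 100\n1 rs2 0 200\n1 rs3 0 300\n"
    )
    (tmp_path / "toy.ped").write_text(
        "F1 I1 0 0 1 2 A A A G C C\n"
        "F2 I2 0 0 2 1 A G G G C T\n"
        "F3 I3 0 0 1 1 A A G G T T\n"
        "F4 I4 0 0 2 2 A G A G 0 0\n"
    )
    ds = read_dataset(tmp_path / "toy.ped", format="ped_map")
    assert ds.attribute_names == ["rs1", "rs2", "rs3"]
    assert [s.n_levels for s in ds.specs] == [3, 3, 3]
    # rs1: alleles A (major, 6 copies) / G (2): codes = minor-allele count
    assert ds.values[:, 0].tolist() == [0, 1, 0, 1]
    # rs2: A appears 2x, G 6x -> G major; minor-allele count per subject
    assert ds.values[:, 1].tolist() == [1, 0, 0, 1]
    # rs3: C major (3 vs 3 -> tie broken to 'C' by sorted order), last missing
    assert ds.values[3, 2] == MISSING
    # phenotype: PLINK 2=case, 1=control
    assert ds.phenotype.tolist() == [1, 0, 0, 1]


def test_tsv_round_trip(tmp_path):
    path = tmp_path / "d.tsv"
    path.write_text(TSV)
    ds = read_dataset(path)
    out = tmp_path / "out.tsv"
    write_dataset_tsv(ds, out)
    ds2 = read_dataset(out)
    assert np.array_equal(ds.values, ds2.values)
    assert np.array_equal(ds.phenotype, ds2.phenotype)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def _dataset_with_missing(n=100, miss_a=3, miss_b=0):
    rng = np.random.default_rng(7)
    values = rng.integers(0, 3, size=(n, 2)).astype(np.int16)
    values[:miss_a, 0] = MISSING
    values[:miss_b, 1] = MISSING
    pheno = np.zeros(n, dtype=np.int8)
    pheno[: n // 2] = 1
    return make_dataset(values, pheno, n_levels=[3, 3])


def test_call_rate_filter_drops_low_rate_snp():
    ds = _dataset_with_missing(n=100, miss_a=3)  # 97/100 called
    out, report = call_rate_filter(ds, min_rate=0.98)
    assert report["dropped_attributes"] == ["attr0"]
    assert out.attribute_names == ["attr1"]
    # fully-called data is untouched
    out2, rep2 = call_rate_filter(ds, min_rate=0.9)
    assert rep2["dropped_attributes"] == []
    assert out2.n_attributes == 2


def test_call_rate_filter_counts():
    rng = np.random.default_rng(1)
    values = rng.integers(0, 2, size=(20, 5)).astype(np.int16)
    values[:10, 1] = MISSING
    values[:10, 3] = MISSING
    pheno = np.array([1] * 5 + [0] * 15, dtype=np.int8)
    ds = make_dataset(values, pheno, n_levels=[2] * 5)
    out, _ = call_rate_filter(ds, min_rate=0.9)
    assert out.n_attributes == 3


def test_listwise_delete_only_selected_columns():
    values = np.array(
        [[0, 0], [MISSING, 1], [1, MISSING], [2, 2], [0, 1]], dtype=np.int16
    )
    pheno = np.array([1, 0, 1, 0, 0], dtype=np.int8)
    ds = make_dataset(values, pheno, n_levels=[3, 3])
    out, removed = listwise_delete(ds)
    assert out.n_subjects == 3 and len(removed) == 2
    # missing only in a non-selected column keeps the subject
    out2, removed2 = listwise_delete(ds, attributes=[1])
    assert out2.n_subjects == 4
    assert removed2 == ["s2"]
    # no missing values: identity
    out3, removed3 = listwise_delete(out)
    assert removed3 == [] and out3.n_subjects == 3


def test_qc_order_filter_before_delete():
    """A low-call-rate attribute is dropped before subject deletion, so its
    missingness does not cost subjects (the documented fixed QC order)."""
    n = 50
    values = np.zeros((n, 2), dtype=np.int16)
    values[: n // 2, 0] = MISSING  # 50% call rate -> dropped at 0.98
    values[:, 1] = np.tile([0, 1, 2], n)[:n]
    pheno = np.tile([1, 0, 0, 0, 0], n // 5).astype(np.int8)
    ds = make_dataset(values, pheno, n_levels=[3, 3])
    clean, report = run_qc(ds, min_call_rate=0.98)
    assert report["dropped_attributes"] == ["attr0"]
    assert clean.n_subjects == n  # nobody deleted
    # the reverse order would have deleted half the sample
    deleted_first, _ = listwise_delete(ds)
    assert deleted_first.n_subjects == n // 2


@pytest.mark.parametrize(
    "counts,expected_chi2",
    [
        ((36, 48, 16), 0.0),  # exactly at HWE for p(A)=0.6
        ((25, 50, 25), 0.0),  # MAF 0.5 at exact HWE proportions
        ((30, 60, 10), 6.25),  # hand-derived: expected (36,48,16)
    ],
)
def test_hwe_known_values(counts, expected_chi2):
    res = hwe_test(GenotypeCounts(*counts))
    assert res.chi_square == pytest.approx(expected_chi2, abs=1e-12)
    if expected_chi2 == 0.0:
        assert res.p == pytest.approx(1.0)


def test_hwe_monomorphic_flag():
    res = hwe_test(GenotypeCounts(40, 0, 0))
    assert res.monomorphic
    assert res.chi_square == 0.0 and res.p == 1.0


def test_hwe_matches_scipy_on_exhaustive_triples():
    """Exhaustive agreement with an independent Pearson computation for all
    genotype-count triples with n <= 30."""
    for n in range(1, 31):
        for n_aa in range(n + 1):
            for n_het in range(n - n_aa + 1):
                counts = GenotypeCounts(n_aa, n_het, n - n_aa - n_het)
                res = hwe_test(counts)
                p_major = (2 * n_aa + n_het) / (2 * n)
                if p_major in (0.0, 1.0):
                    assert res.monomorphic
                    continue
                exp = np.array(
                    [
                        n * p_major**2,
                        2 * n * p_major * (1 - p_major),
                        n * p_major**2 * ((1 - p_major) / p_major) ** 2,
                    ]
                )
                obs = np.array([n_aa, n_het, n - n_aa - n_het], float)
                chi2_ref = stats.chisquare(obs, exp, ddof=1).statistic
                assert res.chi_square == pytest.approx(float(chi2_ref), abs=1e-8)


def test_simulated_hwe_genotypes_pass_qc():
    """Generator output satisfies what the QC assumes: HWE at alpha=0.001
    in at least 99% of replicates at the study sample size."""
    from mdrkit.simulate import simulate_genotypes

    rng = np.random.default_rng(42)
    n_pass = 0
    reps = 1000
    for _ in range(reps):
        col = simulate_genotypes(1310, maf=0.3, seed=rng)
        counts = np.bincount(col, minlength=3)
        res = hwe_test(GenotypeCounts(*counts.tolist()))
        n_pass += res.p > 0.001
    assert n_pass >= 0.99 * reps


# ---------------------------------------------------------------------------
# derived attributes
# ---------------------------------------------------------------------------

def test_dampness_truth_table_and_monotonicity():
    codes = (0, 1, MISSING)
    for m, o, s in itertools.product(codes, repeat=3):
        out = derive_dampness(np.array([m]), np.array([o]), np.array([s]))[0]
        if 1 in (m, o, s):
            assert out == 1
        elif {m, o, s} == {MISSING}:
            assert out == MISSING
        else:
            assert out == 0
        # monotone: flipping any 'no' to 'yes' never turns a 1 into a 0
        if out == 1:
            for flipped in [(1, o, s), (m, 1, s), (m, o, 1)]:
                out2 = derive_dampness(*(np.array([v]) for v in flipped))[0]
                assert out2 == 1


def test_bmi_quartiles_sorting_oracle():
    codes, cuts = bmi_quartiles(np.arange(1.0, 9.0))
    assert codes.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]
    # a value exactly at a cut-point goes to the lower quartile
    codes2, _ = bmi_quartiles(np.array([1.0, 2.0, 3.0, 4.0, cuts[0]]))
    cuts2 = np.quantile([1.0, 2.0, 3.0, 4.0, cuts[0]], [0.25, 0.5, 0.75])
    assert codes2[-1] == np.searchsorted(cuts2, cuts[0], side="left")
    v = np.array([15.0, 18.0, 21.0, 24.0, 21.0])  # 21.0 is the median cut
    c3, cut3 = bmi_quartiles(v)
    assert cut3[1] == 21.0 and c3[2] == 1 and c3[4] == 1


def test_bmi_quartiles_degenerate_and_missing():
    with pytest.raises(DatasetError):
        bmi_quartiles(np.array([20.0, 20.0, 20.0, 20.0, 21.0, 22.0]) * 0 + 20.0)
    codes, _ = bmi_quartiles(np.array([1.0, 2.0, 3.0, 4.0, np.nan]))
    assert codes[-1] == MISSING
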