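"""Case-control dataset container, file readers, and genotype/exposure QC.

The data model is deliberately categorical: every analysis attribute is a
small ordered set of level codes (three-genotype SNPs, present/null deletion
polymorphisms, binary exposures, BMI quartiles).  Values are stored as
integer codes into each attribute's declared level list, with ``-1`` as the
dataset-wide missing sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

MISSING = -1
#: input tokens normalised to the missing sentinel on read
MISSING_CODES = ("NA", "na", "-9", "", ".")

GENOTYPE = "genotype"
ENVIRONMENT = "environment"


class DatasetError(ValueError):
    """Malformed input, failed validation, or an operation that emptied the data."""


@dataclass(frozen=True)
class AttributeSpec:
    """Metadata for one categorical analysis attribute.

    ``levels`` is the ordered list of category labels; values in the dataset
    matrix are indices into it.  For three-level SNPs the convention is
    (major homozygote, heterozygote, minor homozygote); deletion genotypes
    such as GSTT1/GSTM1 use two levels (present, null).
    """

    name: str
    kind: str
    levels: tuple[str, ...]
    missing_code: str = "NA"

    def __post_init__(self) -> None:
        if self.kind not in (GENOTYPE, ENVIRONMENT):
            raise DatasetError(f"{self.name}: unknown attribute kind {self.kind!r}")
        if not (2 <= len(self.levels) <= 4):
            raise DatasetError(
                f"{self.name}: expected 2-4 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise DatasetError(f"{self.name}: duplicate level codes")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one biallelic SNP: (AA, Aa, aa)."""

    n_aa_major: int
    n_het: int
    n_aa_minor: int

    def __post_init__(self) -> None:
        if min(self.n_aa_major, self.n_het, self.n_aa_minor) < 0:
            raise DatasetError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_aa_major + self.n_het + self.n_aa_minor


@dataclass
class CaseControlDataset:
    """Subjects x categorical attributes with a binary phenotype.

    ``values`` holds integer level codes (``MISSING`` = -1); ``phenotype`` is
    1 for cases, 0 for controls.
    """

    subject_ids: list[str]
    phenotype: np.ndarray
    values: np.ndarray
    specs: list[AttributeSpec]

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.values = np.asarray(self.values, dtype=np.int16)
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise DatasetError("subject_ids length does not match value matrix")
        if len(self.specs) != p:
            raise DatasetError("spec count does not match value matrix columns")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DatasetError("phenotype must be strictly binary (0/1)")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DatasetError("dataset needs at least one case and one control")
        for j, spec in enumerate(self.specs):
            col = self.values[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= spec.n_levels))
            if bad.any():
                raise DatasetError(
                    f"attribute {spec.name}: value code outside declared levels"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def attribute_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def column(self, name: str) -> int:
        try:
            return self.attribute_names.index(name)
        except ValueError:
            raise DatasetError(f"no attribute named {name!r}") from None

    def n_levels(self) -> np.ndarray:
        return np.array([s.n_levels for s in self.specs], dtype=np.int64)

    def subset_subjects(self, rows: np.ndarray) -> "CaseControlDataset":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return CaseControlDataset(
            [self.subject_ids[i] for i in rows],
            self.phenotype[rows],
            self.values[rows],
            list(self.specs),
        )

    def select_attributes(self, cols: Sequence[int]) -> "CaseControlDataset":
        cols = list(cols)
        return CaseControlDataset(
            list(self.subject_ids),
            self.phenotype.copy(),
            self.values[:, cols],
            [self.specs[j] for j in cols],
        )

    def call_rate(self, col: int) -> float:
        return float((self.values[:, col] != MISSING).mean())

    def genotype_counts(self, col: int) -> GenotypeCounts:
        spec = self.specs[col]
        if spec.kind != GENOTYPE or spec.n_levels != 3:
            raise DatasetError(f"{spec.name}: not a three-level genotype attribute")
        c = np.bincount(self.values[:, col][self.values[:, col] != MISSING], minlength=3)
        return GenotypeCounts(int(c[0]), int(c[1]), int(c[2]))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _infer_kind(levels: Sequence[str]) -> str:
    env_like = {"0", "1", "yes", "no", "Q1", "Q2", "Q3", "Q4"}
    return ENVIRONMENT if set(levels) <= env_like else GENOTYPE


def read_dataset(
    path: str | Path,
    format: str = "tsv",
    specs: Sequence[AttributeSpec] | None = None,
    missing_codes: Iterable[str] = MISSING_CODES,
) -> CaseControlDataset:
    """Read a case-control table from disk.

    ``tsv``: header row; column 1 subject id, column 2 phenotype (0/1),
    remaining columns attributes; missing values as any of ``missing_codes``.
    ``ped_map``: PLINK-style white-space .ped with companion .map; allele
    pairs are collapsed to three-level genotype attributes.

    When ``specs`` is omitted, levels are inferred as the sorted unique
    non-missing tokens per column (2-4 of them) and the attribute kind is
    guessed from the level alphabet.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path, specs, frozenset(missing_codes))
    if format == "ped_map":
        return _read_ped_map(path, frozenset(missing_codes))
    raise DatasetError(f"unknown format {format!r}")


def _read_tsv(
    path: Path, specs: Sequence[AttributeSpec] | None, missing: frozenset[str]
) -> CaseControlDataset:
    lines = path.read_text().splitlines()
    if not lines:
        raise DatasetError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3:
        raise DatasetError(f"{path}: header needs id, phenotype and >=1 attribute")
    attr_names = header[2:]
    n_cols = len(header)

    ids: list[str] = []
    pheno: list[int] = []
    raw: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_cols:
            raise DatasetError(
                f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        ids.append(fields[0])
        if fields[1] not in ("0", "1"):
            raise DatasetError(
                f"{path}: line {lineno}: phenotype must be 0/1, got {fields[1]!r}"
            )
        pheno.append(int(fields[1]))
        raw.append(fields[2:])

    columns = list(zip(*raw)) if raw else [() for _ in attr_names]
    if specs is None:
        specs = []
        for name, col in zip(attr_names, columns):
            levels = tuple(sorted({v for v in col if v not in missing}))
            if not (2 <= len(levels) <= 4):
                raise DatasetError(
                    f"attribute {name}: found {len(levels)} distinct levels, need 2-4"
                )
            specs.append(AttributeSpec(name, _infer_kind(levels), levels))
    else:
        specs = list(specs)
        if [s.name for s in specs] != attr_names:
            raise DatasetError("provided specs do not match header attribute names")

    values = np.full((len(ids), len(specs)), MISSING, dtype=np.int16)
    for j, (spec, col) in enumerate(zip(specs, columns)):
        index = {lvl: i for i, lvl in enumerate(spec.levels)}
        for i, v in enumerate(col):
            if v in missing:
                continue
            if v not in index:
                raise DatasetError(
                    f"attribute {spec.name}: unknown level code {v!r}"
                )
            values[i, j] = index[v]
    return CaseControlDataset(ids, np.array(pheno), values, specs)


def _read_ped_map(ped_path: Path, missing: frozenset[str]) -> CaseControlDataset:
    """PLINK text pedigree: 6 leading columns then two alleles per marker.

    Phenotype column uses the PLINK convention 2=case, 1=control.  Allele
    '0' marks a missing call.  Genotypes collapse to (major hom, het, minor
    hom) with the major allele determined from the sample frequency.
    """
    if ped_path.suffix == ".ped":
        map_path = ped_path.with_suffix(".map")
    else:
        map_path = Path(str(ped_path) + ".map")
        ped_path = Path(str(ped_path) + ".ped")
    marker_names = [ln.split()[1] for ln in map_path.read_text().splitlines() if ln.strip()]
    m = len(marker_names)

    ids, pheno, allele_rows = [], [], []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m:
            raise DatasetError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, got {len(f)}"
            )
        ids.append(f"{f[0]}_{f[1]}")
        if f[5] not in ("1", "2"):
            raise DatasetError(
                f"{ped_path}: line {lineno}: phenotype must be 1/2, got {f[5]!r}"
            )
        pheno.append(int(f[5]) - 1)
        allele_rows.append(f[6:])

    n = len(ids)
    values = np.full((n, m), MISSING, dtype=np.int16)
    specs = []
    for j in range(m):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        observed = [a for a in a1 + a2 if a != "0"]
        if not observed:
            raise DatasetError(f"marker {marker_names[j]}: no called genotypes")
        alleles = sorted(set(observed))
        if len(alleles) > 2:
            raise DatasetError(f"marker {marker_names[j]}: more than two alleles")
        if len(alleles) == 1:
            alleles = alleles * 2  # monomorphic: treat as major/major
        counts = {a: observed.count(a) for a in set(observed)}
        major = max(sorted(counts), key=lambda a: counts[a])
        minor = [a for a in alleles if a != major]
        minor = minor[0] if minor else major
        het = "".join(sorted((major, minor)))
        levels = (major + major, het, minor + minor)
        specs.append(AttributeSpec(marker_names[j], GENOTYPE, levels))
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            n_minor = (a1[i] == minor) + (a2[i] == minor) if minor != major else 0
            values[i, j] = n_minor
    return CaseControlDataset(ids, np.array(pheno), values, specs)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def call_rate_filter(
    ds: CaseControlDataset, min_rate: float
) -> tuple[CaseControlDataset, dict]:
    """Drop attributes whose non-missing fraction is below ``min_rate``.

    Returns the filtered dataset and a report dict with per-attribute call
    rates and the names dropped.  Survivor order is preserved.
    """
    if not (0 < min_rate <= 1):
        raise DatasetError("min_rate must be in (0, 1]")
    rates = {s.name: ds.call_rate(j) for j, s in enumerate(ds.specs)}
    keep = [j for j, s in enumerate(ds.specs) if rates[s.name] >= min_rate]
    dropped = [s.name for j, s in enumerate(ds.specs) if j not in set(keep)]
    if not keep:
        raise DatasetError("call-rate filter removed every attribute")
    out = ds.select_attributes(keep) if dropped else ds
    return out, {"call_rates": rates, "dropped_attributes": dropped, "min_rate": min_rate}


def listwise_delete(
    ds: CaseControlDataset, attributes: Sequence[int] | None = None
) -> tuple[CaseControlDataset, list[str]]:
    """Remove subjects missing any value among the chosen attribute columns."""
    cols = list(range(ds.n_attributes)) if attributes is None else list(attributes)
    complete = (ds.values[:, cols] != MISSING).all(axis=1)
    removed = [sid for sid, ok in zip(ds.subject_ids, complete) if not ok]
    if not complete.any():
        raise DatasetError("listwise deletion removed every subject")
    out = ds.subset_subjects(np.flatnonzero(complete)) if removed else ds
    return out, removed


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    p: float
    monomorphic: bool = False


def hwe_test(counts: GenotypeCounts | tuple[int, int, int]) -> HweResult:
    """Pearson 1-df chi-square of genotype counts against Hardy-Weinberg
    expectations at the sample allele frequency (no continuity correction).

    A monomorphic SNP returns chi_square 0, p 1 with a warning flag.
    """
    if isinstance(counts, tuple):
        counts = GenotypeCounts(*counts)
    n = counts.n
    if n < 1:
        raise DatasetError("need at least one genotyped subject")
    p_major = (2 * counts.n_aa_major + counts.n_het) / (2 * n)
    if p_major in (0.0, 1.0):
        return HweResult(0.0, 1.0, monomorphic=True)
    q = 1.0 - p_major
    expected = np.array([n * p_major**2, 2 * n * p_major * q, n * q**2])
    observed = np.array([counts.n_aa_major, counts.n_het, counts.n_aa_minor], float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def derive_dampness(
    mould: np.ndarray, odor: np.ndarray, stains: np.ndarray
) -> np.ndarray:
    """Home-dampness indicator: OR of three yes/no questionnaire items.

    Inputs are coded 1=yes, 0=no, -1=missing.  Any affirmative answer yields
    1; a missing item is treated as non-informative, so the result is 0 when
    no item is affirmative but at least one was answered; all three missing
    propagates missing.
    """
    items = np.stack([np.asarray(a) for a in (mould, odor, stains)])
    any_yes = (items == 1).any(axis=0)
    all_missing = (items == MISSING).all(axis=0)
    out = np.where(any_yes, 1, 0).astype(np.int16)
    out[all_missing & ~any_yes] = MISSING
    return out


def bmi_quartiles(bmi_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign BMI (kg/m^2) to empirical quartiles Q1-Q4 (codes 0-3).

    Cut-points are the 25/50/75 percentiles of the non-missing values;
    intervals are half-open at the top, so a value exactly on a cut-point
    falls in the lower quartile.  Missing (NaN) propagates as ``MISSING``.
    """
    v = np.asarray(bmi_values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 4 or len(np.unique(v[ok])) < 4:
        raise DatasetError("need at least four distinct non-missing BMI values")
    cuts = np.quantile(v[ok], [0.25, 0.50, 0.75])
    codes = np.full(v.shape, MISSING, dtype=np.int16)
    codes[ok] = np.searchsorted(cuts, v[ok], side="left")
    return codes, cuts


BMI_LEVELS = ("Q1", "Q2", "Q3", "Q4")


def run_qc(
    ds: CaseControlDataset,
    min_call_rate: float = 0.98,
    attributes: Sequence[int] | None = None,
) -> tuple[CaseControlDataset, dict]:
    """Standard QC sequence: attribute call-rate filter first, then listwise
    deletion of incomplete subjects; HWE statistics on three-level SNPs.

    Returns the analysis-ready dataset and a JSON-serialisable report.
    """
    filtered, crf = call_rate_filter(ds, min_call_rate)
    if attributes is not None:
        names = [ds.specs[j].name for j in attributes]
        cols = [filtered.column(n) for n in names if n in filtered.attribute_names]
    else:
        cols = None
    clean, removed = listwise_delete(filtered, cols)
    hwe: dict[str, dict] = {}
    for j, spec in enumerate(clean.specs):
        if spec.kind == GENOTYPE and spec.n_levels == 3:
            res = hwe_test(clean.genotype_counts(j))
            hwe[spec.name] = {
                "chi_square": res.chi_square,
                "p": res.p,
                "monomorphic": res.monomorphic,
            }
    report = {
        **crf,
        "subjects_removed": removed,
        "n_subjects_analysed": clean.n_subjects,
        "n_cases": clean.n_cases,
        "n_controls": clean.n_controls,
        "hwe": hwe,
    }
    return clean, report


def write_qc_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_dataset_tsv(ds: CaseControlDataset, path: str | Path) -> None:
    """Emit the standard TSV format consumed by :func:`read_dataset`."""
    lines = ["\t".join(["subject_id", "phenotype", *ds.attribute_names])]
    for i in range(ds.n_subjects):
        row = [ds.subject_ids[i], str(int(ds.phenotype[i]))]
        for j, spec in enumerate(ds.specs):
            code = ds.values[i, j]
            row.append("NA" if code == MISSING else spec.levels[code])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
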