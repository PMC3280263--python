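"""Synthetic case-control data with planted interaction structure.

The generator draws attribute vectors from an independent-attribute
population model (Hardy-Weinberg genotypes at specified minor allele
frequencies, Bernoulli exposures, uniform quartiles), assigns case status
from a penetrance table over the *involved* attributes, and rejection-samples
until the target case and control counts are filled — exact for any
penetrance table at the desk scales used here.

``study_emulator`` reproduces the structure of a childhood-asthma
case-control panel: 17 SNP attributes at published minor allele frequencies
(two of them deletion polymorphisms coded present/null), 9 environmental
attributes, and 235 cases / 1,075 controls, with a configurable planted
three-SNP interaction and a planted exposure-pair interaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import ENVIRONMENT, GENOTYPE, AttributeSpec, CaseControlDataset
from .entropy import entropy


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationAttribute:
    """An attribute spec plus its population level distribution."""

    spec: AttributeSpec
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != self.spec.n_levels:
            raise SimulationError(f"{self.spec.name}: probs/levels length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
            raise SimulationError(f"{self.spec.name}: invalid level distribution")


def snp_attribute(name: str, maf: float) -> PopulationAttribute:
    """Three-level SNP under Hardy-Weinberg equilibrium at the given MAF."""
    if not (0 < maf <= 0.5):
        raise SimulationError("MAF must be in (0, 0.5]")
    q = maf
    probs = ((1 - q) ** 2, 2 * q * (1 - q), q**2)
    return PopulationAttribute(
        AttributeSpec(name, GENOTYPE, ("AA", "Aa", "aa")), probs
    )


def deletion_attribute(name: str, null_freq: float = 0.5) -> PopulationAttribute:
    """Binary present/null deletion polymorphism (e.g. GSTT1, GSTM1)."""
    return PopulationAttribute(
        AttributeSpec(name, GENOTYPE, ("present", "null")),
        (1 - null_freq, null_freq),
    )


def binary_exposure(name: str, prevalence: float = 0.3) -> PopulationAttribute:
    return PopulationAttribute(
        AttributeSpec(name, ENVIRONMENT, ("0", "1")), (1 - prevalence, prevalence)
    )


def quartile_attribute(name: str) -> PopulationAttribute:
    return PopulationAttribute(
        AttributeSpec(name, ENVIRONMENT, ("Q1", "Q2", "Q3", "Q4")),
        (0.25, 0.25, 0.25, 0.25),
    )


def simulate_genotypes(n: int, maf: float, seed: int | np.random.Generator) -> np.ndarray:
    """Genotype codes (0, 1, 2) drawn under Hardy-Weinberg at the given MAF."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(3, size=n, p=snp_attribute("_", maf).probs).astype(np.int16)


@dataclass
class PenetranceModel:
    """P(case | joint cell) over the involved attributes' level tuples."""

    attributes: list[PopulationAttribute]
    table: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(a.spec.n_levels for a in self.attributes)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != shape:
            raise SimulationError(
                f"penetrance table shape {self.table.shape} != levels {shape}"
            )
        if (self.table < 0).any() or (self.table > 1).any():
            raise SimulationError("penetrances must lie in [0, 1]")

    def cell_probs(self) -> np.ndarray:
        """Population probability of each joint cell (independent attributes)."""
        probs = np.array(self.attributes[0].probs)
        for a in self.attributes[1:]:
            probs = np.multiply.outer(probs, np.array(a.probs))
        return probs

    def prevalence(self) -> float:
        return float((self.cell_probs() * self.table).sum())

    def marginal_penetrance(self, position: int) -> np.ndarray:
        """P(case | level of one attribute), marginalised over the others."""
        cells = self.cell_probs()
        axes = tuple(i for i in range(cells.ndim) if i != position)
        level_mass = cells.sum(axis=axes)
        return (cells * self.table).sum(axis=axes) / level_mass


def null_penetrance(
    attributes: Sequence[PopulationAttribute], baseline: float
) -> PenetranceModel:
    shape = tuple(a.spec.n_levels for a in attributes)
    return PenetranceModel(list(attributes), np.full(shape, baseline))


def parity_penetrance(
    attributes: Sequence[PopulationAttribute], baseline: float, effect: float
) -> PenetranceModel:
    """Checkerboard model: penetrance baseline+effect where the level-code
    sum is odd, baseline elsewhere (k-way generalisation of XOR)."""
    shape = tuple(a.spec.n_levels for a in attributes)
    table = np.full(shape, baseline)
    for cell in itertools.product(*(range(L) for L in shape)):
        if sum(cell) % 2 == 1:
            table[cell] = baseline + effect
    return PenetranceModel(list(attributes), table)


def xor_penetrance(
    attr_a: PopulationAttribute,
    attr_b: PopulationAttribute,
    baseline: float,
    effect: float,
    require_no_main_effects: bool = True,
) -> PenetranceModel:
    """Two-locus XOR-pattern epistasis with no marginal effects.

    Penetrance is baseline+effect on cells whose level codes have odd sum.
    When each attribute places probability 1/2 on its odd levels (a binary
    attribute at prevalence 0.5, or a Hardy-Weinberg SNP at MAF 0.5, whose
    heterozygote mass is exactly 1/2), both single-locus marginal
    penetrances equal the overall prevalence, i.e. a pure interaction with
    zero main effects.
    """
    if not (0 <= baseline <= 1 and 0 <= baseline + effect <= 1):
        raise SimulationError("baseline and baseline+effect must lie in [0, 1]")
    model = parity_penetrance([attr_a, attr_b], baseline, effect)
    if require_no_main_effects:
        prev = model.prevalence()
        for pos in range(2):
            if np.abs(model.marginal_penetrance(pos) - prev).max() > 1e-9:
                raise SimulationError(
                    "marginal penetrances unequal: XOR construction needs "
                    "probability 1/2 on odd levels (MAF or prevalence 0.5)"
                )
    return model


def carrier_burden_penetrance(
    attributes: Sequence[PopulationAttribute],
    baseline: float,
    effect: float,
    min_carriers: int = 2,
) -> PenetranceModel:
    """Threshold epistasis: risk rises by ``effect`` when at least
    ``min_carriers`` of the loci carry a non-reference level (minor-allele
    carrier for SNPs, exposed/null for binary attributes).

    Joint threshold models of this kind carry positive pairwise interaction
    information about the phenotype: each pair is more informative together
    than its parts.
    """
    shape = tuple(a.spec.n_levels for a in attributes)
    table = np.full(shape, baseline)
    for cell in itertools.product(*(range(L) for L in shape)):
        if sum(1 for v in cell if v >= 1) >= min_carriers:
            table[cell] = baseline + effect
    return PenetranceModel(list(attributes), table)


# ---------------------------------------------------------------------------
# exact population information quantities (for model design and testing)
# ---------------------------------------------------------------------------

def population_mutual_information(
    model: PenetranceModel, positions: Sequence[int]
) -> float:
    """Exact I(attributes at ``positions``; case status) in bits, computed
    from the model's joint distribution (no sampling)."""
    cells = model.cell_probs()
    joint_case = cells * model.table
    joint_ctrl = cells * (1 - model.table)
    axes = tuple(i for i in range(cells.ndim) if i not in positions)
    pa_case = joint_case.sum(axis=axes).ravel()
    pa_ctrl = joint_ctrl.sum(axis=axes).ravel()
    p_joint = np.concatenate([pa_case, pa_ctrl])
    p_attr = pa_case + pa_ctrl
    prev = joint_case.sum()
    h_c = entropy((prev, 1 - prev))
    h_a = entropy(p_attr[p_attr >= 0] / p_attr.sum())
    h_ac = entropy(p_joint / p_joint.sum())
    return h_a + h_c - h_ac


def population_interaction_information(
    model: PenetranceModel, pos_a: int, pos_b: int
) -> float:
    """Exact II(A;B;case status) in bits for two involved attributes."""
    return (
        population_mutual_information(model, (pos_a, pos_b))
        - population_mutual_information(model, (pos_a,))
        - population_mutual_information(model, (pos_b,))
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class SimulationRecipe:
    """Target class counts, penetrance model, noise attributes, and seed."""

    n_cases: int
    n_controls: int
    model: PenetranceModel
    noise: list[PopulationAttribute] = field(default_factory=list)
    seed: int = 0
    column_order: list[str] | None = None
    max_batches: int = 4000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError("need at least one case and one control")


def simulate_case_control(recipe: SimulationRecipe) -> CaseControlDataset:
    """Draw a dataset with exactly the target case/control counts.

    Subjects are sampled from the population model, case status is Bernoulli
    with the cell penetrance, and sampling continues until both classes are
    filled (rejection sampling; surplus subjects of a filled class are
    discarded in draw order).  Noise attributes are drawn independently of
    phenotype.  Byte-identical output for a fixed recipe.
    """
    rng = np.random.default_rng(recipe.seed)
    model = recipe.model
    n_involved = len(model.attributes)
    flat_pen = model.table.ravel()
    strides = np.ones(n_involved, dtype=np.int64)
    for i in range(n_involved - 2, -1, -1):
        strides[i] = strides[i + 1] * model.attributes[i + 1].spec.n_levels

    need_cases, need_controls = recipe.n_cases, recipe.n_controls
    got_vals: list[np.ndarray] = []
    got_pheno: list[np.ndarray] = []
    n_cases = n_controls = 0
    batch = max(256, 2 * (need_cases + need_controls))
    for _ in range(recipe.max_batches):
        cols = [
            rng.choice(a.spec.n_levels, size=batch, p=a.probs)
            for a in model.attributes
        ]
        vals = np.column_stack(cols).astype(np.int16)
        codes = (vals.astype(np.int64) * strides).sum(axis=1)
        status = (rng.random(batch) < flat_pen[codes]).astype(np.int8)
        got_vals.append(vals)
        got_pheno.append(status)
        n_cases += int(status.sum())
        n_controls += int((status == 0).sum())
        if n_cases >= need_cases and n_controls >= need_controls:
            break
    else:
        raise SimulationError(
            "sampling cap reached before both classes filled; penetrance "
            "model leaves a class essentially empty"
        )

    vals = np.concatenate(got_vals)
    pheno = np.concatenate(got_pheno)
    case_rows = np.flatnonzero(pheno == 1)[:need_cases]
    ctrl_rows = np.flatnonzero(pheno == 0)[:need_controls]
    keep = np.sort(np.concatenate([case_rows, ctrl_rows]))
    vals, pheno = vals[keep], pheno[keep]
    n = len(keep)

    specs = [a.spec for a in model.attributes]
    columns = [vals[:, i] for i in range(n_involved)]
    for attr in recipe.noise:
        columns.append(
            rng.choice(attr.spec.n_levels, size=n, p=attr.probs).astype(np.int16)
        )
        specs.append(attr.spec)

    values = np.column_stack(columns).astype(np.int16)
    if recipe.column_order is not None:
        name_to_col = {s.name: j for j, s in enumerate(specs)}
        order = [name_to_col[nm] for nm in recipe.column_order]
        values = values[:, order]
        specs = [specs[j] for j in order]

    ids = [f"S{i + 1:05d}" for i in range(n)]
    return CaseControlDataset(ids, pheno, values, specs)


# ---------------------------------------------------------------------------
# study-structure emulator
# ---------------------------------------------------------------------------

#: SNP panel (name, minor allele frequency) for the emulated study structure
STUDY_SNPS: tuple[tuple[str, float], ...] = (
    ("TNFa_rs1800629", 0.116),
    ("IL4_rs2243250", 0.179),
    ("IL13_rs20541", 0.313),
    ("IL13_rs848", 0.324),
    ("IL13_rs1800925", 0.142),
    ("IL4Ra_rs1805010", 0.493),
    ("STAT6_rs324011", 0.244),
    ("INSIG2_rs7566605", 0.399),
    ("PPARg_rs1801282", 0.045),
    ("ADRB2_rs1042713", 0.415),
    ("ADRB2_rs1042714", 0.096),
    ("ADRB3_rs4994", 0.153),
    ("EPHX1ex4_rs2234922", 0.137),
    ("EPHX1ex3_rs1051740", 0.471),
    ("GSTP1_rs1695", 0.178),
)

#: deletion polymorphisms printed without genotype frequencies: present/null
STUDY_DELETIONS: tuple[str, ...] = ("GSTT1", "GSTM1")

STUDY_EXPOSURES: tuple[str, ...] = (
    "in_utero_ETS",
    "ETS",
    "preterm_birth",
    "pets",
    "cockroaches",
    "incense_burning",
    "carpet",
    "dampness",
)

#: planted three-SNP interaction (antioxidative / inflammatory / obesity axis)
PLANTED_TRIPLE = ("GSTP1_rs1695", "IL4Ra_rs1805010", "INSIG2_rs7566605")
PLANTED_EXPOSURE_PAIR = ("preterm_birth", "dampness")


def study_attributes(
    exposure_prevalence: float = 0.3, null_genotype_freq: float = 0.5
) -> list[PopulationAttribute]:
    """The 26-attribute population panel: 17 SNPs then 9 exposures."""
    attrs = [snp_attribute(name, maf) for name, maf in STUDY_SNPS]
    attrs += [deletion_attribute(name, null_genotype_freq) for name in STUDY_DELETIONS]
    attrs += [binary_exposure(name, exposure_prevalence) for name in STUDY_EXPOSURES]
    attrs.append(quartile_attribute("BMI_quartile"))
    return attrs


def study_emulator(
    seed: int = 0,
    n_cases: int = 235,
    n_controls: int = 1075,
    baseline: float = 0.10,
    snp_effect: float = 0.50,
    env_effect: float = 0.15,
    exposure_prevalence: float = 0.3,
    null_genotype_freq: float = 0.5,
) -> CaseControlDataset:
    """Emulated study dataset: 26 attributes, 235/1,075 class counts.

    A three-SNP joint-carrier interaction is planted among the triple
    GSTP1/IL4Ra/INSIG2 (risk +``snp_effect`` when all three loci carry at
    least one minor allele — at these MAFs the exact pairwise interaction
    information among the triple is positive for every pair) and an
    exposure-pair interaction between preterm birth and home dampness (risk
    +``env_effect`` when both are present).  Setting both effects to 0
    yields a pure-noise panel with the same marginal structure.
    """
    panel = study_attributes(exposure_prevalence, null_genotype_freq)
    by_name = {a.spec.name: a for a in panel}
    involved_names = list(PLANTED_TRIPLE) + list(PLANTED_EXPOSURE_PAIR)
    involved = [by_name[nm] for nm in involved_names]

    shape = tuple(a.spec.n_levels for a in involved)
    table = np.full(shape, baseline)
    for cell in itertools.product(*(range(L) for L in shape)):
        pen = baseline
        if all(v >= 1 for v in cell[:3]):
            pen += snp_effect
        if cell[3] == 1 and cell[4] == 1:
            pen += env_effect
        table[cell] = min(pen, 1.0)
    model = PenetranceModel(involved, table)

    noise = [a for a in panel if a.spec.name not in set(involved_names)]
    recipe = SimulationRecipe(
        n_cases=n_cases,
        n_controls=n_controls,
        model=model,
        noise=noise,
        seed=seed,
        column_order=[a.spec.name for a in panel],
    )
    return simulate_case_control(recipe)
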