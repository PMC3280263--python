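"""Entropy-based synergy analysis.

Interaction information between two attributes A, B and the phenotype C,

    II(A;B;C) = I(A,B;C) - I(A;C) - I(B;C),

is positive when the pair carries more information about case status jointly
than the sum of its parts (synergy, e.g. epistasis) and negative when the
attributes are redundant.  All quantities use the plug-in (maximum
likelihood) estimator from empirical frequencies, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import CaseControlDataset
from .mdr import FactorCombination, joint_codes

#: |interaction information| below this is labeled additive
ADDITIVE_TOLERANCE = 1e-3


def entropy(distribution: Sequence[float]) -> float:
    """Shannon entropy -sum p log2 p of a finite distribution, in bits."""
    p = np.asarray(distribution, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _counts_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    nz = counts[counts > 0] / n
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(
    ds: CaseControlDataset, attributes: tuple[int, ...] | int
) -> float:
    """Plug-in I(joint attribute variable; phenotype) = H(A)+H(C)-H(A,C)."""
    if isinstance(attributes, int):
        attributes = (attributes,)
    if ds.n_subjects == 0:
        raise ValueError("empty dataset")
    codes, size = joint_codes(ds, FactorCombination(tuple(sorted(attributes))))
    joint = np.bincount(codes * 2 + ds.phenotype, minlength=size * 2)
    h_joint = _counts_entropy(joint)
    h_attr = _counts_entropy(np.bincount(codes, minlength=size))
    h_pheno = _counts_entropy(np.bincount(ds.phenotype, minlength=2))
    return h_attr + h_pheno - h_joint


@dataclass(frozen=True)
class InformationDecomposition:
    """Pairwise information decomposition about the phenotype, in bits."""

    i_a: float
    i_b: float
    i_ab: float
    interaction_info: float

    @property
    def label(self) -> str:
        if self.interaction_info > ADDITIVE_TOLERANCE:
            return "synergistic"
        if self.interaction_info < -ADDITIVE_TOLERANCE:
            return "redundant"
        return "additive"


def interaction_information(
    ds: CaseControlDataset, attr_a: int, attr_b: int
) -> InformationDecomposition:
    """II(A;B;phenotype) = I(A,B;C) - I(A;C) - I(B;C) (symmetric in A, B)."""
    i_a = mutual_information(ds, attr_a)
    i_b = mutual_information(ds, attr_b)
    i_ab = mutual_information(ds, (attr_a, attr_b))
    return InformationDecomposition(i_a, i_b, i_ab, i_ab - i_a - i_b)


def pairwise_matrix(
    ds: CaseControlDataset, attributes: Sequence[int] | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise interaction information (diagonal is the
    single-attribute mutual information with the phenotype)."""
    attrs = list(range(ds.n_attributes)) if attributes is None else list(attributes)
    k = len(attrs)
    mat = np.zeros((k, k))
    singles = [mutual_information(ds, a) for a in attrs]
    for i in range(k):
        mat[i, i] = singles[i]
        for j in range(i + 1, k):
            i_ab = mutual_information(ds, (attrs[i], attrs[j]))
            mat[i, j] = mat[j, i] = i_ab - singles[i] - singles[j]
    return mat


def edge_list(
    ds: CaseControlDataset, attributes: Sequence[int] | None = None
) -> list[tuple[str, str, float]]:
    """Pairwise interaction-information edges for graph visualisation."""
    attrs = list(range(ds.n_attributes)) if attributes is None else list(attributes)
    mat = pairwise_matrix(ds, attrs)
    names = [ds.specs[a].name for a in attrs]
    return [
        (names[i], names[j], float(mat[i, j]))
        for i in range(len(attrs))
        for j in range(i + 1, len(attrs))
    ]
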