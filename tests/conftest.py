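import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mdrkit.dataset import GENOTYPE, AttributeSpec, CaseControlDataset


def make_dataset(values, pheno, kinds=None, n_levels=None):
    """Build a CaseControlDataset from raw integer codes."""
    values = np.asarray(values, dtype=np.int16)
    pheno = np.asarray(pheno, dtype=np.int8)
    n, p = values.shape
    specs = []
    for j in range(p):
        L = (
            n_levels[j]
            if n_levels is not None
            else max(2, int(values[:, j].max()) + 1)
        )
        kind = kinds[j] if kinds is not None else GENOTYPE
        labels = tuple(f"L{i}" for i in range(L))
        specs.append(AttributeSpec(f"attr{j}", kind, labels))
    ids = [f"s{i}" for i in range(n)]
    return CaseControlDataset(ids, pheno, values, specs)


@pytest.fixture
def random_small_dataset():
    """Factory for random small complete datasets (oracle comparisons)."""

    def factory(rng, max_subjects=30, max_attributes=3, min_per_class=3):
        while True:
            n = int(rng.integers(2 * min_per_class + 2, max_subjects + 1))
            p = int(rng.integers(1, max_attributes + 1))
            levels = [int(rng.integers(2, 4)) for _ in range(p)]
            values = np.column_stack(
                [rng.integers(0, L, size=n) for L in levels]
            ).astype(np.int16)
            pheno = (rng.random(n) < 0.5).astype(np.int8)
            if min_per_class <= pheno.sum() <= n - min_per_class:
                return make_dataset(values, pheno, n_levels=levels)

    return factory


@pytest.fixture
def xor_fixture():
    """Deterministic XOR dataset: phenotype = A xor B, balanced cells."""
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            for _ in range(5):
                rows.append((a, b, a ^ b))
    values = np.array([(a, b) for a, b, _ in rows], dtype=np.int16)
    pheno = np.array([c for _, _, c in rows], dtype=np.int8)
    return make_dataset(values, pheno, n_levels=[2, 2])
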