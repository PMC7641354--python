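import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from regfire import (
    EqtlSimSpec,
    GenotypeMatrix,
    HapSimSpec,
    HaplotypeSet,
    VariantRecord,
    simulate_eqtl_dataset,
    simulate_haplotypes,
)


@pytest.fixture(scope="session")
def eqtl_panel():
    """A mid-size panel with a planted cis effect, shared across tests."""
    spec = EqtlSimSpec(n_snps=40, beta_cis=0.5, seed=7)
    return simulate_eqtl_dataset(spec)


@pytest.fixture(scope="session")
def neutral_haps():
    """One neutral Wright-Fisher replicate at default scale."""
    return simulate_haplotypes(HapSimSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_haplotype_set(rng, n=8, s=12, length=10_000) -> HaplotypeSet:
    """Small random haplotype fixture with segregating sites only."""
    while True:
        H = (rng.random((n, s)) < rng.uniform(0.2, 0.8, size=s)).astype(np.uint8)
        counts = H.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        if keep.sum() >= 4:
            H = H[:, keep]
            break
    positions = np.sort(rng.choice(length, size=H.shape[1], replace=False))
    return HaplotypeSet(
        haplotypes=H,
        positions=positions,
        population=np.array(["p"] * n, dtype=object),
    )


def toy_genotypes(dosages, pops, positions=None, chrom="chr9") -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(m)]
    variants = [
        VariantRecord(chrom, positions[i], f"v{i}", "A", "G", "A") for i in range(m)
    ]
    return GenotypeMatrix(
        variants,
        dosages,
        [f"s{j}" for j in range(n)],
        np.asarray(pops, dtype=object),
    )
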