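import numpy as np
import pandas as pd
import pytest

from partprs.containers import GenotypeMatrix
from partprs.synthetic import EffectSpec, GenomeSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    """Compact genome: 3 chromosomes x 8 blocks x 6 SNPs, high-LD region
    spanning blocks 2-5 of chromosome 2 (hosts two set genes)."""
    return GenomeSpec(
        n_chromosomes=3,
        chrom_length_bp=8_000_000,
        block_length_bp=1_000_000,
        snps_per_block=6,
        special_region=("2", 2_000_000, 6_000_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    return simulate_cohort(small_genome, EffectSpec(), n_samples=1200, seed=11)


def make_genotypes(dosages: np.ndarray, chrom=None, pos=None, ref="A", alt="G"):
    """Hand-built GenotypeMatrix for fixture-level tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    return GenotypeMatrix(np.array([f"P{i}" for i in range(n)]), variants, dosages)
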