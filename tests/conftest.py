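import numpy as np
import pandas as pd
import pytest

from cvhmr.containers import GenotypeMatrix
from cvhmr.simulate import TwoSampleSimConfig, simulate_summary_stats
from cvhmr.twosample import HarmonizedPairs, harmonize


@pytest.fixture
def small_genotypes():
    """Deterministic 200 x 8 genotype matrix with realistic MAFs."""
    rng = np.random.default_rng(42)
    mafs = np.array([0.1, 0.2, 0.3, 0.4, 0.15, 0.25, 0.35, 0.45])
    dosage = rng.binomial(2, mafs, size=(200, 8)).astype(float)
    snps = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(8)],
        "chrom": [1, 1, 1, 2, 2, 2, 3, 3],
        "pos": [1000, 2000, 3000, 1000, 2000, 3000, 1000, 2000],
        "a1": list("AGACAGAC"),
        "a2": list("GTCGGTCG"),
        "maf": mafs,
    })
    return GenotypeMatrix(dosage=dosage, snps=snps)


@pytest.fixture
def clean_pairs():
    """Thirty harmonized SNP pairs simulated with theta=-0.5, no pleiotropy."""
    exposure, outcome = simulate_summary_stats(
        TwoSampleSimConfig(n_snps=30, theta=-0.5, seed=314)
    )
    return harmonize(exposure, outcome)


def make_pairs(bx, se_x, by, se_y):
    return HarmonizedPairs.from_arrays(bx, se_x, by, se_y)
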