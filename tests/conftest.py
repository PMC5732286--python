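import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from sweepkit.types import GenotypeMatrix, HaplotypeSet, MarkerMap, SampleTable


@pytest.fixture
def small_map():
    """5 SNPs on chromosomes 1 and 2, sorted."""
    return MarkerMap(
        np.array([f"s{i}" for i in range(5)], dtype=object),
        np.array(["1", "1", "1", "2", "2"], dtype=object),
        np.array([100, 200, 300, 100, 250]),
        np.array(list("AACAG"), dtype=object),
        np.array(list("GGTGC"), dtype=object),
    )


@pytest.fixture
def two_pop_samples():
    return SampleTable(
        np.array([f"i{i}" for i in range(6)], dtype=object),
        np.array(["pA", "pA", "pA", "pB", "pB", "pB"], dtype=object),
        np.array(["grp1", "grp1", "grp1", "grp2", "grp2", "grp2"], dtype=object),
    )


def random_genotypes(rng, n_samples, n_snps, miss_rate=0.0):
    vals = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if miss_rate:
        vals[rng.random(vals.shape) < miss_rate] = -1
    return GenotypeMatrix(vals)


def random_haplotypes(rng, n_samples, n_snps, p=0.5):
    return HaplotypeSet((rng.random((2 * n_samples, n_snps)) < p)
                        .astype(np.int8))


def uniform_map(n_snps, chrom="1", step=1000, start=1000):
    return MarkerMap(
        np.array([f"m{i}" for i in range(n_snps)], dtype=object),
        np.full(n_snps, chrom, dtype=object),
        start + step * np.arange(n_snps),
    )
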