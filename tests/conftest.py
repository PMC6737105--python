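import numpy as np
import pandas as pd
import pytest

from popgenpipe import GenotypeMatrix, SimConfig, simulate_wf_population


def make_matrix(calls, positions=None, chrom="chr1", populations=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
            "pos": positions,
            "id": [f"snp{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )
    pops = populations if populations is not None else ["pop"] * n
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(n)], "population": pops})
    return GenotypeMatrix(calls, variants, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wf4():
    """Four-chromosome Wright-Fisher dataset (enough chromosomes for the
    contemporary LD-Ne chromosome jackknife)."""
    cfg = SimConfig(
        n_individuals=30,
        n_chromosomes=4,
        chrom_length_bp=10_000_000,
        marker_density=10,
        ne_trajectory=[(0, 60)],
        n_generations=60,
        seed=17,
    )
    return simulate_wf_population(cfg)


@pytest.fixture(scope="session")
def small_wf():
    """A small Wright-Fisher dataset reused across read-only tests."""
    cfg = SimConfig(
        n_individuals=30,
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        marker_density=10,
        ne_trajectory=[(0, 60)],
        n_generations=60,
        seed=7,
    )
    return simulate_wf_population(cfg)
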