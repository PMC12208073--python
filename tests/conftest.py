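import numpy as np
import pytest

from snacs.core_io import GenotypeMatrix, HashCounts, SnacsConfig
from snacs.synthesis import SimConfig, simulate_multiplexed


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """10 cells x 10 SNPs with hand-placed missingness.

    SNP s5 is missing in 5/10 cells (fraction 0.5 > 0.4 -> dropped);
    cell c9 is missing 5/9 of the SNPs that survive the SNP filter
    (0.556 > 0.4 -> dropped).
    """
    rng = np.random.default_rng(11)
    values = rng.integers(0, 2, size=(10, 10)).astype(float)
    values[:5, 5] = np.nan            # s5 missing in cells c0..c4
    values[9, [0, 1, 2, 3, 4]] = np.nan   # c9 missing 5 retained SNPs
    return GenotypeMatrix([f"c{i}" for i in range(10)],
                          [f"s{j}" for j in range(10)], values)


@pytest.fixture
def small_experiment():
    """Two-sample synthetic experiment small enough for fast end-to-end runs."""
    return simulate_multiplexed(SimConfig(S=2, C=600, p=0.10, seed=123))


@pytest.fixture
def fast_cfg() -> SnacsConfig:
    """Defaults with a fixed seed; thresholds untouched."""
    return SnacsConfig(seed=123)
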