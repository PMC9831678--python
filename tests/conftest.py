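import numpy as np
import pandas as pd
import pytest

from oralmicro import AbundanceTable, MicrobiomeSimSpec, PlantedDifferential


@pytest.fixture
def small_counts() -> AbundanceTable:
    """3 taxa x 2 samples with column sums 40 and 10."""
    return AbundanceTable(pd.DataFrame(
        [[10, 5], [0, 5], [30, 0]],
        index=["Fusobacterium", "Prevotella", "Streptococcus"],
        columns=["s1", "s2"]))


@pytest.fixture
def random_counts() -> AbundanceTable:
    rng = np.random.default_rng(42)
    data = rng.integers(0, 200, size=(5, 8))
    data[0] += 1  # keep every column non-zero
    return AbundanceTable(pd.DataFrame(
        data, index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(8)]))


@pytest.fixture
def paired_study():
    """Default simulated study with one 3-fold planted genus, seed 0."""
    spec = MicrobiomeSimSpec(
        n_patients=10,
        planted_differentials=[PlantedDifferential(
            "Fusobacterium", "outer_tumor", "adjacent_normal", 3.0)],
        seed=0)
    from oralmicro import simulate_paired_study

    return simulate_paired_study(spec)
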