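import numpy as np
import pytest

from hsmscan.datamodel import GenomicWindowGrid, MethylationMatrix, Region
from hsmscan.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def small_matrix():
    """3 samples x 6 windows on chr16, window 3 masked, no missing data."""
    grid = GenomicWindowGrid(
        "chr16", 1001, 6, 100, mask=np.array([0, 0, 1, 0, 0, 0], dtype=bool)
    )
    rng = np.random.default_rng(42)
    scores = rng.random((3, 6))
    scores[:, 2] = np.nan  # masked column carries no data
    return MethylationMatrix(grid, ["a", "b", "c"], scores)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study conditions (seeded), shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


def full_block(matrix) -> Region:
    """Region spanning every unmasked window of a matrix's grid."""
    g = matrix.grid
    return Region(g.chrom, g.start, g.window_to_coords(g.n_unmasked).end, "block")
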