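import numpy as np
import pytest

from melissa import (
    MethylomeDataset,
    RegionAnnotation,
    RegionCellData,
    SyntheticConfig,
    create_basis,
    simulate_dataset,
)


def make_dataset(blocks, n_regions=None):
    """Build a MethylomeDataset from {(cell, region): (positions, states)}."""
    cells = sorted({c for c, _ in blocks})
    region_ids = sorted({r for _, r in blocks})
    if n_regions is not None:
        region_ids = [f"r{j}" for j in range(n_regions)]
    regions = [
        RegionAnnotation(region_id=r, chromosome="chr1", start=1 + 10_000 * j,
                         end=5_001 + 10_000 * j)
        for j, r in enumerate(region_ids)
    ]
    data = {
        key: RegionCellData(np.asarray(p, dtype=float), np.asarray(s))
        for key, (p, s) in blocks.items()
    }
    return MethylomeDataset(cells, regions, data)


@pytest.fixture(scope="session")
def small_sim():
    """A small but well-identified simulated dataset with 3 sub-populations."""
    cfg = SyntheticConfig(
        N=30, M=8, K=3, proportions=(0.4, 0.3, 0.3), dissimilarity=1.0,
        coverage=0.5, cpgs_per_region=30, noise_sd=0.05, seed=11,
    )
    dataset, truth = simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def default_basis():
    return create_basis(4)


@pytest.fixture
def tiny_dataset():
    """N=2 cells, M=1 region, 2-3 CpGs: small enough for brute-force oracles."""
    return make_dataset(
        {
            ("a", "r0"): ([-0.5, 0.5], [1, 1]),
            ("b", "r0"): ([-0.3, 0.2, 0.7], [0, 0, 1]),
        }
    )
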