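"""Simulated single-cell methylomes with known cluster structure.

The generator mirrors the statistical structure of single-cell bisulfite
experiments over annotated regions: K latent sub-populations with fixed
proportions, per-region latent methylation profiles drawn from a small set
of qualitatively distinct prototypes (flat-high, flat-low, rising, falling,
dip), Bernoulli CpG observations through the probit link, Gaussian noise on
the per-CpG success probability (mimicking bisulfite conversion error), and
binomially thinned coverage.  "Cluster dissimilarity" is the fraction of
regions whose prototype is reassigned independently per cluster, so that
clusters share profiles everywhere else.

Defaults: N = 200 cells in K = 4 sub-populations with proportions
40/25/20/15%, M = 100 regions, up to 50 CpGs per region, 40% expected
coverage, noise sd 0.05, and half the regions cluster-discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from .basis import BasisConfig, create_basis, design_matrix
from .region_data import MethylomeDataset, RegionAnnotation, RegionCellData

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_prototypes",
    "simulate_dataset",
    "experiment_grid",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated dataset."""

    N: int = 200
    M: int = 100
    K: int = 4
    proportions: tuple = (0.40, 0.25, 0.20, 0.15)
    dissimilarity: float = 0.5
    coverage: float = 0.4
    cpgs_per_region: int = 50
    noise_sd: float = 0.05
    seed: int = 0
    multinomial_labels: bool = False

    def __post_init__(self) -> None:
        if len(self.proportions) != self.K:
            raise ValueError("proportions must have length K")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("proportions must sum to 1")
        if not 0.0 <= self.dissimilarity <= 1.0:
            raise ValueError("dissimilarity must lie in [0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.N, self.M, self.K, self.cpgs_per_region) < 1:
            raise ValueError("N, M, K, cpgs_per_region must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    labels : (N,) true cluster of each cell.
    profile_assignment : (M, K) prototype index used for region m in
        cluster k; rows of shared regions are constant.
    prototype_weights : (P, D) weight vectors of the latent profiles.
    """

    labels: np.ndarray
    profile_assignment: np.ndarray
    prototype_weights: np.ndarray


_PROTOTYPE_NAMES = ("flat-high", "flat-low", "rising", "falling", "dip")


def _target_eta(name: str, x: np.ndarray) -> np.ndarray:
    if name == "flat-high":
        return np.full_like(x, 2.2)
    if name == "flat-low":
        return np.full_like(x, -2.2)
    if name == "rising":
        return 2.2 * np.tanh(2.0 * x)
    if name == "falling":
        return -2.2 * np.tanh(2.0 * x)
    if name == "dip":
        return 2.2 - 4.5 * np.exp(-4.0 * x**2)
    raise KeyError(name)


def make_prototypes(
    basis: BasisConfig | None = None, n_prototypes: int = 5
) -> np.ndarray:
    """Weight vectors of the built-in latent profiles, in the given basis.

    Each prototype is defined as a target linear predictor over [-1, 1] and
    projected onto the basis by least squares on a fine grid, so any basis
    with at least two RBFs can express the non-flat shapes.  Deterministic.
    """
    basis = basis if basis is not None else create_basis(4)
    if not 2 <= n_prototypes <= len(_PROTOTYPE_NAMES):
        raise ValueError(f"n_prototypes must be in [2, {len(_PROTOTYPE_NAMES)}]")
    if basis.n_rbf < 2:
        raise ValueError("non-flat prototypes need a basis with n_rbf >= 2")
    grid = np.linspace(-1.0, 1.0, 201)
    H = design_matrix(grid, basis)
    weights = []
    for name in _PROTOTYPE_NAMES[:n_prototypes]:
        eta = _target_eta(name, grid)
        w, *_ = np.linalg.lstsq(H, eta, rcond=None)
        weights.append(w)
    return np.asarray(weights)


def _exact_label_counts(config: SyntheticConfig) -> np.ndarray:
    counts = np.array([int(round(p * config.N)) for p in config.proportions])
    counts[int(np.argmax(config.proportions))] += config.N - counts.sum()
    return counts


def simulate_dataset(
    config: SyntheticConfig, basis: BasisConfig | None = None
) -> tuple[MethylomeDataset, SyntheticTruth]:
    """Draw one dataset; identical seed gives identical output.

    Cluster sizes are exact (block assignment of round(p_k N) cells,
    remainder to the largest cluster, then a seeded shuffle over cells)
    unless ``multinomial_labels`` requests sampled sizes.  Per (cell,
    region), the CpG count is Binomial(cpgs_per_region, coverage),
    positions are uniform on [-1, 1], and each state is Bernoulli with
    success probability clamp(Phi(h(x)^T w) + eps, 1e-6, 1 - 1e-6),
    eps ~ N(0, noise_sd^2) drawn per CpG.
    """
    basis = basis if basis is not None else create_basis(4)
    rng = np.random.default_rng(config.seed)
    protos = make_prototypes(basis)
    P = protos.shape[0]

    if config.multinomial_labels:
        labels = rng.choice(config.K, size=config.N, p=np.asarray(config.proportions))
    else:
        counts = _exact_label_counts(config)
        labels = np.repeat(np.arange(config.K), counts)
        labels = labels[rng.permutation(config.N)]

    base = rng.integers(P, size=config.M)
    assignment = np.tile(base[:, None], (1, config.K))
    n_diff = int(np.ceil(config.dissimilarity * config.M))
    if n_diff > 0:
        diff_regions = rng.choice(config.M, size=n_diff, replace=False)
        assignment[diff_regions] = rng.integers(P, size=(n_diff, config.K))

    cells = [f"cell_{i:04d}" for i in range(config.N)]
    regions = [
        RegionAnnotation(
            region_id=f"region_{m:04d}",
            chromosome="chr1",
            start=m * 10_000 + 1,
            end=m * 10_000 + 5_001,
            strand="+",
        )
        for m in range(config.M)
    ]
    data: dict[tuple[str, str], RegionCellData] = {}
    for n, cell in enumerate(cells):
        k = labels[n]
        for m, region in enumerate(regions):
            n_cpg = rng.binomial(config.cpgs_per_region, config.coverage)
            if n_cpg == 0:
                continue
            pos = np.sort(rng.uniform(-1.0, 1.0, size=n_cpg))
            H = design_matrix(pos, basis)
            prob = ndtr(H @ protos[assignment[m, k]])
            if config.noise_sd > 0:
                prob = prob + rng.normal(0.0, config.noise_sd, size=n_cpg)
            prob = np.clip(prob, 1e-6, 1.0 - 1e-6)
            states = (rng.uniform(size=n_cpg) < prob).astype(np.int8)
            data[(cell, region.region_id)] = RegionCellData(pos, states)
    dataset = MethylomeDataset(cells, regions, data)
    truth = SyntheticTruth(
        labels=labels, profile_assignment=assignment, prototype_weights=protos
    )
    return dataset, truth


_GRID_AXES = {"dissimilarity", "N", "coverage"}


def experiment_grid(
    base: SyntheticConfig,
    vary: dict,
    basis: BasisConfig | None = None,
) -> list[tuple[SyntheticConfig, MethylomeDataset, SyntheticTruth]]:
    """Simulate one dataset per value of a single varied axis.

    ``vary`` maps exactly one of ``dissimilarity``, ``N`` or ``coverage``
    to a sequence of values; seeds derive from the base seed plus the grid
    index, so points are independent but reproducible.
    """
    if len(vary) != 1:
        raise ValueError("exactly one axis must be varied")
    (axis, values), = vary.items()
    if axis not in _GRID_AXES:
        raise ValueError(f"axis must be one of {sorted(_GRID_AXES)}")
    out = []
    for i, value in enumerate(values):
        cfg = replace(
            base,
            **{axis: type(getattr(base, axis))(value)},
            seed=int((base.seed + i) % 2**31),
        )
        dataset, truth = simulate_dataset(cfg, basis)
        out.append((cfg, dataset, truth))
    return out
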