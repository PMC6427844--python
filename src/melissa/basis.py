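"""Radial basis function representation of CpG positions.

Every profile model in this package represents the latent methylation
profile of a genomic region as a generalised linear model on basis-expanded
CpG coordinates: eta(x) = w^T h(x), with h(x) a fixed design of an intercept
plus Gaussian radial basis functions on the scaled interval [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BasisConfig", "create_basis", "design_matrix"]


@dataclass(frozen=True)
class BasisConfig:
    """Intercept + RBF basis on [-1, 1].

    Parameters
    ----------
    n_rbf
        Number of radial basis functions (0 gives an intercept-only basis,
        i.e. a constant, rate-like profile model).
    centers
        Strictly increasing RBF centres inside the domain.
    gamma
        Inverse squared length-scale of the Gaussian bumps.
    """

    n_rbf: int
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: float = 1.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if self.n_rbf < 0:
            raise ValueError("n_rbf must be non-negative")
        if centers.size != self.n_rbf:
            raise ValueError("centers length must equal n_rbf")
        if self.n_rbf > 0:
            if not np.all(np.diff(centers) > 0):
                raise ValueError("centers must be strictly increasing")
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")

    @property
    def n_features(self) -> int:
        """Design dimension D = n_rbf + 1 (intercept always included)."""
        return self.n_rbf + 1

    def to_dict(self) -> dict:
        return {
            "n_rbf": int(self.n_rbf),
            "centers": [float(c) for c in self.centers],
            "gamma": float(self.gamma),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisConfig":
        return cls(
            n_rbf=int(d["n_rbf"]),
            centers=np.asarray(d["centers"], dtype=float),
            gamma=float(d["gamma"]),
        )


def create_basis(
    n_rbf: int = 4,
    domain: tuple[float, float] = (-1.0, 1.0),
    gamma: float | None = None,
) -> BasisConfig:
    """Build an evenly spaced RBF basis over ``domain``.

    For ``n_rbf = L`` the centres sit at the L interior points of an
    (L+1)-way equipartition of the domain.  Unless overridden, the width is
    set so adjacent bumps intersect at about half their peak height:
    gamma = 1 / (2 s^2) with s the centre spacing.
    """
    if n_rbf < 0:
        raise ValueError("n_rbf must be non-negative")
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain must be a non-empty interval")
    if n_rbf == 0:
        return BasisConfig(n_rbf=0, centers=np.empty(0), gamma=1.0)
    edges = np.linspace(lo, hi, n_rbf + 2)
    centers = edges[1:-1]
    if gamma is None:
        if n_rbf == 1:
            spacing = (hi - lo) / 2.0
        else:
            spacing = centers[1] - centers[0]
        gamma = 1.0 / (2.0 * spacing**2)
    return BasisConfig(n_rbf=n_rbf, centers=centers, gamma=float(gamma))


def design_matrix(positions: np.ndarray, basis: BasisConfig) -> np.ndarray:
    """Evaluate the basis at scaled positions; rows are h(x)^T.

    Column 0 is the intercept; column j >= 1 is exp(-gamma (x - c_j)^2).
    Positions must lie in [-1, 1]: anything outside signals an upstream
    coordinate-scaling bug and raises.
    """
    x = np.atleast_1d(np.asarray(positions, dtype=float))
    if x.ndim != 1:
        raise ValueError("positions must be one-dimensional")
    if x.size and (x.min() < -1.0 - 1e-12 or x.max() > 1.0 + 1e-12):
        raise ValueError("positions must lie within [-1, 1]; rescale upstream")
    H = np.ones((x.size, basis.n_features))
    if basis.n_rbf > 0:
        diff = x[:, None] - basis.centers[None, :]
        H[:, 1:] = np.exp(-basis.gamma * diff**2)
    return H
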