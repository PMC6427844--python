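"""Gibbs sampling for the methylome mixture model.

Samples the same joint distribution as :mod:`melissa.melissa_vb` using the
full conditionals made conjugate by the probit augmentation.  The sampler
serves as a correctness oracle for the variational engine on small
instances; variational inference remains the practical engine at scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .basis import BasisConfig, create_basis
from .melissa_vb import PriorConfig, _FlatData
from .region_data import MethylomeDataset

__all__ = ["GibbsSamples", "fit_gibbs"]


@dataclass
class GibbsSamples:
    """Thinned post-burn-in draws from the posterior.

    labels : (n_draws, N) cluster assignments per draw.
    weights : (n_draws, M, K, D) profile weight draws.
    pi : (n_draws, K) mixing proportion draws.
    tau : (n_draws, K) precision draws.
    """

    labels: np.ndarray
    weights: np.ndarray
    pi: np.ndarray
    tau: np.ndarray
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    cells: list
    region_ids: list

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    def label_mode(self) -> np.ndarray:
        """Per-cell marginal posterior mode of the cluster assignment.

        Label switching is not corrected here; with well-separated data the
        chain stays within one labelling, and the clustering metrics used
        downstream (ARI) are invariant to relabelling of any single draw.
        """
        K = self.pi.shape[1]
        counts = np.stack(
            [np.sum(self.labels == k, axis=0) for k in range(K)], axis=1
        )
        return np.argmax(counts, axis=1)


def _sample_truncated(
    mu: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw z ~ N(mu, 1) truncated to (0, inf) if y=1 else (-inf, 0]."""
    a = np.where(y == 1, -mu, -np.inf)
    b = np.where(y == 1, np.inf, -mu)
    return truncnorm.rvs(a, b, loc=mu, scale=1.0, random_state=rng)


def fit_gibbs(
    train: MethylomeDataset,
    K: int,
    basis: BasisConfig | None = None,
    priors: PriorConfig | None = None,
    n_iter: int = 3000,
    burn_in: int | None = None,
    thin: int = 5,
    seed: int = 0,
) -> GibbsSamples:
    """Run the collapsed-free Gibbs sampler.

    Conditionals are sampled in order z | rest, w | rest, tau | rest,
    c | rest, pi | rest.  A component with no assigned cells draws its
    weights from the prior (the conjugate update with zero data).  Default
    burn-in is half the chain.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    basis = basis if basis is not None else create_basis(4)
    priors = priors if priors is not None else PriorConfig.broad()
    if burn_in is None:
        burn_in = n_iter // 2
    if not 0 <= burn_in < n_iter:
        raise ValueError("burn_in must lie in [0, n_iter)")
    rng = np.random.default_rng(seed)
    flat = _FlatData(train, basis)
    N, M, D = flat.N, flat.M, flat.D
    eye = np.eye(D)

    # initial state: random labels, neutral weights (a prior draw of w with
    # a near-zero tau saturates the probit and stalls early mixing)
    c = rng.integers(K, size=N)
    tau = np.ones(K)
    w = np.zeros((M, K, D))
    pi = rng.dirichlet(np.full(K, priors.delta0))

    labels_out, weights_out, pi_out, tau_out = [], [], [], []
    for it in range(n_iter):
        # z | rest
        mu = np.einsum("cd,cd->c", flat.H, w[flat.reg_of, c[flat.cell_of]])
        z = _sample_truncated(mu, flat.y, rng)

        # w | rest (conjugate Gaussian given hard assignments)
        onehot = np.zeros((N, K))
        onehot[np.arange(N), c] = 1.0
        prec = np.einsum("nk,nmde->mkde", onehot, flat.G)
        prec += tau[None, :, None, None] * eye[None, None]
        hz = flat.H * z[:, None]
        T = np.stack(
            [flat.bincount_pairs(hz[:, d]) for d in range(D)], axis=-1
        )
        b = np.einsum("nk,nmd->mkd", onehot, T)
        mean = np.linalg.solve(prec, b[..., None])[..., 0]
        chol = np.linalg.cholesky(prec)
        eps = rng.standard_normal((M, K, D))
        w = mean + np.linalg.solve(np.swapaxes(chol, -1, -2), eps[..., None])[..., 0]

        # tau | rest
        shape = priors.alpha0 + 0.5 * M * D
        rate = priors.beta0 + 0.5 * np.einsum("mkd,mkd->k", w, w)
        tau = rng.gamma(shape, 1.0 / rate)

        # c | rest
        logp = np.empty((N, K))
        for k in range(K):
            wk = w[:, k, :][flat.reg_of]
            pk = np.einsum("cd,cd->c", flat.H, wk)
            per_cpg = -0.5 * (z - pk) ** 2
            logp[:, k] = np.bincount(flat.cell_of, weights=per_cpg, minlength=N)
        logp += np.log(pi)[None, :]
        gumbel = rng.gumbel(size=(N, K))
        c = np.argmax(logp + gumbel, axis=1)

        # pi | rest
        counts = np.bincount(c, minlength=K)
        pi = rng.dirichlet(priors.delta0 + counts)

        if it >= burn_in and (it - burn_in) % thin == 0:
            labels_out.append(c.copy())
            weights_out.append(w.copy())
            pi_out.append(pi.copy())
            tau_out.append(tau.copy())

    return GibbsSamples(
        labels=np.asarray(labels_out),
        weights=np.asarray(weights_out),
        pi=np.asarray(pi_out),
        tau=np.asarray(tau_out),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        cells=flat.cells,
        region_ids=flat.region_ids,
    )
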