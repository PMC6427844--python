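"""Variational Bayes for the methylome mixture model.

The model clusters N single cells into K components while smoothing each
cell's methylation profile within every genomic region.  Per region m and
cluster k a weight vector w_mk defines a latent profile Phi(w_mk^T h(x));
binary CpG states arise through the probit augmentation: a latent Gaussian
z ~ N(w^T h(x), 1) whose sign generates the observation.  Priors:

    pi ~ Dirichlet(delta0), c_n | pi ~ Categorical(pi),
    tau_k ~ Gamma(alpha0, beta0), w_mk | tau_k ~ N(0, tau_k^{-1} I).

Inference is mean-field coordinate ascent over q(Z) q(C) q(W) q(pi) q(tau):
each factor update is the exact conditional optimum, so the evidence lower
bound (ELBO) is monotone over sweeps.  Components that receive no
responsibility mass empty out during optimisation, which performs implicit
model selection ("pruning"); the count of occupied components is reported,
never structurally removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln, log_ndtr, logsumexp, xlogy

from .basis import BasisConfig, create_basis, design_matrix
from .region_data import MethylomeDataset

__all__ = [
    "PriorConfig",
    "VariationalState",
    "MelissaFit",
    "fit_vb",
    "cavi_step",
    "elbo",
    "truncated_normal_moments",
    "effective_clusters",
    "save_fit",
    "load_fit",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical priors.

    delta0 is the symmetric per-component Dirichlet concentration; with
    delta0 << 1 ("shrinkage") the prior actively empties redundant
    components, while delta0 ~ 0.5 ("broad") is weakly informative.
    alpha0/beta0 parameterise the Gamma prior on each cluster's weight
    precision tau_k; the defaults favour smooth profiles.
    """

    delta0: float = 0.5
    alpha0: float = 0.5
    beta0: float = 10.0

    def __post_init__(self) -> None:
        if min(self.delta0, self.alpha0, self.beta0) <= 0:
            raise ValueError("all prior hyperparameters must be strictly positive")

    @classmethod
    def broad(cls) -> "PriorConfig":
        return cls(delta0=0.5, alpha0=0.5, beta0=10.0)

    @classmethod
    def shrinkage(cls) -> "PriorConfig":
        return cls(delta0=1e-6, alpha0=0.5, beta0=10.0)

    def to_dict(self) -> dict:
        return {"delta0": self.delta0, "alpha0": self.alpha0, "beta0": self.beta0}


@dataclass
class VariationalState:
    """All mean-field factor parameters.

    r : (N, K) responsibilities q(c_n = k); rows sum to one.
    delta : (K,) Dirichlet posterior over mixing weights.
    lam : (M, K, D) posterior means of the profile weights.
    S : (M, K, D, D) posterior covariances of the profile weights.
    gamma_alpha, gamma_beta : (K,) Gamma posterior over precisions tau_k.
    z_mu, z_mean, z_m2 : per-CpG centre, first and second moment of the
        truncated-Gaussian factor over the augmented variable z (flattened
        in dataset order).
    elbo_trace : ELBO after each completed sweep.
    """

    r: np.ndarray
    delta: np.ndarray
    lam: np.ndarray
    S: np.ndarray
    gamma_alpha: np.ndarray
    gamma_beta: np.ndarray
    z_mu: np.ndarray
    z_mean: np.ndarray
    z_m2: np.ndarray
    elbo_trace: list = field(default_factory=list)

    def copy(self) -> "VariationalState":
        return VariationalState(
            r=self.r.copy(),
            delta=self.delta.copy(),
            lam=self.lam.copy(),
            S=self.S.copy(),
            gamma_alpha=self.gamma_alpha.copy(),
            gamma_beta=self.gamma_beta.copy(),
            z_mu=self.z_mu.copy(),
            z_mean=self.z_mean.copy(),
            z_m2=self.z_m2.copy(),
            elbo_trace=list(self.elbo_trace),
        )


@dataclass
class MelissaFit:
    """Result of a variational fit."""

    state: VariationalState
    basis: BasisConfig
    priors: PriorConfig
    cells: list
    region_ids: list
    K: int
    hard_labels: np.ndarray = None
    effective_K: int = 0
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.hard_labels is None:
            self.hard_labels = np.argmax(self.state.r, axis=1)
        if self.effective_K == 0:
            self.effective_K = effective_clusters(self)

    @property
    def mixing_weights(self) -> np.ndarray:
        """Posterior-mean mixing proportions delta_k / sum_j delta_j."""
        return self.state.delta / self.state.delta.sum()


def truncated_normal_moments(
    mu: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First two moments of a unit-variance Gaussian truncated by sign.

    For y = 1 the support is (0, inf): E[z] = mu + phi(mu)/Phi(mu);
    for y = 0 it is (-inf, 0]: E[z] = mu - phi(mu)/Phi(-mu).  In both
    cases E[z^2] = 1 + mu * E[z].  The Mills ratio is evaluated on the log
    scale, which stays accurate far into the tails (|mu| of tens).
    """
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y)
    sign = np.where(y == 1, 1.0, -1.0)
    # phi(mu)/Phi(sign*mu) computed as exp(log phi - log Phi)
    log_phi = -0.5 * mu**2 - 0.5 * _LOG_2PI
    ratio = np.exp(log_phi - log_ndtr(sign * mu))
    ez = mu + sign * ratio
    ez2 = 1.0 + mu * ez
    return ez, ez2


class _FlatData:
    """Dataset compiled into flat per-CpG arrays for vectorised sweeps."""

    def __init__(self, dataset: MethylomeDataset, basis: BasisConfig) -> None:
        self.cells = list(dataset.cells)
        self.region_ids = list(dataset.region_ids)
        self.N = len(self.cells)
        self.M = len(self.region_ids)
        self.D = basis.n_features
        cidx = {c: i for i, c in enumerate(self.cells)}
        ridx = {r: j for j, r in enumerate(self.region_ids)}
        pos_parts, y_parts, cell_parts, reg_parts = [], [], [], []
        for cell in self.cells:
            for rid in self.region_ids:
                rcd = dataset.get(cell, rid)
                if rcd is None or len(rcd) == 0:
                    continue
                pos_parts.append(rcd.positions)
                y_parts.append(rcd.states)
                cell_parts.append(np.full(len(rcd), cidx[cell], dtype=np.int64))
                reg_parts.append(np.full(len(rcd), ridx[rid], dtype=np.int64))
        if pos_parts:
            positions = np.concatenate(pos_parts)
            self.y = np.concatenate(y_parts).astype(np.int8)
            self.cell_of = np.concatenate(cell_parts)
            self.reg_of = np.concatenate(reg_parts)
        else:  # no observed CpGs: legal for samplers, rejected by fit_vb
            positions = np.empty(0)
            self.y = np.empty(0, dtype=np.int8)
            self.cell_of = np.empty(0, dtype=np.int64)
            self.reg_of = np.empty(0, dtype=np.int64)
        self.H = design_matrix(positions, basis)
        self.C = self.y.size
        self.pair_of = self.cell_of * self.M + self.reg_of
        # per-(cell, region) Gram matrices H^T H, zero where uncovered
        G = np.zeros((self.N * self.M, self.D, self.D))
        HH = self.H[:, :, None] * self.H[:, None, :]
        np.add.at(G, self.pair_of, HH)
        self.G = G.reshape(self.N, self.M, self.D, self.D)
        self.rates = dataset.rate_matrix()

    def bincount_pairs(self, weights: np.ndarray) -> np.ndarray:
        """Sum per-CpG weights into an (N, M) table."""
        return np.bincount(
            self.pair_of, weights=weights, minlength=self.N * self.M
        ).reshape(self.N, self.M)


def _profile_terms(state: VariationalState, flat: _FlatData) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG, per-cluster predictor mean P and quadratic term Q.

    P[c, k] = h_c^T lam_{m(c), k};  Q[c, k] = h_c^T S_{m(c), k} h_c.
    """
    K = state.r.shape[1]
    P = np.empty((flat.C, K))
    Q = np.empty((flat.C, K))
    for k in range(K):
        lam_k = state.lam[:, k, :][flat.reg_of]  # (C, D)
        P[:, k] = np.einsum("cd,cd->c", flat.H, lam_k)
        S_k = state.S[:, k, :, :][flat.reg_of]  # (C, D, D)
        Q[:, k] = np.einsum("cd,cde,ce->c", flat.H, S_k, flat.H)
    return P, Q


def _sweep(
    state: VariationalState,
    flat: _FlatData,
    priors: PriorConfig,
    compute_elbo: bool = True,
) -> tuple[VariationalState, float]:
    """One full CAVI sweep in fixed order q(Z), q(W), q(tau), q(C), q(pi)."""
    st = state
    N, M, D, K = flat.N, flat.M, flat.D, st.r.shape[1]

    # --- q(Z): truncated Gaussian centred at responsibility-weighted predictor
    A = np.einsum("nk,mkd->nmd", st.r, st.lam)  # (N, M, D)
    z_mu = np.einsum("cd,cd->c", flat.H, A[flat.cell_of, flat.reg_of])
    z_mean, z_m2 = truncated_normal_moments(z_mu, flat.y)
    if not np.all(np.isfinite(z_mean)):
        raise FloatingPointError("non-finite moment in the q(Z) factor update")

    # --- q(W): Gaussian, responsibility-weighted ridge normal equations
    e_tau = st.gamma_alpha / st.gamma_beta  # (K,)
    prec = np.einsum("nk,nmde->mkde", st.r, flat.G)  # (M, K, D, D)
    prec += e_tau[None, :, None, None] * np.eye(D)[None, None]
    hz = flat.H * z_mean[:, None]  # (C, D)
    T = np.stack(
        [flat.bincount_pairs(hz[:, d]) for d in range(D)], axis=-1
    )  # (N, M, D)
    b = np.einsum("nk,nmd->mkd", st.r, T)  # (M, K, D)
    S = np.linalg.inv(prec)
    S = 0.5 * (S + np.swapaxes(S, -1, -2))
    lam = np.einsum("mkde,mke->mkd", S, b)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite moment in the q(W) factor update")

    # --- q(tau): Gamma, pooled over regions within each cluster
    ew2 = np.einsum("mkd,mkd->mk", lam, lam) + np.trace(
        S, axis1=-2, axis2=-1
    )  # (M, K)
    gamma_alpha = np.full(K, priors.alpha0 + 0.5 * M * D)
    gamma_beta = priors.beta0 + 0.5 * ew2.sum(axis=0)
    e_tau = gamma_alpha / gamma_beta

    # --- q(C): categorical from expected log joint of each cell's CpGs
    P, Q = _profile_terms(replace_arrays(st, lam=lam, S=S), flat)
    e_ln_pi = digamma(st.delta) - digamma(st.delta.sum())
    log_rho = np.empty((N, K))
    for k in range(K):
        per_cpg = z_mean * P[:, k] - 0.5 * (P[:, k] ** 2 + Q[:, k])
        log_rho[:, k] = np.bincount(flat.cell_of, weights=per_cpg, minlength=N)
    log_rho += e_ln_pi[None, :]
    log_r = log_rho - logsumexp(log_rho, axis=1, keepdims=True)
    r = np.exp(log_r)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite moment in the q(C) factor update")

    # --- q(pi): Dirichlet with expected counts
    delta = priors.delta0 + r.sum(axis=0)

    new = VariationalState(
        r=r,
        delta=delta,
        lam=lam,
        S=S,
        gamma_alpha=gamma_alpha,
        gamma_beta=gamma_beta,
        z_mu=z_mu,
        z_mean=z_mean,
        z_m2=z_m2,
        elbo_trace=list(st.elbo_trace),
    )
    bound = _elbo(new, flat, priors, P=P, Q=Q) if compute_elbo else np.nan
    return new, bound


def replace_arrays(st: VariationalState, **kw) -> VariationalState:
    return replace(st, **kw)


def _elbo(
    state: VariationalState,
    flat: _FlatData,
    priors: PriorConfig,
    P: np.ndarray | None = None,
    Q: np.ndarray | None = None,
) -> float:
    """Evidence lower bound E_q[ln p(Y,Z,C,W,pi,tau | X)] - E_q[ln q].

    ln p(Y | Z) vanishes because each q(z) is truncated to the half-line
    consistent with its observation.
    """
    st = state
    N, M, D, K = flat.N, flat.M, flat.D, st.r.shape[1]
    if P is None or Q is None:
        P, Q = _profile_terms(st, flat)
    delta0, alpha0, beta0 = priors.delta0, priors.alpha0, priors.beta0

    e_tau = st.gamma_alpha / st.gamma_beta
    e_ln_tau = digamma(st.gamma_alpha) - np.log(st.gamma_beta)
    e_ln_pi = digamma(st.delta) - digamma(st.delta.sum())
    ew2 = np.einsum("mkd,mkd->mk", st.lam, st.lam) + np.trace(
        st.S, axis1=-2, axis2=-1
    )

    # E[ln p(Z | C, W, X)] under q(Z) q(C) q(W)
    r_cpg = st.r[flat.cell_of]  # (C, K)
    quad = st.z_m2[:, None] - 2.0 * st.z_mean[:, None] * P + P**2 + Q
    t_lik = float(np.sum(r_cpg * (-0.5 * _LOG_2PI - 0.5 * quad)))

    t_c = float(st.r.sum(axis=0) @ e_ln_pi)
    t_pi = float(
        gammaln(K * delta0) - K * gammaln(delta0) + (delta0 - 1.0) * e_ln_pi.sum()
    )
    t_w = float(
        np.sum(0.5 * M * D * (e_ln_tau - _LOG_2PI) - 0.5 * e_tau * ew2.sum(axis=0))
    )
    t_tau = float(
        np.sum(
            alpha0 * np.log(beta0)
            - gammaln(alpha0)
            + (alpha0 - 1.0) * e_ln_tau
            - beta0 * e_tau
        )
    )

    # entropies
    sign = np.where(flat.y == 1, 1.0, -1.0)
    log_mass = log_ndtr(sign * st.z_mu)
    h_z = float(
        np.sum(
            0.5 * _LOG_2PI
            + log_mass
            + 0.5 * (st.z_m2 - 2.0 * st.z_mu * st.z_mean + st.z_mu**2)
        )
    )
    h_c = float(-np.sum(xlogy(st.r, st.r)))
    h_pi = float(
        np.sum(gammaln(st.delta))
        - gammaln(st.delta.sum())
        + (st.delta.sum() - K) * digamma(st.delta.sum())
        - np.sum((st.delta - 1.0) * digamma(st.delta))
    )
    _, logdet = np.linalg.slogdet(st.S)
    h_w = float(np.sum(0.5 * logdet) + 0.5 * M * K * D * (1.0 + _LOG_2PI))
    h_tau = float(
        np.sum(
            st.gamma_alpha
            - np.log(st.gamma_beta)
            + gammaln(st.gamma_alpha)
            + (1.0 - st.gamma_alpha) * digamma(st.gamma_alpha)
        )
    )
    total = t_lik + t_c + t_pi + t_w + t_tau + h_z + h_c + h_pi + h_w + h_tau
    if not np.isfinite(total):
        raise FloatingPointError("non-finite ELBO")
    return total


def cavi_step(
    state: VariationalState,
    train: MethylomeDataset,
    basis: BasisConfig,
    priors: PriorConfig,
) -> VariationalState:
    """One full coordinate-ascent sweep; appends the post-sweep ELBO."""
    flat = _FlatData(train, basis)
    new, bound = _sweep(state, flat, priors)
    new.elbo_trace.append(bound)
    return new


def elbo(
    state: VariationalState,
    train: MethylomeDataset,
    basis: BasisConfig,
    priors: PriorConfig,
) -> float:
    """Evidence lower bound of a state on a dataset."""
    return _elbo(state, _FlatData(train, basis), priors)


def _init_state(
    flat: _FlatData,
    K: int,
    priors: PriorConfig,
    rng: np.random.Generator,
    use_kmeans: bool,
) -> VariationalState:
    """Initial responsibilities from k-means on per-region mean rates.

    Missing entries of the rate matrix are filled with column means.  The
    soft one-hot (0.9/0.1) keeps every component reachable.  Degenerate
    k-means (fewer distinct rows than K) falls back to random
    responsibilities.
    """
    N, M, D = flat.N, flat.M, flat.D
    r = None
    if use_kmeans:
        X = flat.rates.copy()
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, np.nanmean(X))
        inds = np.where(np.isnan(X))
        X[inds] = col_mean[inds[1]]
        if np.unique(X, axis=0).shape[0] >= K:
            from sklearn.cluster import KMeans

            km = KMeans(
                n_clusters=K,
                n_init=3,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
            r = np.full((N, K), 0.1 / K)
            r[np.arange(N), km.labels_] += 0.9
            r /= r.sum(axis=1, keepdims=True)
    if r is None:
        r = rng.dirichlet(np.ones(K), size=N)
    return VariationalState(
        r=r,
        delta=priors.delta0 + r.sum(axis=0),
        lam=np.zeros((M, K, D)),
        S=np.tile(np.eye(D), (M, K, 1, 1)),
        gamma_alpha=np.full(K, priors.alpha0),
        gamma_beta=np.full(K, priors.beta0),
        z_mu=np.zeros(flat.C),
        z_mean=np.zeros(flat.C),
        z_m2=np.ones(flat.C),
    )


def fit_vb(
    train: MethylomeDataset,
    K: int,
    basis: BasisConfig | None = None,
    priors: PriorConfig | None = None,
    max_iter: int = 400,
    tol: float = 1e-5,
    seed: int = 0,
    n_init: int = 3,
) -> MelissaFit:
    """Fit the mixture by coordinate-ascent variational inference.

    Runs ``n_init`` restarts (the first initialised by k-means on region
    rates, later ones randomly) and keeps the fit with the highest final
    ELBO (ties break to the earliest restart).  Convergence is declared
    when the relative ELBO change drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    basis = basis if basis is not None else create_basis(4)
    priors = priors if priors is not None else PriorConfig.broad()
    flat = _FlatData(train, basis)
    if flat.C == 0:
        raise ValueError("cannot fit: dataset contains no observed CpGs")

    root = np.random.default_rng(seed)
    best: tuple[float, int, VariationalState, bool, int] | None = None
    for restart in range(n_init):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        state = _init_state(flat, K, priors, rng, use_kmeans=(restart == 0))
        converged = False
        prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            state, bound = _sweep(state, flat, priors)
            state.elbo_trace.append(bound)
            if prev > -np.inf and abs(bound - prev) <= tol * abs(prev):
                converged = True
                break
            prev = bound
        final = state.elbo_trace[-1]
        if best is None or final > best[0]:
            best = (final, restart, state, converged, it)

    _, _, state, converged, n_iter = best
    fit = MelissaFit(
        state=state,
        basis=basis,
        priors=priors,
        cells=flat.cells,
        region_ids=flat.region_ids,
        K=K,
        converged=converged,
        n_iter=n_iter,
    )
    return fit


def effective_clusters(fit: MelissaFit, mass_threshold: float | None = None) -> int:
    """Number of components with non-negligible expected occupancy.

    A component counts as occupied when its expected cell count
    sum_n r_nk exceeds one cell-equivalent (or ``mass_threshold * N`` when
    a fraction is given).  Pruned components are reported, never removed.
    """
    occupancy = fit.state.r.sum(axis=0)
    n = fit.state.r.shape[0]
    cutoff = 1.0 if mass_threshold is None else mass_threshold * n
    return int(np.sum(occupancy > cutoff))


def save_fit(fit: MelissaFit, path: str | Path) -> None:
    """Serialise a fit to a single ``.npz`` archive."""
    meta = {
        "basis": fit.basis.to_dict(),
        "priors": fit.priors.to_dict(),
        "cells": list(map(str, fit.cells)),
        "region_ids": list(map(str, fit.region_ids)),
        "K": fit.K,
        "effective_K": fit.effective_K,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
    }
    np.savez_compressed(
        path,
        meta=json.dumps(meta),
        r=fit.state.r,
        delta=fit.state.delta,
        lam=fit.state.lam,
        S=fit.state.S,
        gamma_alpha=fit.state.gamma_alpha,
        gamma_beta=fit.state.gamma_beta,
        z_mu=fit.state.z_mu,
        z_mean=fit.state.z_mean,
        z_m2=fit.state.z_m2,
        elbo_trace=np.asarray(fit.state.elbo_trace),
    )


def load_fit(path: str | Path) -> MelissaFit:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        state = VariationalState(
            r=npz["r"],
            delta=npz["delta"],
            lam=npz["lam"],
            S=npz["S"],
            gamma_alpha=npz["gamma_alpha"],
            gamma_beta=npz["gamma_beta"],
            z_mu=npz["z_mu"],
            z_mean=npz["z_mean"],
            z_m2=npz["z_m2"],
            elbo_trace=list(npz["elbo_trace"]),
        )
    return MelissaFit(
        state=state,
        basis=BasisConfig.from_dict(meta["basis"]),
        priors=PriorConfig(**meta["priors"]),
        cells=meta["cells"],
        region_ids=meta["region_ids"],
        K=int(meta["K"]),
        effective_K=int(meta["effective_K"]),
        converged=bool(meta["converged"]),
        n_iter=int(meta["n_iter"]),
    )
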