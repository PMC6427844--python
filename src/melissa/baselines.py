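"""Comparator methods for imputation and clustering benchmarks.

Four baselines bracket the joint model from below:

* ``Rate`` — the per-(cell, region) mean training state, with a small
  pseudo-count; position-independent and cell-local.
* ``Melissa Rate`` — the full mixture fit constrained to constant profiles
  (intercept-only basis), i.e. clustering on rates without smoothing.
* ``GMM`` — a diagonal Gaussian mixture on per-region average M-values
  (log2 ratio transform of rates), the classic methylome clustering recipe.
* ``BPRMeth`` — independent Bayesian probit profile fits per cell and
  region: smoothing without any sharing across cells.

All expose ``predict_dataset(test)`` returning the same prediction frame
as :func:`melissa.imputation.impute_dataset`, so the evaluation harness is
method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .basis import BasisConfig, create_basis, design_matrix
from .imputation import PREDICTION_COLUMNS, _PROB_EPS
from .melissa_vb import (
    MelissaFit,
    PriorConfig,
    _FlatData,
    fit_vb,
    truncated_normal_moments,
)
from .region_data import MethylomeDataset

__all__ = [
    "RatePredictor",
    "rate_baseline",
    "melissa_rate",
    "m_value",
    "inverse_m_value",
    "GmmFit",
    "gmm_mvalues",
    "BprmethFit",
    "bprmeth_independent",
]


def _prediction_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# ---------------------------------------------------------------------------
# Rate
# ---------------------------------------------------------------------------


@dataclass
class RatePredictor:
    """Per-(cell, region) smoothed mean methylation rate.

    The smoothed rate (sum + 0.5) / (count + 1) keeps predictions strictly
    inside (0, 1) on all-methylated or all-unmethylated regions; a region
    unseen in a cell falls back to that cell's global smoothed mean.
    """

    region_rate: dict = field(default_factory=dict)
    cell_mean: dict = field(default_factory=dict)
    raw_rate: dict = field(default_factory=dict)

    def predict(self, cell: str, region: str, positions: np.ndarray) -> np.ndarray:
        rate = self.region_rate.get((cell, region), self.cell_mean.get(cell, 0.5))
        return np.full(np.atleast_1d(positions).shape[0], rate)

    def predict_dataset(self, test: MethylomeDataset, threshold: float = 0.5):
        rows = []
        for (cell, region), rcd in sorted(test.data.items()):
            if not len(rcd):
                continue
            prob = np.clip(
                self.predict(cell, region, rcd.positions), _PROB_EPS, 1 - _PROB_EPS
            )
            for p, pr, s in zip(rcd.positions, prob, rcd.states):
                rows.append(
                    {
                        "cell": cell,
                        "region": region,
                        "rel_pos": p,
                        "prob": pr,
                        "pred_state": int(pr > threshold),
                        "true_state": float(s),
                    }
                )
        return _prediction_frame(rows)


def rate_baseline(train: MethylomeDataset) -> RatePredictor:
    """Fit the naive rate predictor from training states."""
    pred = RatePredictor()
    totals: dict[str, list[float]] = {c: [0.0, 0.0] for c in train.cells}
    for (cell, region), rcd in train.data.items():
        n = len(rcd)
        if not n:
            continue
        s = float(rcd.states.sum())
        pred.raw_rate[(cell, region)] = s / n
        pred.region_rate[(cell, region)] = (s + 0.5) / (n + 1.0)
        totals[cell][0] += s
        totals[cell][1] += n
    for cell, (s, n) in totals.items():
        pred.cell_mean[cell] = (s + 0.5) / (n + 1.0)
    return pred


# ---------------------------------------------------------------------------
# Melissa Rate
# ---------------------------------------------------------------------------


def melissa_rate(
    train: MethylomeDataset,
    K: int,
    priors: PriorConfig | None = None,
    **opts,
) -> MelissaFit:
    """The full mixture model constrained to constant (rate-like) profiles."""
    return fit_vb(train, K, basis=create_basis(0), priors=priors, **opts)


# ---------------------------------------------------------------------------
# GMM on M-values
# ---------------------------------------------------------------------------


def m_value(rate):
    """M-value transform log2((rate + 0.01) / (1 - rate + 0.01)).

    Maps rates in [0, 1] to a roughly Gaussian scale, bounded by the 0.01
    offset; strictly increasing and antisymmetric about rate = 0.5.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any((rate < 0) | (rate > 1)):
        raise ValueError("rates must lie in [0, 1]")
    return np.log2((rate + 0.01) / (1.0 - rate + 0.01))


def inverse_m_value(m):
    """Inverse of :func:`m_value` (clipped back into [0, 1])."""
    m = np.asarray(m, dtype=float)
    x = np.exp2(m)
    rate = (1.01 * x - 0.01) / (1.0 + x)
    return np.clip(rate, 0.0, 1.0)


@dataclass
class GmmFit:
    """Diagonal-covariance Gaussian mixture fitted on the M-value matrix."""

    means: np.ndarray  # (K, P) in the fitted (possibly PCA) space
    variances: np.ndarray  # (K, P)
    weights: np.ndarray  # (K,)
    responsibilities: np.ndarray  # (N, K)
    loglik_trace: np.ndarray
    cluster_mvalues: np.ndarray  # (K, M) responsibility-weighted region means
    cells: list
    region_ids: list

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def predict_dataset(self, test: MethylomeDataset, threshold: float = 0.5):
        """Impute as the responsibility-weighted mix of cluster mean rates."""
        cidx = {c: i for i, c in enumerate(self.cells)}
        ridx = {r: j for j, r in enumerate(self.region_ids)}
        cluster_rates = inverse_m_value(self.cluster_mvalues)  # (K, M)
        rows = []
        for (cell, region), rcd in sorted(test.data.items()):
            if not len(rcd) or region not in ridx:
                continue
            r_n = self.responsibilities[cidx[cell]]
            prob = float(np.clip(r_n @ cluster_rates[:, ridx[region]],
                                 _PROB_EPS, 1 - _PROB_EPS))
            for p, s in zip(rcd.positions, rcd.states):
                rows.append(
                    {
                        "cell": cell,
                        "region": region,
                        "rel_pos": p,
                        "prob": prob,
                        "pred_state": int(prob > threshold),
                        "true_state": float(s),
                    }
                )
        return _prediction_frame(rows)


def _diag_gmm_em(
    X: np.ndarray, K: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """EM for a diagonal-covariance Gaussian mixture.

    Log-likelihood is non-decreasing per iteration (up to the variance
    floor applied for numerical safety).
    """
    n, p = X.shape
    # initialise means at distinct random data points
    idx = rng.choice(n, size=K, replace=False)
    means = X[idx].copy()
    variances = np.tile(X.var(axis=0) + 1e-3, (K, 1))
    weights = np.full(K, 1.0 / K)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        log_comp = (
            -0.5 * np.sum(np.log(2 * np.pi * variances), axis=1)[None, :]
            - 0.5
            * np.sum(
                (X[:, None, :] - means[None]) ** 2 / variances[None], axis=2
            )
            + np.log(weights)[None, :]
        )
        shift = log_comp.max(axis=1, keepdims=True)
        lse = shift[:, 0] + np.log(np.exp(log_comp - shift).sum(axis=1))
        resp = np.exp(log_comp - lse[:, None])
        ll = float(lse.sum())
        trace.append(ll)
        if prev > -np.inf and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll
        # M-step (weighted moments)
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        variances = (
            np.einsum("nk,nkp->kp", resp, (X[:, None, :] - means[None]) ** 2)
            / nk[:, None]
        )
        variances = np.maximum(variances, 1e-6)
    return means, variances, weights, resp, trace


def gmm_mvalues(
    train: MethylomeDataset,
    K: int,
    seed: int = 0,
    n_pca: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> GmmFit:
    """Cluster cells with a Gaussian mixture on per-region mean M-values.

    Missing entries of the N x M rate matrix are column-mean imputed before
    the M-value transform.  With ``n_pca`` the matrix is projected onto its
    leading principal components before EM (reported by the original
    benchmark to make no practical difference).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > train.n_cells:
        raise ValueError("K cannot exceed the number of cells")
    rates = train.rate_matrix()
    col_mean = np.nanmean(rates, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, np.nanmean(rates))
    inds = np.where(np.isnan(rates))
    rates[inds] = col_mean[inds[1]]
    Mmat = m_value(rates)  # (N, M)
    X = Mmat
    if n_pca is not None and n_pca < Mmat.shape[1]:
        centred = Mmat - Mmat.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        X = centred @ vt[:n_pca].T
    rng = np.random.default_rng(seed)
    means, variances, weights, resp, trace = _diag_gmm_em(
        X, K, rng, max_iter, tol
    )
    nk = resp.sum(axis=0) + 1e-12
    cluster_mvalues = (resp.T @ Mmat) / nk[:, None]
    return GmmFit(
        means=means,
        variances=variances,
        weights=weights,
        responsibilities=resp,
        loglik_trace=np.asarray(trace),
        cluster_mvalues=cluster_mvalues,
        cells=list(train.cells),
        region_ids=list(train.region_ids),
    )


# ---------------------------------------------------------------------------
# Independent BPRMeth profiles
# ---------------------------------------------------------------------------


@dataclass
class BprmethFit:
    """Independent MAP probit profile per (cell, region)."""

    weights: dict  # (cell, region) -> (D,) MAP weight vector
    basis: BasisConfig
    tau0: float
    converged: bool

    def predict(self, cell: str, region: str, positions: np.ndarray) -> np.ndarray:
        w = self.weights[(cell, region)]
        H = design_matrix(np.atleast_1d(positions), self.basis)
        return ndtr(H @ w)

    def predict_dataset(self, test: MethylomeDataset, threshold: float = 0.5):
        rows = []
        for (cell, region), rcd in sorted(test.data.items()):
            if not len(rcd) or (cell, region) not in self.weights:
                continue
            prob = np.clip(
                self.predict(cell, region, rcd.positions), _PROB_EPS, 1 - _PROB_EPS
            )
            for p, pr, s in zip(rcd.positions, prob, rcd.states):
                rows.append(
                    {
                        "cell": cell,
                        "region": region,
                        "rel_pos": p,
                        "prob": pr,
                        "pred_state": int(pr > threshold),
                        "true_state": float(s),
                    }
                )
        return _prediction_frame(rows)


def bprmeth_independent(
    train: MethylomeDataset,
    basis: BasisConfig | None = None,
    tau0: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> BprmethFit:
    """MAP probit profile fits, independent across cells and regions.

    For each covered (cell, region) block the posterior mode of the probit
    GLM with an N(0, tau0^{-1} I) prior is found by expectation-maximisation
    on the augmented model: alternate the truncated-Gaussian mean of z with
    the ridge solve (tau0 I + H^T H) w = H^T E[z].  All blocks iterate in
    one batched loop.  Non-convergence after ``max_iter`` returns the last
    iterate (flagged on the fit).
    """
    basis = basis if basis is not None else create_basis(4)
    flat = _FlatData(train, basis)
    D = flat.D
    present = np.unique(flat.pair_of)
    A = flat.G.reshape(flat.N * flat.M, D, D)[present] + tau0 * np.eye(D)
    A_inv = np.linalg.inv(A)
    pair_pos = np.searchsorted(present, flat.pair_of)
    w = np.zeros((present.size, D))
    converged = False
    for _ in range(max_iter):
        mu = np.einsum("cd,cd->c", flat.H, w[pair_pos])
        ez, _ = truncated_normal_moments(mu, flat.y)
        hz = flat.H * ez[:, None]
        b = np.stack(
            [
                np.bincount(pair_pos, weights=hz[:, d], minlength=present.size)
                for d in range(D)
            ],
            axis=-1,
        )
        w_new = np.einsum("pde,pe->pd", A_inv, b)
        delta = np.max(np.abs(w_new - w))
        w = w_new
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("probit profile fits did not all converge; using last iterate")
    cidx = {i: c for i, c in enumerate(flat.cells)}
    ridx = {j: r for j, r in enumerate(flat.region_ids)}
    weights = {
        (cidx[p // flat.M], ridx[p % flat.M]): w[i]
        for i, p in enumerate(present)
    }
    return BprmethFit(weights=weights, basis=basis, tau0=tau0, converged=converged)
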