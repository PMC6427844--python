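"""Tests of the variational engine against independent oracles.

The reference sweep below re-implements the coordinate updates with plain
loops and scipy.stats.truncnorm moments (no shared code with the package's
vectorised path), and the evidence oracle integrates the tiny model's
marginal likelihood by enumeration over assignments plus numerical
quadrature over weights and precisions.
"""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import digamma, gammaln, ndtr, xlogy
from scipy.stats import norm

from melissa import (
    PriorConfig,
    adjusted_rand_index,
    cavi_step,
    create_basis,
    effective_clusters,
    elbo,
    fit_vb,
    impute_dataset,
    load_fit,
    save_fit,
    truncated_normal_moments,
)
from melissa.basis import design_matrix
from melissa.melissa_vb import MelissaFit, VariationalState, _FlatData

from conftest import make_dataset


# ---------------------------------------------------------------------------
# truncated-normal moments
# ---------------------------------------------------------------------------


class TestTruncatedNormalMoments:
    def test_zero_mean_positive_truncation(self):
        ez, ez2 = truncated_normal_moments(np.array([0.0]), np.array([1]))
        assert ez[0] == pytest.approx(np.sqrt(2 / np.pi), abs=1e-12)
        assert ez2[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("y", [0, 1])
    def test_matches_numerical_integration(self, y):
        # brute-force moments of the truncated density by quadrature
        for mu in [-8.0, -2.5, -0.3, 0.0, 0.7, 3.0, 8.0]:
            lo, hi = (0, np.inf) if y == 1 else (-np.inf, 0)
            mass, _ = integrate.quad(lambda z: norm.pdf(z, mu), lo, hi)
            m1, _ = integrate.quad(lambda z: z * norm.pdf(z, mu), lo, hi)
            m2, _ = integrate.quad(lambda z: z * z * norm.pdf(z, mu), lo, hi)
            ez, ez2 = truncated_normal_moments(np.array([mu]), np.array([y]))
            assert ez[0] == pytest.approx(m1 / mass, abs=1e-8)
            assert ez2[0] == pytest.approx(m2 / mass, abs=1e-8)

    def test_truncation_inactive_in_far_tail(self):
        ez, _ = truncated_normal_moments(np.array([25.0]), np.array([1]))
        assert ez[0] == pytest.approx(25.0, rel=1e-10)

    def test_reflection_symmetry(self):
        mus = np.linspace(-6, 6, 25)
        ez1, _ = truncated_normal_moments(mus, np.ones_like(mus))
        ez0, _ = truncated_normal_moments(-mus, np.zeros_like(mus))
        assert np.allclose(ez0, -ez1, atol=1e-12)

    def test_stable_far_into_tails(self):
        ez, ez2 = truncated_normal_moments(np.array([-30.0, 30.0]),
                                           np.array([1, 0]))
        assert np.all(np.isfinite(ez)) and np.all(np.isfinite(ez2))


# ---------------------------------------------------------------------------
# naive reference implementation
# ---------------------------------------------------------------------------


def reference_sweep(state, dataset, basis, priors):
    """Loop-based CAVI sweep + ELBO, written independently of the package."""
    cells = dataset.cells
    region_ids = dataset.region_ids
    N, M, K = len(cells), len(region_ids), state.r.shape[1]
    D = basis.n_features
    blocks = {}
    for n, cell in enumerate(cells):
        for m, rid in enumerate(region_ids):
            rcd = dataset.get(cell, rid)
            if rcd is not None and len(rcd):
                blocks[(n, m)] = (design_matrix(rcd.positions, basis),
                                  np.asarray(rcd.states, dtype=int))

    r, delta = state.r.copy(), state.delta.copy()
    lam, S = state.lam.copy(), state.S.copy()
    ga, gb = state.gamma_alpha.copy(), state.gamma_beta.copy()

    # q(Z): moments by quadrature of the truncated density
    z_mu, z_mean, z_m2, keys = [], [], [], []
    for (n, m), (H, y) in sorted(blocks.items()):
        for i in range(len(y)):
            mu = sum(r[n, k] * (H[i] @ lam[m, k]) for k in range(K))
            lo, hi = (0, np.inf) if y[i] == 1 else (-np.inf, 0)
            mass, _ = integrate.quad(lambda z: norm.pdf(z, mu), lo, hi)
            m1, _ = integrate.quad(lambda z: z * norm.pdf(z, mu), lo, hi)
            m2, _ = integrate.quad(lambda z: z * z * norm.pdf(z, mu), lo, hi)
            z_mu.append(mu)
            z_mean.append(m1 / mass)
            z_m2.append(m2 / mass)
            keys.append((n, m, i))
    z_mu, z_mean, z_m2 = map(np.array, (z_mu, z_mean, z_m2))
    zlookup = {key: idx for idx, key in enumerate(keys)}

    # q(W)
    e_tau = ga / gb
    for m in range(M):
        for k in range(K):
            prec = e_tau[k] * np.eye(D)
            b_vec = np.zeros(D)
            for n in range(N):
                if (n, m) not in blocks:
                    continue
                H, y = blocks[(n, m)]
                prec += r[n, k] * (H.T @ H)
                ez = np.array([z_mean[zlookup[(n, m, i)]] for i in range(len(y))])
                b_vec += r[n, k] * (H.T @ ez)
            S[m, k] = np.linalg.inv(prec)
            lam[m, k] = S[m, k] @ b_vec

    # q(tau)
    for k in range(K):
        ga[k] = priors.alpha0 + 0.5 * M * D
        gb[k] = priors.beta0 + 0.5 * sum(
            lam[m, k] @ lam[m, k] + np.trace(S[m, k]) for m in range(M)
        )

    # q(C)
    e_ln_pi = digamma(delta) - digamma(delta.sum())
    log_rho = np.zeros((N, K))
    for n in range(N):
        for k in range(K):
            acc = e_ln_pi[k]
            for m in range(M):
                if (n, m) not in blocks:
                    continue
                H, y = blocks[(n, m)]
                for i in range(len(y)):
                    ez = z_mean[zlookup[(n, m, i)]]
                    p = H[i] @ lam[m, k]
                    q = H[i] @ S[m, k] @ H[i]
                    acc += ez * p - 0.5 * (p * p + q)
            log_rho[n, k] = acc
    log_rho -= log_rho.max(axis=1, keepdims=True)
    r = np.exp(log_rho)
    r /= r.sum(axis=1, keepdims=True)

    # q(pi)
    delta = priors.delta0 + r.sum(axis=0)

    # ELBO
    e_tau = ga / gb
    e_ln_tau = digamma(ga) - np.log(gb)
    e_ln_pi = digamma(delta) - digamma(delta.sum())
    total = 0.0
    for (n, m), (H, y) in blocks.items():
        for i in range(len(y)):
            idx = zlookup[(n, m, i)]
            for k in range(K):
                p = H[i] @ lam[m, k]
                q = H[i] @ S[m, k] @ H[i]
                total += r[n, k] * (
                    -0.5 * np.log(2 * np.pi)
                    - 0.5 * (z_m2[idx] - 2 * z_mean[idx] * p + p * p + q)
                )
            # entropy of the truncated factor, by quadrature of -q ln q
            mu = z_mu[idx]
            lo, hi = (0, np.inf) if y[i] == 1 else (-np.inf, 0)
            mass, _ = integrate.quad(lambda z: norm.pdf(z, mu), lo, hi)

            def neg_qlogq(z, mu=mu, mass=mass):
                q = norm.pdf(z, mu) / mass
                return -q * np.log(q) if q > 0 else 0.0

            ent, _ = integrate.quad(neg_qlogq, lo, hi)
            total += ent
    total += float(r.sum(axis=0) @ e_ln_pi)
    total += gammaln(K * priors.delta0) - K * gammaln(priors.delta0) \
        + (priors.delta0 - 1) * e_ln_pi.sum()
    for k in range(K):
        for m in range(M):
            total += 0.5 * D * (e_ln_tau[k] - np.log(2 * np.pi)) - 0.5 * e_tau[k] * (
                lam[m, k] @ lam[m, k] + np.trace(S[m, k])
            )
            sign, logdet = np.linalg.slogdet(S[m, k])
            total += 0.5 * logdet + 0.5 * D * (1 + np.log(2 * np.pi))
        total += (
            priors.alpha0 * np.log(priors.beta0)
            - gammaln(priors.alpha0)
            + (priors.alpha0 - 1) * e_ln_tau[k]
            - priors.beta0 * e_tau[k]
        )
        total += ga[k] - np.log(gb[k]) + gammaln(ga[k]) \
            + (1 - ga[k]) * digamma(ga[k])
    total += -float(np.sum(xlogy(r, r)))
    total += float(
        np.sum(gammaln(delta)) - gammaln(delta.sum())
        + (delta.sum() - K) * digamma(delta.sum())
        - np.sum((delta - 1) * digamma(delta))
    )
    new = VariationalState(
        r=r, delta=delta, lam=lam, S=S, gamma_alpha=ga, gamma_beta=gb,
        z_mu=z_mu, z_mean=z_mean, z_m2=z_m2,
    )
    return new, total


def random_state(flat, K, priors, seed):
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(np.ones(K), size=flat.N)
    return VariationalState(
        r=r,
        delta=priors.delta0 + r.sum(axis=0),
        lam=rng.normal(0, 0.5, (flat.M, K, flat.D)),
        S=np.tile(np.eye(flat.D), (flat.M, K, 1, 1)),
        gamma_alpha=np.full(K, priors.alpha0 + 1.0),
        gamma_beta=np.full(K, priors.beta0),
        z_mu=np.zeros(flat.C),
        z_mean=np.zeros(flat.C),
        z_m2=np.ones(flat.C),
    )


class TestAgainstReferenceImplementation:
    @pytest.mark.parametrize("n_rbf,seed", [(0, 0), (0, 1), (1, 2), (2, 3)])
    def test_sweep_matches_naive_loops(self, tiny_dataset, n_rbf, seed):
        basis = create_basis(n_rbf)
        priors = PriorConfig.broad()
        flat = _FlatData(tiny_dataset, basis)
        state = random_state(flat, K=2, priors=priors, seed=seed)

        ours = cavi_step(state.copy(), tiny_dataset, basis, priors)
        ref, ref_elbo = reference_sweep(state.copy(), tiny_dataset, basis, priors)

        assert np.allclose(ours.r, ref.r, atol=1e-8)
        assert np.allclose(ours.delta, ref.delta, atol=1e-8)
        assert np.allclose(ours.lam, ref.lam, atol=1e-8)
        assert np.allclose(ours.S, ref.S, atol=1e-8)
        assert np.allclose(ours.gamma_beta, ref.gamma_beta, atol=1e-8)
        assert np.allclose(ours.z_mean, ref.z_mean, atol=1e-8)
        assert ours.elbo_trace[-1] == pytest.approx(ref_elbo, abs=1e-8)

    def test_multi_sweep_elbo_track(self, tiny_dataset):
        basis = create_basis(1)
        priors = PriorConfig.broad()
        flat = _FlatData(tiny_dataset, basis)
        ours = random_state(flat, K=2, priors=priors, seed=7)
        ref = ours.copy()
        for _ in range(5):
            ours = cavi_step(ours, tiny_dataset, basis, priors)
            ref, ref_elbo = reference_sweep(ref, tiny_dataset, basis, priors)
            assert ours.elbo_trace[-1] == pytest.approx(ref_elbo, abs=1e-8)


# ---------------------------------------------------------------------------
# evidence oracle
# ---------------------------------------------------------------------------


def log_evidence_tiny(dataset, priors):
    """Exact ln p(Y | X) for an intercept-only (D=1) two-cluster model.

    Enumerates cluster assignments (Dirichlet-multinomial marginal over pi)
    and integrates weights and precisions numerically per cluster.
    """
    K = 2
    d0 = priors.delta0
    cells = dataset.cells
    states = [dataset.get(c, "r0").states for c in cells]
    N = len(cells)

    def cluster_lik(members):
        # int Gamma(tau) int N(w | 0, 1/tau) prod Phi((2y-1) w) dw dtau
        ys = np.concatenate([states[n] for n in members]) if members else np.array([])

        def inner(tau):
            def f(w):
                lik = np.prod(ndtr((2 * ys - 1.0) * w)) if ys.size else 1.0
                return norm.pdf(w, scale=1 / np.sqrt(tau)) * lik

            val, _ = integrate.quad(f, -40, 40, limit=200)
            return val

        def outer(tau):
            dens = (
                priors.beta0**priors.alpha0
                / np.exp(gammaln(priors.alpha0))
                * tau ** (priors.alpha0 - 1)
                * np.exp(-priors.beta0 * tau)
            )
            return dens * inner(tau)

        val, _ = integrate.quad(outer, 1e-12, 60, limit=400)
        return val

    total = 0.0
    for assignment in range(K**N):
        c = [(assignment >> n) & 1 for n in range(N)]
        counts = np.bincount(c, minlength=K)
        log_p_c = (
            gammaln(K * d0)
            - K * gammaln(d0)
            + np.sum(gammaln(d0 + counts))
            - gammaln(K * d0 + N)
        )
        lik = 1.0
        for k in range(K):
            lik *= cluster_lik([n for n in range(N) if c[n] == k])
        total += np.exp(log_p_c) * lik
    return np.log(total)


class TestEvidenceBound:
    def test_elbo_below_exact_evidence(self, tiny_dataset):
        priors = PriorConfig(delta0=0.5, alpha0=1.5, beta0=2.0)
        basis = create_basis(0)
        log_z = log_evidence_tiny(tiny_dataset, priors)
        fit = fit_vb(tiny_dataset, K=2, basis=basis, priors=priors,
                     max_iter=200, tol=1e-10, seed=0, n_init=2)
        bound = fit.state.elbo_trace[-1]
        assert bound <= log_z + 1e-6
        assert log_z - bound < 5.0  # sanity: the bound is not vacuous


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------


class TestInvariants:
    def test_elbo_monotone_and_conservation(self, small_sim):
        _, dataset, _ = small_sim
        priors = PriorConfig.broad()
        fit = fit_vb(dataset, K=5, priors=priors, seed=0, n_init=1, max_iter=100)
        trace = np.asarray(fit.state.elbo_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))
        assert np.allclose(fit.state.r.sum(axis=1), 1.0, atol=1e-8)
        N, K = fit.state.r.shape
        assert fit.state.delta.sum() == pytest.approx(K * priors.delta0 + N)
        assert np.all(fit.state.delta >= priors.delta0 - 1e-12)

    def test_converged_fit_is_a_fixed_point(self, tiny_dataset):
        basis = create_basis(1)
        priors = PriorConfig.broad()
        fit = fit_vb(tiny_dataset, K=2, basis=basis, priors=priors,
                     max_iter=2000, tol=1e-14, seed=3, n_init=1)
        again = cavi_step(fit.state.copy(), tiny_dataset, basis, priors)
        assert np.allclose(again.r, fit.state.r, atol=1e-8)
        assert np.allclose(again.lam, fit.state.lam, atol=1e-8)
        assert again.elbo_trace[-1] == pytest.approx(
            fit.state.elbo_trace[-1], abs=1e-8
        )

    def test_elbo_invariant_under_component_relabelling(self, small_sim):
        _, dataset, _ = small_sim
        basis = create_basis(2)
        priors = PriorConfig.broad()
        fit = fit_vb(dataset, K=4, basis=basis, priors=priors, seed=1,
                     n_init=1, max_iter=10)
        st = fit.state
        perm = np.array([2, 0, 3, 1])
        permuted = VariationalState(
            r=st.r[:, perm], delta=st.delta[perm], lam=st.lam[:, perm],
            S=st.S[:, perm], gamma_alpha=st.gamma_alpha[perm],
            gamma_beta=st.gamma_beta[perm], z_mu=st.z_mu, z_mean=st.z_mean,
            z_m2=st.z_m2,
        )
        assert elbo(permuted, dataset, basis, priors) == pytest.approx(
            elbo(st, dataset, basis, priors), rel=1e-12
        )

    def test_recovers_labels_on_well_separated_data(self, small_sim):
        _, dataset, truth = small_sim
        fit = fit_vb(dataset, K=6, seed=0, n_init=1)
        assert adjusted_rand_index(fit.hard_labels, truth.labels) == 1.0
        assert fit.effective_K == 3

    def test_invalid_inputs_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            fit_vb(tiny_dataset, K=0)
        with pytest.raises(ValueError):
            PriorConfig(delta0=0.0)


class TestEffectiveClusters:
    def make_fit(self, r):
        flatten = make_dataset({("a", "r0"): ([0.0], [1])})
        basis = create_basis(0)
        N, K = r.shape
        state = VariationalState(
            r=r, delta=0.5 + r.sum(axis=0), lam=np.zeros((1, K, 1)),
            S=np.tile(np.eye(1), (1, K, 1, 1)), gamma_alpha=np.ones(K),
            gamma_beta=np.ones(K), z_mu=np.zeros(1), z_mean=np.zeros(1),
            z_m2=np.ones(1),
        )
        return MelissaFit(state=state, basis=basis, priors=PriorConfig.broad(),
                          cells=["a"], region_ids=["r0"], K=K)

    def test_single_occupied_component(self):
        r = np.zeros((10, 4))
        r[:, 2] = 1.0
        assert effective_clusters(self.make_fit(r)) == 1

    def test_uniform_occupancy_counts_all(self):
        r = np.full((12, 4), 0.25)
        fit = self.make_fit(r)
        assert effective_clusters(fit, mass_threshold=0.1) == 4


class TestSerialisation:
    def test_fit_round_trip_reproduces_predictions(self, small_sim, tmp_path):
        _, dataset, _ = small_sim
        fit = fit_vb(dataset, K=3, seed=0, n_init=1, max_iter=30)
        path = tmp_path / "fit.npz"
        save_fit(fit, path)
        again = load_fit(path)
        p1 = impute_dataset(fit, dataset)
        p2 = impute_dataset(again, dataset)
        assert np.array_equal(p1["prob"].to_numpy(), p2["prob"].to_numpy())
        assert again.effective_K == fit.effective_K
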