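"""DMFT kernels, response estimation, and the self-consistency loop."""

import numpy as np
import pytest

import gatedmem as gm
from gatedmem.dmft import (
    estimate_response,
    memory_kernel,
    noise_covariance,
    novikov_response,
    single_site_integrate,
)


class TestGaussianPaths:
    def test_zero_covariance_gives_zero_paths(self):
        paths = gm.sample_gaussian_paths(np.zeros((10, 10)), 5, rng=0)
        assert np.array_equal(paths, np.zeros((5, 10)))

    def test_identity_covariance_white_noise(self):
        M = 4000
        paths = gm.sample_gaussian_paths(np.eye(20), M, rng=1)
        emp = paths.T @ paths / M
        assert np.max(np.abs(emp - np.eye(20))) < 5.0 / np.sqrt(M)
        assert np.max(np.abs(paths.mean(axis=0))) < 5.0 / np.sqrt(M)

    def test_rank_deficient_covariance_handled(self):
        cov = np.ones((15, 15))  # rank 1, PSD only with jitter
        paths = gm.sample_gaussian_paths(cov, 2000, rng=2)
        emp = paths.T @ paths / 2000
        assert np.max(np.abs(emp - cov)) < 0.2

    def test_asymmetric_rejected(self):
        cov = np.eye(4)
        cov[0, 1] = 0.5
        with pytest.raises(ValueError):
            gm.sample_gaussian_paths(cov, 3)


class TestPropagator:
    def test_zero_response_gives_step_kernel(self):
        G = gm.update_propagator(np.zeros((30, 30)), 0.1)
        assert np.array_equal(G, np.tril(np.ones((30, 30))))

    def test_memoryless_kernel_exponential_decay(self):
        # R(t,u) = -lam * delta(t-u): G(t,t') = exp(-lam (t-t')) up to O(dt)
        n, dt, lam = 80, 0.05, 0.7
        R = np.zeros((n, n))
        np.fill_diagonal(R, -lam / dt)
        G = gm.update_propagator(R, dt)
        expected = (1 - lam * dt) ** np.arange(n)  # Euler-exact geometric decay
        assert np.max(np.abs(G[:, 0] - expected)) < 1e-12
        cont = np.exp(-lam * dt * np.arange(n))
        assert np.max(np.abs(G[:, 0] - cont)) < 2 * lam * lam * dt

    def test_strict_causality(self, rng):
        R = np.tril(rng.standard_normal((25, 25)), -1)
        G = gm.update_propagator(R, 0.1)
        assert np.all(np.triu(G, 1) == 0.0)


class TestMemoryKernel:
    def test_neumann_series_oracle(self, rng):
        n, dt, a = 20, 0.1, 1.7
        R = np.tril(rng.standard_normal((n, n)) * 0.3, -1)
        Kt = memory_kernel(R, a, dt)
        # brute Neumann resummation: Kt = sum_{k>=1} a^k dt^{k-1} R^(k)
        term = a * R
        brute = term.copy()
        for _ in range(n):
            term = a * dt * (R @ term)
            brute += term
        assert np.max(np.abs(Kt - brute)) < 1e-10
        assert np.all(np.triu(Kt) == 0.0)

    def test_noise_covariance_matches_propagator_form(self, rng):
        n, dt, g, alpha = 15, 0.2, 1.5, 0.4
        C = rng.standard_normal((n, n))
        C = C @ C.T / n
        Kt = np.tril(rng.standard_normal((n, n)), -1)
        cov = noise_covariance(C, Kt, g, dt)
        G = (g / np.sqrt(alpha)) * (np.eye(n) / dt + Kt)
        ref = alpha * dt * dt * (G @ C @ G.T)
        assert np.max(np.abs(cov - ref)) < 1e-10


def _linear_integrator(M, n, dt, params):
    zero = np.zeros((M, n))

    def integrate(h_ext):
        _, Phi = single_site_integrate(
            zero, zero, np.ones(M), np.zeros(n), np.zeros((n, n)), params, dt,
            np.zeros(M), np.zeros(M), h_ext=h_ext, phi_fn=lambda x: x,
        )
        return Phi.mean(axis=0)

    return integrate


class TestResponse:
    def test_impulse_matches_linear_greens_function(self):
        """phi = identity, gamma = 0: R(t,t') = (1/2) exp(-(t-t')/2) + O(dt)."""
        params = dict(alpha=0.4, g=1.5, gamma=0.0, tau_z=1.0)
        n, dt = 50, 0.1
        R = estimate_response(_linear_integrator(8, n, dt, params), n, 1e-4, dt)
        k = np.arange(1, n)
        discrete = 0.5 * (1 - dt / 2) ** (k - 1)  # Euler-exact kernel
        assert np.max(np.abs(R[k, 0] - discrete)) < 1e-8
        cont = 0.5 * np.exp(-0.5 * (k - 1) * dt)
        assert np.max(np.abs(R[k, 0] - cont)) < 0.05 * dt / 0.1
        assert np.all(np.triu(R) == 0.0)

    def test_frozen_gates_give_zero_response(self):
        params = dict(alpha=0.4, g=1.5, gamma=np.inf, tau_z=1.0)
        M, n, dt = 16, 20, 0.1
        zero = np.zeros((M, n))

        def integrate(h_ext):
            _, Phi = single_site_integrate(
                zero, zero, np.ones(M), np.zeros(n), np.zeros((n, n)), params, dt,
                np.zeros(M), -np.ones(M), h_ext=h_ext,  # z < 0: every gate shut
            )
            return Phi.mean(axis=0)

        R = estimate_response(integrate, n, 1e-4, dt)
        assert np.array_equal(R, np.zeros((n, n)))

    def test_eps_linearity_and_zero_rejected(self):
        params = dict(alpha=0.4, g=1.5, gamma=0.0, tau_z=1.0)
        n, dt = 30, 0.1
        fn = _linear_integrator(8, n, dt, params)
        with pytest.raises(ValueError):
            estimate_response(fn, n, 0.0, dt)
        R1 = estimate_response(fn, n, 1e-3, dt)
        R2 = estimate_response(fn, n, 5e-4, dt)
        assert np.max(np.abs(R1 - R2)) < 1e-9  # linear regime

    def test_novikov_agrees_with_impulse(self):
        """Both estimators target the same derivative on a noisy nonlinear system."""
        params = dict(alpha=0.4, g=1.5, gamma=0.0, tau_z=1.0)
        M, n, dt = 40000, 25, 0.2
        rng = np.random.default_rng(8)
        cov = 2.25 * np.exp(-0.5 * np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * dt)
        eta_x = gm.sample_gaussian_paths(cov, M, rng=rng)
        eta_z = np.zeros((M, n))
        xi = rng.integers(0, 2, M) * 2.0 - 1.0
        x0 = 0.8 * xi + rng.standard_normal(M)
        m = np.full(n, 0.6)
        Kt = np.zeros((n, n))

        def integrate(h_ext):
            _, Phi = single_site_integrate(
                eta_x, eta_z, xi, m, Kt, params, dt, x0, np.zeros(M), h_ext=h_ext
            )
            return Phi.mean(axis=0)

        R_imp = estimate_response(integrate, n, 1e-3, dt)
        _, Phi = single_site_integrate(eta_x, eta_z, xi, m, Kt, params, dt, x0,
                                       np.zeros(M))
        R_nov = novikov_response(Phi, eta_x, cov, dt, ridge=1e-3)
        mask = np.tril(np.ones((n, n)), -1).astype(bool)
        # discrepancy is Monte Carlo noise (~1/sqrt(M)), not systematic bias
        err = np.abs(R_nov - R_imp)[mask]
        assert np.median(err) < 0.06
        assert np.max(err) < 0.30


@pytest.fixture(scope="module")
def solved():
    return gm.solve_dmft(alpha=0.4, gamma=0.0, m0=0.65, T=20.0, dt=0.2,
                         M=800, seed=5, max_iter=30)


class TestSolveDMFT:

    def test_converges_with_decreasing_residual(self, solved):
        assert solved.converged
        h = solved.residual_history
        assert h[-1] < 1e-3 and h[-1] < h[0]

    def test_causality_and_bounds(self, solved):
        assert np.all(np.triu(solved.R) == 0.0)
        assert np.all(np.triu(solved.K_tilde) == 0.0)
        assert np.all(np.diag(solved.C_phi) <= 1.0 + 1e-12)
        assert np.all(np.abs(solved.C_phi) <= 1.0 + 1e-12)
        assert np.all(np.abs(solved.m) <= 1.0)

    def test_noise_covariance_identities(self, solved):
        # cov_z = C_phi exactly; cov_x = alpha dt^2 G C_phi G^T to rounding
        assert np.array_equal(solved.cov_z, solved.C_phi)
        ref = 0.4 * 0.2 * 0.2 * (solved.G @ solved.C_phi @ solved.G.T)
        assert np.max(np.abs(solved.cov_x - ref)) < 1e-8

    def test_psd_after_jitter(self, solved):
        w = np.linalg.eigvalsh(solved.C_phi + 1e-8 * np.eye(len(solved.m)))
        assert w.min() > -1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            gm.solve_dmft(alpha=-0.1)
        with pytest.raises(ValueError):
            gm.solve_dmft(alpha=0.4, response_method="bogus", T=2.0, dt=0.5, M=8)

    def test_scalar_limit_small_alpha(self):
        """At vanishing load the steady overlap hits the scalar root to 1e-3."""
        st = gm.solve_dmft(alpha=0.02, gamma=0.0, m0=0.6, T=20.0, dt=0.2, M=500,
                           seed=2, response_method="impulse", impulse_stride=2,
                           max_iter=30)
        assert st.converged
        assert abs(st.m[-1] - gm.scalar_overlap_root(0.02, 1.5)) < 1e-3


class TestAsymptotic:
    def test_fully_frozen_returns_imposed_overlap(self):
        sol = gm.asymptotic_fixed_point(0.4, mF_ss=0.42, rhoF_ss=1.0)
        assert sol.m_ss == 0.42 and sol.converged

    def test_active_only_low_load_matches_scalar_root(self):
        sol = gm.asymptotic_fixed_point(0.05, rhoF_ss=0.0, m_init=0.9)
        assert sol.converged
        assert abs(sol.m_ss - gm.scalar_overlap_root(0.05, 1.5)) < 1e-2

    def test_ungated_overload_collapses(self):
        sol = gm.asymptotic_fixed_point(0.4, rhoF_ss=0.0, m_init=0.3)
        assert sol.converged and sol.m_ss < 0.15

    def test_band_endpoints_continuous_in_mF(self):
        """Fine mF sweep: the solved branch varies continuously except at a
        single fold where the active population switches branch (the static
        equations are bistable in a narrow mF window)."""
        ms, m_init = [], 0.3
        for mF in np.linspace(0.2, 0.9, 57):
            sol = gm.asymptotic_fixed_point(0.4, mF_ss=mF, rhoF_ss=0.5, qF_ss=0.8,
                                            m_init=m_init)
            ms.append(sol.m_ss)
            m_init = sol.m_ss
        jumps = np.abs(np.diff(ms))
        assert np.sum(jumps > 0.05) <= 1  # at most the one branch switch
        assert np.median(jumps) < 0.02
        assert ms[-1] > ms[0]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gm.asymptotic_fixed_point(0.4, mF_ss=1.5, rhoF_ss=0.5)
        with pytest.raises(ValueError):
            gm.asymptotic_fixed_point(0.4, mF_ss=0.5, rhoF_ss=1.2)
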