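"""Dynamical mean-field theory of the gated network.

In the thermodynamic limit (N, P -> infinity at fixed load alpha = P/N) the
many-body dynamics map onto a self-consistent single-site process

    dx/dt = sigma(z) * [ -x + (g/sqrt(alpha)) xi m(t)
                          + g sqrt(alpha) int_0^t Ktilde(t,u) phi(u) du
                          + eta_x(t) ]
    tau_z dz/dt = -z + eta_z(t)

driven by colored Gaussian noises with

    <eta_z(t) eta_z(t')> = C_phi(t,t'),
    <eta_x(t) eta_x(t')> = g^2 [K C_phi K^T](t,t'),   K = delta + Ktilde,

where C_phi(t,t') = <phi(t) phi(t')> and Ktilde is the causal Volterra
resolvent of (g/sqrt(alpha)) R, with R(t,t') = d<phi(t)>/dh_x(t') the
response to a field inside the gated bracket.  (The network carries no
autapses, so no instantaneous self-term appears in the drive; the delta
part of K survives only in the noise.)  The order parameters
{m, C_phi, R} are closed by damped
fixed-point iteration over a Monte Carlo ensemble of M sample paths.

The time-asymptotic solver reduces the same self-consistency to static
scalar equations under a fixed-point ansatz, parameterized by the imposed
overlap and fraction of the gate-closed sub-population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .model import gate

__all__ = [
    "DMFTState",
    "AsymptoticSolution",
    "sample_gaussian_paths",
    "single_site_integrate",
    "estimate_response",
    "novikov_response",
    "update_propagator",
    "memory_kernel",
    "noise_covariance",
    "solve_dmft",
    "scalar_overlap_root",
    "asymptotic_fixed_point",
    "mss_band",
]


@dataclass
class DMFTState:
    """Discretized two-time solution of the self-consistency loop."""

    tgrid: np.ndarray
    m: np.ndarray
    C_phi: np.ndarray  # (n, n) symmetric, |entries| <= 1
    R: np.ndarray  # (n, n) strictly lower triangular response
    G: np.ndarray  # (n, n) propagator (g/sqrt(alpha)) (I/dt + Ktilde)
    K_tilde: np.ndarray  # regular part of the retarded kernel resolvent
    cov_x: np.ndarray
    cov_z: np.ndarray
    M: int
    iter_count: int
    residual: float
    residual_history: np.ndarray
    converged: bool


@dataclass
class AsymptoticSolution:
    """Fixed point of the time-asymptotic (static) self-consistency."""

    alpha: float
    g: float
    gamma: float
    mF_ss: float
    rhoF_ss: float
    m_ss: float
    mA_ss: float
    C_ss: float  # static self-overlap q = <phi^2>
    chi: float  # static integrated response of the active population
    converged: bool


# ---------------------------------------------------------------------------
# noise paths and kernels


def _stabilized_cholesky(cov: np.ndarray, jitter_scale: float = 1e-10) -> np.ndarray:
    n = cov.shape[0]
    jitter = jitter_scale * max(np.trace(cov) / n, 1e-300)
    for _ in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    # eigenvalue clipping fallback for badly conditioned covariances
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def sample_gaussian_paths(
    cov: np.ndarray,
    M: int,
    rng: np.random.Generator | int | None = None,
    normals: np.ndarray | None = None,
    jitter_scale: float = 1e-10,
) -> np.ndarray:
    """M sample paths of a zero-mean Gaussian process with covariance ``cov``.

    Positive semidefiniteness is enforced by a small diagonal jitter
    (eigenvalue clipping as fallback).  Pass ``normals`` (n, M standard
    normals) to reuse the same underlying randomness across calls (common
    random numbers).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be symmetric")
    if M < 1:
        raise ValueError("M must be >= 1")
    if not np.any(cov):
        return np.zeros((M, cov.shape[0]))
    L = _stabilized_cholesky(cov, jitter_scale)
    if normals is None:
        normals = np.random.default_rng(rng).standard_normal((cov.shape[0], M))
    return (L @ normals).T


def memory_kernel(R: np.ndarray, a: float, dt: float) -> np.ndarray:
    """Causal Volterra resolvent Ktilde = a R + a dt R @ Ktilde.

    ``a = g / sqrt(alpha)`` is the gain of the uncondensed-pattern feedback
    loop.  Ktilde is strictly lower triangular, like R.
    """
    n = R.shape[0]
    A = np.eye(n) - a * dt * np.tril(R, -1)
    Kt = solve_triangular(A, a * np.tril(R, -1), lower=True, unit_diagonal=True)
    return np.tril(Kt, -1)


def noise_covariance(C_phi: np.ndarray, K_tilde: np.ndarray, g: float, dt: float) -> np.ndarray:
    """cov_x = g^2 [ (delta + Ktilde) C_phi (delta + Ktilde)^T ] discretized.

    The delta parts are handled analytically; equivalently
    alpha * dt^2 * G C_phi G^T with G = (g/sqrt(alpha)) (I/dt + Ktilde).
    """
    KC = dt * (K_tilde @ C_phi)
    cov = C_phi + KC + KC.T + dt * (KC @ K_tilde.T)
    cov = g * g * 0.5 * (cov + cov.T)
    return cov


def update_propagator(R: np.ndarray, dt: float) -> np.ndarray:
    """Forward time-stepping of dG(t,t')/dt = delta(t-t') + int du R(t,u) G(u,t').

    The delta is integrated as a unit jump at t = t' (G(t',t') = 1); with
    R = 0 this reduces to the step kernel Theta(t-t').  Strictly causal.
    """
    n = R.shape[0]
    G = np.zeros((n, n))
    for k in range(n):
        G[k, k] = 1.0
        if k + 1 < n:
            G[k + 1, : k + 1] = G[k, : k + 1] + dt * dt * (R[k] @ G[:, : k + 1])
    return np.tril(G)


# ---------------------------------------------------------------------------
# single-site process


def single_site_integrate(
    eta_x: np.ndarray,
    eta_z: np.ndarray,
    xi: np.ndarray,
    m: np.ndarray,
    K_tilde: np.ndarray,
    params: dict,
    dt: float,
    x0: np.ndarray,
    z0: np.ndarray,
    h_ext: np.ndarray | None = None,
    phi_fn=np.tanh,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler integration of M effective single-site paths.

    ``params`` carries {alpha, g, gamma, tau_z}.  ``h_ext`` is an optional
    external field (length n) added inside the gated bracket, used to
    measure the response function.  Returns (X, Phi), each (M, n).
    """
    alpha, g = params["alpha"], params["g"]
    gamma, tau_z = params["gamma"], params["tau_z"]
    a = g / np.sqrt(alpha)
    b = g * np.sqrt(alpha)
    M, n = eta_x.shape
    X = np.empty((M, n))
    Phi = np.empty((M, n))
    x = np.asarray(x0, dtype=float).copy()
    z = np.asarray(z0, dtype=float).copy()
    for k in range(n):
        X[:, k] = x
        phi = phi_fn(x)
        Phi[:, k] = phi
        if k == n - 1:
            break
        h_ret = b * dt * (Phi[:, : k + 1] @ K_tilde[k, : k + 1])
        drift = -x + a * xi * m[k] + h_ret + eta_x[:, k]
        if h_ext is not None:
            drift = drift + h_ext[k]
        sig = 0.5 if gamma == 0 else gate(z, gamma)
        x = x + dt * sig * drift
        z = z + (dt / tau_z) * (-z + eta_z[:, k])
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite single-site path at step {k + 1}")
    return X, Phi


def estimate_response(
    integrate_fn,
    n: int,
    eps: float,
    dt: float,
    t_primes: np.ndarray | None = None,
) -> np.ndarray:
    """Response R(t,t') = [<phi(t)>_pert - <phi(t)>]/eps by impulse reruns.

    ``integrate_fn(h_ext) -> mean phi path`` must reuse the same random
    numbers for every call (common random numbers), so the Monte Carlo
    noise cancels at first order.  The impulse at t' has area ``eps``
    (height eps/dt for one step).  If ``t_primes`` is given, only those
    columns are measured and the rest filled by linear interpolation
    along t' at fixed lag.
    """
    if eps == 0:
        raise ValueError("perturbation eps must be nonzero")
    base = integrate_fn(None)
    cols = np.arange(n - 1) if t_primes is None else np.asarray(t_primes, dtype=int)
    R = np.zeros((n, n))
    for tp in cols:
        h = np.zeros(n)
        h[tp] = eps / dt
        pert = integrate_fn(h)
        R[tp + 1 :, tp] = (pert[tp + 1 :] - base[tp + 1 :]) / eps
    if t_primes is not None and len(cols) < n - 1:
        R = _interp_response_columns(R, cols, n)
    return np.tril(R, -1)


def _interp_response_columns(R: np.ndarray, cols: np.ndarray, n: int) -> np.ndarray:
    """Fill unmeasured t' columns by interpolating along t' at fixed lag t-t'."""
    full = np.zeros((n, n))
    lags = np.arange(1, n)
    for lag in lags:
        valid = cols[cols + lag < n]
        if len(valid) == 0:
            continue
        vals = R[valid + lag, valid]
        tps = np.arange(n - lag)
        full[tps + lag, tps] = np.interp(tps, valid, vals)
    return np.tril(full, -1)


def novikov_response(
    Phi: np.ndarray,
    eta_x: np.ndarray,
    cov_x: np.ndarray,
    dt: float,
    ridge: float = 1e-3,
) -> np.ndarray:
    """Response from noise-path correlations (Novikov/Furutsu identity).

    For Gaussian eta_x entering exactly like the perturbing field,
    E[phi(t) eta_x(t')] = int du cov_x(t',u) R(t,u); each row of R is
    recovered by solving the (ridge-regularized) discretized linear system
    restricted to the causal block u < t.
    """
    M, n = Phi.shape
    B = Phi.T @ eta_x / M  # (n, n): B[t, j] = E[phi_t eta_j]
    lam = ridge * dt * max(np.trace(cov_x) / n, 1e-300)
    R = np.zeros((n, n))
    for t in range(1, n):
        A = dt * cov_x[:t, :t] + lam * np.eye(t)
        R[t, :t] = np.linalg.solve(A, B[t, :t])
    return np.tril(R, -1)


# ---------------------------------------------------------------------------
# self-consistency loop


def _cue_coefficient(xi: np.ndarray, eta0: np.ndarray, m0: float) -> float:
    u = xi * eta0
    lo, hi = 0.0, 20.0
    if np.mean(np.tanh(hi + u)) <= m0:
        raise ValueError(f"initial overlap {m0} unreachable")
    if np.mean(np.tanh(u)) >= m0:
        return 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.mean(np.tanh(mid + u)) < m0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_dmft(
    alpha: float,
    g: float = 1.5,
    gamma: float = 0.0,
    tau_z: float = 1.0,
    m0: float = 0.65,
    T: float = 50.0,
    dt: float = 0.2,
    M: int = 2000,
    tol: float = 1e-3,
    damping: float = 0.5,
    max_iter: int = 40,
    seed: int | None = 0,
    ridge: float = 1e-3,
    response_method: str = "novikov",
    impulse_eps: float = 1e-3,
    impulse_stride: int = 1,
) -> DMFTState:
    """Damped fixed-point iteration of the DMFT self-consistency.

    The ensemble of M paths shares one set of standard normal draws across
    iterations (common random numbers), so the loop converges to the fixed
    point of a *fixed* finite-M estimator rather than chasing Monte Carlo
    noise.  The initial condition mirrors the many-body cue protocol
    (x(0) = c1 xi + eta with the realized overlap tuned to m0, z(0)
    standard normal).

    ``response_method`` selects the estimator for R: ``"novikov"``
    (noise-path correlations; cheap, adequate at order-one alpha) or
    ``"impulse"`` (perturbed re-simulation with common random numbers;
    slower but nearly noise-free, needed at small alpha where the
    resolvent amplifies estimator noise exponentially).  With
    ``impulse_stride > 1`` only every stride-th perturbation time is
    simulated and the rest interpolated at fixed lag.
    """
    if min(alpha, g, tau_z, T, dt, M) <= 0:
        raise ValueError("alpha, g, tau_z, T, dt, M must all be positive")
    n = int(round(T / dt)) + 1
    tgrid = np.arange(n) * dt
    params = {"alpha": alpha, "g": g, "gamma": gamma, "tau_z": tau_z}
    a = g / np.sqrt(alpha)

    rng = np.random.default_rng(seed)
    xi = rng.integers(0, 2, size=M) * 2.0 - 1.0
    eta0 = rng.standard_normal(M)
    z0 = rng.standard_normal(M)
    Zx = rng.standard_normal((n, M))
    Zz = rng.standard_normal((n, M))
    c1 = _cue_coefficient(xi, eta0, m0)
    x0 = c1 * xi + eta0

    # initial guesses: constant overlap, rank-one correlation, no memory
    q0 = float(np.mean(np.tanh(x0) ** 2))
    m = np.full(n, m0)
    C_phi = np.full((n, n), q0)
    R = np.zeros((n, n))
    K_tilde = np.zeros((n, n))

    resid_hist = []
    converged = False
    cov_x = noise_covariance(C_phi, K_tilde, g, dt)
    for it in range(1, max_iter + 1):
        eta_x = sample_gaussian_paths(cov_x, M, normals=Zx)
        eta_z = sample_gaussian_paths(C_phi, M, normals=Zz)
        _, Phi = single_site_integrate(
            eta_x, eta_z, xi, m, K_tilde, params, dt, x0, z0
        )
        m_new = (xi[:, None] * Phi).mean(axis=0)
        C_new = Phi.T @ Phi / M
        if response_method == "novikov":
            R_new = novikov_response(Phi, eta_x, cov_x, dt, ridge)
        elif response_method == "impulse":

            def integrate_fn(h_ext, _ex=eta_x, _ez=eta_z):
                _, P_ = single_site_integrate(
                    _ex, _ez, xi, m, K_tilde, params, dt, x0, z0, h_ext=h_ext
                )
                return P_.mean(axis=0)

            R_new = estimate_response(
                integrate_fn, n, impulse_eps, dt,
                t_primes=np.arange(0, n - 1, impulse_stride),
            )
        else:
            raise ValueError(f"unknown response_method {response_method!r}")

        resid = float(np.max(np.abs(m_new - m)))
        resid_hist.append(resid)
        d = damping
        m = (1 - d) * m + d * m_new
        C_phi = (1 - d) * C_phi + d * C_new
        R = (1 - d) * R + d * R_new
        K_tilde = memory_kernel(R, a, dt)
        cov_x = noise_covariance(C_phi, K_tilde, g, dt)
        if resid < tol:
            converged = True
            break

    G = (g / np.sqrt(alpha)) * (np.eye(n) / dt + K_tilde)
    return DMFTState(
        tgrid=tgrid,
        m=m,
        C_phi=C_phi,
        R=R,
        G=G,
        K_tilde=K_tilde,
        cov_x=cov_x,
        cov_z=C_phi,
        M=M,
        iter_count=it,
        residual=resid_hist[-1] if resid_hist else np.inf,
        residual_history=np.array(resid_hist),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# time-asymptotic (static) self-consistency


def scalar_overlap_root(alpha: float, g: float, tol: float = 1e-12) -> float:
    """Noise-free condensed-limit overlap: root of m = tanh((g/sqrt(alpha)) m).

    In the alpha -> 0 limit the uncondensed noise and memory kernel
    decouple and the DMFT steady state reduces to this scalar
    self-consistency.
    """
    c = g / np.sqrt(alpha)
    m = 1.0
    for _ in range(10000):
        m_new = np.tanh(c * m)
        if abs(m_new - m) < tol:
            return float(m_new)
        m = m_new
    return float(m)


def _solve_site(h: np.ndarray, B: float) -> np.ndarray:
    """Roots of x = h + B tanh(x), continued from x = h (damped iteration)."""
    x = h.copy()
    for _ in range(500):
        x_new = 0.5 * x + 0.5 * (h + B * np.tanh(x))
        if np.max(np.abs(x_new - x)) < 1e-12:
            return x_new
        x = x_new
    return x


def asymptotic_fixed_point(
    alpha: float,
    g: float = 1.5,
    gamma: float = np.inf,
    mF_ss: float = 0.0,
    rhoF_ss: float = 0.0,
    qF_ss: float | None = None,
    n_quad: int = 81,
    damping: float = 0.3,
    tol: float = 1e-9,
    max_iter: int = 4000,
    m_init: float | None = None,
) -> AsymptoticSolution:
    """Static self-consistency under a stable-fixed-point ansatz.

    The gate-closed sub-population contributes an imposed overlap
    ``mF_ss`` with weight ``rhoF_ss`` (and frozen self-overlap ``qF_ss``,
    defaulting to the active population's); the active population sits at
    fixed points of x = (g/sqrt(alpha)) xi m + B tanh(x) + sqrt(Sigma) w,
    with the static memory-kernel closure B = g sqrt(alpha) chi_K,
    chi_K = a chi / (1 - a chi), Sigma = g^2 (1 + chi_K)^2 q, and chi the
    static susceptibility of the active sites.  Solved by damped iteration
    with Gauss-Hermite quadrature over the static Gaussian field.
    """
    if not (0.0 <= rhoF_ss <= 1.0) or abs(mF_ss) > 1.0:
        raise ValueError("need 0 <= rhoF_ss <= 1 and |mF_ss| <= 1")
    if rhoF_ss == 1.0:
        return AsymptoticSolution(alpha, g, gamma, mF_ss, 1.0, mF_ss, np.nan,
                                  qF_ss if qF_ss is not None else mF_ss**2,
                                  0.0, True)
    a = g / np.sqrt(alpha)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    rhoA = 1.0 - rhoF_ss

    m = m_init if m_init is not None else max(rhoF_ss * mF_ss + rhoA * 0.5, 0.05)
    qA, chi = 0.5, 0.0
    converged = False
    for _ in range(max_iter):
        chi_K = a * chi / max(1.0 - a * chi, 1e-3)
        B = g * np.sqrt(alpha) * chi_K  # static memory-kernel self-interaction
        qF = qA if qF_ss is None else qF_ss
        q_tot = rhoF_ss * qF + rhoA * qA
        Sigma = (g * (1.0 + chi_K)) ** 2 * q_tot
        h = a * m + np.sqrt(max(Sigma, 0.0)) * nodes  # xi = +1 by symmetry
        x_star = _solve_site(h, B)
        phi = np.tanh(x_star)
        dphi = 1.0 - phi * phi
        mA = float(weights @ phi)
        qA_new = float(weights @ (phi * phi))
        denom = np.clip(1.0 - B * dphi, 1e-3, None)
        chi_new = float(weights @ (dphi / denom))
        chi_new = min(chi_new, 0.95 / a)  # keep the geometric resummation finite
        m_new = rhoF_ss * mF_ss + rhoA * mA

        resid = max(abs(m_new - m), abs(qA_new - qA), abs(chi_new - chi))
        m = (1 - damping) * m + damping * m_new
        qA = (1 - damping) * qA + damping * qA_new
        chi = (1 - damping) * chi + damping * chi_new
        if resid < tol:
            converged = True
            break
    return AsymptoticSolution(
        alpha=alpha, g=g, gamma=gamma, mF_ss=mF_ss, rhoF_ss=rhoF_ss,
        m_ss=float(m), mA_ss=float(mA), C_ss=float(q_tot), chi=float(chi),
        converged=converged,
    )


def frozen_population_stats(
    alpha: float,
    m0: float,
    N: int = 500,
    n_reps: int = 4,
    g: float = 1.5,
    tau_z: float = 1.0,
    T: float = 2000.0,
    dt: float = 0.2,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Steady-state (mF, rhoF, qF) of the gate-closed sub-population.

    Extracted from binary-gated many-body runs cued at overlap ``m0``:
    overlap, fraction, and self-overlap <phi^2> of the neurons whose gate
    is closed at the final time, averaged over realizations.
    """
    from .simulate import SimConfig, run_ensemble

    cfg = SimConfig(dt=dt, T=T, convergence_tol=1e-8)
    P = max(1, int(round(alpha * N)))
    out = run_ensemble(N, P, np.inf, m0, n_reps, cfg, g=g, tau_z=tau_z,
                       seed=seed, return_states=True)
    phi = np.tanh(out["X"])
    closed = out["Z"] < 0
    mFs, rhos, qFs = [], [], []
    for r in range(n_reps):
        c = closed[r]
        rhos.append(float(c.mean()))
        if c.any():
            mFs.append(float(np.mean(out["Xi"][r, 0][c] * phi[r][c])))
            qFs.append(float(np.mean(phi[r][c] ** 2)))
    if not mFs:
        return float("nan"), 0.0, float("nan")
    return float(np.mean(mFs)), float(np.mean(rhos)), float(np.mean(qFs))


def mss_band(
    alphas,
    N: int = 500,
    n_reps: int = 4,
    m0_extremes: tuple[float, float] = (0.01, 0.995),
    g: float = 1.5,
    seed: int = 0,
    T: float = 2000.0,
):
    """Steady-state overlap band of the binary-gated network vs memory load.

    For each alpha the band endpoints come from the time-asymptotic DMFT
    solved at the two extreme closed-population overlaps mF_ss, extracted
    from many-body runs cued at minimal and maximal initial overlap
    (m0 near 0 and near 1).  Returns a table of
    (alpha, mF_lo, mF_hi, m_ss_low, m_ss_high).
    """
    import pandas as pd

    rows = []
    for i, alpha in enumerate(alphas):
        sols, mFs = [], []
        for j, m0 in enumerate(m0_extremes):
            mF, rhoF, qF = frozen_population_stats(
                alpha, m0, N=N, n_reps=n_reps, g=g, T=T,
                seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % 2**31),
            )
            mFs.append(mF)
            sol = asymptotic_fixed_point(
                alpha, g=g, mF_ss=mF, rhoF_ss=rhoF, qF_ss=qF,
                m_init=rhoF * mF + (1 - rhoF) * max(mF, 0.1),
            )
            sols.append(sol.m_ss)
        rows.append({
            "alpha": alpha, "mF_lo": min(mFs), "mF_hi": max(mFs),
            "m_ss_low": min(sols), "m_ss_high": max(sols),
        })
    return pd.DataFrame(rows)
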