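"""Euler integration of the gated dynamics, cued initial conditions, and
retrieval observables.

The coupled dynamics integrated here are

    dx_i/dt = sigma(z_i) * ( -x_i + (g/sqrt(PN)) sum_{j != i} J_ij phi(x_j) )
    tau_z dz_i/dt = -z_i + (1/sqrt(N)) sum_j W_ij phi(x_j)

with phi = tanh and the logistic gate sigma of steepness gamma.  The gate
multiplies the *entire* drift, so sigma(z_i) = 0 freezes neuron i exactly;
gamma = 0 reproduces the ungated Amari-Hopfield network up to the global
time rescaling t -> t/2 (sigma = 1/2).

Retrieval is quantified by the overlap (Mattis magnetization)
m_mu(t) = (1/N) sum_i xi_i^mu phi(x_i(t)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    BINARY_GATE,
    NetworkSpec,
    NetworkState,
    activation,
    gate,
    recurrent_drive,
    sample_patterns,
)

__all__ = [
    "SimConfig",
    "TrajectoryRecord",
    "InfeasibleOverlapError",
    "overlap",
    "construct_cued_state",
    "euler_step",
    "run_trajectory",
    "subpopulation_overlaps",
    "gate_population_trace",
    "run_ensemble",
]


class InfeasibleOverlapError(ValueError):
    """Requested initial overlap exceeds what the drawn cue noise allows."""

    def __init__(self, target: float, max_achievable: float):
        self.target = target
        self.max_achievable = max_achievable
        super().__init__(
            f"target overlap {target:.4f} unreachable; "
            f"maximum achievable with this noise draw is {max_achievable:.4f}"
        )


@dataclass
class SimConfig:
    """Numerical integration settings.

    ``convergence_tol`` (on max_i |dx_i|/dt) enables early stopping once the
    state is stationary; leave ``None`` to integrate the full horizon, as
    done when reproducing the reference phase diagrams.
    """

    dt: float = 0.2
    T: float = 2000.0
    record_every: int = 10
    convergence_tol: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be a positive integer")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class TrajectoryRecord:
    """Recorded time series of overlaps and (optionally) states and gates."""

    times: np.ndarray
    m: np.ndarray  # (n_records, n_tracked)
    mF: np.ndarray | None = None
    mA: np.ndarray | None = None
    rhoF: np.ndarray | None = None
    rhoA: np.ndarray | None = None
    gate_trace: np.ndarray | None = None  # (n_records, N) boolean open-gate mask
    x_snapshots: np.ndarray | None = None
    z_snapshots: np.ndarray | None = None
    converged: bool = False

    @property
    def m_final(self) -> np.ndarray:
        """Overlap(s) at the last recorded time (steady state if converged)."""
        return self.m[-1]


def overlap(pattern: np.ndarray, x: np.ndarray) -> float:
    """Mattis magnetization m = (1/N) sum_i xi_i tanh(x_i)."""
    pattern = np.asarray(pattern, dtype=float)
    x = np.asarray(x, dtype=float)
    if pattern.shape[-1] != x.shape[-1]:
        raise ValueError("pattern and state must have equal length")
    return float(np.mean(pattern * activation(x), axis=-1))


def _solve_cue_coefficient(
    pattern: np.ndarray,
    eta: np.ndarray,
    target_m0: float,
    c_max: float = 20.0,
    tol: float = 1e-3,
) -> float:
    """Bisection for c such that overlap(pattern, c*pattern + eta) = target_m0.

    The realized overlap (1/N) sum tanh(c + xi_i eta_i) is strictly
    increasing in c, so bisection on [0, c_max] is exact.  Targets at or
    below the c = 0 overlap map to c = 0 (undirected cue).
    """
    u = pattern * eta  # overlap is mean(tanh(c + u))

    def realized(c: float) -> float:
        return float(np.mean(np.tanh(c + u)))

    m_max = realized(c_max)
    if target_m0 >= m_max:
        raise InfeasibleOverlapError(target_m0, m_max)
    if target_m0 <= realized(0.0):
        return 0.0
    lo, hi = 0.0, c_max
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_m0:
            lo = mid
        else:
            hi = mid
        if abs(realized(mid) - target_m0) < 0.1 * tol:
            break
    return 0.5 * (lo + hi)


def construct_cued_state(
    pattern: np.ndarray,
    target_m0: float,
    rng: np.random.Generator | int | None = None,
    c_max: float = 20.0,
    tol: float = 1e-3,
    with_z: bool = True,
) -> NetworkState:
    """Initial condition x(0) = c1*xi + eta with the realized overlap tuned.

    ``eta`` is iid standard normal; ``c1`` is found by bisection so that
    overlap(xi, x(0)) matches ``target_m0`` within ``tol``.  ``z(0)`` is iid
    standard normal (drawn from the same stream) when ``with_z``.
    """
    rng = np.random.default_rng(rng)
    pattern = np.asarray(pattern, dtype=float)
    N = pattern.shape[0]
    eta = rng.standard_normal(N)
    c1 = _solve_cue_coefficient(pattern, eta, target_m0, c_max, tol)
    x0 = c1 * pattern + eta
    z0 = rng.standard_normal(N) if with_z else None
    return NetworkState(x=x0, z=z0, t=0.0)


def euler_step(state: NetworkState, spec: NetworkSpec, dt: float) -> NetworkState:
    """One explicit Euler step of the coupled gated dynamics."""
    phi = activation(state.x)
    drive = recurrent_drive(spec, phi)
    if spec.gamma == 0:
        sig = 0.5
    else:
        if state.z is None:
            raise ValueError("gated dynamics (gamma != 0) require a z state")
        sig = gate(state.z, spec.gamma)
    x_new = state.x + dt * sig * (-state.x + drive)
    if state.z is not None and spec.W is not None:
        u = (spec.W @ phi) / np.sqrt(spec.N)
        z_new = state.z + (dt / spec.tau_z) * (-state.z + u)
    else:
        z_new = None if state.z is None else state.z.copy()
    if not (np.all(np.isfinite(x_new)) and (z_new is None or np.all(np.isfinite(z_new)))):
        raise FloatingPointError(
            f"non-finite state after Euler step at t={state.t + dt:.3f} "
            f"(max |x|={np.max(np.abs(state.x)):.3g}); reduce dt"
        )
    return NetworkState(x=x_new, z=z_new, t=state.t + dt)


def _subpop_stats(phi: np.ndarray, z: np.ndarray, pattern: np.ndarray):
    """(mF, mA, rhoF, rhoA) from precomputed phi; empty populations give nan."""
    open_mask = z >= 0  # sigma in {1, 1/2}; the z == 0 tie is measure zero
    N = phi.shape[0]
    nA = int(open_mask.sum())
    nF = N - nA
    xi_phi = pattern * phi
    mA = float(xi_phi[open_mask].mean()) if nA else float("nan")
    mF = float(xi_phi[~open_mask].mean()) if nF else float("nan")
    return mF, mA, nF / N, nA / N


def subpopulation_overlaps(
    x: np.ndarray,
    z: np.ndarray,
    pattern: np.ndarray,
    gamma: float = BINARY_GATE,
):
    """Closed/active sub-population overlaps in the binary gating limit.

    Neurons are partitioned by their binary gate state (open: sigma(z)=1,
    i.e. z > 0; closed: sigma(z)=0).  Returns ``(mF, mA, rhoF, rhoA)`` with
    the exact decomposition m = rhoF*mF + rhoA*mA.  An empty sub-population
    reports ``nan`` with weight 0.
    """
    if not np.isinf(gamma):
        raise ValueError("sub-population overlaps are defined in the binary gate limit")
    return _subpop_stats(activation(np.asarray(x, float)), np.asarray(z, float),
                         np.asarray(pattern, float))


def gate_population_trace(traj: TrajectoryRecord) -> np.ndarray:
    """Number of neurons whose binary gate flipped between consecutive records.

    Reaches 0 once the dynamics (and hence the sub-populations) are
    stationary.
    """
    if traj.gate_trace is None:
        raise ValueError("trajectory was recorded without gate_trace")
    g = traj.gate_trace
    return (g[1:] != g[:-1]).sum(axis=1)


def run_trajectory(
    spec: NetworkSpec,
    init: NetworkState,
    cfg: SimConfig,
    tracked_patterns: tuple[int, ...] = (0,),
    record_gates: bool = False,
    record_states: bool = False,
) -> TrajectoryRecord:
    """Integrate the network and record overlap observables.

    Observables are recorded every ``cfg.record_every`` steps (and at the
    final step).  In the binary gating limit the closed/active
    sub-population decomposition of the first tracked pattern is recorded as
    well.  With ``cfg.convergence_tol`` set, integration stops early once
    max_i |dx_i| / dt falls below the tolerance.
    """
    Xi = spec.patterns.patterns
    tracked = Xi[list(tracked_patterns)]  # (n_tracked, N)
    binary = np.isinf(spec.gamma)
    gated = spec.gamma != 0
    if gated and (init.z is None or spec.W is None):
        raise ValueError("gated dynamics require z(0) and W")

    x = init.x.astype(float).copy()
    z = None if init.z is None else init.z.astype(float).copy()
    N = spec.N
    coef = spec.g / np.sqrt(spec.P * spec.N)
    diag = np.sum(Xi**2, axis=0)  # autapse term, excluded from the drive
    sqN = np.sqrt(N)

    times, m_rec, gate_rec = [], [], []
    sub_rec: list[tuple] = []
    x_rec, z_rec = [], []

    def record(t: float, phi: np.ndarray) -> None:
        times.append(t)
        m_rec.append(tracked @ phi / N)
        if binary:
            sub_rec.append(_subpop_stats(phi, z, tracked[0]))
            if record_gates:
                gate_rec.append(z >= 0)
        if record_states:
            x_rec.append(x.copy())
            if z is not None:
                z_rec.append(z.copy())

    dt = cfg.dt
    converged = False
    phi = activation(x)
    record(init.t, phi)
    for k in range(1, cfg.n_steps + 1):
        sig = gate(z, spec.gamma) if gated else 0.5
        dx = dt * sig * (-x + coef * ((phi @ Xi.T) @ Xi - diag * phi))
        if z is not None and spec.W is not None:
            z += (dt / spec.tau_z) * (-z + (spec.W @ phi) / sqN)
        x += dx
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite state at t={init.t + k * dt:.2f}; reduce dt"
            )
        phi = activation(x)
        last = k == cfg.n_steps
        if cfg.convergence_tol is not None and np.max(np.abs(dx)) / dt < cfg.convergence_tol:
            converged = True
        if k % cfg.record_every == 0 or last or converged:
            record(init.t + k * dt, phi)
        if converged:
            break

    sub = np.array(sub_rec) if sub_rec else None
    return TrajectoryRecord(
        times=np.array(times),
        m=np.array(m_rec),
        mF=sub[:, 0] if sub is not None else None,
        mA=sub[:, 1] if sub is not None else None,
        rhoF=sub[:, 2] if sub is not None else None,
        rhoA=sub[:, 3] if sub is not None else None,
        gate_trace=np.array(gate_rec) if gate_rec else None,
        x_snapshots=np.array(x_rec) if x_rec else None,
        z_snapshots=np.array(z_rec) if z_rec else None,
        converged=converged,
    )


def run_ensemble(
    N: int,
    P: int,
    gamma: float,
    m0: float,
    n_reps: int,
    cfg: SimConfig,
    g: float = 1.5,
    tau_z: float = 1.0,
    kind: str = "binary",
    seed: int | None = 0,
    record_every: int | None = None,
    return_states: bool = False,
) -> dict:
    """Integrate ``n_reps`` independent quenched-disorder realizations at once.

    All quenched disorder (patterns, W, cue noise, z(0)) is redrawn per
    realization from child streams of ``seed``.  States are advanced in a
    single batched loop, which is the workhorse behind phase sweeps and
    capacity estimation.  Returns final overlaps with the cued pattern and,
    if ``record_every`` is given, the recorded overlap time series.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    gated = gamma != 0

    Xi = np.empty((n_reps, P, N))
    X = np.empty((n_reps, N))
    Z = np.empty((n_reps, N)) if gated else None
    W = np.empty((n_reps, N, N)) if gated else None
    for r, child in enumerate(children):
        sub = child.spawn(3)
        Xi[r] = sample_patterns(N, P, kind, np.random.default_rng(sub[0])).patterns
        state = construct_cued_state(Xi[r, 0], m0, np.random.default_rng(sub[1]),
                                     with_z=gated)
        X[r] = state.x
        if gated:
            Z[r] = state.z
            W[r] = np.random.default_rng(sub[2]).standard_normal((N, N))

    coef = g / np.sqrt(P * N)
    diag = np.sum(Xi**2, axis=1)  # (R, N) autapse weights, excluded
    sqN = np.sqrt(N)
    dt = cfg.dt
    times, m_t = [], []
    Phi = np.tanh(X)

    def m1(Phi_):
        return np.einsum("rn,rn->r", Xi[:, 0], Phi_) / N

    if record_every:
        times.append(0.0)
        m_t.append(m1(Phi))
    converged = False
    for k in range(1, cfg.n_steps + 1):
        proj = np.matmul(Xi, Phi[:, :, None])  # (R, P, 1)
        drive = coef * (np.matmul(np.swapaxes(Xi, 1, 2), proj)[:, :, 0] - diag * Phi)
        if gated:
            sig = gate(Z, gamma)
            U = np.matmul(W, Phi[:, :, None])[:, :, 0] / sqN
            Z += (dt / tau_z) * (-Z + U)
            dX = dt * sig * (-X + drive)
        else:
            dX = 0.5 * dt * (-X + drive)
        X += dX
        Phi = np.tanh(X)
        if cfg.convergence_tol is not None:
            converged = bool(np.max(np.abs(dX)) / dt < cfg.convergence_tol)
        if record_every and (k % record_every == 0 or k == cfg.n_steps or converged):
            times.append(k * dt)
            m_t.append(m1(Phi))
        if converged:
            break

    out = {"m_final": m1(Phi), "converged": converged,
           "t_final": min(k * dt, cfg.T)}
    if return_states:
        out["X"] = X
        out["Z"] = Z
        out["Xi"] = Xi
    if record_every:
        out["times"] = np.array(times)
        out["m_t"] = np.array(m_t).T  # (n_reps, n_records)
    return out
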