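"""Two-pattern attractor geometry: flow maps, displacement, clustering.

With two stored orthogonal patterns the retrieval dynamics can be tracked
in the overlap plane (m1, m2).  The ungated network funnels every initial
condition into one of four discrete fixed points near (+-1, 0) and
(0, +-1); the binary-gated network instead reaches a continuum of distinct
fixed points ("continuous multistability").  The quenched disorder
(patterns, W, z(0)) is held fixed across the whole grid of initial
conditions -- only x(0) varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import root

from .model import NetworkSpec, NetworkState, gate
from .simulate import InfeasibleOverlapError, SimConfig

__all__ = [
    "FlowField",
    "construct_two_pattern_init",
    "make_overlap_grid",
    "flow_map",
    "cluster_attractors",
]


@dataclass
class FlowField:
    """Endpoints and displacements of trajectories started on an overlap grid."""

    init_targets: np.ndarray  # (n_points, 2) requested (m1_0, m2_0)
    init_realized: np.ndarray  # (n_points, 2)
    endpoints: np.ndarray  # (n_points, 2) realized (m1_T, m2_T)
    displacement: np.ndarray  # (n_points,)
    quenched_seed: int
    gamma: float
    trajectories: np.ndarray | None = None  # (n_points, n_records, 2)
    times: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m1_0": self.init_targets[:, 0],
                "m2_0": self.init_targets[:, 1],
                "m1_T": self.endpoints[:, 0],
                "m2_T": self.endpoints[:, 1],
                "displacement": self.displacement,
            }
        )

    def plus_minus(self, which: str = "endpoints") -> np.ndarray:
        """Coordinates (m+, m-) = (m1 + m2, m1 - m2) used for reporting."""
        m = getattr(self, which)
        return np.stack([m[:, 0] + m[:, 1], m[:, 0] - m[:, 1]], axis=1)


def _realized_overlaps(xi1, xi2, x):
    phi = np.tanh(x)
    return np.array([np.mean(xi1 * phi), np.mean(xi2 * phi)])


def construct_two_pattern_init(
    xi1: np.ndarray,
    xi2: np.ndarray,
    target: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-3,
) -> NetworkState:
    """x(0) = c1 xi1 + c2 xi2 + eta with realized overlaps tuned to ``target``.

    (c1, c2) is found by 2-d root finding against the realized overlaps for
    the drawn noise ``eta``; each component must match within ``tol``.
    No z(0) is attached -- the flow-map protocol fixes z(0) separately.
    """
    rng = np.random.default_rng(rng)
    xi1 = np.asarray(xi1, dtype=float)
    xi2 = np.asarray(xi2, dtype=float)
    N = xi1.shape[0]
    eta = rng.standard_normal(N)
    t = np.asarray(target, dtype=float)

    def resid(c):
        return _realized_overlaps(xi1, xi2, c[0] * xi1 + c[1] * xi2 + eta) - t

    def jac(c):
        dphi = 1.0 - np.tanh(c[0] * xi1 + c[1] * xi2 + eta) ** 2
        return np.array(
            [
                [np.mean(xi1 * xi1 * dphi), np.mean(xi1 * xi2 * dphi)],
                [np.mean(xi2 * xi1 * dphi), np.mean(xi2 * xi2 * dphi)],
            ]
        )

    best = None
    for x0 in (2.0 * t, 2.0 * t + 0.25, np.array([0.5, -0.5])):
        sol = root(resid, x0=x0, jac=jac, method="hybr", tol=1e-12)
        err = float(np.max(np.abs(resid(sol.x))))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err <= tol:
            break
    err, c = best
    if err > tol:
        raise InfeasibleOverlapError(float(np.max(np.abs(t))), float("nan"))
    return NetworkState(x=c[0] * xi1 + c[1] * xi2 + eta, z=None, t=0.0)


def make_overlap_grid(spacing: float = 0.1, radius: float = 0.9) -> np.ndarray:
    """Grid of (m1_0, m2_0) targets covering the feasible overlap diamond
    |m1| + |m2| <= radius."""
    v = np.round(np.arange(-1.0, 1.0 + 1e-9, spacing), 12) + 0.0  # kill -0.0
    pts = np.array([(a, b) for a in v for b in v if abs(a) + abs(b) <= radius])
    return pts


def flow_map(
    spec: NetworkSpec,
    grid: np.ndarray,
    cfg: SimConfig,
    seed: int = 0,
    record_every: int | None = None,
) -> FlowField:
    """Integrate the two-pattern network from every grid initial condition.

    The quenched disorder in ``spec`` (orthogonal pattern pair, W) and a
    single z(0) draw are shared by all grid points; each point gets its own
    cue noise eta from a deterministic child stream of ``seed``.  All
    points are advanced in one batched Euler loop.
    """
    if spec.P != 2:
        raise ValueError("flow maps require a two-pattern network")
    Xi = spec.patterns.patterns
    xi1, xi2 = Xi[0], Xi[1]
    if abs(float(xi1 @ xi2)) > 1e-9:
        raise ValueError("flow maps require an orthogonal pattern pair")
    grid = np.asarray(grid, dtype=float)
    G, N = grid.shape[0], spec.N
    gated = spec.gamma != 0
    if gated and spec.W is None:
        raise ValueError("gated flow map requires W")

    ss = np.random.SeedSequence(seed)
    z_child, *point_children = ss.spawn(G + 1)
    z0 = np.random.default_rng(z_child).standard_normal(N)

    X = np.empty((G, N))
    realized0 = np.empty((G, 2))
    for p, child in enumerate(point_children):
        st = construct_two_pattern_init(xi1, xi2, grid[p], np.random.default_rng(child))
        X[p] = st.x
        realized0[p] = _realized_overlaps(xi1, xi2, st.x)

    Z = np.tile(z0, (G, 1)) if gated else None
    coef = spec.g / np.sqrt(spec.P * N)
    diag = np.sum(Xi**2, axis=0)  # autapse weights, excluded from the drive
    sqN = np.sqrt(N)
    dt = cfg.dt
    Phi = np.tanh(X)
    times, traj = [], []

    def m12(Phi_):
        return np.stack([Phi_ @ xi1 / N, Phi_ @ xi2 / N], axis=1)

    if record_every:
        times.append(0.0)
        traj.append(m12(Phi))
    for k in range(1, cfg.n_steps + 1):
        drive = coef * ((Phi @ Xi.T) @ Xi - diag * Phi)
        if gated:
            sig = gate(Z, spec.gamma)
            U = Phi @ spec.W.T / sqN
            Z += (dt / spec.tau_z) * (-Z + U)
            dX = dt * sig * (-X + drive)
        else:
            dX = 0.5 * dt * (-X + drive)
        X += dX
        Phi = np.tanh(X)
        stop = cfg.convergence_tol is not None and np.max(np.abs(dX)) / dt < cfg.convergence_tol
        if record_every and (k % record_every == 0 or k == cfg.n_steps or stop):
            times.append(k * dt)
            traj.append(m12(Phi))
        if stop:
            break

    endpoints = m12(Phi)
    disp = np.linalg.norm(endpoints - realized0, axis=1)
    return FlowField(
        init_targets=grid,
        init_realized=realized0,
        endpoints=endpoints,
        displacement=disp,
        quenched_seed=spec.seed if spec.seed is not None else -1,
        gamma=spec.gamma,
        trajectories=np.swapaxes(np.array(traj), 0, 1) if traj else None,
        times=np.array(times) if times else None,
    )


def cluster_attractors(
    endpoints: np.ndarray, radius: float = 0.1
) -> tuple[int, np.ndarray, np.ndarray]:
    """Single-linkage clustering of trajectory endpoints in the (m1, m2) plane.

    Two endpoints belong to the same attractor cluster when connected by a
    chain of links shorter than ``radius``.  Returns the cluster count,
    centroids, and per-point membership labels (0-based).
    """
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.ndim != 2 or endpoints.shape[0] == 0:
        raise ValueError("endpoints must be a nonempty (n, 2) array")
    if endpoints.shape[0] == 1:
        return 1, endpoints.copy(), np.zeros(1, dtype=int)
    Zl = linkage(endpoints, method="single")
    labels = fcluster(Zl, t=radius, criterion="distance") - 1
    count = int(labels.max()) + 1
    centers = np.array([endpoints[labels == c].mean(axis=0) for c in range(count)])
    return count, centers, labels
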