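"""Steady-state-overlap phase diagrams, capacity and retrieval boundary.

Sweeps the (memory load alpha, initial overlap m0) plane at fixed gate
steepness gamma, averaging the final overlap over independent
quenched-disorder realizations.  The ungated network (gamma = 0) shows a
sharp retrieval collapse at the critical capacity alpha_c (about 0.13 for
gain g = 1.5), which the binary-gated network bypasses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimConfig, run_ensemble

__all__ = [
    "PhaseGrid",
    "steady_state_overlap_stat",
    "phase_diagram",
    "delta_map",
    "estimate_critical_capacity",
    "estimate_retrieval_boundary",
]


@dataclass
class PhaseGrid:
    """Mean/std of the steady-state overlap over an (alpha, m0) grid."""

    alphas: np.ndarray
    m0s: np.ndarray
    gamma: float
    mss_mean: np.ndarray  # (len(alphas), len(m0s))
    mss_std: np.ndarray
    n_reps: int
    seed_base: int
    N: int = 1000

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (alpha, m0, gamma, mean, std, n)."""
        a, m = np.meshgrid(self.alphas, self.m0s, indexing="ij")
        return pd.DataFrame(
            {
                "alpha": a.ravel(),
                "m0": m.ravel(),
                "gamma": self.gamma,
                "mean": self.mss_mean.ravel(),
                "std": self.mss_std.ravel(),
                "n": self.n_reps,
            }
        )


def _cell_seed(seed_base: int, i: int, j: int) -> int:
    # deterministic per-cell seed; keeps cells independent and reproducible
    return int(np.random.SeedSequence([seed_base, i, j]).generate_state(1)[0] % (2**31))


def steady_state_overlap_stat(
    alpha: float,
    m0: float,
    gamma: float,
    n_reps: int,
    cfg: SimConfig,
    seed_base: int = 0,
    N: int = 1000,
    g: float = 1.5,
    tau_z: float = 1.0,
) -> tuple[float, float]:
    """Mean and std of m(T) over ``n_reps`` quenched-disorder realizations."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    P = max(1, int(round(alpha * N)))
    out = run_ensemble(N, P, gamma, m0, n_reps, cfg, g=g, tau_z=tau_z, seed=seed_base)
    m = out["m_final"]
    return float(np.mean(m)), float(np.std(m))


def phase_diagram(
    alphas: np.ndarray,
    m0s: np.ndarray,
    gamma: float,
    n_reps: int,
    cfg: SimConfig,
    seed_base: int = 0,
    N: int = 1000,
    g: float = 1.5,
    tau_z: float = 1.0,
) -> PhaseGrid:
    """Full (alpha, m0) grid of steady-state overlap statistics.

    Each cell runs its own independent realization batch seeded
    deterministically from ``seed_base`` and the cell indices, so the grid
    is reproducible cell by cell and trivially parallel.
    """
    alphas = np.sort(np.asarray(alphas, dtype=float))
    m0s = np.sort(np.asarray(m0s, dtype=float))
    if alphas.size == 0 or m0s.size == 0:
        raise ValueError("alpha and m0 grids must be nonempty")
    mean = np.empty((alphas.size, m0s.size))
    std = np.empty_like(mean)
    for i, a in enumerate(alphas):
        for j, m0 in enumerate(m0s):
            mean[i, j], std[i, j] = steady_state_overlap_stat(
                a, m0, gamma, n_reps, cfg, _cell_seed(seed_base, i, j), N, g, tau_z
            )
    return PhaseGrid(alphas, m0s, gamma, mean, std, n_reps, seed_base, N)


def delta_map(gated: PhaseGrid, ungated: PhaseGrid) -> np.ndarray:
    """Cellwise overlap difference Delta m_ss = m_ss(gated) - m_ss(ungated)."""
    if not (
        np.array_equal(gated.alphas, ungated.alphas)
        and np.array_equal(gated.m0s, ungated.m0s)
    ):
        raise ValueError("phase grids must share identical (alpha, m0) axes")
    return gated.mss_mean - ungated.mss_mean


def estimate_critical_capacity(
    alphas: np.ndarray,
    cfg: SimConfig,
    gamma: float = 0.0,
    m0: float = 0.95,
    threshold: float = 0.5,
    n_reps: int = 20,
    seed_base: int = 0,
    N: int = 1000,
    g: float = 1.5,
    refine: int = 0,
) -> float:
    """Critical memory load from a 1-d sweep at a high-overlap cue.

    Reports the largest alpha whose mean steady-state overlap exceeds
    ``threshold`` times the retrieval-plateau value (the maximum mean over
    the sweep); ``refine`` additional bisection steps shrink the bracket
    below the grid spacing.  Raises if the sweep does not straddle the
    collapse.
    """
    alphas = np.sort(np.asarray(alphas, dtype=float))

    def mean_at(a: float, i: int) -> float:
        return steady_state_overlap_stat(
            a, m0, gamma, n_reps, cfg, _cell_seed(seed_base, i, 0), N, g
        )[0]

    means = np.array([mean_at(a, i) for i, a in enumerate(alphas)])
    plateau = means.max()
    above = means > threshold * plateau
    if above.all() or not above.any():
        raise ValueError(
            "no retrieval collapse inside the alpha sweep; widen the range "
            f"(means span [{means.min():.3f}, {means.max():.3f}])"
        )
    last_above = int(np.max(np.nonzero(above)))
    lo = alphas[last_above]
    hi = alphas[min(last_above + 1, alphas.size - 1)]
    for r in range(refine):
        mid = 0.5 * (lo + hi)
        if mean_at(mid, 1000 + r) > threshold * plateau:
            lo = mid
        else:
            hi = mid
    return float(lo)


def estimate_retrieval_boundary(grid: PhaseGrid, level: float = 0.5) -> np.ndarray:
    """Critical cue overlap m_c(alpha): smallest m0 whose mean overlap
    exceeds ``level``, linearly interpolated between grid cells.

    Entries are ``nan`` where retrieval never occurs along the m0 column.
    """
    mc = np.full(grid.alphas.size, np.nan)
    for i in range(grid.alphas.size):
        col = grid.mss_mean[i]
        above = col > level
        if not above.any():
            continue
        j = int(np.min(np.nonzero(above)))
        if j == 0:
            mc[i] = grid.m0s[0]
        else:
            # linear interpolation of the level crossing between cells j-1, j
            f = (level - col[j - 1]) / (col[j] - col[j - 1])
            mc[i] = grid.m0s[j - 1] + f * (grid.m0s[j] - grid.m0s[j - 1])
    return mc
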