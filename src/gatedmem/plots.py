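"""Plotting helpers (matplotlib optional; styling intentionally plain)."""

from __future__ import annotations

import numpy as np


def plot_phase_grid(grid, ax=None, **imshow_kwargs):
    """Heatmap of the steady-state overlap over the (alpha, m0) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        grid.mss_mean.T,
        origin="lower",
        aspect="auto",
        extent=(grid.alphas[0], grid.alphas[-1], grid.m0s[0], grid.m0s[-1]),
        vmin=0.0,
        vmax=1.0,
        **imshow_kwargs,
    )
    ax.set_xlabel(r"memory load $\alpha$")
    ax.set_ylabel(r"initial overlap $m(0)$")
    ax.figure.colorbar(im, ax=ax, label=r"$m_{ss}$")
    return ax


def plot_flow_field(ff, ax=None, plus_minus=True):
    """Endpoints and displacement heatmap of a two-pattern flow map.

    With ``plus_minus`` the axes are (m+, m-) = (m1 + m2, m1 - m2).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    start = ff.plus_minus("init_realized") if plus_minus else ff.init_realized
    end = ff.plus_minus("endpoints") if plus_minus else ff.endpoints
    sc = ax.scatter(start[:, 0], start[:, 1], c=ff.displacement, s=18,
                    cmap="viridis")
    ax.quiver(start[:, 0], start[:, 1],
              end[:, 0] - start[:, 0], end[:, 1] - start[:, 1],
              angles="xy", scale_units="xy", scale=1.0, width=3e-3, alpha=0.5)
    ax.plot(end[:, 0], end[:, 1], "k.", ms=8)
    labels = (r"$m_+$", r"$m_-$") if plus_minus else (r"$m_1$", r"$m_2$")
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.figure.colorbar(sc, ax=ax, label=r"$\|\Delta m\|$")
    return ax


def plot_overlap_trajectories(times, m_t, ax=None, **kwargs):
    """Overlap time series: individual runs (thin) and their mean (thick)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m_t = np.atleast_2d(m_t)
    for row in m_t:
        ax.plot(times, row, color="0.7", lw=0.6)
    ax.plot(times, m_t.mean(axis=0), lw=2.0, **kwargs)
    ax.set_xlabel("t")
    ax.set_ylabel("m(t)")
    ax.set_ylim(-1, 1)
    return ax
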