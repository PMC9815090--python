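"""Plot helpers for lifelines, residence distributions and the pool response.

Each function draws on a provided (or fresh) matplotlib Axes and returns it,
so figures compose the usual way.
"""

from __future__ import annotations

import numpy as np

from .arcs import ArcJointStatistics
from .lifelines import Lifeline
from .metabolism import MetabolicTrajectory

__all__ = [
    "plot_lifeline",
    "plot_residence_distributions",
    "plot_arc_statistics",
    "plot_metabolic_response",
]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_lifeline(lifeline: Lifeline, ax=None, spec=None, **kwargs):
    """One parcel's scaled uptake versus time, with regime boundaries."""
    ax = _axes(ax)
    ax.plot(lifeline.times, lifeline.values, lw=0.6, **kwargs)
    lo = spec.starvation_threshold if spec is not None else 0.05
    hi = spec.excess_threshold if spec is not None else 0.95
    for level in (lo, hi):
        ax.axhline(level, color="0.5", ls="--", lw=0.8)
    ax.set_xlabel("time [s]")
    ax.set_ylabel(r"$q_s / q_{s,max}$ [-]")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_residence_distributions(distributions: dict, ax=None, log=False):
    """Residence-time histograms per transition pattern (step outlines)."""
    ax = _axes(ax)
    for pattern, dist in distributions.items():
        if dist.n_visits == 0:
            continue
        ax.stairs(dist.counts, dist.bin_edges, label=pattern)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel(r"$\tau_{reg}$ [s]")
    ax.set_ylabel("counts")
    ax.legend(fontsize="small")
    return ax


def plot_arc_statistics(stats: ArcJointStatistics, ax=None):
    """Arc magnitude versus arc duration: joint density plus the mean curve."""
    ax = _axes(ax)
    extent = (
        stats.duration_edges[0],
        stats.duration_edges[-1],
        stats.magnitude_edges[0],
        stats.magnitude_edges[-1],
    )
    ax.imshow(
        stats.density, origin="lower", aspect="auto", extent=extent, cmap="viridis"
    )
    centers = 0.5 * (stats.duration_edges[:-1] + stats.duration_edges[1:])
    ax.plot(centers, stats.mean_magnitude, color="w", lw=1.5)
    ax.set_xlabel(r"$\tau_{arc}$ [s]")
    ax.set_ylabel(r"$\Omega_{s,max}$ [-]")
    return ax


def plot_metabolic_response(trajectories, pools=None, ax=None):
    """Ensemble-mean pool trajectories (and qp) versus process time."""
    ax = _axes(ax)
    first: MetabolicTrajectory = trajectories[0]
    pools = pools if pools is not None else list(first.pool_names)
    times = first.times_h
    for name in pools:
        i = first.pool_names.index(name)
        mean = np.mean([t.states[i] for t in trajectories], axis=0)
        ax.plot(times, mean, label=name)
    qp_mean = np.mean([t.qp for t in trajectories], axis=0)
    ax.plot(times, qp_mean, "k--", label="qp")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("pool level / qp [-]")
    ax.legend(fontsize="small", ncol=2)
    return ax
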