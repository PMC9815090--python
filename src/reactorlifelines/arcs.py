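"""Arc analysis: excursions of a lifeline about a single uptake threshold.

Arc analysis tracks parcel movement with respect to one threshold (0.05 by
default, i.e. the starvation boundary): the durations between successive
crossings define alternating *above* and *below* arcs, with the same
moving-average filter and hysteresis margin used for regime analysis. For
every above-side arc the maximum scaled uptake reached, ``Omega_s_max``, is
logged so that arc magnitude can be correlated with arc duration. With the
threshold placed on the starvation boundary, below-arc durations coincide
exactly with the starvation-regime residence times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .lifelines import Lifeline, LifelineSet
from .regimes import RegimeSpec, smooth

__all__ = [
    "ArcRecord",
    "ArcJointStatistics",
    "arc_analysis",
    "arc_analysis_set",
    "arc_joint_statistics",
]


@dataclass(frozen=True)
class ArcRecord:
    """One threshold excursion.

    ``magnitude`` is the maximum smoothed ``q_rel`` over the arc (above-side
    arcs only, None below). First/last arcs of a lifeline are censored and
    excluded from statistics.
    """

    side: str  # 'above' | 'below'
    t_enter: float
    t_exit: float
    magnitude: float | None
    censored: bool

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


def arc_analysis(
    lifeline: Lifeline,
    threshold: float = 0.05,
    hysteresis: float = 0.01,
    lag_window: float = 0.36,
    presmoothed: bool = False,
) -> list:
    """Classify a lifeline into alternating above/below arcs.

    The smoothed signal switches from above to below only strictly under
    ``threshold - hysteresis`` and back only strictly over ``threshold +
    hysteresis`` (same no-chatter rule as regime analysis).
    """
    if not 0 < threshold < 1:
        raise InvalidConfigurationError("threshold must be in (0, 1)")
    if not 0 <= hysteresis < threshold:
        raise InvalidConfigurationError("need 0 <= hysteresis < threshold")
    ll = lifeline if presmoothed else smooth(lifeline, lag_window)
    x = ll.values
    t0, dt = ll.t_start, ll.sample_dt
    n = x.size
    lo, hi = threshold - hysteresis, threshold + hysteresis

    idx_up = np.flatnonzero(x > hi)
    idx_dn = np.flatnonzero(x < lo)

    above = x[0] >= threshold
    arcs: list[ArcRecord] = []
    pos = 0
    seg_start = 0
    first = True
    while True:
        targets = idx_dn if above else idx_up
        j = np.searchsorted(targets, pos, side="right")
        if j >= targets.size:
            break
        j = int(targets[j])
        mag = float(x[seg_start:j].max()) if above else None
        arcs.append(
            ArcRecord(
                side="above" if above else "below",
                t_enter=t0 + seg_start * dt,
                t_exit=t0 + j * dt,
                magnitude=mag,
                censored=first,
            )
        )
        above = not above
        seg_start, pos, first = j, j, False
    mag = float(x[seg_start:].max()) if above else None
    arcs.append(
        ArcRecord(
            side="above" if above else "below",
            t_enter=t0 + seg_start * dt,
            t_exit=t0 + (n - 1) * dt,
            magnitude=mag,
            censored=True,
        )
    )
    return arcs


def arc_analysis_set(
    lifeline_set: LifelineSet,
    threshold: float = 0.05,
    spec: RegimeSpec | None = None,
) -> list:
    """Pooled arc records of a lifeline set (filter taken from ``spec``)."""
    spec = spec or RegimeSpec()
    pooled = []
    for ll in lifeline_set:
        pooled.extend(
            arc_analysis(
                ll,
                threshold=threshold,
                hysteresis=spec.hysteresis,
                lag_window=spec.lag_window,
            )
        )
    return pooled


@dataclass(frozen=True)
class ArcJointStatistics:
    """Binned joint distribution of (arc duration, arc magnitude).

    ``density`` is the magnitude distribution within each duration bin,
    normalised per column (each non-empty duration-bin column sums to 1);
    ``mean_magnitude`` is the average magnitude per duration bin.
    """

    duration_edges: np.ndarray
    magnitude_edges: np.ndarray
    counts: np.ndarray  # (n_mag_bins, n_dur_bins)
    density: np.ndarray
    mean_magnitude: np.ndarray  # per duration bin, NaN when empty

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d in range(self.duration_edges.size - 1):
            rows.append(
                {
                    "tau_arc_low_s": self.duration_edges[d],
                    "tau_arc_high_s": self.duration_edges[d + 1],
                    "mean_magnitude": self.mean_magnitude[d],
                    "n_arcs": int(self.counts[:, d].sum()),
                }
            )
        return pd.DataFrame(rows)


def arc_joint_statistics(
    arcs,
    duration_bin_width: float = 0.3,
    n_magnitude_bins: int = 20,
) -> ArcJointStatistics:
    """Joint (duration, magnitude) statistics of uncensored above-side arcs."""
    data = [
        (a.duration, a.magnitude)
        for a in arcs
        if a.side == "above" and not a.censored and a.duration > 0
    ]
    if not data:
        edges = np.array([0.0, duration_bin_width])
        medges = np.linspace(0.0, 1.0, n_magnitude_bins + 1)
        z = np.zeros((n_magnitude_bins, 1))
        return ArcJointStatistics(edges, medges, z, z, np.array([np.nan]))
    durations = np.array([d for d, _ in data])
    magnitudes = np.array([m for _, m in data])
    n_dur = max(1, int(np.ceil(durations.max() / duration_bin_width - 1e-12)))
    dur_edges = np.arange(n_dur + 1) * duration_bin_width
    mag_edges = np.linspace(0.0, 1.0, n_magnitude_bins + 1)
    counts, _, _ = np.histogram2d(magnitudes, durations, bins=(mag_edges, dur_edges))
    col_sums = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(col_sums > 0, counts / col_sums, 0.0)
    which = np.clip(np.digitize(durations, dur_edges) - 1, 0, n_dur - 1)
    mean_mag = np.full(n_dur, np.nan)
    for d in range(n_dur):
        sel = which == d
        if sel.any():
            mean_mag[d] = magnitudes[sel].mean()
    return ArcJointStatistics(dur_edges, mag_edges, counts, density, mean_mag)
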