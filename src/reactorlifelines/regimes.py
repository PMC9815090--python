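"""Regime analysis of lifelines: smoothing, hysteresis classification,
residence-time distributions and regime fractions.

The broth is divided into three metabolic regimes by uptake saturation:
starvation (S) for ``q_rel < 0.05``, excess (E) for ``q_rel > 0.95`` and
limitation (L) in between. To suppress short, low-amplitude chatter the
lifeline is first smoothed with a moving-average window (0.36 s by default)
and a transition is registered only when the signal passes the regime
boundary by a hysteresis margin of 0.01: excess -> limitation only below
0.94, the converse only above 0.96, and symmetrically at the starvation
boundary (0.04 / 0.06). Comparisons are strict: a sample resting exactly on
a shifted boundary does not trigger.

Each classified interval is a :class:`Visit`. Passages through limitation
carry a three-letter pattern (origin, residence, destination): ELE, ELS, SLE
or SLS; excess and starvation visits are coded LEL and LSL since limitation
is their only possible neighbour. The mean residence time per pattern is the
count-weighted mean  ``sum(tau * n_tau) / sum(n_tau)``  applied to the exact
(un-binned) durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .lifelines import Lifeline, LifelineSet

__all__ = [
    "RegimeSpec",
    "Visit",
    "ResidenceDistribution",
    "smooth",
    "detect_visits",
    "classify_samples",
    "residence_distributions",
    "regime_fractions",
    "PATTERNS",
]

PATTERNS = ("LEL", "LSL", "ELE", "ELS", "SLE", "SLS")


@dataclass(frozen=True)
class RegimeSpec:
    """Thresholds and filter parameters for regime classification.

    Defaults: starvation below 0.05, excess above 0.95, hysteresis margin
    0.01, moving-average window 0.36 s.
    """

    starvation_threshold: float = 0.05
    excess_threshold: float = 0.95
    hysteresis: float = 0.01
    lag_window: float = 0.36

    def __post_init__(self):
        if not 0 < self.starvation_threshold < self.excess_threshold < 1:
            raise InvalidConfigurationError(
                "need 0 < starvation_threshold < excess_threshold < 1"
            )
        if not 0 <= self.hysteresis < self.starvation_threshold:
            raise InvalidConfigurationError(
                "need 0 <= hysteresis < starvation_threshold"
            )
        if self.lag_window < 0:
            raise InvalidConfigurationError("lag_window must be >= 0")


@dataclass(frozen=True)
class Visit:
    """One residence interval in a regime.

    ``origin``/``destination`` are the neighbouring regimes (None when the
    lifeline starts or ends inside the visit, i.e. censored). Zero-duration
    limitation visits encode a direct E<->S jump between two samples; they
    keep the visit sequence alternating and are excluded from statistics.
    """

    regime: str
    t_enter: float
    t_exit: float
    origin: str | None
    destination: str | None
    censored: bool

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter

    @property
    def pattern(self) -> str | None:
        """Three-letter transition code, or None when censored."""
        if self.censored or self.origin is None or self.destination is None:
            return None
        return f"{self.origin}{self.regime}{self.destination}"


@dataclass(frozen=True)
class ResidenceDistribution:
    """Histogram and mean of residence times for one transition pattern."""

    pattern: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float | None
    n_visits: int

    @classmethod
    def from_durations(cls, pattern, durations, bin_width):
        durations = np.asarray(durations, dtype=float)
        if durations.size == 0:
            return cls(pattern, np.array([0.0, bin_width]), np.zeros(1, int), None, 0)
        n_bins = max(1, int(np.ceil(durations.max() / bin_width - 1e-12)))
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(durations, bins=edges)
        # count-weighted mean over exact durations == arithmetic mean
        mean = float(durations.sum() / durations.size)
        return cls(pattern, edges, counts, mean, int(durations.size))


def smooth(lifeline: Lifeline, lag_window: float = 0.36) -> Lifeline:
    """Centered moving average with window ``round(lag_window / sample_dt)``.

    An even window of width ``w`` centered on sample ``k`` spans samples
    ``[k - w//2, k + w - 1 - w//2]`` (i.e. ``[k-6, k+5]`` at the defaults
    w=12); at the series ends the window is truncated to the available
    samples. Output length equals input length. A window shorter than one
    sample is a no-op with a warning.
    """
    dt = lifeline.sample_dt
    if lag_window < dt:
        if lag_window > 0:
            warnings.warn(
                f"lag_window {lag_window} s below sample interval {dt} s: "
                "smoothing is a no-op",
                stacklevel=2,
            )
        return lifeline
    w = int(round(lag_window / dt))
    if w <= 1:
        return lifeline
    left, right = w // 2, w - 1 - w // 2
    v = lifeline.values
    n = v.size
    c = np.concatenate([[0.0], np.cumsum(v)])
    k = np.arange(n)
    lo = np.maximum(0, k - left)
    hi = np.minimum(n, k + right + 1)
    out = (c[hi] - c[lo]) / (hi - lo)
    return Lifeline(
        parcel_id=lifeline.parcel_id,
        t_start=lifeline.t_start,
        sample_dt=dt,
        values=np.clip(out, 0.0, 1.0),
    )


def _first_index_after(sorted_idx: np.ndarray, pos: int) -> int:
    """First element of ``sorted_idx`` strictly greater than ``pos`` (or -1)."""
    j = np.searchsorted(sorted_idx, pos, side="right")
    return int(sorted_idx[j]) if j < sorted_idx.size else -1


def _plain_regime(x, spec):
    if x < spec.starvation_threshold:
        return "S"
    if x > spec.excess_threshold:
        return "E"
    return "L"


def detect_visits(
    lifeline: Lifeline,
    spec: RegimeSpec = RegimeSpec(),
    presmoothed: bool = False,
) -> list:
    """Run the hysteresis state machine and return the ordered visit list.

    The lifeline is smoothed first (unless ``presmoothed``). The initial
    regime is assigned by the plain thresholds on the first smoothed sample;
    the first and last visits are censored. A single-sample jump across both
    boundaries (E directly to S or vice versa) registers both transitions at
    the same timestamp with a zero-duration limitation visit in between, so
    consecutive visits never share a regime.
    """
    ll = lifeline if presmoothed else smooth(lifeline, spec.lag_window)
    x = ll.values
    t0, dt = ll.t_start, ll.sample_dt
    n = x.size
    h = spec.hysteresis
    s_lo, s_hi = spec.starvation_threshold - h, spec.starvation_threshold + h
    e_lo, e_hi = spec.excess_threshold - h, spec.excess_threshold + h

    idx_gt_shi = np.flatnonzero(x > s_hi)   # exit S upward
    idx_lt_slo = np.flatnonzero(x < s_lo)   # enter S
    idx_gt_ehi = np.flatnonzero(x > e_hi)   # enter E
    idx_lt_elo = np.flatnonzero(x < e_lo)   # exit E downward

    state = _plain_regime(x[0], spec)
    visits: list[Visit] = []
    seg_start = 0.0  # time offset from t0
    origin: str | None = None
    pos = 0
    while True:
        if state == "S":
            j = _first_index_after(idx_gt_shi, pos)
            if j < 0:
                break
            t_j = j * dt
            visits.append(Visit("S", t0 + seg_start, t0 + t_j, origin, "L",
                                censored=origin is None))
            if x[j] > e_hi:  # S -> L -> E in one sample
                visits.append(Visit("L", t0 + t_j, t0 + t_j, "S", "E", False))
                state, origin = "E", "L"
            else:
                state, origin = "L", "S"
            seg_start, pos = t_j, j
        elif state == "E":
            j = _first_index_after(idx_lt_elo, pos)
            if j < 0:
                break
            t_j = j * dt
            visits.append(Visit("E", t0 + seg_start, t0 + t_j, origin, "L",
                                censored=origin is None))
            if x[j] < s_lo:  # E -> L -> S in one sample
                visits.append(Visit("L", t0 + t_j, t0 + t_j, "E", "S", False))
                state, origin = "S", "L"
            else:
                state, origin = "L", "E"
            seg_start, pos = t_j, j
        else:  # limitation
            j_e = _first_index_after(idx_gt_ehi, pos)
            j_s = _first_index_after(idx_lt_slo, pos)
            candidates = [j for j in (j_e, j_s) if j >= 0]
            if not candidates:
                break
            j = min(candidates)
            dest = "E" if j == j_e else "S"
            t_j = j * dt
            visits.append(Visit("L", t0 + seg_start, t0 + t_j, origin, dest,
                                censored=origin is None))
            state, origin = dest, "L"
            seg_start, pos = t_j, j
    # trailing (censored) visit up to the final sample
    visits.append(
        Visit(state, t0 + seg_start, t0 + (n - 1) * dt, origin, None, True)
    )
    return visits


def classify_samples(
    lifeline: Lifeline,
    spec: RegimeSpec = RegimeSpec(),
    presmoothed: bool = False,
) -> np.ndarray:
    """Per-sample regime state ('S'/'L'/'E') under the hysteresis machine.

    Sample ``k`` carries the regime of the visit covering its time (visits
    cover ``[t_enter, t_exit)``; the final visit includes its end point).
    """
    visits = detect_visits(lifeline, spec, presmoothed=presmoothed)
    n = lifeline.n_samples
    dt = lifeline.sample_dt
    out = np.empty(n, dtype="<U1")
    for v in visits:
        k_enter = int(round((v.t_enter - lifeline.t_start) / dt))
        k_exit = int(round((v.t_exit - lifeline.t_start) / dt))
        out[k_enter:k_exit] = v.regime
    out[-1] = visits[-1].regime
    return out


def residence_distributions(
    visits,
    bin_width: float = 0.3,
) -> dict:
    """Residence-time distribution per transition pattern.

    ``visits`` is an iterable of :class:`Visit` (typically pooled over a
    whole lifeline set). Censored and zero-duration visits are excluded. A
    pattern with no uncensored visits yields an empty distribution whose mean
    is ``None`` (absent, not zero).
    """
    if bin_width <= 0:
        raise InvalidConfigurationError("bin_width must be > 0")
    durations: dict[str, list[float]] = {p: [] for p in PATTERNS}
    for v in visits:
        p = v.pattern
        if p is None or v.duration <= 0:
            continue
        durations[p].append(v.duration)
    return {
        p: ResidenceDistribution.from_durations(p, durations[p], bin_width)
        for p in PATTERNS
    }


def visits_of_set(lifeline_set: LifelineSet, spec: RegimeSpec = RegimeSpec()):
    """All visits of a lifeline set, pooled (helper for distributions)."""
    pooled = []
    for ll in lifeline_set:
        pooled.extend(detect_visits(ll, spec))
    return pooled


def regime_fractions(
    lifeline_set: LifelineSet,
    spec: RegimeSpec = RegimeSpec(),
) -> dict:
    """Percent of parcel-sample time spent in each regime (Lagrangian view).

    Returns ``{'E': ..., 'L': ..., 'S': ...}`` in percent, summing to 100
    within 0.01.
    """
    counts = {"E": 0, "L": 0, "S": 0}
    total = 0
    for ll in lifeline_set:
        states = classify_samples(ll, spec)
        for regime in counts:
            counts[regime] += int(np.sum(states == regime))
        total += states.size
    if total == 0:
        raise InvalidConfigurationError("empty lifeline set")
    return {regime: 100.0 * counts[regime] / total for regime in counts}


def residence_table(distributions: dict) -> pd.DataFrame:
    """Mean residence time per pattern as a tidy table."""
    rows = [
        {
            "pattern": p,
            "mean_residence_s": d.mean if d.mean is not None else np.nan,
            "n_visits": d.n_visits,
        }
        for p, d in distributions.items()
    ]
    return pd.DataFrame(rows)


def histogram_table(distributions: dict) -> pd.DataFrame:
    """Residence histograms in long format (pattern, bin_low_s, bin_high_s, count)."""
    rows = []
    for p, d in distributions.items():
        for lo, hi, c in zip(d.bin_edges[:-1], d.bin_edges[1:], d.counts):
            rows.append(
                {"pattern": p, "bin_low_s": lo, "bin_high_s": hi, "count": int(c)}
            )
    return pd.DataFrame(rows)
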