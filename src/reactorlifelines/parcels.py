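"""Stochastic massless-parcel transport over a compartment network.

Parcels represent micron-sized cell clusters with Stokes number ~ 0: they
follow the liquid exactly, so at compartment granularity their motion is a
continuous-time Markov chain with jump rate ``flows[i, j] / V_i`` from
compartment ``i`` to ``j``. Trajectories are generated event-by-event (exact
exponential waiting times, no per-step jump probabilities), which removes
time-discretisation bias and makes the first-passage oracle in
:mod:`reactorlifelines.network` an exact reference. The scaled uptake of the
parcel's current compartment is then sampled on a fixed grid, decoupled from
the jump process, to form the lifeline.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidConfigurationError
from .lifelines import Lifeline, LifelineSet
from .network import CompartmentNetwork
from .substrate import SubstrateField

__all__ = ["simulate_parcels", "simulate_compartment_paths"]

_CHUNK = 256


def simulate_compartment_paths(
    network: CompartmentNetwork,
    n_parcels: int,
    duration: float,
    seed: int,
):
    """Exact CTMC trajectories: per parcel, jump times and visited compartments.

    Parcels start distributed proportionally to compartment volume (the
    stationary occupancy of the flow-balanced chain). Returns a list of
    ``(jump_times, states)`` pairs; ``jump_times[0] == 0`` and ``states[k]``
    holds on ``[jump_times[k], jump_times[k+1])``.
    """
    if n_parcels < 1:
        raise InvalidConfigurationError("n_parcels must be >= 1")
    if duration <= 0:
        raise InvalidConfigurationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    q = network.rate_matrix()
    n = network.n_compartments
    rates = -np.diag(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rates[:, None] > 0, q / rates[:, None], 0.0)
    np.fill_diagonal(probs, 0.0)
    cum_probs = np.cumsum(probs, axis=1)

    starts = rng.choice(n, size=n_parcels, p=network.stationary_occupancy())
    paths = []
    for p in range(n_parcels):
        state = int(starts[p])
        times = [0.0]
        states = [state]
        t = 0.0
        exp_pool = rng.exponential(size=_CHUNK)
        uni_pool = rng.random(size=_CHUNK)
        k = 0
        while True:
            rate = rates[state]
            if rate <= 0:  # absorbing compartment (e.g. single-box network)
                break
            if k == _CHUNK:
                exp_pool = rng.exponential(size=_CHUNK)
                uni_pool = rng.random(size=_CHUNK)
                k = 0
            t += exp_pool[k] / rate
            if t >= duration:
                break
            state = int(np.searchsorted(cum_probs[state], uni_pool[k], side="right"))
            k += 1
            times.append(t)
            states.append(state)
        paths.append((np.asarray(times), np.asarray(states, dtype=np.intp)))
    return paths


def simulate_parcels(
    network: CompartmentNetwork,
    field: SubstrateField,
    n_parcels: int,
    duration: float,
    sample_dt: float,
    seed: int,
) -> LifelineSet:
    """Generate parcel lifelines over a quasi-steady substrate field.

    Each parcel's compartment path is simulated as an exact CTMC and the
    field's ``q_rel`` of the current compartment is registered every
    ``sample_dt`` (first sample at t=0), yielding
    ``floor(duration/sample_dt) + 1`` samples per lifeline.
    """
    if sample_dt <= 0:
        raise InvalidConfigurationError("sample_dt must be > 0")
    q_rel = np.asarray(field.q_rel, dtype=float)
    if q_rel.size != network.n_compartments:
        raise InvalidConfigurationError("field does not match the network")

    paths = simulate_compartment_paths(network, n_parcels, duration, seed)
    n_samples = int(np.floor(duration / sample_dt + 1e-9)) + 1
    sample_times = np.arange(n_samples) * sample_dt

    lifelines = []
    for pid, (times, states) in enumerate(paths):
        idx = np.searchsorted(times, sample_times, side="right") - 1
        values = q_rel[states[idx]]
        lifelines.append(
            Lifeline(parcel_id=pid, t_start=0.0, sample_dt=sample_dt, values=values)
        )
    return LifelineSet(
        lifelines=tuple(lifelines),
        metadata={
            "source": "simulate_parcels",
            "seed": int(seed),
            "duration": float(duration),
            "n_parcels": int(n_parcels),
        },
    )
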