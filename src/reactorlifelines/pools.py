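"""Pluggable structured kinetic (multi-pool) models of the production strain.

A :class:`PoolModelSpec` bundles a vector field over intracellular pool
states driven by the instantaneous scaled uptake ``u = qs/qs_max`` of a
lifeline, plus the instantaneous specific production rate ``qp`` it implies.
Models are deliberately pluggable: the pipeline's composite-lifeline,
chemostat-initialisation and ensemble-averaging machinery works with any
spec, from the documented two-pool toy below to the nine-pool structure in
:mod:`reactorlifelines.nine_pool_synthetic`.

Conventions: time unit is hours; pool states are non-negative and scaled
dimensionless (metabolite pools in units of their typical chemostat level);
``rates(x, u)`` is vectorised over a trailing ensemble axis; pools listed in
``frozen`` have identically zero derivative (e.g. a clamped glucose-transport
capacity mimicking chemostat conditions) and are excluded from fixed-point
solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["PoolModelSpec", "two_pool_toy"]


@dataclass(frozen=True)
class PoolModelSpec:
    """A structured kinetic model driven by scaled substrate uptake.

    Attributes
    ----------
    pool_names : tuple of str
    rates : callable
        ``rates(x, u) -> (dx_dt, qp)`` with ``x`` of shape ``(n_pools, ...)``
        and scalar or broadcastable ``u`` in [0, 1]; derivatives are per
        hour.
    initial_guess : ndarray
        Documented starting state for fixed-point searches.
    frozen : tuple of int
        Indices of pools whose equation is inert (derivative identically 0).
    fastest_rate : float
        Largest relaxation rate constant in the model [1/h]; used to check
        explicit-integration stability margins.
    """

    pool_names: tuple
    rates: Callable
    initial_guess: np.ndarray
    frozen: tuple = ()
    fastest_rate: float = 60.0
    name: str = "pool-model"

    def __post_init__(self):
        object.__setattr__(
            self, "initial_guess", np.asarray(self.initial_guess, dtype=float)
        )
        if self.initial_guess.shape != (len(self.pool_names),):
            raise ValueError("initial_guess length must match pool_names")

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    @property
    def free_indices(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_pools) if i not in set(self.frozen)], dtype=int
        )


def two_pool_toy(k_precursor: float = 60.0, K_qp: float = 0.1) -> PoolModelSpec:
    """Documented two-pool toy model: transport capacity + product precursor.

    Pool 0 is a frozen glucose-transport capacity (chemostat clamp); pool 1
    is a product precursor that relaxes towards the instantaneous uptake,
    ``dx/dt = k (u - x)`` with ``k`` = 60/h (one-minute turnover). The
    production rate ``qp = x / (K + x)`` saturates in the precursor, so qp is
    concave in the experienced uptake and any fluctuation around a fixed mean
    lowers the average production (Jensen loss) -- the minimal mechanism by
    which substrate heterogeneity costs productivity.
    """

    def rates(x, u):
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        dx = np.zeros_like(x)
        dx[1] = k_precursor * (u - x[1])
        qp = x[1] / (K_qp + x[1])
        return dx, qp

    return PoolModelSpec(
        pool_names=("transport_capacity", "precursor"),
        rates=rates,
        initial_guess=np.array([1.0, 0.3]),
        frozen=(0,),
        fastest_rate=k_precursor,
        name="two-pool-toy",
    )
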