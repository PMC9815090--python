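"""Monod uptake kinetics for glucose-limited broth.

Specific substrate uptake follows the Monod law

    qs = qs_max * Cs / (Ks + Cs)

with ``qs_max`` the maximum biomass-specific uptake rate, ``Ks`` the affinity
constant and ``Cs`` the local dissolved glucose concentration. Throughout the
package uptake is handled in scaled form ``q_rel = qs / qs_max = Cs/(Ks+Cs)``,
the quantity recorded along parcel lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigurationError

__all__ = ["KineticsParams", "monod_q"]


@dataclass(frozen=True)
class KineticsParams:
    """Monod parameters plus the (Eulerian) biomass concentration.

    Parameters
    ----------
    qs_max : float
        Maximum specific uptake rate [mol / g_dw / s].
    Ks : float
        Affinity (half-saturation) constant [mol/kg].
    Cx : float
        Biomass concentration [g_dw / kg broth].
    """

    qs_max: float
    Ks: float
    Cx: float

    def __post_init__(self) -> None:
        for name in ("qs_max", "Ks", "Cx"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidConfigurationError(
                    f"KineticsParams.{name} must be strictly positive, "
                    f"got {getattr(self, name)!r}"
                )

    @classmethod
    def penicillin_reference(cls) -> "KineticsParams":
        """Glucose uptake parameters of the industrial penicillin fermentation.

        qs_max = 1600e-6 mol/g_dw/h (converted to per-second), Ks = 7.8e-6
        mol/kg, Cx = 55 g_dw/kg.
        """
        return cls(qs_max=1600e-6 / 3600.0, Ks=7.8e-6, Cx=55.0)

    @property
    def max_volumetric_rate(self) -> float:
        """Maximum volumetric consumption rate qs_max * Cx [mol / kg / s]."""
        return self.qs_max * self.Cx


def monod_q(Cs, params: KineticsParams):
    """Scaled Monod uptake ``q_rel = Cs / (Ks + Cs)``.

    Parameters
    ----------
    Cs : float or ndarray
        Substrate concentration [mol/kg]; must be non-negative.
    params : KineticsParams

    Returns
    -------
    float or ndarray in [0, 1), monotone increasing in ``Cs``.
    """
    Cs = np.asarray(Cs, dtype=float)
    if np.any(Cs < 0):
        raise ValueError("negative substrate concentration")
    q = Cs / (params.Ks + Cs)
    return float(q) if q.ndim == 0 else q
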