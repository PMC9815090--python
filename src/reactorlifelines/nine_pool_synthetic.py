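"""Synthetic nine-pool structured model of penicillin production.

This is a *synthetic stand-in*: the published nine-pool penicillin model is
parameterised in literature supplementary material that is not reproduced
here, so this module provides a structured model with the same pool layout
and the qualitative regulatory mechanisms reported for industrial
*Penicillium chrysogenum*, with parameters chosen on mechanistic grounds
(documented in docs/methods.md). It is suitable for studying *relative*
production-rate losses under fluctuating substrate supply; its absolute
rates carry no literature pedigree.

Pools (scaled dimensionless, time in hours):

==========  ==================================================================
``xE11``    glucose transport capacity; frozen (chemostat clamp), inert.
``xgly``    glycolytic intermediate pool; tracks uptake within ~1 min.
``xatp``    energy charge; saturating function of glycolytic supply, ~30 s.
``xaaa``    alpha-aminoadipate precursor pool (~10 min turnover).
``xcys``    cysteine pool (~10 min).
``xval``    valine pool (~10 min).
``xacv``    ACV tripeptide, condensed from the three amino acids at ATP cost.
``xipn``    isopenicillin N, downstream of ACV.
``xpps``    penicillin synthase expression level: *slowly* (tau ~ 2 h)
            relaxes to an induction level that requires substrate but is
            repressed at high glucose (carbon catabolite repression).
==========  ==================================================================

The production rate ``qp`` is the synthase-catalysed flux out of the IPN
pool, saturating in IPN and in energy charge and proportional to ``xpps``.
Two mechanisms make qp fall under gradient-driven fluctuations at fixed mean
uptake: starvation episodes drain the fast energy/precursor pools, and
excess episodes repress synthase expression; both are reported features of
large-scale penicillin fermentations.
"""

from __future__ import annotations

import numpy as np

from .pools import PoolModelSpec

__all__ = ["nine_pool_synthetic"]

POOL_NAMES = (
    "xE11", "xgly", "xatp", "xaaa", "xcys", "xval", "xacv", "xipn", "xpps",
)

# turnover rates [1/h]
K_GLY = 60.0    # ~1 min
K_ATP = 120.0   # ~30 s (fastest pool)
K_AA = 6.0      # ~10 min, all three amino-acid pools
K_ACV = 6.0
K_IPN = 6.0
K_PPS = 0.5     # ~2 h synthase expression

# saturation constants (scaled units)
KM_ATP = 0.05   # glycolytic supply half-saturating energy charge
KM_AA = 0.10    # atp/gly requirement of amino-acid synthesis
KM_POOL = 0.30  # pathway Michaelis constants
KM_QP_IPN = 0.10
KM_QP_ATP = 0.20
REPRESSION_U = 0.5   # uptake level giving half-maximal glucose repression
REPRESSION_N = 4.0   # Hill steepness of repression
INDUCTION_KU = 0.02  # minimal-substrate requirement of expression


def _mm(x, k):
    return x / (k + x)


def nine_pool_synthetic() -> PoolModelSpec:
    """Build the synthetic nine-pool model (see module docstring)."""

    def rates(x, u):
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        gly, atp = x[1], x[2]
        aaa, cys, val = x[3], x[4], x[5]
        acv, ipn, pps = x[6], x[7], x[8]

        dx = np.zeros_like(x)
        # xE11 frozen: dx[0] stays 0
        dx[1] = K_GLY * (u - gly)
        dx[2] = K_ATP * (_mm(gly, KM_ATP) - atp)
        supply = atp * _mm(gly, KM_AA)
        dx[3] = K_AA * (supply - aaa)
        dx[4] = K_AA * (supply - cys)
        dx[5] = K_AA * (supply - val)
        v_acv = (
            K_ACV
            * _mm(aaa, KM_POOL) * _mm(cys, KM_POOL) * _mm(val, KM_POOL)
            * _mm(atp, KM_QP_ATP)
        )
        dx[6] = v_acv - K_ACV * acv
        v_ipn = K_IPN * _mm(acv, KM_POOL)
        dx[7] = v_ipn - K_IPN * ipn
        induction = _mm(u, INDUCTION_KU) / (1.0 + (u / REPRESSION_U) ** REPRESSION_N)
        dx[8] = K_PPS * (induction - pps)

        qp = pps * _mm(ipn, KM_QP_IPN) * _mm(atp, KM_QP_ATP)
        return dx, qp

    return PoolModelSpec(
        pool_names=POOL_NAMES,
        rates=rates,
        initial_guess=np.array([1.0, 0.3, 0.8, 0.5, 0.5, 0.5, 0.4, 0.4, 0.5]),
        frozen=(0,),
        fastest_rate=K_ATP,
        name="nine-pool-synthetic",
    )
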