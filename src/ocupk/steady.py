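"""Untreated VEGF steady state (no drug anywhere).

With r = u = w = 0 the VEGF balance is linear: the retina supplies VEGF
to the vitreous at rate ``phi_vit_v``; it diffuses into the aqueous and is
removed by aqueous turnover, with optional first-order degradation in
either compartment.  The fixed point is used for initial conditions and
as an analytic oracle for the simulator.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet

__all__ = ["untreated_vegf_steady_state", "with_steady_state_init"]


def untreated_vegf_steady_state(params: ParameterSet) -> tuple[float, float]:
    """Steady-state free-VEGF concentrations ``(v_aq, v_vit)``, pmol mL^-1.

    In the degradation-free default the balance closes in two steps:
    everything supplied must leave through aqueous turnover, so
    ``v_aq = phi / psi_aq``, and the aqueous-vitreous flux must carry the
    supply, so ``v_vit = v_aq + phi / (beta_aq_vit_v * A_aq_vit)``.  With
    nonzero degradation the 2x2 linear balance is solved instead.

    Raises
    ------
    ValueError
        If every sink is zero (no steady state exists).
    """
    phi = params.phi_vit_v
    ex = params.beta_aq_vit_v * params.A_aq_vit  # mL h^-1 exchange conductance
    if phi == 0.0:
        return 0.0, 0.0
    if params.delta_aq_v == 0.0 and params.delta_vit_v == 0.0:
        if params.psi_aq <= 0.0 or ex <= 0.0:
            raise ValueError("no untreated steady state: aqueous turnover and exchange must be positive")
        v_aq = phi / params.psi_aq
        v_vit = v_aq + phi / ex
        return v_aq, v_vit
    # general balance:
    #   aqueous:  ex*(v_vit - v_aq) = (psi_aq + delta_aq_v*V_aq) * v_aq
    #   vitreous: phi = ex*(v_vit - v_aq) + delta_vit_v*V_vit * v_vit
    A = np.array(
        [
            [ex + params.psi_aq + params.delta_aq_v * params.V_aq, -ex],
            [-ex, ex + params.delta_vit_v * params.V_vit],
        ]
    )
    b = np.array([0.0, phi])
    if abs(np.linalg.det(A)) < 1e-300:
        raise ValueError("no untreated steady state: all sinks are zero")
    v_aq, v_vit = np.linalg.solve(A, b)
    return float(v_aq), float(v_vit)


def with_steady_state_init(params: ParameterSet) -> ParameterSet:
    """Return ``params`` with ``v_aq_init``/``v_vit_init`` replaced by the
    recomputed untreated steady state (used when a swept parameter alters
    the VEGF balance)."""
    v_aq, v_vit = untreated_vegf_steady_state(params)
    return params.replace(v_aq_init=v_aq, v_vit_init=v_vit)
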