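"""Reference implementation of the three-compartment binding/transport model.

State variables (concentrations in pmol mL^-1, tear volume in mL):

==========  =========================================================
``V_tear``  tear-film volume (algebraic, not integrated)
``r_tear``  drug (R) in the tear film
``v_aq``    free VEGF (V) in the aqueous
``r_aq``    free drug in the aqueous
``u_aq``    single-bound complex (VR) in the aqueous
``w_aq``    double-bound complex (RVR) in the aqueous
``v_vit``   free VEGF in the vitreous
``r_vit``   free drug in the vitreous
``u_vit``   VR in the vitreous
``w_vit``   RVR in the vitreous
==========  =========================================================

The functions here are the readable, vectorised reference used by the
scipy integration backend and by the tests; :mod:`ocupk._kernel` contains
a numerically identical compiled version used by the default simulation
backend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ModelConfig, ParameterSet

__all__ = ["EyeState", "STATE_VARS", "reaction_terms", "tear_volume", "rhs"]

#: order of the nine integrated concentration variables
STATE_VARS = ("r_tear", "v_aq", "r_aq", "u_aq", "w_aq", "v_vit", "r_vit", "u_vit", "w_vit")

#: tolerance below which a negative concentration is attributed to round-off
NEG_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class EyeState:
    """Instantaneous state of the eye (all concentrations pmol mL^-1)."""

    V_tear: float
    r_tear: float
    v_aq: float
    r_aq: float
    u_aq: float
    w_aq: float
    v_vit: float
    r_vit: float
    u_vit: float
    w_vit: float

    def __post_init__(self) -> None:
        for name in ("V_tear",) + STATE_VARS:
            value = getattr(self, name)
            if value < 0:
                if value > -NEG_CLAMP_TOL:
                    object.__setattr__(self, name, 0.0)
                else:
                    raise ValueError(f"{name} is negative ({value}); increase solver accuracy")

    @classmethod
    def zero(cls) -> "EyeState":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def to_array(self) -> np.ndarray:
        """Nine integrated concentrations, in ``STATE_VARS`` order."""
        return np.array([getattr(self, n) for n in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, V_tear: float) -> "EyeState":
        return cls(V_tear, *(float(x) for x in y))

    def replace(self, **changes) -> "EyeState":
        return replace(self, **changes)

    def total_r_moles(self, params: ParameterSet, tear: bool = True) -> float:
        """Total drug amount (pmol), counting two R per RVR complex."""
        total = (
            params.V_aq * (self.r_aq + self.u_aq + 2.0 * self.w_aq)
            + params.V_vit * (self.r_vit + self.u_vit + 2.0 * self.w_vit)
        )
        if tear:
            total += self.V_tear * self.r_tear
        return total

    def total_v_moles(self, params: ParameterSet) -> float:
        """Total VEGF amount (pmol), free plus bound."""
        return params.V_aq * (self.v_aq + self.u_aq + self.w_aq) + params.V_vit * (
            self.v_vit + self.u_vit + self.w_vit
        )


def reaction_terms(v: float, r: float, u: float, w: float, k_on: float, k_off: float):
    """Mass-action rates of the two-site binding scheme.

    V + R <-> VR with forward rate ``2 k_on`` (two free sites) and backward
    rate ``k_off``; R + VR <-> RVR with forward rate ``k_on`` and backward
    rate ``2 k_off`` (either bound R may leave).

    Returns ``(dv, dr, du, dw)``.  The scheme conserves both totals:
    ``dv + du + dw == 0`` and ``dr + du + 2 dw == 0``.
    """
    v, r, u, w = (np.asarray(x, dtype=float) for x in (v, r, u, w))
    if np.any(v < 0) or np.any(r < 0) or np.any(u < 0) or np.any(w < 0):
        raise ValueError("concentrations must be non-negative")
    first = k_off * u - 2.0 * k_on * v * r  # V + R <-> VR, net V gain
    second = 2.0 * k_off * w - k_on * r * u  # R + VR <-> RVR, net VR gain
    dv = first
    dr = first + second
    du = -first + second
    dw = -second
    return dv, dr, du, dw


def tear_volume(t_local: float, config: ModelConfig, params: ParameterSet) -> float:
    """Tear-film volume at time ``t_local`` (h) since the last drop.

    The depleting modes decay linearly and are cut off by a Heaviside step
    (with H(0) = 1) once drainage is complete: the human film returns to
    its normal volume at ``tau_loss``; the ex vivo porcine drop runs off
    entirely.
    """
    if t_local < 0:
        raise ValueError("t_local must be >= 0")
    mode = config.tear_volume_mode
    if mode == "constant_norm":
        return params.V_tear_norm
    if mode == "constant_drop_porcine":
        return params.V_drop
    frac = 1.0 - t_local / params.tau_loss
    if t_local > params.tau_loss:  # H(tau_loss - t) = 0 strictly beyond tau_loss
        frac = 0.0
    if mode == "depleting_human":
        return params.V_tear_norm + (params.V_tear_res - params.V_tear_norm) * frac
    if mode == "depleting_porcine":
        return params.V_drop * frac
    raise ValueError(f"unknown tear_volume_mode {mode!r}")


def rhs(
    t_local: float,
    state: EyeState | np.ndarray,
    config: ModelConfig,
    params: ParameterSet,
) -> np.ndarray:
    """Time-derivatives of the nine concentration variables.

    ``t_local`` is the time since the last drop (it only enters through the
    algebraic tear volume).  The tear volume itself is not integrated.
    Returns an array ordered as ``STATE_VARS``.
    """
    if isinstance(state, EyeState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    p = params.ex_vivo() if config.ex_vivo else params
    r_tear, v_aq, r_aq, u_aq, w_aq, v_vit, r_vit, u_vit, w_vit = y
    dy = np.zeros(9)

    vegf = config.vegf_active

    # tear film ----------------------------------------------------------
    tear_flux_to_aq = 0.0
    if config.tear_active:
        V_tear = tear_volume(t_local, config, p)
        # freeze the porcine film just short of total drainage (the 1/V
        # loss rate is singular at tau_loss but its integral is negligible)
        if config.tear_volume_mode == "depleting_porcine" and V_tear <= p.V_drop * 1e-6:
            V_tear = 0.0
        if config.tear_conc_mode == "held_constant":
            dy[0] = 0.0
            tear_flux_to_aq = p.beta_tear_aq_r * p.A_tear_aq * r_tear
        elif V_tear <= 0.0:
            # porcine drop fully run off: the tear compartment is frozen
            dy[0] = 0.0
        else:
            dy[0] = -(p.beta_tear_aq_r * p.A_tear_aq + p.psi_tear) / V_tear * r_tear
            tear_flux_to_aq = p.beta_tear_aq_r * p.A_tear_aq * r_tear

    # reactions ----------------------------------------------------------
    if vegf:
        dv_a, dr_a, du_a, dw_a = reaction_terms(v_aq, r_aq, u_aq, w_aq, p.k_on, p.k_off)
        dv_v, dr_v, du_v, dw_v = reaction_terms(v_vit, r_vit, u_vit, w_vit, p.k_on, p.k_off)
    else:
        dv_a = dr_a = du_a = dw_a = dv_v = dr_v = du_v = dw_v = 0.0

    def exchange(beta: float, x_vit: float, x_aq: float) -> float:
        """Diffusive flux across the aqueous-vitreous interface, pmol h^-1
        (positive from vitreous to aqueous)."""
        return beta * p.A_aq_vit * (x_vit - x_aq)

    # aqueous ------------------------------------------------------------
    dy[2] = (
        dr_a
        - p.delta_aq_r * r_aq
        + tear_flux_to_aq / p.V_aq
        + exchange(p.beta_aq_vit_r, r_vit, r_aq) / p.V_aq
        - p.psi_aq / p.V_aq * r_aq
    )
    if vegf:
        dy[1] = (
            dv_a
            - p.delta_aq_v * v_aq
            + exchange(p.beta_aq_vit_v, v_vit, v_aq) / p.V_aq
            - p.psi_aq / p.V_aq * v_aq
        )
        dy[3] = (
            du_a
            - p.delta_aq_u * u_aq
            + exchange(p.beta_aq_vit_u, u_vit, u_aq) / p.V_aq
            - p.psi_aq / p.V_aq * u_aq
        )
        dy[4] = (
            dw_a
            - p.delta_aq_w * w_aq
            + exchange(p.beta_aq_vit_w, w_vit, w_aq) / p.V_aq
            - p.psi_aq / p.V_aq * w_aq
        )

    # vitreous -----------------------------------------------------------
    # The vitreo-retinal interface terms enter the drug/complex equations
    # with a positive sign, as in the source formulation; see the methods
    # note on the sign convention (the coefficient is ~2% of the exchange
    # conductance, so the system remains strongly dissipative).
    dy[6] = (
        dr_v
        - p.delta_vit_r * r_vit
        - exchange(p.beta_aq_vit_r, r_vit, r_aq) / p.V_vit
        + p.beta_vit_ret_r * p.A_vit_ret / p.V_vit * r_vit
    )
    if vegf:
        dy[5] = (
            dv_v
            - p.delta_vit_v * v_vit
            - exchange(p.beta_aq_vit_v, v_vit, v_aq) / p.V_vit
            + p.phi_vit_v / p.V_vit
        )
        dy[7] = (
            du_v
            - p.delta_vit_u * u_vit
            - exchange(p.beta_aq_vit_u, u_vit, u_aq) / p.V_vit
            + p.beta_vit_ret_u * p.A_vit_ret / p.V_vit * u_vit
        )
        dy[8] = (
            dw_v
            - p.delta_vit_w * w_vit
            - exchange(p.beta_aq_vit_w, w_vit, w_aq) / p.V_vit
            + p.beta_vit_ret_w * p.A_vit_ret / p.V_vit * w_vit
        )
    return dy
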