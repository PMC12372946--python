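"""Compiled Dormand-Prince 5(4) integration kernel.

The regimen sweeps and sensitivity analysis integrate the model across
thousands of dosing intervals; a compiled adaptive Runge-Kutta stepper with
cubic-Hermite dense output keeps those workloads interactive.  The kernel
is numerically interchangeable with integrating :func:`ocupk.model.rhs`
with scipy's RK45 (the test suite cross-checks the two backends).

Parameter-array layout (see :func:`pack_params`): the kernel receives the
:class:`~ocupk.params.ParameterSet` as a flat float64 vector and the
structural configuration as small integers, so a single compilation serves
every submodel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelConfig, ParameterSet

# indices into the packed parameter vector
_FIELDS = (
    "tau_loss", "V_drop", "V_tear_norm", "V_tear_res", "V_aq", "V_vit",
    "A_tear_aq", "A_aq_vit", "A_vit_ret", "k_on", "k_off",
    "delta_aq_v", "delta_aq_r", "delta_aq_u", "delta_aq_w",
    "delta_vit_v", "delta_vit_r", "delta_vit_u", "delta_vit_w",
    "beta_tear_aq_r",
    "beta_aq_vit_v", "beta_aq_vit_r", "beta_aq_vit_u", "beta_aq_vit_w",
    "beta_vit_ret_r", "beta_vit_ret_u", "beta_vit_ret_w",
    "phi_vit_v", "psi_tear", "psi_aq", "r_dose",
)
IDX = {name: i for i, name in enumerate(_FIELDS)}

# tear volume mode codes
TV_CONST_NORM = 0
TV_DEPLETING_HUMAN = 1
TV_CONST_DROP = 2
TV_DEPLETING_PORCINE = 3

TV_CODES = {
    "constant_norm": TV_CONST_NORM,
    "depleting_human": TV_DEPLETING_HUMAN,
    "constant_drop_porcine": TV_CONST_DROP,
    "depleting_porcine": TV_DEPLETING_PORCINE,
}

NEG_CLAMP_TOL = 1e-12


def pack_params(params: ParameterSet, config: ModelConfig) -> np.ndarray:
    """Flatten a ParameterSet for the kernel, applying the ex vivo switches."""
    p = params.ex_vivo() if config.ex_vivo else params
    return np.array([getattr(p, name) for name in _FIELDS], dtype=np.float64)


@njit(cache=True)
def tear_volume_k(t_local, p, tv_mode):
    if tv_mode == TV_CONST_NORM:
        return p[2]
    if tv_mode == TV_CONST_DROP:
        return p[1]
    frac = 1.0 - t_local / p[0]
    if t_local > p[0]:
        frac = 0.0
    if tv_mode == TV_DEPLETING_HUMAN:
        return p[2] + (p[3] - p[2]) * frac
    return p[1] * frac  # depleting porcine


@njit(cache=True)
def rhs_k(t_local, y, p, tv_mode, conc_held, tear_active, vegf_active, dy):
    r_tear = y[0]
    v_aq = y[1]
    r_aq = y[2]
    u_aq = y[3]
    w_aq = y[4]
    v_vit = y[5]
    r_vit = y[6]
    u_vit = y[7]
    w_vit = y[8]

    k_on = p[9]
    k_off = p[10]
    V_aq = p[4]
    V_vit = p[5]
    A_av = p[7]

    for i in range(9):
        dy[i] = 0.0

    tear_flux = 0.0
    if tear_active:
        if conc_held:
            tear_flux = p[19] * p[6] * r_tear
        else:
            V_tear = tear_volume_k(t_local, p, tv_mode)
            # The porcine run-off mode drains to zero volume at tau_loss,
            # where the 1/V rate is singular; the drug actually lost in the
            # final sliver is negligible, so freeze the film just short of
            # total drainage.
            if tv_mode == TV_DEPLETING_PORCINE and V_tear <= p[1] * 1e-6:
                V_tear = 0.0
            if V_tear > 0.0:
                dy[0] = -(p[19] * p[6] + p[28]) / V_tear * r_tear
                tear_flux = p[19] * p[6] * r_tear

    if vegf_active:
        first_a = k_off * u_aq - 2.0 * k_on * v_aq * r_aq
        second_a = 2.0 * k_off * w_aq - k_on * r_aq * u_aq
        first_v = k_off * u_vit - 2.0 * k_on * v_vit * r_vit
        second_v = 2.0 * k_off * w_vit - k_on * r_vit * u_vit
    else:
        first_a = second_a = first_v = second_v = 0.0

    ex_v = p[20] * A_av * (v_vit - v_aq)
    ex_r = p[21] * A_av * (r_vit - r_aq)
    ex_u = p[22] * A_av * (u_vit - u_aq)
    ex_w = p[23] * A_av * (w_vit - w_aq)

    # vitreo-retinal terms enter with a positive sign (source convention)
    dy[2] = (first_a + second_a) - p[12] * r_aq + (tear_flux + ex_r) / V_aq - p[29] / V_aq * r_aq
    dy[6] = (first_v + second_v) - p[16] * r_vit - ex_r / V_vit + p[24] * p[8] / V_vit * r_vit
    if vegf_active:
        dy[1] = first_a - p[11] * v_aq + ex_v / V_aq - p[29] / V_aq * v_aq
        dy[3] = (-first_a + second_a) - p[13] * u_aq + ex_u / V_aq - p[29] / V_aq * u_aq
        dy[4] = -second_a - p[14] * w_aq + ex_w / V_aq - p[29] / V_aq * w_aq
        dy[5] = first_v - p[15] * v_vit - ex_v / V_vit + p[27] / V_vit
        dy[7] = (-first_v + second_v) - p[17] * u_vit - ex_u / V_vit + p[25] * p[8] / V_vit * u_vit
        dy[8] = -second_v - p[18] * w_vit - ex_w / V_vit + p[26] * p[8] / V_vit * w_vit


# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0, 1.0, 1.0])
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0, 0.0],
        [44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0, 0.0, 0.0, 0.0],
        [19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0, 0.0, 0.0],
        [9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0, -5103.0 / 18656.0, 0.0],
    ]
)
_B = np.array([35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0])
# b - b_hat (error estimator weights, including the FSAL stage)
_E = np.array(
    [
        35.0 / 384.0 - 5179.0 / 57600.0,
        0.0,
        500.0 / 1113.0 - 7571.0 / 16695.0,
        125.0 / 192.0 - 393.0 / 640.0,
        -2187.0 / 6784.0 + 92097.0 / 339200.0,
        11.0 / 84.0 - 187.0 / 2100.0,
        -1.0 / 40.0,
    ]
)


@njit(cache=True)
def integrate_interval(
    t0,
    t1,
    tloc0,
    y,
    p,
    tv_mode,
    conc_held,
    tear_active,
    vegf_active,
    rtol,
    atol,
    out_times,
    out_states,
    out_start,
):
    """Integrate from global time ``t0`` to ``t1``; ``y`` is updated in place.

    ``tloc0`` is the local (since-last-drop) time at ``t0``.  Dense output
    is written into ``out_states`` for every entry of ``out_times`` in
    ``(t0, t1]``, starting at row ``out_start``; the new row cursor and a
    status code (0 = ok, 1 = step size underflow, 2 = negative state) are
    returned.
    """
    n = 9
    k = np.empty((7, n))
    ytmp = np.empty(n)
    ynew = np.empty(n)
    t = t0
    iout = out_start
    nout = out_times.shape[0]
    while iout < nout and out_times[iout] <= t0:
        iout += 1

    rhs_k(tloc0, y, p, tv_mode, conc_held, tear_active, vegf_active, k[0])
    h = min(1e-3, t1 - t0)
    if h <= 0.0:
        return iout, 0

    while t < t1:
        if h > t1 - t:
            h = t1 - t
        # stages
        for s in range(1, 6):
            for i in range(n):
                acc = 0.0
                for j in range(s):
                    acc += _A[s, j] * k[j, i]
                ytmp[i] = y[i] + h * acc
            rhs_k(tloc0 + (t - t0) + _C[s] * h, ytmp, p, tv_mode, conc_held, tear_active, vegf_active, k[s])
        for i in range(n):
            acc = 0.0
            for j in range(6):
                acc += _B[j] * k[j, i]
            ynew[i] = y[i] + h * acc
        rhs_k(tloc0 + (t - t0) + h, ynew, p, tv_mode, conc_held, tear_active, vegf_active, k[6])
        # error estimate
        err = 0.0
        for i in range(n):
            e = 0.0
            for j in range(7):
                e += _E[j] * k[j, i]
            e *= h
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            q = e / sc
            err += q * q
        err = np.sqrt(err / n)
        if err <= 1.0:
            # accept: dense output by cubic Hermite over [t, t+h]
            while iout < nout and out_times[iout] <= t + h:
                s01 = (out_times[iout] - t) / h
                h00 = (1.0 + 2.0 * s01) * (1.0 - s01) ** 2
                h10 = s01 * (1.0 - s01) ** 2
                h01 = s01 * s01 * (3.0 - 2.0 * s01)
                h11 = s01 * s01 * (s01 - 1.0)
                for i in range(n):
                    val = h00 * y[i] + h10 * h * k[0, i] + h01 * ynew[i] + h11 * h * k[6, i]
                    if val < 0.0 and val > -1e-9:
                        val = 0.0
                    out_states[iout, i] = val
                iout += 1
            t += h
            for i in range(n):
                val = ynew[i]
                if val < 0.0:
                    if val > -NEG_CLAMP_TOL:
                        val = 0.0
                    else:
                        return iout, 2
                y[i] = val
            rhs_k(tloc0 + (t - t0), y, p, tv_mode, conc_held, tear_active, vegf_active, k[0])
            fac = 1.25 if err == 0.0 else min(5.0, 0.9 * err ** (-0.2))
            h *= fac
        else:
            h *= max(0.2, 0.9 * err ** (-0.2))
        if h < 1e-14 * max(1.0, abs(t)):
            return iout, 1
    return iout, 0
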