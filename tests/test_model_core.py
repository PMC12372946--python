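"""Reaction kinetics, tear-volume law and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocupk import EyeState, ModelConfig, human_parameters, porcine_parameters
from ocupk.model import STATE_VARS, reaction_terms, rhs, tear_volume

K_ON, K_OFF = 0.576, 2.63e-2

conc = st.floats(min_value=0.0, max_value=1e5, allow_nan=False)


class TestReactionTerms:
    def test_empty_system_is_inert(self):
        assert reaction_terms(0, 0, 0, 0, K_ON, K_OFF) == (0, 0, 0, 0)

    def test_hand_evaluated_rates(self):
        # v = r = 1, no complexes: only the first binding step fires at 2*k_on
        dv, dr, du, dw = reaction_terms(1.0, 1.0, 0.0, 0.0, K_ON, K_OFF)
        assert dv == pytest.approx(-1.152)
        assert dr == pytest.approx(-1.152)
        assert du == pytest.approx(1.152)
        assert dw == 0.0

    def test_chemical_equilibrium_is_fixed_point(self):
        # detailed balance: u/(v r) = 2 k_on / k_off, w/(r u) = k_on / (2 k_off)
        v, r = 0.7, 1.3
        ratio = 2.0 * K_ON / K_OFF
        assert ratio == pytest.approx(43.8, rel=1e-3)
        u = ratio * v * r
        w = K_ON / (2.0 * K_OFF) * r * u
        rates = reaction_terms(v, r, u, w, K_ON, K_OFF)
        for d in rates:
            assert abs(d) < 1e-10 * u

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            reaction_terms(-1.0, 0.0, 0.0, 0.0, K_ON, K_OFF)

    @settings(max_examples=200, derandomize=True)
    @given(v=conc, r=conc, u=conc, w=conc)
    def test_conservation_of_both_totals(self, v, r, u, w):
        # binding shuffles molecules between species but creates none:
        # total VEGF (v + u + w) and total drug (r + u + 2w) are conserved
        dv, dr, du, dw = reaction_terms(v, r, u, w, K_ON, K_OFF)
        scale = max(abs(dv), abs(dr), abs(du), abs(dw), 1.0)
        assert abs(dv + du + dw) <= 1e-12 * scale
        assert abs(dr + du + 2 * dw) <= 1e-12 * scale


class TestTearVolume:
    def test_human_depletion_profile(self, human):
        cfg = ModelConfig.human_drops()
        assert tear_volume(0.0, cfg, human) == pytest.approx(3.00e-2)
        # linear midpoint
        assert tear_volume(human.tau_loss / 2, cfg, human) == pytest.approx(1.8175e-2)
        # H(0) = 1: exactly at tau_loss the volume is back to baseline
        assert tear_volume(human.tau_loss, cfg, human) == pytest.approx(6.35e-3)
        assert tear_volume(10.0, cfg, human) == pytest.approx(6.35e-3)

    def test_constant_modes(self, human, porcine):
        assert tear_volume(7.0, ModelConfig.human_lens(), human) == human.V_tear_norm
        cfg = ModelConfig.ex_vivo_topical(constant_volume=True)
        assert tear_volume(7.0, cfg, porcine) == porcine.V_drop

    def test_porcine_runoff_drains_to_zero(self, porcine):
        cfg = ModelConfig.ex_vivo_topical(constant_volume=False)
        assert tear_volume(0.0, cfg, porcine) == porcine.V_drop
        assert tear_volume(porcine.tau_loss, cfg, porcine) == 0.0
        assert tear_volume(1.0, cfg, porcine) == 0.0

    def test_negative_time_rejected(self, human):
        with pytest.raises(ValueError):
            tear_volume(-0.1, ModelConfig.human_drops(), human)


class TestRhs:
    def test_only_vegf_supply_survives_at_zero_state(self, human):
        dy = rhs(0.0, np.zeros(9), ModelConfig.human_injection(), human)
        expected = np.zeros(9)
        expected[STATE_VARS.index("v_vit")] = human.phi_vit_v / human.V_vit
        assert expected[STATE_VARS.index("v_vit")] == pytest.approx(5.2e-5, rel=1e-3)
        np.testing.assert_allclose(dy, expected)

    def test_ex_vivo_zero_state_is_inert(self, porcine):
        dy = rhs(0.0, np.zeros(9), ModelConfig.ex_vivo_topical(), porcine)
        np.testing.assert_array_equal(dy, np.zeros(9))

    @settings(max_examples=100, derandomize=True)
    @given(y=st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=9, max_size=9))
    def test_closed_system_conserves_moles(self, y):
        # no turnover, supply, degradation, or boundary fluxes: the time
        # derivative of both compartment-volume-weighted totals vanishes
        p = human_parameters().replace(
            psi_tear=0.0, psi_aq=0.0, phi_vit_v=0.0, beta_tear_aq_r=0.0,
            beta_vit_ret_r=0.0, beta_vit_ret_u=0.0, beta_vit_ret_w=0.0,
        )
        y = np.asarray(y)
        dy = rhs(0.0, y, ModelConfig.human_drops(), p)
        d = dict(zip(STATE_VARS, dy))
        dV = p.V_aq * (d["v_aq"] + d["u_aq"] + d["w_aq"]) + p.V_vit * (
            d["v_vit"] + d["u_vit"] + d["w_vit"]
        )
        dR = p.V_aq * (d["r_aq"] + d["u_aq"] + 2 * d["w_aq"]) + p.V_vit * (
            d["r_vit"] + d["u_vit"] + 2 * d["w_vit"]
        )
        scale = max(1.0, np.abs(dy).max()) * max(p.V_aq, p.V_vit)
        assert abs(dV) <= 1e-10 * scale
        assert abs(dR) <= 1e-10 * scale

    @settings(max_examples=100, derandomize=True)
    @given(x_aq=conc, x_vit=conc)
    def test_exchange_antisymmetry(self, x_aq, x_vit):
        # the mole flux leaving one compartment enters the other exactly;
        # probe with drug only (all other couplings off)
        p = human_parameters().replace(
            psi_aq=0.0, beta_vit_ret_r=0.0, beta_tear_aq_r=0.0, phi_vit_v=0.0
        )
        y = np.zeros(9)
        y[STATE_VARS.index("r_aq")] = x_aq
        y[STATE_VARS.index("r_vit")] = x_vit
        dy = rhs(0.0, y, ModelConfig.human_injection(), p)
        flux_aq = p.V_aq * dy[STATE_VARS.index("r_aq")]
        flux_vit = p.V_vit * dy[STATE_VARS.index("r_vit")]
        assert flux_aq + flux_vit == pytest.approx(0.0, abs=1e-10 * max(1.0, abs(flux_aq)))

    def test_vegf_disabled_matches_full_model_without_vegf(self, porcine):
        # with no VEGF anywhere there is no binding, so the drug-only
        # submodel and the full model agree on the drug derivatives
        y = np.zeros(9)
        y[STATE_VARS.index("r_tear")] = 2.07e4
        y[STATE_VARS.index("r_aq")] = 0.05
        y[STATE_VARS.index("r_vit")] = 0.01
        cfg_on = ModelConfig.ex_vivo_topical(vegf=True)
        cfg_off = ModelConfig.ex_vivo_topical(vegf=False)
        np.testing.assert_allclose(rhs(0.0, y, cfg_on, porcine), rhs(0.0, y, cfg_off, porcine))

    def test_frozen_porcine_tear_after_runoff(self, porcine):
        cfg = ModelConfig.ex_vivo_topical(constant_volume=False)
        y = np.zeros(9)
        y[0] = 2.07e4
        dy = rhs(porcine.tau_loss + 0.01, y, cfg, porcine)
        # tear is frozen and the tear->aqueous flux is off
        np.testing.assert_array_equal(dy, np.zeros(9))


class TestEyeState:
    def test_roundoff_negatives_clamped_larger_rejected(self):
        s = EyeState(0.0, -1e-13, 0, 0, 0, 0, 0, 0, 0, 0)
        assert s.r_tear == 0.0
        with pytest.raises(ValueError):
            EyeState(0.0, -1e-6, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_array_roundtrip(self):
        s = EyeState(1e-2, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
        assert EyeState.from_array(s.to_array(), 1e-2) == s
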