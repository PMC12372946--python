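"""Dose resets, regimen construction and schedule invariants."""

import numpy as np
import pytest

from ocupk import Regimen, TreatmentEvent, apply_drop, apply_injection, apply_lens, build_standard_regimen
from ocupk.dosing import daily_drops, hourly_drops, lens_cycles, merge, periodic_injections
from ocupk.model import EyeState


class TestDropMixing:
    def test_first_drop_gives_reference_tear_concentration(self, human):
        s = apply_drop(EyeState.zero(), human)
        assert s.r_tear == pytest.approx(1.81e4, rel=5e-3)
        assert s.V_tear == human.V_tear_res

    def test_mixing_identical_fluids_is_fixed_point(self, human):
        s = apply_drop(EyeState.zero().replace(r_tear=human.r_dose), human)
        assert s.r_tear == pytest.approx(human.r_dose, rel=1e-12)

    def test_convex_combination(self, human):
        s = apply_drop(EyeState.zero().replace(r_tear=1.0e3), human)
        expected = 1.0e3 * 6.35e-3 / 5.135e-2 + 2.07e4 * 4.5e-2 / 5.135e-2
        assert s.r_tear == pytest.approx(expected, rel=1e-12)
        assert s.r_tear == pytest.approx(1.826e4, rel=1e-3)

    def test_porcine_drop_takes_full_dose(self, porcine):
        s = apply_drop(EyeState.zero(), porcine)
        assert s.r_tear == porcine.r_dose
        assert s.V_tear == porcine.V_drop

    def test_drop_touches_only_tear_variables(self, human):
        before = EyeState(6.35e-3, 0.0, 1e-3, 2e-3, 3e-3, 4e-3, 5e-3, 6e-3, 7e-3, 8e-3)
        after = apply_drop(before, human)
        for name in ("v_aq", "r_aq", "u_aq", "w_aq", "v_vit", "r_vit", "u_vit", "w_vit"):
            assert getattr(after, name) == getattr(before, name)


class TestInjection:
    def test_human_bolus(self, human):
        assert apply_injection(EyeState.zero(), human).r_vit == pytest.approx(2.07e2)

    def test_porcine_bolus(self, porcine):
        assert apply_injection(EyeState.zero(), porcine).r_vit == pytest.approx(3.00e2, rel=2e-3)

    def test_zero_dose_is_identity(self, human):
        p = human.replace(r_dose=0.0)
        s = EyeState(0.0, 0.0, 1e-3, 0, 0, 0, 2e-3, 5.0, 0, 0)
        assert apply_injection(s, p) == s

    def test_bolus_adds_exact_drug_amount(self, human):
        s0 = EyeState(0.0, 0.0, 1e-3, 0, 1e-4, 0, 2e-3, 5.0, 1e-4, 0)
        s1 = apply_injection(s0, human)
        assert (s1.r_vit - s0.r_vit) * human.V_vit == pytest.approx(human.r_dose * human.V_drop)
        # VEGF amounts untouched
        assert s1.total_v_moles(human) == s0.total_v_moles(human)

    def test_drop_preserves_vegf_moles(self, human):
        s0 = EyeState(6.35e-3, 0.0, 1e-3, 0, 1e-4, 2e-5, 2e-3, 0, 1e-4, 2e-5)
        assert apply_drop(s0, human).total_v_moles(human) == s0.total_v_moles(human)


class TestLens:
    def test_insertion_pins_reference_concentration(self, human):
        s = apply_lens(EyeState.zero().replace(r_tear=123.0), human, on=True)
        assert s.r_tear == human.r_tear_init == pytest.approx(1.81e4)

    def test_removal_leaves_concentration(self, human):
        s = apply_lens(EyeState.zero().replace(r_tear=9.0, V_tear=human.V_tear_norm), human, on=False)
        assert s.r_tear == 9.0

    def test_post_removal_decay_rate(self, human):
        # linear decay coefficient (beta A + psi) / V_norm at baseline volume
        rate = (human.beta_tear_aq_r * human.A_tear_aq + human.psi_tear) / human.V_tear_norm
        assert rate == pytest.approx(11.34, rel=1e-3)


class TestRegimenValidation:
    def test_events_sorted_and_lens_alternation(self):
        with pytest.raises(ValueError):
            Regimen((TreatmentEvent(0.0, "lens_off"),), 10.0)
        with pytest.raises(ValueError):
            Regimen(
                (TreatmentEvent(0.0, "lens_on"), TreatmentEvent(1.0, "lens_on")), 10.0
            )
        r = Regimen((TreatmentEvent(5.0, "drop"), TreatmentEvent(1.0, "drop")), 10.0)
        assert [e.time for e in r.events] == [1.0, 5.0]

    def test_drop_spacing_constraint(self, human):
        r = Regimen((TreatmentEvent(0.0, "drop"), TreatmentEvent(0.01, "drop")), 1.0)
        with pytest.raises(ValueError):
            r.validate_drop_spacing(human.tau_loss)

    def test_horizon_must_cover_events(self):
        with pytest.raises(ValueError):
            Regimen((TreatmentEvent(5.0, "drop"),), 4.0)

    def test_json_roundtrip(self):
        r = periodic_injections(4, 16 * 168.0)
        assert Regimen.from_json(r.to_json()) == r


class TestBuilders:
    def test_monthly_injections_fall_at_week_starts(self):
        r = build_standard_regimen("injections", interval_weeks=4, t_end=16 * 168.0)
        assert [e.time for e in r.events] == [0.0, 672.0, 1344.0, 2016.0]
        assert all(e.kind == "injection" for e in r.events)

    def test_one_drop_per_day(self):
        r = daily_drops(1, n_days=3, t_end=4 * 24.0)
        assert [e.time for e in r.events] == [0.0, 24.0, 48.0]

    def test_sixteen_drops_hourly(self):
        r = daily_drops(16, n_days=1, t_end=24.0)
        assert [e.time for e in r.events] == [float(h) for h in range(16)]

    def test_four_drops_spacing(self):
        r = daily_drops(4, n_days=1, t_end=24.0)
        assert [e.time for e in r.events] == [0.0, 4.0, 8.0, 12.0]

    def test_hourly_drops_cover_whole_day(self):
        r = hourly_drops(2, t_end=49.0)
        assert len(r.events) == 48
        assert r.events[-1].time == 47.0

    def test_lens_cycles_thirty_days_on_one_off(self):
        r = lens_cycles(30, n_cycles=4, t_end=152 * 24.0)
        ons = [e.time for e in r.events if e.kind == "lens_on"]
        offs = [e.time for e in r.events if e.kind == "lens_off"]
        assert ons == [0.0, 31 * 24.0, 62 * 24.0, 93 * 24.0]
        assert offs == [30 * 24.0, 61 * 24.0, 92 * 24.0, 123 * 24.0]

    def test_out_of_range_intensities_rejected(self):
        with pytest.raises(ValueError):
            daily_drops(0, 1, 24.0)
        with pytest.raises(ValueError):
            daily_drops(17, 1, 24.0)
        with pytest.raises(ValueError):
            lens_cycles(31, 1, 40 * 24.0)
        with pytest.raises(ValueError):
            periodic_injections(9, 16 * 168.0)
        with pytest.raises(ValueError):
            build_standard_regimen("nope")

    def test_merge_keeps_both_schedules(self):
        dual = build_standard_regimen("drops+injections", interval_weeks=4)
        kinds = dual.kinds()
        assert kinds == {"drop", "injection"}
        inj = [e.time for e in dual.events if e.kind == "injection"]
        assert inj == [0.0, 672.0, 1344.0, 2016.0]
        # a drop and an injection coincide at t = 0; the drop sorts first
        first_two = [e.kind for e in dual.events[:2]]
        assert first_two == ["drop", "injection"]
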