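"""Trajectory integration: oracles, invariants and backend agreement."""

import numpy as np
import pytest

from ocupk import (
    ModelConfig,
    Regimen,
    TimeSeries,
    TreatmentEvent,
    simulate,
    summarize,
    total_ranibizumab,
)
from ocupk.dosing import build_standard_regimen, daily_drops
from ocupk.model import EyeState


def closed_params(human):
    return human.replace(
        psi_tear=0.0, psi_aq=0.0, phi_vit_v=0.0, beta_tear_aq_r=0.0,
        beta_vit_ret_r=0.0, beta_vit_ret_u=0.0, beta_vit_ret_w=0.0,
    )


class TestTotalRanibizumab:
    def test_free_drug_counts_once(self):
        assert total_ranibizumab(EyeState.zero().replace(r_vit=1.0)) == 1.0

    def test_double_bound_counts_twice(self):
        assert total_ranibizumab(EyeState.zero().replace(w_vit=1.0)) == 2.0

    def test_post_injection_total(self, human):
        from ocupk import apply_injection

        s = apply_injection(EyeState.zero(), human)
        assert total_ranibizumab(s) == pytest.approx(207.0)


class TestSimulate:
    def test_untreated_human_stays_at_steady_state(self, human):
        from ocupk import untreated_vegf_steady_state

        v_aq, v_vit = untreated_vegf_steady_state(human)
        p = human.replace(v_aq_init=v_aq, v_vit_init=v_vit)
        ts = simulate(Regimen((), 200.0), p, ModelConfig.human_injection())
        np.testing.assert_allclose(ts.column("v_aq"), v_aq, rtol=1e-6)
        np.testing.assert_allclose(ts.column("v_vit"), v_vit, rtol=1e-6)

    def test_ex_vivo_zero_state_stays_zero(self, porcine):
        ts = simulate(Regimen((), 5.0), porcine, ModelConfig.ex_vivo_injection())
        np.testing.assert_array_equal(ts.states[:, 1:], 0.0)

    def test_single_injection_vegf_collapse(self, human):
        # deep, fast vitreal VEGF suppression minutes after the bolus
        reg = build_standard_regimen("single_dose", kind="injection", t_end=672.0)
        ts = simulate(reg, human, ModelConfig.human_injection())
        v = ts.column("v_vit")
        t_min = ts.times[v.argmin()]
        assert v.min() == pytest.approx(2.21e-7, rel=0.02)
        assert t_min == pytest.approx(0.2, abs=0.1)  # ~12 min
        assert ts.column("r_vit").max() == pytest.approx(207.0, rel=1e-3)

    def test_mole_conservation_along_trajectory(self, human):
        p = closed_params(human)
        y0 = EyeState(0.0, 0.0, 1.5e-3, 0.0, 1e-3, 5e-4, 2.2e-3, 0.0, 1e-3, 5e-4)
        reg = Regimen((TreatmentEvent(0.0, "injection"),), 10.0)
        ts = simulate(reg, p, ModelConfig.human_injection(), y0=y0)
        V = p.V_aq * (ts.column("v_aq") + ts.column("u_aq") + ts.column("w_aq")) + p.V_vit * (
            ts.column("v_vit") + ts.column("u_vit") + ts.column("w_vit")
        )
        R = p.V_aq * ts.r_tot_aq + p.V_vit * ts.r_tot_vit
        assert np.abs(V / V[0] - 1).max() < 1e-6
        assert np.abs(R[1:] / R[1] - 1).max() < 1e-6  # after the bolus row

    def test_backends_agree(self, human):
        reg = build_standard_regimen("single_dose", kind="injection", t_end=48.0)
        a = simulate(reg, human, ModelConfig.human_injection(), backend="compiled")
        b = simulate(reg, human, ModelConfig.human_injection(), backend="scipy")
        np.testing.assert_array_equal(a.times, b.times)
        scale = np.abs(b.states).max(axis=0) + 1e-30
        assert np.abs(a.states - b.states).max(axis=0) / scale == pytest.approx(
            np.zeros(10), abs=1e-5
        )

    def test_stiff_fallback_agrees(self, human):
        reg = Regimen((TreatmentEvent(0.0, "injection"),), 10.0)
        a = simulate(reg, human, ModelConfig.human_injection())
        b = simulate(reg, human, ModelConfig.human_injection(), backend="scipy", method="LSODA")
        iv = TimeSeries.COLUMNS.index("v_vit")
        assert np.abs(a.states[:, iv] - b.states[:, iv]).max() < 1e-4 * b.states[:, iv].max()

    def test_noop_event_split_equals_unsplit(self, human):
        # splitting the integration at a zero-dose event must not change
        # the trajectory beyond solver tolerance
        p = human.replace(r_dose=0.0)
        y0 = EyeState(0.0, 0.0, human.v_aq_init, 0, 0, 0, human.v_vit_init, 50.0, 0, 0)
        plain = simulate(Regimen((), 48.0), p, ModelConfig.human_injection(), y0=y0)
        split = simulate(
            Regimen((TreatmentEvent(24.0, "injection"),), 48.0),
            p, ModelConfig.human_injection(), y0=y0,
        )
        for col in ("v_vit", "r_vit", "r_aq"):
            i = TimeSeries.COLUMNS.index(col)
            a = np.interp([10.0, 30.0, 47.0], plain.times, plain.states[:, i])
            b = np.interp([10.0, 30.0, 47.0], split.times, split.states[:, i])
            np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_tolerance_refinement_is_converged(self, human):
        reg = daily_drops(4, 3, 4 * 24.0)
        cfg = ModelConfig.human_drops()
        a = summarize(simulate(reg, human, cfg), (48.0, 96.0))
        b = summarize(simulate(reg, human, cfg, rtol=5e-9, atol=5e-13), (48.0, 96.0))
        for f in ("v_vit_max", "v_vit_mean", "v_vit_min", "r_tot_vit_mean"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-3)

    def test_sustained_dosing_settles_to_periodic_pattern(self, human):
        # after ~2 months of daily drops the weekly statistics repeat
        reg = daily_drops(16, 84, 12 * 168.0)
        ts = simulate(reg, human, ModelConfig.human_drops())
        late = summarize(ts, (9 * 168.0, 12 * 168.0))
        earlier = summarize(ts, (6 * 168.0, 9 * 168.0))
        for f in ("v_vit_max", "v_vit_mean", "v_vit_min",
                  "r_tot_vit_max", "r_tot_vit_mean", "r_tot_vit_min"):
            assert getattr(late, f) == pytest.approx(getattr(earlier, f), rel=5e-3)

    def test_grid_too_coarse_rejected(self, human):
        with pytest.raises(ValueError):
            simulate(Regimen((), 1.0), human, ModelConfig.human_injection(), grid_dt=0.5)

    def test_event_times_sampled_twice(self, human):
        reg = Regimen((TreatmentEvent(24.0, "injection"),), 48.0)
        ts = simulate(reg, human, ModelConfig.human_injection())
        hits = np.where(ts.times == 24.0)[0]
        assert len(hits) >= 2
        iv = TimeSeries.COLUMNS.index("r_vit")
        jump = ts.states[hits[-1], iv] - ts.states[hits[0], iv]
        assert jump == pytest.approx(207.0, rel=1e-6)

    def test_trajectory_is_nonnegative(self, human):
        reg = daily_drops(16, 2, 3 * 24.0)
        ts = simulate(reg, human, ModelConfig.human_drops())
        assert ts.states.min() >= 0.0


class TestSummarize:
    def test_constant_trajectory(self, human):
        ts = simulate(Regimen((), 50.0), human, ModelConfig.human_injection())
        s = summarize(ts, (10.0, 40.0))
        assert s.v_vit_min <= s.v_vit_mean <= s.v_vit_max
        assert s.v_vit_mean == pytest.approx(2.24e-3, rel=1e-3)

    def test_sawtooth_mean_is_trapezoid_value(self, human):
        # hand-built piecewise-linear signal: mean must equal the exact
        # integral, not the sample average
        times = np.array([0.0, 1.0, 3.0, 4.0])
        v = np.array([0.0, 1.0, 1.0, 0.0])
        states = np.zeros((4, 10))
        states[:, TimeSeries.COLUMNS.index("v_vit")] = v
        ts = TimeSeries(times, states, human, ModelConfig.human_injection())
        s = summarize(ts, (0.0, 4.0))
        assert s.v_vit_mean == pytest.approx(3.0 / 4.0)
        assert s.v_vit_max == 1.0 and s.v_vit_min == 0.0

    def test_window_outside_span_rejected(self, human):
        ts = simulate(Regimen((), 10.0), human, ModelConfig.human_injection())
        with pytest.raises(ValueError):
            summarize(ts, (5.0, 20.0))

    def test_csv_export_roundtrip(self, human, tmp_path):
        ts = simulate(Regimen((), 1.0), human, ModelConfig.human_injection())
        path = tmp_path / "traj.csv"
        ts.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time_h"] + list(TimeSeries.COLUMNS)
        np.testing.assert_allclose(df["v_vit"], ts.column("v_vit"))
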