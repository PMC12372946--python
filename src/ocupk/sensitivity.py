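"""Local sensitivity analysis and dosing-regimen sweeps.

One parameter at a time is varied across a uniform grid over its
biologically realistic range while all others are held at their defaults.
For each value the in vivo human model is run for 12 weeks under a fixed
regimen and the max / time-mean / min of vitreal VEGF and total vitreal
drug are computed over weeks 9-12, where the solution has settled to a
steady or periodic pattern.  The *sensitivity factor* of an output is the
largest value it attains across the sweep divided by the smallest; a
factor above 1.5 is deemed significant.

Parameters that enter the untreated VEGF balance (supply, aqueous
turnover, VEGF exchange permeability, VEGF degradation) change the
pre-treatment steady state, so the initial conditions are re-derived for
each draw by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosing import (
    HOURS_PER_DAY,
    HOURS_PER_WEEK,
    Regimen,
    TreatmentEvent,
    daily_drops,
    hourly_drops,
    lens_cycles,
    merge,
    periodic_injections,
    weekly_lens_weeks,
)
from .params import SENSITIVITY_RANGES, ModelConfig, ParameterSet, human_parameters
from .simulate import SummaryStats, simulate, summarize
from .steady import with_steady_state_init

__all__ = ["sweep_parameter", "regimen_sweep", "SENSITIVITY_REGIMENS", "sensitivity_table"]

#: parameters whose variation alters the untreated VEGF steady state
STEADY_STATE_PARAMS = frozenset(
    {"phi_vit_v", "psi_aq", "beta_aq_vit_v", "A_aq_vit", "delta_aq_v", "delta_vit_v", "V_aq", "V_vit"}
)

SIGNIFICANCE_THRESHOLD = 1.5

OUTPUT_NAMES = (
    "v_vit_max", "v_vit_mean", "v_vit_min",
    "r_tot_vit_max", "r_tot_vit_mean", "r_tot_vit_min",
)

#: the three single-mode regimens considered by the sensitivity analysis
SENSITIVITY_REGIMENS = ("drops", "lens", "injections")

_TWELVE_WEEKS = 12 * HOURS_PER_WEEK
_WINDOW = (9 * HOURS_PER_WEEK, 12 * HOURS_PER_WEEK)


def _sensitivity_setup(regimen_name: str) -> tuple[Regimen, ModelConfig]:
    if regimen_name == "drops":
        # one drop on the hour, every hour, for the full 12 weeks
        reg = hourly_drops(n_days=84, t_end=_TWELVE_WEEKS)
        return reg, ModelConfig.human_drops()
    if regimen_name == "lens":
        # a lens worn continuously for the full 12 weeks
        reg = Regimen((TreatmentEvent(0.0, "lens_on"),), _TWELVE_WEEKS)
        return reg, ModelConfig.human_lens()
    if regimen_name == "injections":
        # injections at the start of weeks 1, 5 and 9
        events = tuple(TreatmentEvent(w * HOURS_PER_WEEK, "injection") for w in (0.0, 4.0, 8.0))
        return Regimen(events, _TWELVE_WEEKS), ModelConfig.human_injection()
    raise ValueError(f"unknown sensitivity regimen {regimen_name!r}")


def _summary_outputs(params: ParameterSet, regimen_name: str, grid_dt: float) -> np.ndarray:
    reg, cfg = _sensitivity_setup(regimen_name)
    ts = simulate(reg, params, cfg, grid_dt=grid_dt)
    s = summarize(ts, _WINDOW)
    return np.array(
        [s.v_vit_max, s.v_vit_mean, s.v_vit_min, s.r_tot_vit_max, s.r_tot_vit_mean, s.r_tot_vit_min]
    )


def sweep_parameter(
    param_name: str,
    value_range: tuple[float, float] | None = None,
    n_values: int = 101,
    regimen: str = "drops",
    base_params: ParameterSet | None = None,
    recompute_init: bool = True,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Sweep one parameter and return its sensitivity-factor rows.

    Returns a tidy frame with one row per output: columns ``parameter``,
    ``regimen``, ``output``, ``factor``, ``significant``, plus the swept
    ``values`` min/max for provenance.  A zero output minimum yields an
    infinite factor flagged significant.
    """
    if base_params is None:
        base_params = human_parameters()
    if value_range is None:
        if param_name not in SENSITIVITY_RANGES:
            raise KeyError(f"no default range for parameter {param_name!r}")
        value_range = SENSITIVITY_RANGES[param_name]
    values = np.linspace(value_range[0], value_range[1], n_values)
    outputs = np.empty((n_values, 6))
    for i, val in enumerate(values):
        p = base_params.replace(**{param_name: float(val)})
        if recompute_init and param_name in STEADY_STATE_PARAMS:
            p = with_steady_state_init(p)
        outputs[i] = _summary_outputs(p, regimen, grid_dt)
    rows = []
    for j, out_name in enumerate(OUTPUT_NAMES):
        col = outputs[:, j]
        if col.min() <= 0.0:
            factor = np.inf
        else:
            factor = float(col.max() / col.min())
        rows.append(
            {
                "parameter": param_name,
                "regimen": regimen,
                "output": out_name,
                "factor": factor,
                "significant": bool(factor > SIGNIFICANCE_THRESHOLD),
                "value_min": value_range[0],
                "value_max": value_range[1],
                "n_values": n_values,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_table(
    param_names=None,
    regimens=SENSITIVITY_REGIMENS,
    n_values: int = 101,
    base_params: ParameterSet | None = None,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Sensitivity factors for several parameters under several regimens
    (tidy, one row per parameter x regimen x output)."""
    if param_names is None:
        param_names = list(SENSITIVITY_RANGES)
    frames = [
        sweep_parameter(name, n_values=n_values, regimen=reg, base_params=base_params, grid_dt=grid_dt)
        for name in param_names
        for reg in regimens
    ]
    return pd.concat(frames, ignore_index=True)


# -- dosing-regimen sweeps ------------------------------------------------


def regimen_sweep(
    mode: str,
    base_params: ParameterSet | None = None,
    intensities=None,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Vary the dosing intensity of a regimen family and summarise the
    vitreal outcomes over the final settled window.

    ``mode``:

    - ``"drops"``: 1-16 drops/day (first at 0 h, spacing 16/n h), 12-week
      horizon, window weeks 9-12.
    - ``"lens"``: lenses worn 1-30 days with 1-day breaks, 124-day
      horizon, window = the final (n_day + 1)-day cycle.
    - ``"injections"``: interinjection interval 1-8 weeks, first at the
      start of week 1, 32-week horizon, window = final interval.
    - ``"drops+injections"``: injections as above plus four drops/day at
      4, 8, 12 and 16 h.
    - ``"lens+injections"``: injections as above plus lenses worn days
      2-7 of every week.
    """
    if base_params is None:
        base_params = human_parameters()
    known = ("drops", "lens", "injections", "drops+injections", "lens+injections")
    if mode not in known:
        raise ValueError(f"mode must be one of {known}")

    defaults = {
        "drops": range(1, 17),
        "lens": range(1, 31),
        "injections": range(1, 9),
        "drops+injections": range(1, 9),
        "lens+injections": range(1, 9),
    }
    if intensities is None:
        intensities = defaults[mode]

    rows = []
    for k in intensities:
        k = int(k)
        if k not in defaults[mode]:
            raise ValueError(f"intensity {k} out of range for mode {mode!r}")
        if mode == "drops":
            t_end = _TWELVE_WEEKS
            reg = daily_drops(k, n_days=84, t_end=t_end)
            cfg = ModelConfig.human_drops()
            window = _WINDOW
        elif mode == "lens":
            t_end = 124 * HOURS_PER_DAY
            n_cycles = int(np.floor(124 / (k + 1)))
            reg = lens_cycles(k, n_cycles=n_cycles, t_end=t_end)
            cfg = ModelConfig.human_lens()
            cycle_h = (k + 1) * HOURS_PER_DAY
            last_start = (n_cycles - 1) * cycle_h
            window = (last_start, last_start + cycle_h)
        else:
            t_end = 32 * HOURS_PER_WEEK
            inj = periodic_injections(k, t_end)
            last_inj = max(e.time for e in inj.events)
            cycle = k * HOURS_PER_WEEK
            # final complete inter-injection cycle within the horizon
            if last_inj + cycle <= t_end:
                window = (last_inj, last_inj + cycle)
            else:
                window = (last_inj - cycle, last_inj)
            if mode == "injections":
                reg, cfg = inj, ModelConfig.human_injection()
            elif mode == "drops+injections":
                drops = Regimen(
                    tuple(
                        TreatmentEvent(day * HOURS_PER_DAY + h, "drop")
                        for day in range(32 * 7)
                        for h in (4.0, 8.0, 12.0, 16.0)
                    ),
                    t_end,
                )
                reg, cfg = merge(drops, inj, t_end), ModelConfig.human_drops()
            else:
                lens = weekly_lens_weeks(32, t_end)
                reg, cfg = merge(lens, inj, t_end), ModelConfig.human_lens()

        ts = simulate(reg, base_params, cfg, grid_dt=grid_dt)
        s = summarize(ts, window)
        rows.append(
            {
                "mode": mode,
                "intensity": k,
                "v_vit_max": s.v_vit_max,
                "v_vit_mean": s.v_vit_mean,
                "v_vit_min": s.v_vit_min,
                "r_tot_vit_max": s.r_tot_vit_max,
                "r_tot_vit_mean": s.r_tot_vit_mean,
                "r_tot_vit_min": s.r_tot_vit_min,
            }
        )
    return pd.DataFrame(rows)
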