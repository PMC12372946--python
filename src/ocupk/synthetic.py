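"""Synthetic bench measurements for parameter-recovery studies.

Emulates the ex vivo porcine sampling design: concentrations measured in
the aqueous and vitreous at 20 min, 40 min, 1 h and 3.5 h with three
replicate eyes per point.  Replicates are the model trajectory plus
additive Gaussian noise truncated at zero -- mimicking an immunoassay
with a detection floor (real datasets of this design contain exact
zeros).  The generator lets the fitting and Metropolis-Hastings code be
validated by recovering known permeabilities without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosing import Regimen, TreatmentEvent
from .fitting import FIT_TIMES_ALL, MeasurementSet
from .model import EyeState
from .params import ModelConfig, ParameterSet, porcine_parameters
from .simulate import simulate

__all__ = ["MeasurementDesign", "NoiseModel", "generate_measurements"]


@dataclass(frozen=True)
class MeasurementDesign:
    """Which bench experiment is emulated and when it is sampled."""

    group: str = "topical_cpp"  # topical_cpp | invit_plain
    times: tuple[float, ...] = FIT_TIMES_ALL
    n_replicates: int = 3
    #: initial state override for the injection design (aqueous, vitreal)
    injected_state: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in ("topical_cpp", "invit_plain"):
            raise ValueError("group must be 'topical_cpp' or 'invit_plain'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, sd = max(absolute floor, proportional x
    signal), truncated at zero."""

    sd_absolute: float = 0.0
    sd_proportional: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_absolute < 0 or self.sd_proportional < 0:
            raise ValueError("noise scales must be >= 0")

    def sd_for(self, signal: np.ndarray) -> np.ndarray:
        return np.maximum(self.sd_absolute, self.sd_proportional * np.abs(signal))


def _true_trajectory(params: ParameterSet, design: MeasurementDesign, vegf: bool):
    """Noise-free aqueous and vitreal drug concentrations at the design
    times for the requested submodel."""
    t_end = max(design.times) + 1e-6
    if design.group == "topical_cpp":
        cfg = ModelConfig.ex_vivo_topical(constant_volume=True, vegf=vegf)
        reg = Regimen((TreatmentEvent(0.0, "drop"),), t_end)
        ts = simulate(reg, params, cfg, grid_dt=0.005)
    else:
        cfg = ModelConfig.ex_vivo_injection(vegf=vegf)
        reg = Regimen((TreatmentEvent(0.0, "injection"),), t_end)
        ts = simulate(reg, params, cfg, grid_dt=0.005)
    times = np.asarray(design.times, float)
    r_aq = np.interp(times, ts.times, ts.column("r_aq"))
    r_vit = np.interp(times, ts.times, ts.column("r_vit"))
    return r_aq, r_vit


def generate_measurements(
    true_params: ParameterSet | None = None,
    design: MeasurementDesign | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    vegf: bool = False,
) -> MeasurementSet:
    """Simulate the chosen bench submodel and sample noisy replicates.

    Returns a :class:`MeasurementSet` with the same schema as the real
    summary table (per-point mean, sd over ``n_replicates``).  With a
    zero-noise model the means equal the exact trajectory and sd = 0.

    Seeding: the single ``seed`` is fanned out to one independent stream
    per (compartment, time, replicate), so increasing the replicate count
    extends -- rather than reshuffles -- the earlier replicates.
    """
    params = true_params or porcine_parameters()
    design = design or MeasurementDesign()
    noise = noise_model or NoiseModel()

    r_aq, r_vit = _true_trajectory(params, design, vegf)
    rows = []
    root = np.random.SeedSequence(seed)
    for c_idx, (comp, signal) in enumerate((("Aq", r_aq), ("Vit", r_vit))):
        for t_idx, t in enumerate(design.times):
            sd = float(noise.sd_for(np.array([signal[t_idx]]))[0])
            reps = []
            for k in range(design.n_replicates):
                child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(c_idx, t_idx, k))
                rng = np.random.default_rng(child)
                reps.append(max(0.0, signal[t_idx] + sd * rng.standard_normal()))
            reps = np.asarray(reps)
            rows.append(
                {
                    "group": design.group,
                    "analyte": "RBZ",
                    "compartment": comp,
                    "time_h": float(t),
                    "mean": float(reps.mean()),
                    "sd": float(reps.std(ddof=1)) if len(reps) > 1 else 0.0,
                    "n": design.n_replicates,
                }
            )
    return MeasurementSet(pd.DataFrame(rows))
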