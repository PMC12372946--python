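"""Least-squares fits and Metropolis-Hastings identifiability on the
ex vivo porcine measurements.

Two permeabilities are not available from the literature and are inferred
from the bench data: the corneal permeability to the drug in the presence
of cell-penetrating peptides (``beta_tear_aq_r``) and the
aqueous-vitreous interface permeability to the drug (``beta_aq_vit_r``).

*Topical fit* (two free permeabilities): single drop at t = 0 on an
ex vivo eye, constant tear volume equal to the drop volume, depleting
tear concentration, VEGF disabled; the objective is the mean squared
error against the aqueous drug means at the retained time points.

*Intravitreal fit* (one free permeability): injection submodel without a
tear compartment, initialised at t = 20 min from the measured aqueous and
vitreal means; MSE against the later aqueous means.

With VEGF disabled the drug-only submodel is *linear*, so predictions are
evaluated exactly via the matrix exponential of the small rate matrix;
the test suite cross-checks this against the general simulator.  The
optional ``include_vegf`` path runs the full nonlinear simulator instead.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .dosing import Regimen, TreatmentEvent
from .model import EyeState
from .params import ModelConfig, ParameterSet, porcine_parameters
from .simulate import simulate

__all__ = [
    "MeasurementSet",
    "FitResult",
    "McmcResult",
    "load_porcine_measurements",
    "fit_topical",
    "fit_intravitreal",
    "mcmc_identifiability",
]

FIT_TIMES_ALL = (1.0 / 3.0, 2.0 / 3.0, 1.0, 3.5)

#: log-uniform prior supports (cm h^-1)
PRIOR_BOUNDS = {"beta_tear_aq_r": (1e-9, 1e-4), "beta_aq_vit_r": (1e-2, 1e1)}


@dataclass(frozen=True)
class MeasurementSet:
    """Per-group, per-compartment concentration summaries.

    Thin wrapper over a tidy DataFrame with columns
    ``group, analyte, compartment, time_h, mean, sd, n``.
    """

    data: pd.DataFrame

    REQUIRED = ("group", "analyte", "compartment", "time_h", "mean", "sd", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["mean"] < 0).any() or (self.data["sd"] < 0).any():
            raise ValueError("means and sds must be non-negative")

    def subset(self, group: str, analyte: str, compartment: str) -> pd.DataFrame:
        d = self.data
        out = d[
            (d["group"] == group) & (d["analyte"] == analyte) & (d["compartment"] == compartment)
        ].sort_values("time_h")
        return out

    def values(self, group: str, analyte: str, compartment: str):
        sub = self.subset(group, analyte, compartment)
        return (
            sub["time_h"].to_numpy(float),
            sub["mean"].to_numpy(float),
            sub["sd"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        return cls(pd.read_csv(path))


def load_porcine_measurements() -> MeasurementSet:
    """The bundled ex vivo porcine ELISA summary data (means, sds, n = 3
    per treated point; the controls carry no time point)."""
    with importlib.resources.files("ocupk.data").joinpath("porcine_elisa.csv").open() as fh:
        return MeasurementSet(pd.read_csv(fh))


@dataclass
class FitResult:
    """Point estimates from a least-squares fit."""

    estimates: dict[str, float]
    objective: float  # mean squared error, pmol^2 mL^-2
    converged: bool
    degenerate: bool = False
    n_points: int = 0
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "objective_mse": self.objective,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_points": self.n_points,
        }


@dataclass
class McmcResult:
    """Posterior samples and summaries from a random-walk chain."""

    param_names: tuple[str, ...]
    samples: np.ndarray  # (n_kept, n_params), natural scale
    mean: dict[str, float]
    sd: dict[str, float]
    acceptance_rate: float
    n_steps: int
    burn_in: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "mean": self.mean,
            "sd": self.sd,
            "acceptance_rate": self.acceptance_rate,
            "n_steps": self.n_steps,
            "burn_in": self.burn_in,
            "seed": self.seed,
        }


# -- linear (drug-only) predictors ---------------------------------------


def topical_rate_matrix(beta_ta: float, beta_av: float, p: ParameterSet) -> np.ndarray:
    """Rate matrix of the linear drug-only topical submodel over
    ``(r_tear, r_aq, r_vit)`` with constant tear volume ``V_drop``."""
    a = beta_ta * p.A_tear_aq
    c = beta_av * p.A_aq_vit
    return np.array(
        [
            [-a / p.V_drop, 0.0, 0.0],
            [a / p.V_aq, -c / p.V_aq, c / p.V_aq],
            [0.0, c / p.V_vit, -c / p.V_vit],
        ]
    )


def intravit_rate_matrix(beta_av: float, p: ParameterSet) -> np.ndarray:
    """Rate matrix of the linear drug-only injection submodel over
    ``(r_aq, r_vit)``."""
    c = beta_av * p.A_aq_vit
    return np.array([[-c / p.V_aq, c / p.V_aq], [c / p.V_vit, -c / p.V_vit]])


def predict_topical_r_aq(beta_ta: float, beta_av: float, times, p: ParameterSet) -> np.ndarray:
    """Aqueous drug concentration at ``times`` (h from the drop)."""
    M = topical_rate_matrix(beta_ta, beta_av, p)
    r0 = np.array([p.r_dose, 0.0, 0.0])
    return np.array([(expm(M * t) @ r0)[1] for t in np.atleast_1d(times)])


def predict_intravit_r_aq(
    beta_av: float, times, p: ParameterSet, t0: float = 1.0 / 3.0,
    r_aq0: float = 4.73e-2, r_vit0: float = 4.29,
) -> np.ndarray:
    """Aqueous drug concentration at ``times`` given the state measured at
    ``t0`` (the injection-group means at 20 min)."""
    M = intravit_rate_matrix(beta_av, p)
    r0 = np.array([r_aq0, r_vit0])
    return np.array([(expm(M * (t - t0)) @ r0)[0] for t in np.atleast_1d(times)])


# -- nonlinear (simulator) predictors ------------------------------------


def _simulated_topical_r_aq(beta_ta, beta_av, times, p: ParameterSet, v_init=None) -> np.ndarray:
    pp = p.replace(beta_tear_aq_r=beta_ta, beta_aq_vit_r=beta_av)
    vegf = v_init is not None
    if vegf:
        pp = pp.replace(v_aq_init=v_init[0], v_vit_init=v_init[1])
    cfg = ModelConfig.ex_vivo_topical(constant_volume=True, vegf=vegf)
    reg = Regimen((TreatmentEvent(0.0, "drop"),), t_end=max(times) + 1e-6)
    ts = simulate(reg, pp, cfg, grid_dt=0.005)
    return np.interp(times, ts.times, ts.column("r_aq"))


def _simulated_intravit_r_aq(beta_av, times, p: ParameterSet, t0, r_aq0, r_vit0, v_init=None) -> np.ndarray:
    pp = p.replace(beta_aq_vit_r=beta_av)
    vegf = v_init is not None
    if vegf:
        pp = pp.replace(v_aq_init=v_init[0], v_vit_init=v_init[1])
    cfg = ModelConfig.ex_vivo_injection(vegf=vegf)
    y0 = EyeState(
        0.0, 0.0,
        v_init[0] if vegf else 0.0, r_aq0, 0.0, 0.0,
        v_init[1] if vegf else 0.0, r_vit0, 0.0, 0.0,
    )
    reg = Regimen((), t_end=max(times) + 1e-6)
    ts = simulate(reg, pp, cfg, grid_dt=0.005, y0=y0, t_start=t0)
    return np.interp(times, ts.times, ts.column("r_aq"))


# -- objectives and fits --------------------------------------------------


def _topical_fit_data(data: MeasurementSet, fit_times=None):
    t, m, _ = data.values("topical_cpp", "RBZ", "Aq")
    if fit_times is None:
        # data-driven exclusion: points entirely below the assay's
        # detection limit (mean and sd exactly 0) are anomalous
        _, _, sd = data.values("topical_cpp", "RBZ", "Aq")
        keep = ~((m == 0.0) & (sd == 0.0))
    else:
        keep = np.isin(np.round(t, 9), np.round(np.asarray(fit_times), 9))
    return t[keep], m[keep]


def fit_topical(
    data: MeasurementSet,
    params: ParameterSet | None = None,
    fit_times=None,
    include_vegf: bool = False,
    v_init=None,
    multistart: bool = True,
    x0=None,
) -> FitResult:
    """Fit ``(beta_tear_aq_r, beta_aq_vit_r)`` to the topical-group aqueous
    drug means by Nelder-Mead on the log-parameters.

    Points flagged as below detection (mean and sd both zero) are dropped
    unless ``fit_times`` selects times explicitly.  ``include_vegf`` runs
    the full nonlinear simulator with initial VEGF ``v_init = (v_aq, v_vit)``.
    """
    p = (params or porcine_parameters()).ex_vivo()
    times, target = _topical_fit_data(data, fit_times)
    if len(times) == 0:
        raise ValueError("no data points to fit")

    if include_vegf and v_init is None:
        v_init = (p.v_aq_init, p.v_vit_init)

    def predict(beta_ta, beta_av):
        if include_vegf:
            return _simulated_topical_r_aq(beta_ta, beta_av, times, p, v_init)
        return predict_topical_r_aq(beta_ta, beta_av, times, p)

    trace = []

    def objective(theta):
        # keep the simplex inside the numerically sane range
        if np.any(theta < -14.0) or np.any(theta > 4.0):
            return 1e300
        beta_ta, beta_av = 10.0 ** theta
        with np.errstate(over="ignore", invalid="ignore"):
            mse = float(np.mean((predict(beta_ta, beta_av) - target) ** 2))
        if not np.isfinite(mse):
            return 1e300
        trace.append((10.0 ** theta, mse))
        return mse

    if x0 is not None:
        starts = [np.log10(np.asarray(x0, float))]
    elif multistart:
        starts = [np.array([a, b]) for a in (-8.0, -6.0, -4.0) for b in (-2.0, 0.0, 2.0)]
    else:
        starts = [np.array([-6.0, 0.0])]

    best = None
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    est = 10.0 ** best.x
    degenerate = _is_degenerate(objective, best.x, best.fun)
    return FitResult(
        estimates={"beta_tear_aq_r": float(est[0]), "beta_aq_vit_r": float(est[1])},
        objective=float(best.fun),
        converged=bool(best.success),
        degenerate=degenerate,
        n_points=len(times),
        trace=trace,
    )


def fit_intravitreal(
    data: MeasurementSet,
    params: ParameterSet | None = None,
    include_vegf: bool = False,
    v_init=None,
    multistart: bool = True,
    x0=None,
) -> FitResult:
    """Fit ``beta_aq_vit_r`` to the plain-injection-group aqueous drug
    means at 40 min, 1 h and 3.5 h, initialising the state at 20 min from
    the measured means."""
    p = (params or porcine_parameters()).ex_vivo()
    t_all, m_all, _ = data.values("invit_plain", "RBZ", "Aq")
    _, m_vit, _ = data.values("invit_plain", "RBZ", "Vit")
    t0, r_aq0, r_vit0 = t_all[0], m_all[0], m_vit[0]
    times, target = t_all[1:], m_all[1:]

    if include_vegf and v_init is None:
        v_init = (p.v_aq_init, p.v_vit_init)

    def predict(beta_av):
        if include_vegf:
            return _simulated_intravit_r_aq(beta_av, times, p, t0, r_aq0, r_vit0, v_init)
        return predict_intravit_r_aq(beta_av, times, p, t0, r_aq0, r_vit0)

    trace = []

    def objective(theta):
        if np.any(theta < -14.0) or np.any(theta > 4.0):
            return 1e300
        beta_av = 10.0 ** theta[0]
        with np.errstate(over="ignore", invalid="ignore"):
            mse = float(np.mean((predict(beta_av) - target) ** 2))
        if not np.isfinite(mse):
            return 1e300
        trace.append((np.array([beta_av]), mse))
        return mse

    if x0 is not None:
        starts = [np.log10(np.atleast_1d(np.asarray(x0, float)))]
    elif multistart:
        starts = [np.array([b]) for b in (-2.0, -1.0, 0.0, 1.0)]
    else:
        starts = [np.array([0.0])]

    best = None
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    est = 10.0 ** best.x[0]
    degenerate = _is_degenerate(objective, best.x, best.fun)
    return FitResult(
        estimates={"beta_aq_vit_r": float(est)},
        objective=float(best.fun),
        converged=bool(best.success),
        degenerate=degenerate,
        n_points=len(times),
        trace=trace,
    )


def _is_degenerate(objective, x_opt, f_opt, rel=1e-12) -> bool:
    """Objective flat under two-fold parameter changes => unidentifiable."""
    probes = [x_opt + np.log10(2.0) * e for e in np.eye(len(x_opt))]
    probes += [x_opt - np.log10(2.0) * e for e in np.eye(len(x_opt))]
    scale = max(abs(f_opt), 1e-300)
    return all(abs(objective(xp) - f_opt) / scale < rel for xp in probes)


# -- Metropolis-Hastings identifiability ----------------------------------


def mcmc_identifiability(
    data: MeasurementSet,
    which: str,
    n_steps: int = 100_000,
    burn_frac: float = 0.2,
    proposal_sd: float = 0.025,
    seed: int = 0,
    params: ParameterSet | None = None,
    theta0=None,
    error_model: str = "fixed",
    sigma: float | None = None,
    noise_frac: float = 0.01,
) -> McmcResult:
    """Random-walk Metropolis-Hastings over the fitted permeabilities.

    The likelihood is an independent Gaussian on the fitted means.  With
    ``error_model="fixed"`` (default) the noise scale is fixed at
    ``sigma`` if given, else at ``noise_frac`` times the largest fitted
    mean -- an instrument-precision scale on the group means.  This sets
    only the posterior width; the location of the (single, sharp) peak is
    the least-squares optimum either way.  ``error_model="marginal"``
    instead treats the scale as unknown with a Jeffreys-style prior and
    marginalises it, giving the heavy-tailed marginal likelihood
    ``SSE(theta) ** (-n/2)``; with only three fitted means that posterior
    is Student-like with at most two degrees of freedom and spreads far
    beyond the least-squares uncertainty, so it is kept only as a
    conservative variant.

    Priors are log-uniform on the supports in ``PRIOR_BOUNDS``; the walk
    is Gaussian in log10-parameter space.
    """
    if which not in ("topical", "intravitreal"):
        raise ValueError("which must be 'topical' or 'intravitreal'")
    if error_model not in ("fixed", "marginal"):
        raise ValueError("error_model must be 'fixed' or 'marginal'")
    p = (params or porcine_parameters()).ex_vivo()

    if which == "topical":
        names = ("beta_tear_aq_r", "beta_aq_vit_r")
        times, target = _topical_fit_data(data, None)

        def sse(theta):
            pred = predict_topical_r_aq(10.0 ** theta[0], 10.0 ** theta[1], times, p)
            return float(np.sum((pred - target) ** 2))

    else:
        names = ("beta_aq_vit_r",)
        t_all, m_all, _ = data.values("invit_plain", "RBZ", "Aq")
        _, m_vit, _ = data.values("invit_plain", "RBZ", "Vit")
        t0, r_aq0, r_vit0 = t_all[0], m_all[0], m_vit[0]
        times, target = t_all[1:], m_all[1:]

        def sse(theta):
            pred = predict_intravit_r_aq(10.0 ** theta[0], times, p, t0, r_aq0, r_vit0)
            return float(np.sum((pred - target) ** 2))

    lo = np.log10([PRIOR_BOUNDS[n][0] for n in names])
    hi = np.log10([PRIOR_BOUNDS[n][1] for n in names])
    ndata = len(times)
    if sigma is None:
        sigma = noise_frac * float(np.max(target))

    def log_post(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        s = sse(theta)
        if error_model == "fixed":
            return -0.5 * s / (sigma * sigma)
        if s <= 0.0:
            return np.inf
        return -0.5 * ndata * np.log(s)

    rng = np.random.default_rng(seed)
    if theta0 is None:
        # start from the least-squares optimum of the same objective
        if which == "topical":
            fit = fit_topical(data, params=p)
            theta = np.log10([fit.estimates["beta_tear_aq_r"], fit.estimates["beta_aq_vit_r"]])
        else:
            fit = fit_intravitreal(data, params=p)
            theta = np.log10([fit.estimates["beta_aq_vit_r"]])
    else:
        theta = np.log10(np.asarray(theta0, float))
    lp = log_post(theta)
    k = len(names)
    chain = np.empty((n_steps, k))
    accepted = 0
    for i in range(n_steps):
        prop = theta + proposal_sd * rng.standard_normal(k)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        chain[i] = theta
    rate = accepted / n_steps
    if not 0.1 <= rate <= 0.6 and proposal_sd > 0:
        warnings.warn(
            f"MCMC acceptance rate {rate:.2f} outside [0.1, 0.6]; "
            "adjust proposal_sd (smaller to raise acceptance, larger to lower it)",
            stacklevel=2,
        )
    burn = int(burn_frac * n_steps)
    kept = 10.0 ** chain[burn:]
    return McmcResult(
        param_names=names,
        samples=kept,
        mean={n: float(kept[:, j].mean()) for j, n in enumerate(names)},
        sd={n: float(kept[:, j].std(ddof=1)) for j, n in enumerate(names)},
        acceptance_rate=rate,
        n_steps=n_steps,
        burn_in=burn,
        seed=seed,
    )
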