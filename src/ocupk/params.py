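"""Model parameters and configuration.

All quantities use a single unit system package-wide: hours (h), millilitres
(mL), centimetres (cm) and picomoles (pmol).  Because 1 cm^3 = 1 mL, a
permeability ``beta`` (cm h^-1) multiplied by an interface area (cm^2) and
divided by a compartment volume (mL) yields a first-order rate in h^-1 with
no conversion factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "ModelConfig",
    "SENSITIVITY_RANGES",
    "human_parameters",
    "porcine_parameters",
]


@dataclass(frozen=True)
class ParameterSet:
    """Physical and kinetic parameters of the three-compartment eye model.

    The drug (R, ranibizumab) enters through the tear film or directly into
    the vitreous; the ligand (V, VEGF) is supplied by the retina.  R binds
    V at two identical, independent sites, forming the single-bound complex
    VR (``u``) and the double-bound complex RVR (``w``).

    Attributes
    ----------
    tau_loss : float
        Time for the tear volume to return to baseline (human) or to drain
        completely (ex vivo porcine) after a drop, h.
    V_drop : float
        Volume of an eye drop / intravitreal injection, mL.
    V_tear_norm, V_tear_res : float
        Normal tear-film volume and maximal (reservoir) tear volume, mL.
        Not applicable to the ex vivo porcine eye (stored as 0).
    V_aq, V_vit : float
        Aqueous and vitreal compartment volumes, mL.
    A_tear_aq, A_aq_vit, A_vit_ret : float
        Interface areas (cornea, zonule, inner limiting membrane), cm^2.
    k_on : float
        Binding rate of R to a single free site on V, pmol^-1 mL h^-1.
    k_off : float
        Unbinding rate of R from a filled site, h^-1.
    delta_* : float
        First-order degradation rates per compartment and species, h^-1.
    beta_tear_aq_r : float
        Corneal permeability to R in the presence of cell-penetrating
        peptides, cm h^-1.
    beta_aq_vit_* : float
        Aqueous-vitreous interface permeabilities per species, cm h^-1.
    beta_vit_ret_* : float
        Vitreo-retinal loss permeabilities (R and complexes only), cm h^-1.
    phi_vit_v : float
        Rate at which the retina supplies VEGF to the vitreous, pmol h^-1.
    psi_tear, psi_aq : float
        Tear and aqueous fluid turnover rates, mL h^-1.
    r_dose : float
        R concentration of the administered dose, pmol mL^-1.
    v_aq_init, v_vit_init : float
        Untreated steady-state VEGF concentrations, pmol mL^-1.
    r_tear_init, r_vit_init : float
        Post-dose drug concentrations used as initial conditions,
        pmol mL^-1.
    species : str
        ``"human"`` or ``"porcine"``.
    """

    tau_loss: float
    V_drop: float
    V_tear_norm: float
    V_tear_res: float
    V_aq: float
    V_vit: float
    A_tear_aq: float
    A_aq_vit: float
    A_vit_ret: float
    k_on: float
    k_off: float
    delta_aq_v: float
    delta_aq_r: float
    delta_aq_u: float
    delta_aq_w: float
    delta_vit_v: float
    delta_vit_r: float
    delta_vit_u: float
    delta_vit_w: float
    beta_tear_aq_r: float
    beta_aq_vit_v: float
    beta_aq_vit_r: float
    beta_aq_vit_u: float
    beta_aq_vit_w: float
    beta_vit_ret_r: float
    beta_vit_ret_u: float
    beta_vit_ret_w: float
    phi_vit_v: float
    psi_tear: float
    psi_aq: float
    r_dose: float
    v_aq_init: float
    v_vit_init: float
    r_tear_init: float
    r_vit_init: float
    species: str = "human"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "species":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {value}")
        if self.species not in ("human", "porcine"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.species == "human":
            if not (self.V_tear_norm <= self.V_tear_res <= self.V_tear_norm + self.V_drop):
                raise ValueError(
                    "tear volumes must satisfy "
                    "V_tear_norm <= V_tear_res <= V_tear_norm + V_drop"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        return cls.from_dict(json.loads(s))

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    # -- derived quantities ------------------------------------------------

    def delta(self, compartment: str, species: str) -> float:
        """Degradation rate for ``compartment`` in {'aq','vit'}, ``species``
        in {'v','r','u','w'}."""
        return getattr(self, f"delta_{compartment.lower()}_{species}")

    def ex_vivo(self) -> "ParameterSet":
        """Parameters with the processes absent from an ex vivo eye zeroed:
        no fluid turnover, no VEGF supply, no retino-choroidal clearance."""
        return self.replace(
            psi_tear=0.0,
            psi_aq=0.0,
            phi_vit_v=0.0,
            beta_vit_ret_r=0.0,
            beta_vit_ret_u=0.0,
            beta_vit_ret_w=0.0,
        )


def human_parameters() -> ParameterSet:
    """Default in vivo human parameter values."""
    return ParameterSet(
        tau_loss=5.00e-2,
        V_drop=4.50e-2,
        V_tear_norm=6.35e-3,
        V_tear_res=3.00e-2,
        V_aq=0.160,
        V_vit=4.50,
        A_tear_aq=1.30,
        A_aq_vit=0.349,
        A_vit_ret=10.9,
        k_on=0.576,
        k_off=2.63e-2,
        delta_aq_v=0.0,
        delta_aq_r=0.0,
        delta_aq_u=0.0,
        delta_aq_w=0.0,
        delta_vit_v=0.0,
        delta_vit_r=0.0,
        delta_vit_u=0.0,
        delta_vit_w=0.0,
        beta_tear_aq_r=1.10e-6,
        beta_aq_vit_v=0.985,
        beta_aq_vit_r=0.929,
        beta_aq_vit_u=0.755,
        beta_aq_vit_w=0.653,
        beta_vit_ret_r=6.80e-4,
        beta_vit_ret_u=6.44e-4,
        beta_vit_ret_w=6.23e-4,
        phi_vit_v=2.34e-4,
        psi_tear=7.20e-2,
        psi_aq=0.150,
        r_dose=2.07e4,
        v_aq_init=1.56e-3,
        v_vit_init=2.24e-3,
        r_tear_init=1.81e4,
        r_vit_init=2.07e2,
        species="human",
    )


def porcine_parameters() -> ParameterSet:
    """Default ex vivo porcine parameter values.

    The normal/reservoir tear volumes have no meaning for an enucleated eye
    (a tear film cannot be maintained) and are stored as 0; topical porcine
    submodels use the drop volume as the tear volume.  Turnover, VEGF
    supply and retino-choroidal clearance are absent ex vivo and default
    to 0.
    """
    return ParameterSet(
        tau_loss=5.00e-2,
        V_drop=4.50e-2,
        V_tear_norm=0.0,
        V_tear_res=0.0,
        V_aq=0.310,
        V_vit=3.10,
        A_tear_aq=1.51,
        A_aq_vit=0.301,
        A_vit_ret=0.0,
        k_on=0.576,
        k_off=2.63e-2,
        delta_aq_v=0.0,
        delta_aq_r=0.0,
        delta_aq_u=0.0,
        delta_aq_w=0.0,
        delta_vit_v=0.0,
        delta_vit_r=0.0,
        delta_vit_u=0.0,
        delta_vit_w=0.0,
        beta_tear_aq_r=5.93e-7,
        beta_aq_vit_v=0.985,
        beta_aq_vit_r=0.929,
        beta_aq_vit_u=0.755,
        beta_aq_vit_w=0.653,
        beta_vit_ret_r=0.0,
        beta_vit_ret_u=0.0,
        beta_vit_ret_w=0.0,
        phi_vit_v=0.0,
        psi_tear=0.0,
        psi_aq=0.0,
        r_dose=2.07e4,
        v_aq_init=0.0,
        v_vit_init=0.0,
        r_tear_init=2.07e4,
        r_vit_init=4.29,
        species="porcine",
    )


#: Biologically realistic ranges for the local sensitivity analysis of the
#: in vivo human model (inclusive endpoints; same units as ParameterSet).
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "tau_loss": (1.67e-2, 8.33e-2),
    "V_drop": (4.05e-2, 4.95e-2),
    "V_tear_norm": (0.340e-2, 1.07e-2),
    "V_tear_res": (2.70e-2, 3.30e-2),
    "V_aq": (0.121, 0.286),
    "V_vit": (3.50, 5.40),
    "A_tear_aq": (1.04, 1.56),
    "A_aq_vit": (0.111, 0.521),
    "A_vit_ret": (9.81, 12.0),
    "k_on": (0.205, 4.21),
    "k_off": (1.40e-2, 3.60e-2),
    "delta_aq_v": (0.0, 0.770),
    "delta_aq_r": (0.0, 0.770),
    "delta_aq_u": (0.0, 0.770),
    "delta_aq_w": (0.0, 0.770),
    "delta_vit_v": (0.0, 0.770),
    "delta_vit_r": (0.0, 0.770),
    "delta_vit_u": (0.0, 0.770),
    "delta_vit_w": (0.0, 0.770),
    "beta_tear_aq_r": (0.990e-6, 1.21e-6),
    "beta_aq_vit_v": (0.887, 1.08),
    "beta_aq_vit_r": (0.836, 1.02),
    "beta_aq_vit_u": (0.680, 0.831),
    "beta_aq_vit_w": (0.588, 0.718),
    "beta_vit_ret_r": (6.12e-4, 7.48e-4),
    "beta_vit_ret_u": (5.80e-4, 7.08e-4),
    "beta_vit_ret_w": (5.61e-4, 6.85e-4),
    "phi_vit_v": (1.02e-4, 4.46e-4),
    "psi_tear": (0.300e-1, 1.32e-1),
    "psi_aq": (0.660e-1, 2.52e-1),
    "r_dose": (1.86e4, 2.28e4),
}


TEAR_VOLUME_MODES = (
    "constant_norm",
    "depleting_human",
    "constant_drop_porcine",
    "depleting_porcine",
)
TEAR_CONC_MODES = ("held_constant", "depleting")


@dataclass(frozen=True)
class ModelConfig:
    """Structural configuration of a submodel.

    Parameters
    ----------
    tear_active : bool
        Whether the tear compartment exists (False for injection-only
        submodels).
    tear_volume_mode : str
        One of ``constant_norm`` (lens / baseline), ``depleting_human``
        (drop drains back to the normal film volume), ``constant_drop_porcine``
        (the whole drop stays on the ex vivo cornea), ``depleting_porcine``
        (the whole drop runs off in ``tau_loss``).
    tear_conc_mode : str
        ``held_constant`` while a drug-eluting lens is worn, else
        ``depleting``.
    vegf_active : bool
        Whether VEGF and the bound complexes are modelled (fitting runs on
        drug-only data disable them).
    ex_vivo : bool
        Forces the turnover/supply/retinal-loss processes off (porcine
        bench experiment).
    """

    tear_active: bool = True
    tear_volume_mode: str = "depleting_human"
    tear_conc_mode: str = "depleting"
    vegf_active: bool = True
    ex_vivo: bool = False

    def __post_init__(self) -> None:
        if self.tear_volume_mode not in TEAR_VOLUME_MODES:
            raise ValueError(f"unknown tear_volume_mode {self.tear_volume_mode!r}")
        if self.tear_conc_mode not in TEAR_CONC_MODES:
            raise ValueError(f"unknown tear_conc_mode {self.tear_conc_mode!r}")
        if self.tear_conc_mode == "held_constant" and self.tear_volume_mode != "constant_norm":
            raise ValueError("a held-constant tear concentration (lens) implies a constant tear volume")

    def validate_against(self, params: ParameterSet) -> None:
        if self.ex_vivo and params.species != "porcine":
            raise ValueError("ex vivo configuration requires porcine parameters")
        if self.tear_volume_mode in ("constant_drop_porcine", "depleting_porcine") and params.species != "porcine":
            raise ValueError("porcine tear-volume modes require porcine parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def replace(self, **changes) -> "ModelConfig":
        return replace(self, **changes)

    # convenience constructors for the standard submodels -----------------

    @classmethod
    def human_drops(cls, vegf: bool = True) -> "ModelConfig":
        return cls(True, "depleting_human", "depleting", vegf, False)

    @classmethod
    def human_lens(cls, vegf: bool = True) -> "ModelConfig":
        return cls(True, "constant_norm", "held_constant", vegf, False)

    @classmethod
    def human_injection(cls, vegf: bool = True) -> "ModelConfig":
        return cls(False, "constant_norm", "depleting", vegf, False)

    @classmethod
    def ex_vivo_topical(cls, constant_volume: bool = True, vegf: bool = False) -> "ModelConfig":
        mode = "constant_drop_porcine" if constant_volume else "depleting_porcine"
        return cls(True, mode, "depleting", vegf, True)

    @classmethod
    def ex_vivo_injection(cls, vegf: bool = False) -> "ModelConfig":
        return cls(False, "constant_norm", "depleting", vegf, True)
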