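"""Unit system, physical constants and parameter containers.

The model is run in a single consistent unit system:

====================  =================
quantity              internal unit
====================  =================
length                micrometre (μm)
time                  second (s)
pressure              pascal (Pa)
amount of substance   millimole (mmol)
concentration         mmol μm⁻³
====================  =================

Concentrations cross the API boundary in millimolar (mM); 1 mM equals
1 mol m⁻³ equals 1e-15 mmol μm⁻³.  In this system the osmolyte uptake rate
constant (mmol μm⁻² s⁻¹), the consumption rate constant (mmol μm⁻³ s⁻¹) and
the hydraulic conductivity (μm s⁻¹ Pa⁻¹) compose without conversion
factors, and the ratio k_uptake/k_consumption carries units of length (μm),
which is what ties the final cell radius to osmolyte homeostasis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GAS_CONSTANT",
    "MM_TO_INTERNAL",
    "INTERNAL_TO_MM",
    "MIN_TO_S",
    "S_TO_MIN",
    "MPA_TO_PA",
    "PA_TO_MPA",
    "PhysicalConstants",
    "CellParams",
    "default_params",
    "osmolarity_to_pressure",
    "pressure_to_osmolarity",
    "load_params",
    "save_params",
]

#: Ideal gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT = 8.314

# Conversion factors between reporting units and the internal system.
MM_TO_INTERNAL = 1e-15  # mM -> mmol μm⁻³
INTERNAL_TO_MM = 1e15   # mmol μm⁻³ -> mM
MIN_TO_S = 60.0
S_TO_MIN = 1.0 / 60.0
MPA_TO_PA = 1e6
PA_TO_MPA = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant and absolute temperature.

    303 K is the optimal growth temperature of *S. cerevisiae* and the
    standard condition the default parameter set refers to.
    """

    R: float = GAS_CONSTANT  # J mol⁻¹ K⁻¹
    T: float = 303.0         # K

    def __post_init__(self) -> None:
        if self.R != GAS_CONSTANT:
            raise ValueError(f"gas constant must be {GAS_CONSTANT} J/(mol K)")
        if self.T <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def RT(self) -> float:
        """R·T in Pa per mol m⁻³, i.e. Pa per mM."""
        return self.R * self.T

    @property
    def RT_internal(self) -> float:
        """R·T in Pa per (mmol μm⁻³)."""
        return self.R * self.T * INTERNAL_TO_MM


@dataclass(frozen=True)
class CellParams:
    """Physical and kinetic parameters of one cell compartment.

    Defaults are the reference parameter set for a haploid yeast cell at
    303 K.  All fields are in the internal unit system except ``c_e``
    (mM), which is converted where it enters the dynamics.

    Attributes
    ----------
    L_p : hydraulic conductivity of the membrane per unit area, μm s⁻¹ Pa⁻¹.
    E : Young's modulus of the cell wall (3D), Pa.
    nu : Poisson's ratio of the wall, dimensionless, in (0, 0.5].
    d : cell wall thickness, μm (assumed constant).
    phi : wall extensibility — rate coefficient of irreversible (plastic)
        expansion above the yield threshold, Pa⁻¹ s⁻¹.
    Pi_ct : critical turgor pressure (plastic yield threshold), Pa.
    k_uptake : osmolyte uptake rate constant per membrane area,
        mmol μm⁻² s⁻¹.
    k_consumption : osmolyte consumption rate constant per osmotic volume,
        mmol μm⁻³ s⁻¹.
    c_e : external osmolarity, mM.
    r_b0 : radius of the solid (osmotically inactive) volume, μm.
    r_os0 : initial radius of the osmotic volume, μm.
    Pi_t0 : initial turgor pressure, Pa.
    """

    L_p: float = 1.19e-6
    E: float = 2.58e6
    nu: float = 0.5
    d: float = 0.115
    phi: float = 1.0e-3
    Pi_ct: float = 2.0e5
    k_uptake: float = 2.0e-16
    k_consumption: float = 2.0e-16
    c_e: float = 240.0
    r_b0: float = 0.3
    r_os0: float = 0.1
    Pi_t0: float = 2.0e5
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        positive = (
            "L_p", "E", "d", "phi", "Pi_ct", "k_uptake", "k_consumption",
            "r_b0", "r_os0",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.nu <= 0.5:
            raise ValueError("Poisson's ratio nu must lie in (0, 0.5]")
        if self.c_e < 0:
            raise ValueError("external osmolarity c_e must be >= 0")
        if self.Pi_t0 < 0:
            raise ValueError("initial turgor Pi_t0 must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def k_ratio(self) -> float:
        """k_uptake / k_consumption, in μm."""
        return self.k_uptake / self.k_consumption

    @property
    def V_b(self) -> float:
        """Solid (osmotically inactive) volume, μm³."""
        return 4.0 / 3.0 * math.pi * self.r_b0**3

    @property
    def V_os0(self) -> float:
        """Initial osmotic volume, μm³."""
        return 4.0 / 3.0 * math.pi * self.r_os0**3

    def replace(self, **changes) -> "CellParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def default_params() -> CellParams:
    """Reference parameter set (haploid yeast, 303 K, 240 mM medium)."""
    return CellParams()


def osmolarity_to_pressure(c: float, constants: PhysicalConstants | None = None) -> float:
    """Osmotic pressure Π = c·R·T (Boyle–van 't Hoff) in Pa for ``c`` in mM.

    A concentration in mM is numerically a concentration in mol m⁻³, so the
    product with R (J mol⁻¹ K⁻¹) and T (K) is directly in Pa.
    """
    if c < 0:
        raise ValueError("osmolarity must be non-negative")
    constants = constants or PhysicalConstants()
    return c * constants.RT


def pressure_to_osmolarity(Pi: float, constants: PhysicalConstants | None = None) -> float:
    """Inverse of :func:`osmolarity_to_pressure`: mM for ``Pi`` in Pa."""
    constants = constants or PhysicalConstants()
    return Pi / constants.RT


# -- parameter file I/O -----------------------------------------------------

_PARAM_KEYS = {
    "L_p", "E", "nu", "d", "phi", "Pi_ct", "k_uptake", "k_consumption",
    "c_e", "r_b0", "r_os0", "Pi_t0", "T",
}


def load_params(path: str | Path) -> CellParams:
    """Load a parameter set from a YAML/JSON file keyed by symbol names.

    Values are expected in the reporting units documented on
    :class:`CellParams` (these coincide with the internal units except that
    concentrations are in mM).  Unknown keys and non-positive values raise
    ``ValueError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {k: float(v) for k, v in raw.items() if k != "T"}
    if "T" in raw:
        kwargs["constants"] = PhysicalConstants(T=float(raw["T"]))
    return CellParams(**kwargs)


def save_params(params: CellParams, path: str | Path) -> None:
    """Write a parameter set as YAML (inverse of :func:`load_params`)."""
    data = {
        k: getattr(params, k)
        for k in sorted(_PARAM_KEYS - {"T"})
    }
    data["T"] = params.constants.T
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
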