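"""Closed-form results for unperturbed growth.

During steady growth the turgor pressure locks onto the critical turgor
Π_ct (the Bingham element relaxes any excess on a millisecond timescale)
and the internal osmolarity approaches the flux balance
``c_i = c_e + Π_ct/RT``.  Under this quasi-steady state the radius obeys an
exponential-approach law towards a final radius set purely by osmolyte
homeostasis:

    r_final = 3 · k_uptake / k_consumption
    r̃(t) = r_final − (r_final − r_0) · exp(−λ (t − t_0)),
    λ = k_uptake · RT / (r_final · (Π_ct + Π_e))

Wall mechanics (E, ν, d, ϕ) and water permeability (L_p) set transients but
drop out of the final size — the central prediction of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import CellParams, osmolarity_to_pressure

__all__ = [
    "GrowthLaw",
    "r_final",
    "growth_law",
    "steady_osmolarity",
    "initial_osmolarity_from_turgor",
    "elastic_strain",
]


def r_final(params: CellParams) -> float:
    """Long-time radius limit ``3·k_uptake/k_consumption``, μm."""
    if params.k_consumption <= 0:
        raise ZeroDivisionError("k_consumption must be positive for a finite final radius")
    return 3.0 * params.k_uptake / params.k_consumption


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential-approach growth law for the cell radius.

    ``r̃(t) = r_final − (r_final − r_0)·exp(−λ(t−t_0))`` — monotone and
    bounded between ``r_0`` and ``r_final`` for all ``t ≥ t_0``.
    """

    r_final: float
    r_0: float
    t_0: float
    lam: float  # rate constant λ, s⁻¹

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.r_final - (self.r_final - self.r_0) * np.exp(-self.lam * (t - self.t_0))

    @property
    def time_constant(self) -> float:
        """1/λ in seconds."""
        return 1.0 / self.lam

    def to_dict(self) -> dict:
        return {"r_final": self.r_final, "r_0": self.r_0, "t_0": self.t_0, "lam": self.lam}


def growth_law(params: CellParams, r_0: float, t_0: float = 0.0) -> GrowthLaw:
    """Analytic approximation of the radius trajectory during growth."""
    if r_0 <= 0:
        raise ValueError("r_0 must be positive")
    rf = r_final(params)
    Pi_e = osmolarity_to_pressure(params.c_e, params.constants)
    lam = (
        params.k_uptake * params.constants.RT_internal
        / (rf * (params.Pi_ct + Pi_e))
    )
    return GrowthLaw(r_final=rf, r_0=r_0, t_0=t_0, lam=lam)


def steady_osmolarity(params: CellParams) -> float:
    """Internal osmolarity (mM) at the growth steady state.

    Zero water flux at Π_t = Π_ct requires ``c_i = c_e + Π_ct/RT``.
    """
    return params.c_e + params.Pi_ct / params.constants.RT


def initial_osmolarity_from_turgor(Pi_t0: float, params: CellParams) -> float:
    """Internal osmolarity (mM) that zeroes water flux at turgor ``Pi_t0``."""
    if Pi_t0 < 0:
        raise ValueError("turgor must be non-negative")
    return params.c_e + Pi_t0 / params.constants.RT


def elastic_strain(Pi_t: float, r: float, params: CellParams) -> float:
    """Hookean strain of a thin spherical shell, ``(1−ν)/E · Π_t·r/(2d)``."""
    if r <= 0 or params.d <= 0:
        raise ValueError("radius and wall thickness must be positive")
    return (1.0 - params.nu) / params.E * Pi_t * r / (2.0 * params.d)
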