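"""Single-compartment growth model: state, dynamics and simulation driver.

The model tracks three coupled quantities for a spherical walled cell:

* the osmotic volume ``V_os`` (water-accessible volume), which changes by
  transmembrane water flux ``V̇_os = −J_w``;
* the internal osmolarity ``c_i``, fed by surface-proportional osmolyte
  uptake, depleted by volume-proportional consumption, and diluted by
  volume expansion;
* the turgor pressure ``Π_t``, the hydrostatic pressure borne by the
  elasto-viscoplastic cell wall, modelled as a Hookean spring (reversible
  strain ∝ Π_t) in series with a Bingham element (irreversible strain rate
  ∝ max(Π_t − Π_ct, 0)) on a thin spherical shell.

Water flux follows Kedem–Katchalsky, ``J_w = L_p G (Π_t + Π_e − Π_i)``
(positive outward), with osmotic pressures given by Boyle–van 't Hoff
``Π = c R T``.  Alongside the physical radius the simulation co-integrates
a *reference radius* — the unstressed wall size accumulating only plastic
deformation — whose stagnation identifies purely elastic episodes such as
the response to hyperosmotic shock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _integrate
from ._integrate import Compartment, IntegrationError, System
from .units import (
    INTERNAL_TO_MM,
    MIN_TO_S,
    MM_TO_INTERNAL,
    CellParams,
    osmolarity_to_pressure,
)

__all__ = [
    "CellState",
    "ShockProtocol",
    "Trajectory",
    "IntegrationError",
    "initial_state",
    "water_flux",
    "osmolyte_rate",
    "turgor_rate",
    "rhs",
    "simulate",
    "classify_regime",
]

FOUR_PI = 4.0 * math.pi


def _radius_of_volume(V: float) -> float:
    return (3.0 * V / FOUR_PI) ** (1.0 / 3.0)


@dataclass
class CellState:
    """Instantaneous state of one compartment.

    Attributes
    ----------
    V_os : osmotic volume, μm³ (strictly positive).
    V_b : solid (osmotically inactive) volume, μm³, constant in time.
    Pi_t : turgor pressure, Pa.
    c_i : internal osmolarity, mM.
    """

    V_os: float
    V_b: float
    Pi_t: float
    c_i: float

    def __post_init__(self) -> None:
        if self.V_os <= 0:
            raise ValueError("osmotic volume must be positive")
        if self.V_b < 0:
            raise ValueError("solid volume must be non-negative")
        if self.c_i < 0:
            raise ValueError("internal osmolarity must be non-negative")

    @property
    def V_t(self) -> float:
        """Total cell volume V_os + V_b, μm³."""
        return self.V_os + self.V_b

    @property
    def r(self) -> float:
        """Radius of the sphere with the total volume, μm."""
        return _radius_of_volume(self.V_t)

    @property
    def G(self) -> float:
        """Surface area 4πr², μm²."""
        return FOUR_PI * self.r**2


def initial_state(params: CellParams) -> CellState:
    """Initial state implied by a parameter set.

    The initial osmolarity is chosen so that water flux vanishes at the
    initial turgor (``c_i = c_e + Π_t0/RT``), i.e. the cell starts in
    osmotic equilibrium.
    """
    return CellState(
        V_os=params.V_os0,
        V_b=params.V_b,
        Pi_t=params.Pi_t0,
        c_i=params.c_e + params.Pi_t0 / params.constants.RT,
    )


@dataclass(frozen=True)
class ShockProtocol:
    """Right-continuous piecewise-constant external osmolarity c_e(t).

    ``steps`` is an ordered list of ``(time_s, c_e_mM)``; before the first
    step time the baseline ``c0`` applies.
    """

    c0: float
    steps: tuple = ()

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError("baseline osmolarity must be non-negative")
        times = [t for t, _ in self.steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("step times must be strictly increasing")
        if any(c < 0 for _, c in self.steps):
            raise ValueError("osmolarities must be non-negative")
        object.__setattr__(self, "steps", tuple((float(t), float(c)) for t, c in self.steps))

    @classmethod
    def constant(cls, c_e_mM: float) -> "ShockProtocol":
        return cls(c0=c_e_mM)

    @classmethod
    def from_yaml(cls, path: str | Path, c0: float = 240.0) -> "ShockProtocol":
        """Read a protocol from a YAML list of ``{t_min, c_e_mM}`` entries.

        The first entry may carry ``t_min: 0`` to override the baseline.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError("protocol file must contain a list of steps")
        steps = []
        for entry in raw:
            t = float(entry["t_min"]) * MIN_TO_S
            c = float(entry["c_e_mM"])
            if t == 0.0:
                c0 = c
            else:
                steps.append((t, c))
        return cls(c0=c0, steps=tuple(sorted(steps)))

    def c_e(self, t: float) -> float:
        c = self.c0
        for t_step, c_step in self.steps:
            if t >= t_step:
                c = c_step
            else:
                break
        return c

    def change_times(self) -> list:
        return [t for t, _ in self.steps]


def classify_regime(Pi_t: float, Pi_ct: float) -> str:
    """Wall-mechanics regime: ``"EP"`` (elasto-plastic) iff Π_t ≥ Π_ct, else ``"E"``.

    The boundary belongs to the plastic branch, matching the Bingham
    activation ``f_m = Π_t − Π_ct if Π_t ≥ Π_ct else 0`` (both conventions
    agree numerically at the boundary, where f_m = 0).
    """
    return "EP" if Pi_t >= Pi_ct else "E"


# -- right-hand-side pieces (exposed for direct evaluation and testing) -----

def water_flux(state: CellState, params: CellParams, c_e_now: float) -> float:
    """Kedem–Katchalsky volumetric water flux, μm³ s⁻¹, positive outward.

    ``J_w = L_p · G · (Π_t + Π_e − Π_i)`` with ``Π = cRT``; the osmotic
    volume obeys ``V̇_os = −J_w``.
    """
    Pi_e = osmolarity_to_pressure(c_e_now, params.constants)
    Pi_i = osmolarity_to_pressure(state.c_i, params.constants)
    return params.L_p * state.G * (state.Pi_t + Pi_e - Pi_i)


def osmolyte_rate(state: CellState, params: CellParams, Vdot: float) -> float:
    """Rate of change of the internal osmolarity, mM s⁻¹.

    ``ċ_i = (k_uptake·G − k_consumption·V_os − c_i·V̇_os) / V_os``: uptake
    scales with the membrane surface, consumption and dilution with the
    osmotic volume (osmolytes reside in, and are diluted by, the
    osmotically active water).
    """
    c_int = state.c_i * MM_TO_INTERNAL
    dc_int = (
        params.k_uptake * state.G
        - params.k_consumption * state.V_os
        - c_int * Vdot
    ) / state.V_os
    return dc_int * INTERNAL_TO_MM


def turgor_rate(state: CellState, params: CellParams, rdot: float) -> float:
    """Rate of change of turgor pressure, Pa s⁻¹.

    Thin-shell elasto-viscoplastic wall:
    ``Π̇_t = 2Ed/(1−ν)·ṙ/r² − Π_t·ṙ/r − Eϕ/(1−ν)·f_m(Π_t, Π_ct)`` with the
    Bingham activation ``f_m = max(Π_t − Π_ct, 0)``.
    """
    r = state.r
    fm = max(state.Pi_t - params.Pi_ct, 0.0)
    return (
        2.0 * params.E * params.d / (1.0 - params.nu) * rdot / r**2
        - state.Pi_t * rdot / r
        - params.E * params.phi / (1.0 - params.nu) * fm
    )


def rhs(t: float, state: CellState, params: CellParams, protocol: ShockProtocol) -> dict:
    """Consistent derivative of the full single-cell state at time ``t``.

    Returns a dict with keys ``V_os, V_b, Pi_t, c_i`` (V_b is constant, so
    its derivative is always 0).  The radius rate used in the turgor
    equation follows from the geometric chain rule ``ṙ = V̇_t/(4πr²)``.
    """
    if not all(np.isfinite([state.V_os, state.Pi_t, state.c_i])):
        raise IntegrationError("non-finite state", t, np.array([state.V_os, state.Pi_t, state.c_i]))
    J_w = water_flux(state, params, protocol.c_e(t))
    Vdot = -J_w
    rdot = Vdot / state.G
    return {
        "V_os": Vdot,
        "V_b": 0.0,
        "Pi_t": turgor_rate(state, params, rdot),
        "c_i": osmolyte_rate(state, params, Vdot),
    }


# -- trajectory container ---------------------------------------------------

@dataclass
class Trajectory:
    """Time-sampled solution of one compartment with derived series.

    All arrays share the time grid ``t`` (seconds).  ``V_b`` is the
    (constant) solid volume; concentrations are in mM.
    """

    t: np.ndarray
    V_os: np.ndarray
    Pi_t: np.ndarray
    c_i: np.ndarray
    r_ref: np.ndarray
    c_e: np.ndarray
    V_b: float
    params: CellParams

    @property
    def V_t(self) -> np.ndarray:
        return self.V_os + self.V_b

    @property
    def r(self) -> np.ndarray:
        return (3.0 * self.V_t / FOUR_PI) ** (1.0 / 3.0)

    @property
    def G(self) -> np.ndarray:
        return FOUR_PI * self.r**2

    @property
    def Pi_i(self) -> np.ndarray:
        return self.c_i * self.params.constants.RT

    @property
    def Pi_e(self) -> np.ndarray:
        return self.c_e * self.params.constants.RT

    @property
    def J_w(self) -> np.ndarray:
        return self.params.L_p * self.G * (self.Pi_t + self.Pi_e - self.Pi_i)

    @property
    def regime(self) -> np.ndarray:
        """Per-sample wall regime flag: ``"EP"`` iff Π_t ≥ Π_ct else ``"E"``."""
        return np.where(self.Pi_t >= self.params.Pi_ct, "EP", "E")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export with one row per output time."""
        return pd.DataFrame(
            {
                "time_s": self.t,
                "V_os_um3": self.V_os,
                "V_t_um3": self.V_t,
                "r_um": self.r,
                "Pi_t_Pa": self.Pi_t,
                "c_i_mM": self.c_i,
                "c_e_mM": self.c_e,
                "J_w_um3_s": self.J_w,
                "r_ref_um": self.r_ref,
                "regime": self.regime,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Quick-look volume/turgor plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t / MIN_TO_S, self.V_t, label="V_t (μm³)")
        ax2 = ax.twinx()
        ax2.plot(self.t / MIN_TO_S, self.Pi_t / 1e5, "C1", label="Π_t (bar)")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("total volume (μm³)")
        ax2.set_ylabel("turgor (10⁵ Pa)")
        return ax


def _pack_state(state: CellState, r_ref0: float | None = None) -> np.ndarray:
    r_ref0 = state.r if r_ref0 is None else r_ref0
    return np.array([state.V_os, state.Pi_t, state.c_i, r_ref0])


def simulate(
    params: CellParams,
    initial: CellState | None = None,
    protocol: ShockProtocol | None = None,
    t_end: float = 3.6e4,
    dt_out: float = 60.0,
    t_eval: np.ndarray | None = None,
    rtol: float = _integrate.RTOL,
) -> Trajectory:
    """Integrate the single-cell model and sample it on a regular grid.

    Parameters
    ----------
    params : parameter set.
    initial : starting state; defaults to :func:`initial_state`.
    protocol : external-osmolarity protocol; defaults to constant
        ``params.c_e``.
    t_end, dt_out : horizon and output spacing in seconds (ignored if
        ``t_eval`` is given).
    t_eval : explicit output time grid in seconds.

    The integration is stiff-capable (LSODA) with event handling at
    protocol steps, at Π_t = Π_ct crossings (the Bingham kink) and at the
    turgor floor Π_t = 0; see :mod:`scgm._integrate`.
    """
    if initial is None:
        initial = initial_state(params)
    if protocol is None:
        protocol = ShockProtocol.constant(params.c_e)
    if t_eval is None:
        if t_end <= 0 or dt_out <= 0:
            raise ValueError("t_end and dt_out must be positive")
        t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
        t_eval[-1] = min(t_eval[-1], t_end)
    t_eval = np.asarray(t_eval, dtype=float)

    system = System(comps=[Compartment(params=params, V_b=initial.V_b)])
    y0 = _pack_state(initial)
    out = _integrate.integrate(
        system, y0, 0.0, float(t_eval[-1]), protocol, t_eval, rtol=rtol,
    )
    return Trajectory(
        t=t_eval,
        V_os=out[0],
        Pi_t=out[1],
        c_i=out[2],
        r_ref=out[3],
        c_e=np.array([protocol.c_e(t) for t in t_eval]),
        V_b=initial.V_b,
        params=params,
    )
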