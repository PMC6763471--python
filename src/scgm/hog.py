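"""Active osmotic-stress response (HOG-type) coupled to the growth model.

Hyperosmotic stress in *S. cerevisiae* activates the Hog1 MAP-kinase
cascade, which drives production and retention of glycerol to restore
osmotic balance.  This module couples the growth model to a minimal
phenomenological description of that loop: a turgor deficit below a
set-point activates a signalling species ``H`` (the active/nuclear Hog1
fraction), and ``H`` drives production of an internal osmolyte pool
``c_gly`` that adds to the internal osmotic pressure:

    Ḣ      = k_act · max(0, 1 − Π_t/Π_ref) · (1 − H) − k_deact · H
    ċ_gly  = k_gly · H − k_leak · c_gly − c_gly · V̇_os/V_os

The surrogate has the same coupling contract as a full mechanistic HOG
model — input: turgor; output: osmolyte production — so a detailed
signalling model can be slotted in behind the same interface.  With
``k_gly = 0`` the active branch has no feedback on the cell and the
simulation reduces exactly to the passive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _integrate
from ._integrate import Compartment, HogCoupling, System
from .core import CellState, ShockProtocol, Trajectory, initial_state, simulate
from .units import CellParams

__all__ = ["HogParams", "HogTrajectory", "hog_rhs", "simulate_with_hog"]


@dataclass(frozen=True)
class HogParams:
    """Parameters of the turgor-deficit-sensing response.

    Defaults were calibrated once so that recovery from a 240→500 mM
    hyperosmotic step completes within ~15–30 simulated minutes, clearly
    faster than the passive response (see docs/methods.md).

    Attributes
    ----------
    k_act : activation rate at full turgor deficit, s⁻¹.
    k_deact : deactivation rate, s⁻¹.
    k_gly : glycerol production rate per unit active fraction, mM s⁻¹.
    k_leak : first-order glycerol leak rate, s⁻¹.
    Pi_ref : turgor set-point, Pa (defaults to the unstressed turgor).
    """

    k_act: float = 0.01
    k_deact: float = 0.005
    k_gly: float = 1.0
    k_leak: float = 1e-4
    Pi_ref: float = 2.0e5

    def __post_init__(self) -> None:
        for name in ("k_act", "k_deact", "k_gly", "k_leak", "Pi_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def coupling(self) -> HogCoupling:
        return HogCoupling(
            k_act=self.k_act,
            k_deact=self.k_deact,
            k_gly=self.k_gly,
            k_leak=self.k_leak,
            Pi_ref=self.Pi_ref,
        )


def hog_rhs(
    state: CellState,
    H: float,
    c_gly: float,
    params: CellParams,
    hog: HogParams,
    Vdot: float = 0.0,
) -> tuple:
    """Derivatives (Ḣ, ċ_gly in mM/s) of the active-response states."""
    deficit = max(0.0, 1.0 - state.Pi_t / hog.Pi_ref)
    dH = hog.k_act * deficit * (1.0 - H) - hog.k_deact * H
    dc_gly = hog.k_gly * H - hog.k_leak * c_gly - c_gly * Vdot / state.V_os
    return dH, dc_gly


@dataclass
class HogTrajectory(Trajectory):
    """Trajectory of the growth model with the active-response states."""

    H: np.ndarray = None
    c_gly: np.ndarray = None

    @property
    def Pi_i(self) -> np.ndarray:
        """Internal osmotic pressure including the glycerol pool."""
        return (self.c_i + self.c_gly) * self.params.constants.RT

    def to_frame(self) -> pd.DataFrame:
        frame = super().to_frame()
        frame["hog1_active_fraction"] = self.H
        frame["c_gly_mM"] = self.c_gly
        return frame


def simulate_with_hog(
    params: CellParams,
    hog: HogParams,
    protocol: ShockProtocol | None = None,
    t_end: float = 3.6e4,
    dt_out: float = 60.0,
    initial: CellState | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = _integrate.RTOL,
) -> HogTrajectory:
    """Joint integration of the growth model and the active response.

    When ``k_gly = 0`` the response states do not feed back on the cell;
    in that case the cell trajectory is computed by the passive solver
    (bitwise identical to :func:`scgm.core.simulate`) and the signalling
    states are integrated on top of its dense turgor output.

    For coupled runs the default initial radius should be at least 1.2 μm
    (see docs/methods.md); the caller controls this via ``params.r_os0``
    or ``initial``.
    """
    if initial is None:
        initial = initial_state(params)
    if protocol is None:
        protocol = ShockProtocol.constant(params.c_e)
    if t_eval is None:
        t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = np.asarray(t_eval, dtype=float)

    if hog.k_gly == 0.0:
        passive = simulate(
            params, initial=initial, protocol=protocol, t_eval=t_eval, rtol=rtol
        )
        H, c_gly = _signalling_on_top(passive, hog, rtol)
        return HogTrajectory(
            t=passive.t, V_os=passive.V_os, Pi_t=passive.Pi_t, c_i=passive.c_i,
            r_ref=passive.r_ref, c_e=passive.c_e, V_b=passive.V_b,
            params=passive.params, H=H, c_gly=c_gly,
        )

    system = System(
        comps=[Compartment(params=params, V_b=initial.V_b)],
        hog=hog.coupling(),
    )
    y0 = np.array([
        initial.V_os, initial.Pi_t, initial.c_i, initial.r,
        0.0, 0.0,
    ])
    out = _integrate.integrate(
        system, y0, 0.0, float(t_eval[-1]), protocol, t_eval, rtol=rtol
    )
    return HogTrajectory(
        t=t_eval,
        V_os=out[0],
        Pi_t=out[1],
        c_i=out[2],
        r_ref=out[3],
        c_e=np.array([protocol.c_e(t) for t in t_eval]),
        V_b=initial.V_b,
        params=params,
        H=np.clip(out[4], 0.0, 1.0),
        c_gly=out[5],
    )


def _signalling_on_top(passive: Trajectory, hog: HogParams, rtol: float):
    """Integrate H (and a feedback-free glycerol pool) driven by Π_t(t)."""
    t = passive.t
    Pi_t = passive.Pi_t

    def drive(tq: float) -> float:
        return float(np.interp(tq, t, Pi_t))

    def rhs(tq, y):
        H = y[0]
        deficit = max(0.0, 1.0 - drive(tq) / hog.Pi_ref)
        return [hog.k_act * deficit * (1.0 - H) - hog.k_deact * H]

    # Cap the step so the solver cannot leap across a shock-induced turgor
    # transient while H is still identically zero.
    sol = solve_ivp(
        rhs, (float(t[0]), float(t[-1])), [0.0], method="LSODA",
        t_eval=t, rtol=rtol, atol=1e-10, max_step=60.0,
    )
    H = np.clip(sol.y[0], 0.0, 1.0)
    return H, np.zeros_like(H)
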