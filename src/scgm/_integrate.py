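"""Event-driven stiff integration of one or more coupled cell compartments.

This private module implements the ODE right-hand side and the integration
driver used by :mod:`scgm.core` (single cell), :mod:`scgm.coupled`
(mother + bud(s)) and :mod:`scgm.hog` (single cell with active osmotic
response).  All public simulation entry points funnel through the same
machinery, so a coupled simulation restricted to its mother-only phase is
numerically identical to a single-cell simulation.

State layout: four states per compartment

    [V_os (μm³), Pi_t (Pa), c_i (mM), r_ref (μm)]

optionally followed by two active-response states ``[H, c_gly]`` (active
Hog1 fraction, glycerol concentration in mM) for compartment 0.
Concentrations are kept in mM *inside the solver state* so that all state
magnitudes (and hence the numerically differenced Jacobian) are reasonably
scaled; rate constants are converted from the internal amount units where
they enter the right-hand side.

Events (terminal; integration is restarted at the event time so the
turgor-floor switch always falls on a step boundary):

* ``clamp``   — Pi_t reaches 0 from above: the membrane is assumed to detach
  from the wall rather than pull it inward, so turgor is frozen at 0;
* ``release`` — while clamped, net water flow turns inward again, which
  re-pressurises the wall: normal turgor dynamics resume.

A small guard window prevents an event from re-firing at the restart point
where its switching function is exactly zero.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .units import CellParams, INTERNAL_TO_MM, MM_TO_INTERNAL

FOUR_PI = 4.0 * math.pi

#: Default solver tolerances (see docs/methods.md).
RTOL = 1e-8
ATOL_COMP = (1e-6, 1e-2, 1e-9, 1e-6)    # V_os, Pi_t, c_i (mM), r_ref
ATOL_HOG = (1e-9, 1e-9)                 # H, c_gly (mM)

_EVENT_GUARD = 1e-6   # s: window in which a just-fired event is masked


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last valid state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(f"{message} (t={t_last:.6g} s)")
        self.t_last = t_last
        self.y_last = y_last


@dataclass
class Compartment:
    """One cell compartment: parameters, solid volume and turgor-floor flag."""

    params: CellParams
    V_b: float
    clamped: bool = False


@dataclass
class Link:
    """Exchange coupling of one spoke compartment to the hub.

    Either constant coefficients (``L_x``, ``k_x``) or coefficients that
    scale with the spoke's current surface area: ``L_x = water_scale ·
    L_p · G`` and ``k_x = osmo_scale · k_uptake · G / c_e`` — the latter is
    the regime in which inter-compartment gradients genuinely vanish: the
    residual concentration edge the spoke can hold is ~Π_e/osmo_scale in
    pressure units, and it must stay far below the sub-pascal Bingham
    excess that drives plastic growth.
    """

    L_x: float | None = None
    k_x: float | None = None
    water_scale: float = 1e7
    osmo_scale: float = 1e11

    def coefficients(self, params: CellParams, G: float) -> tuple[float, float]:
        c_e_int = params.c_e * MM_TO_INTERNAL
        L = self.L_x if self.L_x is not None else self.water_scale * params.L_p * G
        k = (
            self.k_x
            if self.k_x is not None
            else self.osmo_scale * params.k_uptake * G / c_e_int
        )
        return L, k


@dataclass
class HogCoupling:
    """Turgor-deficit-sensing osmolyte production attached to compartment 0."""

    k_act: float
    k_deact: float
    k_gly: float     # mM s⁻¹ per unit active fraction
    k_leak: float
    Pi_ref: float


@dataclass
class System:
    """A hub-and-spoke assembly of compartments.

    Compartment 0 is the hub (the mother); every further compartment
    exchanges water and osmolytes with the hub only, with coefficients
    ``links[j] = (L_x, k_x)`` for compartment ``j+1`` (μm³ s⁻¹ Pa⁻¹ and
    μm³ s⁻¹).
    """

    comps: list[Compartment]
    links: list[Link] = field(default_factory=list)
    hog: HogCoupling | None = None

    @property
    def n_states(self) -> int:
        return 4 * len(self.comps) + (2 if self.hog is not None else 0)

    def atol(self) -> np.ndarray:
        a = list(ATOL_COMP) * len(self.comps)
        if self.hog is not None:
            a += list(ATOL_HOG)
        return np.asarray(a)

    # -- right-hand side ----------------------------------------------------

    def _const_cache(self):
        """Per-compartment constants folded once (hot path: rhs)."""
        cache = []
        for comp in self.comps:
            p = comp.params
            cache.append((
                p.L_p,
                p.constants.RT,
                p.k_uptake * INTERNAL_TO_MM,
                p.k_consumption * INTERNAL_TO_MM,
                p.Pi_ct,
                2.0 * p.E * p.d / (1.0 - p.nu),
                p.E * p.phi / (1.0 - p.nu),
                p.phi / (2.0 * p.d),
                comp.V_b,
            ))
        return cache

    def rhs(self, t: float, y: np.ndarray, c_e_mM: float) -> np.ndarray:
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = self._const_cache()
        comps = self.comps
        n = len(comps)
        hog = self.hog

        r = [0.0] * n
        G = [0.0] * n
        Pi_t_eff = [0.0] * n
        Pi_i = [0.0] * n
        J_w = [0.0] * n
        Pi_e = c_e_mM * cache[0][1]
        for i in range(n):
            L_p, RT, _, _, _, _, _, _, V_b = cache[i]
            V_os = y[4 * i]
            Pi_t = y[4 * i + 1]
            c_tot = y[4 * i + 2]
            if hog is not None and i == 0:
                c_tot = c_tot + y[4 * n + 1]
            V_t = V_os + V_b
            if V_t < 1e-12:  # guard against solver probes below 0
                V_t = 1e-12
            ri = (3.0 * V_t / FOUR_PI) ** (1.0 / 3.0)
            r[i] = ri
            G[i] = FOUR_PI * ri * ri
            Pi_i[i] = c_tot * RT
            Pi_t_eff[i] = 0.0 if comps[i].clamped else Pi_t
            J_w[i] = L_p * G[i] * (Pi_t_eff[i] + Pi_e - Pi_i[i])

        # Inter-compartment exchange (hub = compartment 0). Water moves down
        # the water-potential difference psi = Pi_t - Pi_i; osmolytes down
        # the concentration difference.
        dV = [-J for J in J_w]
        Q_s = [0.0] * n
        psi0 = Pi_t_eff[0] - Pi_i[0]
        for j in range(1, n):
            link = self.links[j - 1]
            L_x, k_x = link.coefficients(comps[j].params, G[j])
            Q_w = L_x * (psi0 - (Pi_t_eff[j] - Pi_i[j]))
            q_s = k_x * (y[2] - y[4 * j + 2])
            dV[0] -= Q_w
            dV[j] += Q_w
            Q_s[0] -= q_s
            Q_s[j] += q_s

        dy = np.empty_like(y)
        for i in range(n):
            _, _, ku, kc, Pi_ct, elast, plast, strain, _ = cache[i]
            V_os = y[4 * i]
            Pi_t = y[4 * i + 1]
            c_i = y[4 * i + 2]
            r_ref = y[4 * i + 3]
            clamped = comps[i].clamped
            ri = r[i]
            rdot = dV[i] / G[i]
            fm = Pi_t - Pi_ct if (not clamped and Pi_t >= Pi_ct) else 0.0
            dy[4 * i] = dV[i]
            dy[4 * i + 1] = 0.0 if clamped else (
                elast * rdot / (ri * ri) - Pi_t * rdot / ri - plast * fm
            )
            dy[4 * i + 2] = (ku * G[i] - kc * V_os - c_i * dV[i] + Q_s[i]) / V_os
            dy[4 * i + 3] = r_ref * strain * ri * fm

        if hog is not None:
            H = y[4 * n]
            c_gly = y[4 * n + 1]
            deficit = 1.0 - y[1] / hog.Pi_ref
            if deficit < 0.0:
                deficit = 0.0
            dy[4 * n] = hog.k_act * deficit * (1.0 - H) - hog.k_deact * H
            dy[4 * n + 1] = hog.k_gly * H - hog.k_leak * c_gly - c_gly * dV[0] / y[0]
        return dy

    # -- event functions ----------------------------------------------------

    def events(self, c_e_mM: float):
        """Build (func, direction, kind, comp_index) for the current flags.

        Only the turgor floor is event-handled.  The Bingham kink at
        Π_t = Π_ct is continuous (f_m → 0 at the threshold) and — crucially
        — steady growth sits permanently a fraction of a pascal *above* the
        threshold, so terminal events there would chatter; the stiff solver
        integrates across the kink without them.
        """
        evs = []
        for i, comp in enumerate(self.comps):
            if not comp.clamped:
                evs.append((self._clamp_fn(i), -1, "clamp", i))
            else:
                evs.append((self._release_fn(i, c_e_mM), 1, "release", i))
        return evs

    def _clamp_fn(self, i: int):
        def fn(t, y, *args):
            return y[4 * i + 1]

        return fn

    def _release_fn(self, i: int, c_e_mM: float):
        def fn(t, y, *args):
            return self.rhs(t, y, c_e_mM)[4 * i]

        return fn


def integrate(
    system: System,
    y0: np.ndarray,
    t0: float,
    t_end: float,
    protocol,
    t_eval: np.ndarray,
    rtol: float = RTOL,
    budget_s: float | None = None,
) -> np.ndarray:
    """Integrate ``system`` over ``[t0, t_end]`` and sample at ``t_eval``.

    ``protocol`` must provide ``c_e(t)`` (mM, right-continuous piecewise
    constant) and ``change_times()``.  Returns an array of shape
    ``(n_states, len(t_eval))``.

    ``budget_s`` caps the wall-clock time of this call: a pathological
    parameter set probed by an optimiser can make the stiff solver grind
    through millions of steps, and the cap turns that into an
    :class:`IntegrationError` the caller can treat as a failed evaluation.
    """
    deadline = None if budget_s is None else _time.monotonic() + budget_s
    if deadline is not None:
        inner_rhs = system.rhs
        counter = [0]

        def guarded_rhs(t, y, c_e):
            counter[0] += 1
            if counter[0] % 512 == 0 and _time.monotonic() > deadline:
                raise IntegrationError("integration budget exceeded", t, y)
            return inner_rhs(t, y, c_e)
    else:
        guarded_rhs = system.rhs
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < t0 - 1e-9 or t_eval[-1] > t_end + 1e-9):
        raise ValueError("t_eval outside integration span")
    out = np.empty((len(y0), t_eval.size))
    filled = np.zeros(t_eval.size, dtype=bool)
    if t_end <= t0:  # degenerate span: every requested point is t0 itself
        out[:] = np.asarray(y0, dtype=float)[:, None]
        return out

    breaks = [t for t in protocol.change_times() if t0 < t < t_end]
    edges = [t0, *breaks, t_end]
    atol = system.atol()
    y = np.asarray(y0, dtype=float).copy()

    for a0, b in zip(edges[:-1], edges[1:]):
        c_e = protocol.c_e(0.5 * (a0 + b))
        a = a0
        guard_until: dict[tuple[str, int], float] = {}
        while a < b:
            ev_all = system.events(c_e)
            # Mask events whose switching function is already at zero (e.g.
            # a run started exactly at Pi_t = Pi_ct): they would re-fire
            # immediately at the left endpoint.
            for fn, _, kind, ci in ev_all:
                scale = system.comps[ci].params.Pi_ct if kind == "clamp" else 1.0
                if abs(fn(a, y)) < 1e-7 * scale:
                    guard_until[(kind, ci)] = max(
                        guard_until.get((kind, ci), -np.inf), a + _EVENT_GUARD
                    )
            active = [
                ev for ev in ev_all
                if guard_until.get((ev[2], ev[3]), -np.inf) <= a
            ]
            # While any event is masked, only integrate to the guard horizon.
            b_seg = b
            pending = [v for v in guard_until.values() if v > a]
            if len(active) < len(ev_all) and pending:
                b_seg = min(b, max(pending))
            ev_funcs = []
            for fn, direction, _, _ in active:
                fn.terminal = True
                fn.direction = direction
                ev_funcs.append(fn)

            if not np.all(np.isfinite(y)):
                raise IntegrationError("non-finite state", a, y)
            # LSODA is fast and accurate for a single compartment; the very
            # stiff inter-compartment exchange defeats its Newton iteration,
            # while BDF with the same tolerances handles it robustly.
            method = "BDF" if system.links else "LSODA"
            sol = solve_ivp(
                guarded_rhs, (a, b_seg), y, method=method, args=(c_e,),
                dense_output=True, events=ev_funcs, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise IntegrationError(sol.message, sol.t[-1], sol.y[:, -1])

            t_reached = sol.t[-1]
            sel = (~filled) & (t_eval >= a - 1e-12) & (t_eval <= t_reached + 1e-12)
            if np.any(sel):
                out[:, sel] = sol.sol(np.clip(t_eval[sel], sol.t[0], t_reached))
                filled |= sel

            if sol.status == 1:  # an event fired
                idx = min(
                    (k for k, te in enumerate(sol.t_events) if te.size),
                    key=lambda k: sol.t_events[k][0],
                )
                t_ev = sol.t_events[idx][0]
                y = sol.y_events[idx][0].copy()
                _, _, kind, ci = active[idx]
                if kind == "clamp":
                    system.comps[ci].clamped = True
                    y[4 * ci + 1] = 0.0
                elif kind == "release":
                    system.comps[ci].clamped = False
                    y[4 * ci + 1] = 0.0
                guard_until[(kind, ci)] = t_ev + _EVENT_GUARD
                if kind == "release":
                    guard_until[("clamp", ci)] = t_ev + _EVENT_GUARD
                elif kind == "clamp":
                    guard_until[("release", ci)] = t_ev + _EVENT_GUARD
                a = t_ev
            else:
                y = sol.y[:, -1].copy()
                a = b_seg
    # Numerical guard: t_eval points equal to t_end within round-off.
    if not np.all(filled):
        missing = np.where(~filled)[0]
        raise IntegrationError("output grid not fully covered", t_end, y)
    return out
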