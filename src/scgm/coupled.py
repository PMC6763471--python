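"""Coupled mother–bud growth model.

Budding yeast grows as two connected compartments: a mother and, after a
delay ``t_budstart``, a bud sharing the mother's cytoplasm through the bud
neck.  Each compartment is a full single-cell model; they exchange water
down the water-potential difference and osmolytes down the concentration
difference, with exchange coefficients chosen fast enough that the
inter-compartment gradients vanish on the observation timescale.

The compartments differ only in their wall mechanics: the bud's
extensibility is ``ϕ_bud = q·ϕ_mother``.  Because the plastic strain rate
scales with radius, a small bud expands much more slowly than its mother at
equal extensibility — bud expansion requires a substantially more
extensible bud wall (large q), and between two equal buds any size
difference is self-amplifying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _integrate
from ._integrate import Compartment, Link, System
from .core import FOUR_PI, ShockProtocol, Trajectory, initial_state
from .units import MIN_TO_S, MM_TO_INTERNAL, CellParams

__all__ = [
    "CoupledParams",
    "CoupledTrajectory",
    "exchange_fluxes",
    "simulate_coupled",
    "simulate_two_buds",
    "sweep_extensibility_ratio",
    "bud_expansion_threshold",
    "sweep_young_modulus",
]


@dataclass(frozen=True)
class CoupledParams:
    """Parameters of the mother–bud assembly.

    Attributes
    ----------
    mother : parameter set of the mother compartment.
    q : extensibility ratio ϕ_bud/ϕ_mother (> 0).
    t_budstart : bud initialisation time, seconds.
    r_bud_init : initial osmotic radius of the bud, μm; defaults to the
        mother's initial osmotic radius (mother and bud start from the same
        small volume).
    L_x : mother↔bud water exchange coefficient, μm³ s⁻¹ Pa⁻¹.  ``None``
        (default) scales it with the bud's current surface,
        ``10⁷·L_p·G_bud(t)`` — fast relative to the membrane flux.
    k_x : mother↔bud osmolyte exchange coefficient, μm³ s⁻¹.  ``None``
        (default) scales it with the bud's current surface,
        ``10¹¹·k_uptake·G_bud(t)/c_e``.  The factor must be large enough
        that the concentration edge the bud's own uptake can sustain
        (≈ Π_e/factor in pressure units) stays far below the sub-pascal
        turgor excess that drives plastic wall expansion; otherwise the
        bud grows like a free cell regardless of q.
    E_bud_ratio : Young's-modulus ratio E_bud/E_mother (1 except in the
        modulus sweep).
    """

    mother: CellParams = field(default_factory=CellParams)
    q: float = 230.0
    t_budstart: float = 117.0 * MIN_TO_S
    r_bud_init: float | None = None
    L_x: float | None = None
    k_x: float | None = None
    E_bud_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("extensibility ratio q must be positive")
        if self.t_budstart < 0:
            raise ValueError("t_budstart must be non-negative")
        if self.E_bud_ratio <= 0:
            raise ValueError("E_bud_ratio must be positive")

    @property
    def r_bud(self) -> float:
        return self.mother.r_os0 if self.r_bud_init is None else self.r_bud_init

    @property
    def G_bud_init(self) -> float:
        return FOUR_PI * self.r_bud**2

    def link(self) -> Link:
        """Exchange coupling (constant if L_x/k_x set, surface-scaled else)."""
        return Link(L_x=self.L_x, k_x=self.k_x)

    def exchange_coefficients(self, G_bud: float) -> tuple[float, float]:
        """(L_x, k_x) at a given bud surface area, μm³ s⁻¹ Pa⁻¹ / μm³ s⁻¹."""
        return self.link().coefficients(self.mother, G_bud)

    def bud_params(self) -> CellParams:
        """Bud parameter set: the mother's, with ϕ (and possibly E) scaled."""
        return self.mother.replace(
            phi=self.q * self.mother.phi,
            E=self.E_bud_ratio * self.mother.E,
        )


def exchange_fluxes(mother, bud, coupled: CoupledParams):
    """Water and osmolyte flux from mother to bud.

    Water: ``L_x·[(Π_t,m − Π_i,m) − (Π_t,b − Π_i,b)]`` (μm³ s⁻¹) — down the
    water-potential difference, the compartments sharing the external
    reference.  Osmolytes: ``k_x·(c_i,m − c_i,b)`` converted to mmol s⁻¹.
    Both are antisymmetric under swapping the compartments.
    """
    RT = coupled.mother.constants.RT
    L_x, k_x = coupled.exchange_coefficients(bud.G)
    psi_m = mother.Pi_t - mother.c_i * RT
    psi_b = bud.Pi_t - bud.c_i * RT
    water = L_x * (psi_m - psi_b)
    osmolyte = k_x * (mother.c_i - bud.c_i) * MM_TO_INTERNAL
    return water, osmolyte


@dataclass
class CoupledTrajectory:
    """Mother trajectory plus one or two bud trajectories.

    Bud series are NaN before ``t_budstart``.  ``mother`` and the buds are
    full :class:`~scgm.core.Trajectory` objects on the shared grid.
    """

    t: np.ndarray
    mother: Trajectory
    buds: list
    t_budstart: float

    @property
    def bud(self) -> Trajectory:
        return self.buds[0]

    def to_frame(self) -> pd.DataFrame:
        """Fitting-input dialect: time in minutes, total volumes in μm³."""
        data = {
            "time_min": self.t / MIN_TO_S,
            "v_mother_um3": self.mother.V_t,
            "v_bud_um3": self.buds[0].V_t,
        }
        if len(self.buds) > 1:
            data["v_bud2_um3"] = self.buds[1].V_t
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bud_initial_packed(cp: CoupledParams, y_mother: np.ndarray, V_b_mother: float):
    """Initial packed state of a bud created from the mother's state.

    The bud inherits the mother's instantaneous osmolarity (continuity of
    the shared cytoplasm); its solid volume is the mother's scaled by
    (r_bud_init/r_os0)³.  The freshly deposited wall starts *unstressed*:
    reference radius equal to the actual radius and zero turgor — turgor
    is wall stress, not a cytoplasmic property, and a zero-strain wall
    cannot carry pressure.  Water influx pressurises the bud within
    seconds of its creation.
    """
    m = cp.mother
    V_os = FOUR_PI / 3.0 * cp.r_bud**3
    V_b = V_b_mother * (cp.r_bud / m.r_os0) ** 3
    V_t = V_os + V_b
    r_tot = (3.0 * V_t / FOUR_PI) ** (1.0 / 3.0)
    return np.array([V_os, 0.0, y_mother[2], r_tot]), V_b


def _simulate_multi(
    cp: CoupledParams,
    bud_radii: list,
    t_end: float,
    dt_out: float,
    t_eval: np.ndarray | None,
    rtol: float,
    budget_s: float | None = None,
) -> CoupledTrajectory:
    m = cp.mother
    if t_eval is None:
        if t_end <= cp.t_budstart:
            raise ValueError("t_end must exceed t_budstart")
        t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[-1] <= cp.t_budstart:
        raise ValueError("output grid must extend beyond t_budstart")
    protocol = ShockProtocol.constant(m.c_e)

    init = initial_state(m)
    y_m = np.array([init.V_os, init.Pi_t, init.c_i, init.r])

    pre = t_eval[t_eval < cp.t_budstart]
    post = t_eval[t_eval >= cp.t_budstart]

    n_buds = len(bud_radii)
    out = np.full((4 * (1 + n_buds), t_eval.size), np.nan)

    # Mother-only phase: the same one-compartment system as scgm.core.simulate.
    sys1 = System(comps=[Compartment(params=m, V_b=m.V_b)])
    grid1 = np.concatenate([pre, [cp.t_budstart]])
    out1 = _integrate.integrate(sys1, y_m, 0.0, cp.t_budstart, protocol, grid1,
                                rtol=rtol, budget_s=budget_s)
    out[:4, : pre.size] = out1[:, :-1]
    y_m = out1[:, -1]

    # Joint phase: instantiate the buds and integrate the coupled system.
    comps = [Compartment(params=m, V_b=m.V_b)]
    links = []
    y0 = [y_m]
    for r_b in bud_radii:
        cp_b = cp if r_b is None else CoupledParams(
            mother=m, q=cp.q, t_budstart=cp.t_budstart, r_bud_init=r_b,
            L_x=cp.L_x, k_x=cp.k_x, E_bud_ratio=cp.E_bud_ratio,
        )
        y_b, V_b_b = _bud_initial_packed(cp_b, y_m, m.V_b)
        comps.append(Compartment(params=cp.bud_params(), V_b=V_b_b))
        links.append(cp.link())
        y0.append(y_b)
    sys2 = System(comps=comps, links=links)
    grid2 = np.concatenate([[cp.t_budstart], post]) if (post.size == 0 or post[0] > cp.t_budstart) else post
    # Integrate the joint phase on its own clock: the bud-creation
    # transient can need steps far below the float spacing at t_budstart,
    # and c_e is constant here, so shifting the origin is exact.
    out2 = _integrate.integrate(
        sys2, np.concatenate(y0), 0.0, float(t_eval[-1]) - cp.t_budstart,
        protocol, grid2 - cp.t_budstart, rtol=rtol, budget_s=budget_s,
    )
    keep = grid2.size - post.size
    out[:, pre.size:] = out2[:, keep:]

    def _traj(block_row: int, params: CellParams, V_b: float) -> Trajectory:
        rows = out[block_row: block_row + 4]
        return Trajectory(
            t=t_eval,
            V_os=rows[0],
            Pi_t=rows[1],
            c_i=rows[2],
            r_ref=rows[3],
            c_e=np.full(t_eval.size, m.c_e),
            V_b=V_b,
            params=params,
        )

    mother_traj = _traj(0, m, m.V_b)
    buds = []
    for j in range(n_buds):
        V_b_b = comps[1 + j].V_b
        buds.append(_traj(4 * (1 + j), cp.bud_params(), V_b_b))
    return CoupledTrajectory(t=t_eval, mother=mother_traj, buds=buds, t_budstart=cp.t_budstart)


def simulate_coupled(
    cp: CoupledParams,
    t_end: float,
    dt_out: float = 180.0,
    t_eval: np.ndarray | None = None,
    rtol: float = _integrate.RTOL,
    budget_s: float | None = None,
) -> CoupledTrajectory:
    """Simulate mother and bud.

    The mother grows alone until ``t_budstart``; then a bud with osmotic
    radius ``r_bud_init`` is created from the mother's instantaneous state
    and the joint system is integrated.  Uptake and consumption constants
    are identical in both compartments; only wall mechanics differ.
    """
    return _simulate_multi(cp, [None], t_end, dt_out, t_eval, rtol, budget_s)


def simulate_two_buds(
    cp: CoupledParams,
    r_bud2_init: float,
    t_end: float,
    dt_out: float = 180.0,
    t_eval: np.ndarray | None = None,
    rtol: float = _integrate.RTOL,
) -> CoupledTrajectory:
    """Simulate a mother with two buds (both created at ``t_budstart``).

    Each bud exchanges water and osmolytes with the mother only, not with
    its sibling.  Equal initial radii give identical bud trajectories;
    unequal radii are amplified — only the larger bud grows.
    """
    if r_bud2_init <= 0:
        raise ValueError("second bud radius must be positive")
    return _simulate_multi(cp, [None, r_bud2_init], t_end, dt_out, t_eval, rtol)


# -- parameter sweeps -------------------------------------------------------

#: A bud counts as expanding when its total volume at the end of the sweep
#: horizon is at least this multiple of its initial total volume (doubling:
#: genuine wall growth, not elastic swelling).
EXPANSION_FACTOR = 2.0


def _grows(V: np.ndarray, factor: float) -> bool:
    V = V[np.isfinite(V)]
    return bool(V.size >= 2 and V[-1] >= factor * V[0])


def sweep_extensibility_ratio(
    base: CoupledParams,
    q_grid: np.ndarray,
    t_end: float = 600.0 * MIN_TO_S,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Bud-expansion outcome over a grid of extensibility ratios q."""
    rows = []
    for q in np.asarray(q_grid, dtype=float):
        cp = CoupledParams(
            mother=base.mother, q=float(q), t_budstart=base.t_budstart,
            r_bud_init=base.r_bud_init, L_x=base.L_x, k_x=base.k_x,
        )
        tr = simulate_coupled(cp, t_end=t_end, dt_out=600.0, rtol=rtol)
        V_bud = tr.bud.V_t
        rows.append(
            {
                "q": float(q),
                "bud_expands": _grows(V_bud, EXPANSION_FACTOR),
                "v_bud_end_um3": float(V_bud[np.isfinite(V_bud)][-1]),
                "v_mother_end_um3": float(tr.mother.V_t[-1]),
            }
        )
    return pd.DataFrame(rows)


def bud_expansion_threshold(sweep: pd.DataFrame) -> float:
    """Smallest expanding q in a sweep table (NaN if none expands)."""
    expanding = sweep.loc[sweep["bud_expands"], "q"]
    return float(expanding.min()) if len(expanding) else float("nan")


def sweep_young_modulus(
    base: CoupledParams,
    E_ratios: np.ndarray,
    t_end: float = 600.0 * MIN_TO_S,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Growth outcome per Young's-modulus ratio E_bud/E_mother (at q = 1).

    Reports whether bud and mother volumes increase over the horizon; the
    mother's growth is compared against her volume at bud start.
    """
    rows = []
    for ratio in np.asarray(E_ratios, dtype=float):
        cp = CoupledParams(
            mother=base.mother, q=1.0, t_budstart=base.t_budstart,
            r_bud_init=base.r_bud_init, L_x=base.L_x, k_x=base.k_x,
            E_bud_ratio=float(ratio),
        )
        tr = simulate_coupled(cp, t_end=t_end, dt_out=600.0, rtol=rtol)
        V_bud = tr.bud.V_t
        V_m = tr.mother.V_t
        i0 = np.searchsorted(tr.t, cp.t_budstart)
        rows.append(
            {
                "E_ratio": float(ratio),
                "bud_grows": _grows(V_bud, EXPANSION_FACTOR),
                "mother_grows": bool(V_m[-1] > 1.05 * V_m[min(i0, V_m.size - 1)]),
                "v_bud_end_um3": float(V_bud[np.isfinite(V_bud)][-1]),
                "v_mother_end_um3": float(V_m[-1]),
            }
        )
    return pd.DataFrame(rows)
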