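"""Fit the coupled mother–bud model to volume-trajectory pairs.

The observable is the pair of total-volume time series (mother, bud) as
produced by brightfield microscopy segmentation: time in minutes (3-min
sampling), volumes in μm³, bud values missing before the bud appears.
Six parameters are free:

* ``k_uptake`` — osmolyte uptake rate constant (global growth rate),
* ``k_ratio`` = k_uptake/k_consumption (μm; sets the maximum volume),
* ``phi_mother`` — wall extensibility of the mother,
* ``q`` = ϕ_bud/ϕ_mother — extensibility ratio (identified only as a
  lower bound: the fit is flat in q above its expansion threshold),
* ``r_0`` — initial osmotic radius (free initial condition),
* ``t_budstart`` — bud initialisation time (free unless supplied by the
  data, in which case a 5-parameter fit is performed).

The objective is an unweighted χ² over both compartments,
``χ² = Σ[(V_obs − V_sim)/σ]²`` with a constant volume noise scale σ
(default 1 μm³).  The post-fit filter retains fits with ``k_ratio ≥ 1 μm``
and ``χ² ≤ 50``; both thresholds are inclusive on the keep side and are
meaningful only relative to the declared σ and the trajectory length.

The module follows the statsmodels convention: build a
:class:`CoupledVolumeModel` from data, call :meth:`~CoupledVolumeModel.fit`,
get a :class:`CoupledVolumeResults` with estimates, standard errors and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from ._integrate import IntegrationError
from .coupled import CoupledParams, simulate_coupled
from .units import MIN_TO_S, CellParams

__all__ = [
    "FitSpec",
    "CoupledVolumeModel",
    "CoupledVolumeResults",
    "chi2",
    "fit_pair",
    "filter_fits",
    "summarize_fits",
]

PARAM_NAMES = ("k_uptake", "k_ratio", "phi_mother", "q", "r_0", "t_budstart_min")

#: Parameters optimised on a log10 scale.
_LOG_PARAMS = {"k_uptake", "phi_mother", "q"}


def _default_bounds(T_obs_min: float) -> dict:
    return {
        "k_uptake": (1e-17, 1e-14),
        "k_ratio": (0.3, 3.0),
        "phi_mother": (1e-9, 1e-1),
        "q": (1.0, 1e6),
        "r_0": (0.5, 3.0),
        "t_budstart_min": (0.0, 0.8 * T_obs_min),
    }


@dataclass(frozen=True)
class FitSpec:
    """Optimisation settings for one trajectory-pair fit.

    ``free`` lists the free parameters; when ``t_budstart`` is supplied by
    the data it is dropped from the free set.  ``n_starts`` Latin-hypercube
    starting points are drawn deterministically from ``seed``.
    """

    free: tuple = PARAM_NAMES
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    n_starts: int = 16
    seed: int = 0
    max_nfev: int | None = None

    def resolved_bounds(self, T_obs_min: float) -> dict:
        out = _default_bounds(T_obs_min)
        out.update(self.bounds)
        return out


def chi2(observed: np.ndarray, simulated: np.ndarray, sigma: float) -> float:
    """χ² = Σ (observed − simulated)² / σ², skipping missing observations."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.shape != simulated.shape:
        raise ValueError("observed and simulated series must share a time grid")
    mask = np.isfinite(observed)
    return float(np.sum(((observed[mask] - simulated[mask]) / sigma) ** 2))


class CoupledVolumeModel:
    """Coupled mother–bud growth model bound to one observed trajectory pair.

    Parameters
    ----------
    data : DataFrame with columns ``time_min``, ``v_mother_um3``,
        ``v_bud_um3`` (bud entries may be NaN before the bud appears).
    base_params : fixed physical parameters (wall mechanics, membrane
        permeability, medium osmolarity, solid radius); defaults to the
        reference set.
    sigma : volume noise scale, μm³.
    t_budstart_min : if given, the bud-start time is taken from the data
        and excluded from the free parameters.
    fit_rtol : ODE tolerance used inside the objective (looser than the
        presentation tolerance, for speed).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        base_params: CellParams | None = None,
        sigma: float = 1.0,
        t_budstart_min: float | None = None,
        fit_rtol: float = 1e-6,
    ) -> None:
        required = {"time_min", "v_mother_um3", "v_bud_um3"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns: {sorted(missing)}")
        data = data.reset_index(drop=True)
        t = data["time_min"].to_numpy(dtype=float)
        if t.size < 10:
            raise ValueError("need at least 10 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing (alignment error)")
        vm = data["v_mother_um3"].to_numpy(dtype=float)
        vb = data["v_bud_um3"].to_numpy(dtype=float)
        if np.any(vm[np.isfinite(vm)] <= 0) or np.any(vb[np.isfinite(vb)] <= 0):
            raise ValueError("volumes must be positive")
        if not np.all(np.isfinite(vm)):
            raise ValueError("mother volume series must be complete")
        self.data = data
        self.t_min = t
        self.v_mother = vm
        self.v_bud = vb
        self.bud_mask = np.isfinite(vb)
        self.sigma = float(sigma)
        self.base_params = base_params or CellParams()
        self.t_budstart_min = t_budstart_min
        self.fit_rtol = fit_rtol
        #: wall-clock cap per forward simulation inside the objective; a
        #: pathological trial point counts as a failed evaluation instead
        #: of stalling the optimiser.
        self.sim_budget_s = 10.0

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CoupledVolumeModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- forward model ------------------------------------------------------

    def _coupled_params(self, theta: dict) -> CoupledParams:
        base = self.base_params
        t_bud_min = (
            self.t_budstart_min
            if self.t_budstart_min is not None
            else theta["t_budstart_min"]
        )
        mother = base.replace(
            k_uptake=theta["k_uptake"],
            k_consumption=theta["k_uptake"] / theta["k_ratio"],
            phi=theta["phi_mother"],
            r_os0=theta["r_0"],
        )
        return CoupledParams(
            mother=mother,
            q=theta["q"],
            t_budstart=t_bud_min * MIN_TO_S,
        )

    def predict(self, theta: dict, rtol: float | None = None):
        """Simulated (mother, bud) total volumes on the observed grid.

        For observed-bud times earlier than the model's bud start the bud
        prediction is held at the bud's initial volume, so such points
        penalise rather than crash a misplaced ``t_budstart``.
        """
        cp = self._coupled_params(theta)
        t_s = self.t_min * MIN_TO_S
        grid = np.unique(np.concatenate([t_s, [cp.t_budstart * 1.0]]))
        grid = grid[grid >= 0.0]
        if grid[-1] <= cp.t_budstart:
            grid = np.append(grid, cp.t_budstart * 1.0 + 1.0)
        traj = simulate_coupled(
            cp, t_end=float(grid[-1]), t_eval=grid,
            rtol=self.fit_rtol if rtol is None else rtol,
            budget_s=self.sim_budget_s,
        )
        idx = np.searchsorted(grid, t_s)
        v_m = traj.mother.V_t[idx]
        v_b = traj.bud.V_t[idx]
        finite = np.isfinite(traj.bud.V_t)
        v_bud_init = traj.bud.V_t[finite][0] if np.any(finite) else np.nan
        v_b = np.where(np.isfinite(v_b), v_b, v_bud_init)
        return v_m, v_b

    def residuals(self, theta: dict) -> np.ndarray:
        try:
            v_m, v_b = self.predict(theta)
        except IntegrationError:
            # un-integrable trial point: a flat penalty steers the
            # optimiser away without aborting the whole start
            n = self.v_mother.size + int(self.bud_mask.sum())
            return np.full(n, 1e6)
        res_m = (self.v_mother - v_m) / self.sigma
        res_b = (self.v_bud[self.bud_mask] - v_b[self.bud_mask]) / self.sigma
        return np.concatenate([res_m, res_b])

    def chi2_of(self, theta: dict) -> float:
        """χ² of the data under a given parameter dict (no optimisation)."""
        r = self.residuals(theta)
        return float(np.sum(r * r))

    # -- optimisation -------------------------------------------------------

    def _free_names(self, spec: FitSpec) -> list:
        names = [n for n in spec.free if n in PARAM_NAMES and n not in spec.fixed]
        if self.t_budstart_min is not None:
            names = [n for n in names if n != "t_budstart_min"]
        return names

    def _to_internal(self, name: str, value: float) -> float:
        return math.log10(value) if name in _LOG_PARAMS else value

    def _from_internal(self, name: str, z: float) -> float:
        return 10.0 ** z if name in _LOG_PARAMS else z

    def _theta_from_z(self, z: np.ndarray, names: list, fixed: dict) -> dict:
        theta = dict(fixed)
        for name, zi in zip(names, z):
            theta[name] = self._from_internal(name, zi)
        return theta

    def data_driven_start(self) -> dict:
        """Heuristic initial guess read off the observed series.

        Bud start from the first observed bud point; initial radius from
        the first mother volume; the uptake/consumption ratio from the
        largest observed volume via the final-radius law r_final = 3·k_ratio
        (a lower bound when the plateau is not reached).
        """
        v0 = self.v_mother[0]
        r0 = (3.0 * max(v0 - self.base_params.V_b, 1e-3) / (4.0 * math.pi)) ** (1.0 / 3.0)
        vmax = float(np.nanmax(self.v_mother))
        r_inf = (3.0 * vmax / (4.0 * math.pi)) ** (1.0 / 3.0)
        t_bud = (
            float(self.t_min[self.bud_mask][0])
            if np.any(self.bud_mask)
            else 0.5 * float(self.t_min[-1])
        )
        return {
            "k_uptake": self.base_params.k_uptake,
            "k_ratio": r_inf / 3.0,
            "phi_mother": self.base_params.phi,
            "q": 230.0,
            "r_0": r0,
            "t_budstart_min": t_bud,
        }

    def fit(self, spec: FitSpec | None = None, start_values: dict | None = None) -> "CoupledVolumeResults":
        """Multi-start bounded least squares over the free parameters.

        One start is read off the data (:meth:`data_driven_start`), the
        rest are Latin-hypercube draws over the (log-scaled) bounds.
        Deterministic for a given ``spec.seed``.  Never raises on
        optimisation failure: if every start fails, a non-converged result
        with infinite χ² is returned.
        """
        spec = spec or FitSpec()
        names = self._free_names(spec)
        bounds = spec.resolved_bounds(float(self.t_min[-1]))
        lo = np.array([self._to_internal(n, bounds[n][0]) for n in names])
        hi = np.array([self._to_internal(n, bounds[n][1]) for n in names])

        # Nominal values for parameters held fixed during the fit.
        fixed = {
            "k_uptake": self.base_params.k_uptake,
            "k_ratio": self.base_params.k_ratio,
            "phi_mother": self.base_params.phi,
            "q": 230.0,
            "r_0": self.base_params.r_os0,
            "t_budstart_min": self.t_budstart_min if self.t_budstart_min is not None else 90.0,
        }
        fixed.update(spec.fixed)

        dds = self.data_driven_start()
        z_dds = np.clip(
            [self._to_internal(n, dds[n]) for n in names], lo, hi
        )
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(max(spec.n_starts - 1, 0))
        starts = np.vstack([z_dds, lo + unit * (hi - lo)])
        if start_values:
            z0 = np.array([
                self._to_internal(n, start_values.get(n, fixed[n])) for n in names
            ])
            starts = np.vstack([np.clip(z0, lo, hi), starts])

        x_scale = np.array([1.0 if n in _LOG_PARAMS else
                            (0.1 if n in ("k_ratio", "r_0") else 10.0 if n == "t_budstart_min" else 1.0)
                            for n in names])

        def objective(z: np.ndarray) -> np.ndarray:
            theta = self._theta_from_z(z, names, fixed)
            return self.residuals(theta)

        best = None
        log = []
        for z0 in starts:
            try:
                # diff_step must sit well above the ODE solver noise floor
                # (rtol ~1e-6), otherwise the numerical Jacobian is noise.
                sol = least_squares(
                    objective, z0, bounds=(lo, hi), method="trf",
                    x_scale=x_scale, diff_step=1e-3, max_nfev=spec.max_nfev,
                )
                cost = 2.0 * sol.cost  # chi^2
                log.append({"z0": z0.copy(), "chi2": cost, "success": bool(sol.success)})
                # a start stopped by the evaluation cap (status 0) still
                # carries its best point; keep it as a candidate
                if np.isfinite(cost) and (best is None or cost < best[0]):
                    best = (cost, sol)
            except (IntegrationError, ValueError, FloatingPointError) as err:
                log.append({"z0": z0.copy(), "chi2": np.inf, "success": False, "error": str(err)})

        if best is None:
            params = pd.Series({n: np.nan for n in PARAM_NAMES})
            return CoupledVolumeResults(
                model=self, params=params, bse=params.copy(), chi2=np.inf,
                converged=False, free_names=names, starts_log=log, spec=spec,
            )

        cost, sol = best
        theta = self._theta_from_z(sol.x, names, fixed)
        params = pd.Series({n: theta[n] for n in PARAM_NAMES})
        bse = self._standard_errors(sol, names, theta)
        return CoupledVolumeResults(
            model=self, params=params, bse=bse, chi2=cost,
            converged=bool(sol.success), free_names=names, starts_log=log,
            spec=spec, residual=sol.fun,
        )

    def profile(
        self,
        name: str,
        values,
        spec: FitSpec | None = None,
        start_values: dict | None = None,
    ) -> pd.DataFrame:
        """Profile χ² over one parameter: re-optimise the rest at each value.

        This is how practical identifiability is judged — a parameter whose
        profile is flat (χ² within ~1 of the global best over decades) is
        identified at best as a bound.  Returns a DataFrame with columns
        ``value`` and ``chi2``.
        """
        spec = spec or FitSpec(n_starts=1)
        rows = []
        for value in values:
            point_spec = FitSpec(
                free=spec.free, bounds=spec.bounds, fixed={**spec.fixed, name: value},
                n_starts=spec.n_starts, seed=spec.seed, max_nfev=spec.max_nfev,
            )
            res = self.fit(point_spec, start_values=start_values)
            rows.append({"value": value, "chi2": res.chi2})
        return pd.DataFrame(rows)

    def _standard_errors(self, sol, names: list, theta: dict) -> pd.Series:
        bse = pd.Series({n: np.nan for n in PARAM_NAMES})
        try:
            J = sol.jac
            cov_z = np.linalg.pinv(J.T @ J)
            se_z = np.sqrt(np.clip(np.diag(cov_z), 0.0, np.inf))
            for n, se in zip(names, se_z):
                # delta method back to the natural scale for log parameters
                bse[n] = se * theta[n] * math.log(10.0) if n in _LOG_PARAMS else se
        except np.linalg.LinAlgError:
            pass
        return bse


@dataclass
class CoupledVolumeResults:
    """Estimates, uncertainty and diagnostics of one trajectory-pair fit."""

    model: CoupledVolumeModel
    params: pd.Series
    bse: pd.Series
    chi2: float
    converged: bool
    free_names: list
    starts_log: list
    spec: FitSpec
    residual: np.ndarray | None = None

    #: Post-fit retention rule (inclusive on the keep side).
    K_RATIO_MIN = 1.0
    CHI2_MAX = 50.0

    @property
    def retained(self) -> bool:
        """Keep iff k_ratio ≥ 1 μm and χ² ≤ 50 (and the fit converged)."""
        return bool(
            self.converged
            and self.params["k_ratio"] >= self.K_RATIO_MIN
            and self.chi2 <= self.CHI2_MAX
        )

    @property
    def fittedvalues(self):
        """Simulated (mother, bud) volumes at the best-fit parameters."""
        return self.model.predict(dict(self.params))

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "chi2": float(self.chi2),
            "converged": self.converged,
            "retained": self.retained,
        }

    def summary(self) -> str:
        lines = [
            "Coupled mother-bud volume model — least squares fit",
            "=" * 58,
            f"n obs (mother/bud): {self.model.v_mother.size}/{int(self.model.bud_mask.sum())}"
            f"    sigma: {self.model.sigma:g} um^3",
            f"chi2: {self.chi2:.4g}    converged: {self.converged}"
            f"    retained: {self.retained}",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>14}{'std err':>14}{'free':>8}",
            "-" * 58,
        ]
        for name in PARAM_NAMES:
            free = "yes" if name in self.free_names else "no"
            lines.append(
                f"{name:<16}{self.params[name]:>14.4g}{self.bse[name]:>14.3g}{free:>8}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


def fit_pair(data: pd.DataFrame, spec: FitSpec | None = None, **model_kwargs) -> CoupledVolumeResults:
    """Convenience wrapper: build a :class:`CoupledVolumeModel` and fit it."""
    return CoupledVolumeModel(data, **model_kwargs).fit(spec)


def filter_fits(results: list) -> list:
    """Retain fits with k_ratio ≥ 1 μm and χ² ≤ 50 (idempotent)."""
    return [r for r in results if r.retained]


def summarize_fits(retained: list) -> dict:
    """Cohort summary: per-parameter median/IQR and a Pearson correlogram.

    The correlation matrix includes the maximal observed mother and bud
    volumes read from each fit's data.  Requires at least two results;
    degenerate (zero-variance) columns yield NaN correlations, reported as
    missing rather than raising.
    """
    if len(retained) < 2:
        raise ValueError("need at least two fit results to summarise")
    rows = []
    for res in retained:
        row = {n: res.params[n] for n in PARAM_NAMES}
        row["chi2"] = res.chi2
        row["max_V_mother"] = float(np.nanmax(res.model.v_mother))
        row["max_V_bud"] = float(np.nanmax(res.model.v_bud))
        rows.append(row)
    table = pd.DataFrame(rows)
    quantiles = table[list(PARAM_NAMES)].quantile([0.25, 0.5, 0.75])
    corr_cols = list(PARAM_NAMES) + ["max_V_mother", "max_V_bud"]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = table[corr_cols].corr(method="pearson")
    return {
        "n": len(retained),
        "median": quantiles.loc[0.5],
        "iqr_low": quantiles.loc[0.25],
        "iqr_high": quantiles.loc[0.75],
        "correlogram": corr,
        "table": table,
    }
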