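"""Shared fixtures: reference runs and fitted synthetic cells.

The expensive artefacts (plateau run, noiseless recovery fit, noisy-cohort
fits) are session-scoped so the simulation/optimisation cost is paid once
and shared between the module tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scgm
from scgm import CellParams, ShockProtocol
from scgm.fitting import CoupledVolumeModel, FitSpec
from scgm.synthetic import CohortSpec, generate_cell, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MIN = 60.0


@pytest.fixture(scope="session")
def params() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def plateau_run(params):
    """Unperturbed growth until the radius plateau (reference conditions)."""
    return scgm.simulate(params, t_end=1.5e5, dt_out=600.0)


@pytest.fixture(scope="session")
def hyper_shock_run(params):
    """Passive response to a 240→500 mM step at 70 min."""
    protocol = ShockProtocol(240.0, ((70 * MIN, 500.0),))
    return scgm.simulate(params, protocol=protocol, t_end=150 * MIN, dt_out=5.0)


@pytest.fixture(scope="session")
def recovery_cell():
    """One noiseless mother+bud pair at cohort-median parameters."""
    spec = CohortSpec(noise_sigma=0.0, seed=1)
    rng = np.random.default_rng(1)
    truth = dict(spec.medians)
    obs, rec = generate_cell(truth, spec, rng)
    return obs, truth, rec


@pytest.fixture(scope="session")
def recovery_fit(recovery_cell):
    """Multi-start fit of the noiseless pair (shared: it is the slow part)."""
    obs, truth, _ = recovery_cell
    model = CoupledVolumeModel(obs, sigma=1.0)
    result = model.fit(FitSpec(n_starts=3, seed=0, max_nfev=80))
    return model, result, truth


@pytest.fixture(scope="session")
def q_profile(recovery_cell):
    """Profile χ² over the extensibility ratio at and above the generating
    value (the rest of the parameters re-optimised at each point)."""
    obs, truth, _ = recovery_cell
    model = CoupledVolumeModel(obs, sigma=1.0)
    phi_bud = truth["q"] * truth["phi_mother"]
    values = [truth["q"], 1e3, 1e4]
    prof = model.profile(
        "q", values, FitSpec(n_starts=1, seed=0, max_nfev=60),
        start_values={**truth, "phi_mother": phi_bud / truth["q"]},
    )
    return prof, truth


@pytest.fixture(scope="session")
def noisy_cohort_fits():
    """Six noisy synthetic cells (σ = 1 μm³) fitted end to end."""
    spec = CohortSpec(n_cells=6, noise_sigma=1.0, horizon_min=300.0, seed=7)
    cohort, truth = generate_cohort(spec)
    results = []
    for cell_id, group in cohort.groupby("cell_id"):
        model = CoupledVolumeModel(
            group.drop(columns="cell_id").reset_index(drop=True), sigma=1.0
        )
        results.append(model.fit(FitSpec(n_starts=1, seed=11, max_nfev=40)))
    return results, truth, spec
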