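"""Single-cell dynamics: flux terms, fixed point, growth, shocks, regimes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scgm
from scgm import ShockProtocol
from scgm.analytic import r_final, steady_osmolarity
from scgm.core import (
    CellState,
    classify_regime,
    initial_state,
    osmolyte_rate,
    rhs,
    turgor_rate,
    water_flux,
)
from scgm.units import MM_TO_INTERNAL

MIN = 60.0


def _state_of_radius(r, params, Pi_t, c_i, V_b=0.0):
    V_t = 4.0 / 3.0 * np.pi * r**3
    return CellState(V_os=V_t - V_b, V_b=V_b, Pi_t=Pi_t, c_i=c_i)


class TestWaterFlux:
    def test_balanced_pressures(self, params):
        c_i = steady_osmolarity(params)
        state = _state_of_radius(1.2, params, params.Pi_ct, c_i)
        assert water_flux(state, params, params.c_e) == pytest.approx(0.0, abs=1e-10)

    def test_reference_evaluation(self, params):
        # r = 1.2 μm (G = 18.10 μm²), Π_t+Π_e−Π_i ≈ +560 Pa → ≈ +1.20e-2 μm³/s
        state = _state_of_radius(1.2, params, 2.0e5, 319.17)
        J = water_flux(state, params, 240.0)
        assert state.G == pytest.approx(18.10, rel=1e-3)
        assert J == pytest.approx(1.205e-2, rel=1e-2)
        assert J > 0  # outward

    def test_concentrated_interior_drives_influx(self, params):
        state = _state_of_radius(1.2, params, 2.0e5, 2 * 319.17)
        assert water_flux(state, params, 240.0) < 0  # influx: V̇_os > 0


class TestOsmolyteRate:
    def test_zero_at_homeostatic_radius(self, params):
        # at r = 3 k_u/k_c the surface uptake balances volume consumption
        state = _state_of_radius(3.0 * params.k_ratio, params, 2.0e5, 300.0)
        assert osmolyte_rate(state, params, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_positive_below_homeostatic_radius(self, params):
        state = _state_of_radius(1.5, params, 2.0e5, 300.0)
        assert osmolyte_rate(state, params, 0.0) > 0

    def test_reference_evaluation(self, params):
        # r = 1 μm, V_b = 0, V̇ = 0 → ċ_i = 2·k_consumption = 0.4 mM/s
        state = _state_of_radius(1.0, params, 2.0e5, 300.0)
        assert osmolyte_rate(state, params, 0.0) == pytest.approx(0.4, rel=1e-9)

    def test_dilution_term(self, params):
        state = _state_of_radius(1.0, params, 2.0e5, 300.0)
        Vdot = 0.01
        expected_dilution = -state.c_i * Vdot / state.V_os
        assert osmolyte_rate(state, params, Vdot) - osmolyte_rate(
            state, params, 0.0
        ) == pytest.approx(expected_dilution, rel=1e-9)


class TestTurgorRate:
    def test_static_elastic(self, params):
        state = _state_of_radius(1.2, params, 1.5e5, 300.0)
        assert turgor_rate(state, params, 0.0) == 0.0

    def test_stress_relaxation_above_yield(self, params):
        state = _state_of_radius(1.2, params, 2.5e5, 300.0)
        rate = turgor_rate(state, params, 0.0)
        expected = -params.E * params.phi / (1 - params.nu) * 0.5e5
        assert rate == pytest.approx(expected, rel=1e-12)
        assert rate < 0

    def test_reference_evaluation(self, params):
        # r = 1.2, ṙ = 1e-4 μm/s, Π_t = Π_ct: 82.4 − 16.7 ≈ 65.8 Pa/s
        state = _state_of_radius(1.2, params, params.Pi_ct, 300.0)
        assert turgor_rate(state, params, 1e-4) == pytest.approx(65.75, rel=1e-3)


class TestRhs:
    def test_growth_fixed_point(self, params):
        """All derivatives vanish at (Π_ct, c_e + Π_ct/RT, r = 3k_u/k_c)
        when the solid volume is zero."""
        state = _state_of_radius(
            r_final(params), params, params.Pi_ct, steady_osmolarity(params)
        )
        d = rhs(0.0, state, params, ShockProtocol.constant(params.c_e))
        assert d["V_os"] == pytest.approx(0.0, abs=1e-10)
        assert d["c_i"] == pytest.approx(0.0, abs=1e-12)
        assert d["Pi_t"] == pytest.approx(0.0, abs=1e-8)

    def test_solid_volume_constant(self, params):
        state = initial_state(params)
        d = rhs(0.0, state, params, ShockProtocol.constant(params.c_e))
        assert d["V_b"] == 0.0

    def test_nonfinite_state_rejected(self, params):
        state = _state_of_radius(1.0, params, 2.0e5, 300.0)
        state.Pi_t = float("nan")
        with pytest.raises(scgm.IntegrationError):
            rhs(0.0, state, params, ShockProtocol.constant(params.c_e))


class TestUnperturbedGrowth:
    def test_radius_plateau(self, params, plateau_run):
        # r(t→∞) → 3 k_uptake/k_consumption (small offset from solid volume)
        assert plateau_run.r[-1] == pytest.approx(3.0, rel=2e-3)

    def test_plateau_exact_without_solid_volume(self, params):
        p = params.replace(r_b0=1e-6)
        traj = scgm.simulate(p, t_end=1.5e5, dt_out=1000.0)
        assert traj.r[-1] == pytest.approx(3.0, rel=1e-4)

    def test_turgor_converges_to_critical(self, plateau_run, params):
        assert plateau_run.Pi_t[-1] == pytest.approx(params.Pi_ct, rel=1e-4)

    def test_osmolarity_converges_to_steady_state(self, plateau_run, params):
        assert plateau_run.c_i[-1] == pytest.approx(steady_osmolarity(params), rel=1e-4)

    def test_radius_nondecreasing_after_transient(self, plateau_run):
        # non-decreasing up to solver noise at the plateau (~1e-8 μm)
        r = plateau_run.r[plateau_run.t > 120.0]
        assert np.all(np.diff(r) > -1e-6)

    def test_joint_rate_scaling_preserves_final_size(self, params):
        """Doubling uptake and consumption together keeps the plateau but
        doubles the speed of approach."""
        slow = scgm.simulate(params, t_end=2e5, dt_out=2000.0)
        fast = scgm.simulate(
            params.replace(k_uptake=2 * params.k_uptake, k_consumption=2 * params.k_consumption),
            t_end=2e5, dt_out=2000.0,
        )
        assert fast.r[-1] == pytest.approx(slow.r[-1], rel=1e-6)
        t_slow = slow.t[np.searchsorted(slow.r, 1.5)]
        t_fast = fast.t[np.searchsorted(fast.r, 1.5)]
        assert t_fast == pytest.approx(0.5 * t_slow, rel=0.05)

    @pytest.mark.parametrize("field", ["E", "phi", "d", "L_p"])
    @pytest.mark.parametrize("factor", [0.1, 10.0])
    def test_final_size_invariant_to_wall_and_membrane(self, params, field, factor):
        """The plateau depends only on k_uptake/k_consumption, not on wall
        mechanics or water permeability (±10× sweeps, < 0.1% change)."""
        p = params.replace(**{field: getattr(params, field) * factor})
        traj = scgm.simulate(p, t_end=2e5, dt_out=5000.0)
        assert traj.r[-1] == pytest.approx(3.00299, rel=1e-3)

    def test_osmolyte_bookkeeping(self, plateau_run, params):
        """The change in total osmolyte amount matches the integral of
        uptake − consumption (dilution only redistributes)."""
        n = plateau_run.c_i * MM_TO_INTERNAL * plateau_run.V_os
        prod = params.k_uptake * plateau_run.G - params.k_consumption * plateau_run.V_os
        lhs = n[-1] - n[0]
        rhs_ = np.trapezoid(prod, plateau_run.t)
        assert lhs == pytest.approx(rhs_, rel=5e-3)


class TestShockResponse:
    def test_rapid_volume_loss(self, hyper_shock_run):
        """A 240→500 mM step causes a volume drop completing (90%) within
        60 s of the step."""
        tr = hyper_shock_run
        i_s = np.searchsorted(tr.t, 70 * MIN)
        V_pre = tr.V_t[i_s - 1]
        window = (tr.t >= 70 * MIN) & (tr.t <= 100 * MIN)
        V_min = tr.V_t[window].min()
        V_60 = tr.V_t[np.searchsorted(tr.t, 70 * MIN + 60.0)]
        assert V_min < 0.8 * V_pre
        assert V_60 <= V_pre - 0.9 * (V_pre - V_min)

    def test_shock_is_purely_elastic(self, hyper_shock_run, params):
        """During the post-shock episode with Π_t < Π_ct the reference
        radius (accumulated plastic strain) stays exactly constant."""
        tr = hyper_shock_run
        elastic = (tr.t > 70 * MIN) & (tr.Pi_t < params.Pi_ct)
        assert elastic.sum() > 10
        r_ref = tr.r_ref[elastic]
        assert np.ptp(r_ref) == pytest.approx(0.0, abs=1e-9)

    def test_regime_flag_switches(self, hyper_shock_run):
        tr = hyper_shock_run
        i_s = np.searchsorted(tr.t, 70 * MIN)
        assert tr.regime[i_s - 1] == "EP"
        assert tr.regime[i_s + 5] == "E"

    def test_turgor_floor(self, params):
        """An extreme step (→2000 mM) drives turgor to the floor at 0 and
        the cell recovers afterwards; turgor never goes negative."""
        protocol = ShockProtocol(240.0, ((70 * MIN, 2000.0),))
        tr = scgm.simulate(params, protocol=protocol, t_end=100 * MIN, dt_out=1.0)
        assert tr.Pi_t.min() >= -1e-6
        assert tr.V_os.min() > 0
        i_s = np.searchsorted(tr.t, 70 * MIN)
        assert tr.Pi_t[i_s + 1] < 1e3  # collapsed within seconds
        assert tr.Pi_t[-1] > 1e4      # rebuilding

    def test_hypoosmotic_overshoot(self, params):
        """After full adaptation to 500 mM, a drop to 325 mM transiently
        lifts the volume above the unshocked trajectory; the excess then
        decays back toward the growth trend."""
        protocol = ShockProtocol(240.0, ((70 * MIN, 500.0), (240 * MIN, 325.0)))
        p = params.replace(r_os0=1.2)
        run = scgm.simulate(p, protocol=protocol, t_end=400 * MIN, dt_out=30.0)
        ctrl = scgm.simulate(p, t_end=400 * MIN, dt_out=30.0)
        diff = run.V_t - ctrl.V_t
        i_h = np.searchsorted(run.t, 240 * MIN)
        assert diff[i_h - 1] < 0          # still behind the control pre-step
        peak = diff[i_h:].max()
        assert peak > 1.0                 # transient overshoot above control
        assert diff[-1] < 0.5 * peak      # and it decays again


class TestReferenceRadius:
    def test_constant_without_extensibility(self, params):
        # vanishing extensibility: no plastic channel, r_ref frozen
        p = params.replace(phi=1e-30)
        tr = scgm.simulate(p, t_end=3600.0, dt_out=60.0)
        assert np.ptp(tr.r_ref) == pytest.approx(0.0, abs=1e-9)

    def test_nondecreasing(self, plateau_run):
        # up to solver noise at the plateau
        assert np.all(np.diff(plateau_run.r_ref) >= -1e-7)

    def test_tracks_growth_during_plastic_phase(self, plateau_run, params):
        """At fixed turgor = Π_ct plastic strain is the only growth channel
        beyond the elastic stretch: the strain split gives
        d ln r_ref = (1 − αr)·d ln r with α = (1−ν)Π_ct/(2dE)."""
        t = plateau_run.t
        sel = (t > 2e4) & (t < 4e4)
        r = plateau_run.r[sel]
        d_log_r = np.diff(np.log(r))
        d_log_rr = np.diff(np.log(plateau_run.r_ref[sel]))
        alpha = (1 - params.nu) * params.Pi_ct / (2 * params.d * params.E)
        r_mid = 0.5 * (r[1:] + r[:-1])
        np.testing.assert_allclose(d_log_rr, (1.0 - alpha * r_mid) * d_log_r,
                                   rtol=0.05)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "Pi_t,Pi_ct,expected",
        [(1.9e5, 2.0e5, "E"), (2.0e5, 2.0e5, "EP"), (2.1e5, 2.0e5, "EP")],
    )
    def test_threshold_convention(self, Pi_t, Pi_ct, expected):
        assert classify_regime(Pi_t, Pi_ct) == expected

    def test_growth_steady_state_is_elastoplastic(self, plateau_run):
        # sample during active growth; at the exact plateau the flag is
        # ill-conditioned (Π_t → Π_ct from above within solver noise)
        idx = np.searchsorted(plateau_run.r, 2.0)
        assert plateau_run.regime[idx] == "EP"


class TestProtocol:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "prot.yaml"
        path.write_text("- {t_min: 0, c_e_mM: 240}\n- {t_min: 70, c_e_mM: 500}\n")
        prot = ShockProtocol.from_yaml(path)
        assert prot.c_e(0.0) == 240.0
        assert prot.c_e(70 * MIN - 1e-9) == 240.0
        assert prot.c_e(70 * MIN) == 500.0  # right-continuous

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            ShockProtocol(240.0, ((100.0, 500.0), (100.0, 300.0)))
        with pytest.raises(ValueError):
            ShockProtocol(240.0, ((100.0, -5.0),))

    @given(st.floats(0, 1e5))
    def test_piecewise_constant_lookup(self, t):
        prot = ShockProtocol(240.0, ((100.0, 500.0), (200.0, 300.0)))
        expected = 240.0 if t < 100.0 else (500.0 if t < 200.0 else 300.0)
        assert prot.c_e(t) == expected


class TestTrajectoryExport:
    def test_tidy_frame_columns(self, hyper_shock_run):
        frame = hyper_shock_run.to_frame()
        assert list(frame.columns) == [
            "time_s", "V_os_um3", "V_t_um3", "r_um", "Pi_t_Pa", "c_i_mM",
            "c_e_mM", "J_w_um3_s", "r_ref_um", "regime",
        ]
        assert (frame["V_os_um3"] > 0).all()

    def test_volume_positive_everywhere(self, plateau_run, hyper_shock_run):
        assert (plateau_run.V_os > 0).all()
        assert (hyper_shock_run.V_os > 0).all()

    def test_regime_flag_consistent_with_turgor(self, hyper_shock_run, params):
        flags = hyper_shock_run.regime
        expected = np.where(hyper_shock_run.Pi_t >= params.Pi_ct, "EP", "E")
        assert (flags == expected).all()
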