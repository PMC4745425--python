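"""1D pulse-wave solver tests: tube law, wave physics, conservation,
boundary behaviour and cross-checks against the analytic oracles."""

import math

import numpy as np
import pytest

from artwave.model import SegmentedVessel, default_fluid
from artwave.pulsewave import (
    PulseWaveState,
    SolverError,
    SolverSettings,
    TubeLaw,
    advance,
    characteristic_impedance,
    junction_reflection,
    simulate,
    step,
    tube_law_for,
    wave_speed,
)
from artwave.waveform import MeanVelocitySeries, decompose
from artwave.womersley import solve_womersley

from .conftest import COMPLIANT, STIFF


class TestTubeLaw:
    def test_reference_pressure_is_external(self, geometry):
        law = tube_law_for(geometry, COMPLIANT, external_pressure=300.0)
        assert law.pressure(law.reference_area) == pytest.approx(300.0)

    def test_pressure_increases_with_area(self, geometry):
        law = tube_law_for(geometry, COMPLIANT)
        areas = np.linspace(0.5, 2.0, 50) * law.reference_area
        assert np.all(np.diff(law.pressure(areas)) > 0)

    def test_stiffness_coefficient_closed_form(self, geometry):
        law = tube_law_for(geometry, COMPLIANT)
        expected = (
            math.sqrt(math.pi) * 0.001 * 5e6
            / ((1 - 0.499**2) * geometry.lumen_area)
        )
        assert law.stiffness_coefficient == pytest.approx(expected)


class TestWaveSpeed:
    def test_compliant_segment_moens_korteweg(self, geometry, fluid):
        """c0 = sqrt(h E / (2 rho R0 (1 - nu^2))) ~ 28.1 m/s at 5 MPa."""
        law = tube_law_for(geometry, COMPLIANT)
        c = wave_speed(law, law.reference_area, fluid)
        closed = math.sqrt(
            0.001 * 5e6 / (2 * 1050.0 * 0.004 * (1 - 0.499**2))
        )
        assert c == pytest.approx(closed, rel=1e-12)
        assert c == pytest.approx(28.1, rel=0.005)

    def test_stiff_over_compliant_is_sqrt_E_ratio(self, geometry, fluid):
        cs = wave_speed(tube_law_for(geometry, STIFF),
                        geometry.lumen_area, fluid)
        cc = wave_speed(tube_law_for(geometry, COMPLIANT),
                        geometry.lumen_area, fluid)
        assert cs / cc == pytest.approx(math.sqrt(40.0), rel=1e-12)

    def test_floppy_limit(self, geometry, fluid):
        law = TubeLaw(reference_area=geometry.lumen_area,
                      stiffness_coefficient=0.0)
        assert wave_speed(law, law.reference_area, fluid) == 0.0


class TestJunctionReflection:
    def test_matched_junction_does_not_reflect(self, geometry, fluid):
        law = tube_law_for(geometry, STIFF)
        assert junction_reflection(law, law, fluid) == 0.0

    def test_stiff_into_compliant_value(self, geometry, fluid):
        """|R| = (sqrt(E1) - sqrt(E2)) / (sqrt(E1) + sqrt(E2)), negative."""
        r = junction_reflection(
            tube_law_for(geometry, STIFF), tube_law_for(geometry, COMPLIANT),
            fluid,
        )
        expected = (math.sqrt(200) - math.sqrt(5)) / (
            math.sqrt(200) + math.sqrt(5)
        )
        assert r == pytest.approx(-expected, rel=1e-9)
        assert r == pytest.approx(-0.727, abs=5e-4)

    def test_antisymmetry(self, geometry, fluid):
        a = tube_law_for(geometry, STIFF)
        b = tube_law_for(geometry, COMPLIANT)
        assert junction_reflection(a, b, fluid) == pytest.approx(
            -junction_reflection(b, a, fluid), rel=1e-12
        )

    def test_impedance_definition(self, geometry, fluid):
        law = tube_law_for(geometry, COMPLIANT)
        c0 = wave_speed(law, law.reference_area, fluid)
        assert characteristic_impedance(law, fluid) == pytest.approx(
            fluid.density * c0 / law.reference_area
        )


def _uniform_state(law, n=400, dx=5e-4, flow=None, area=None):
    x = (np.arange(n) + 0.5) * dx
    a0 = law.reference_area
    area = np.full(n, a0) if area is None else area
    flow = np.zeros(n) if flow is None else flow
    return PulseWaveState(x_grid=x, area=area, flow=flow)


class TestStep:
    def test_rest_is_a_fixed_point(self, geometry, fluid):
        """Uniform A0, Q=0, u_in=0: the state must not move at all."""
        law = tube_law_for(geometry, COMPLIANT)
        state = _uniform_state(law, n=100)
        dt = 0.5 * 5e-4 / wave_speed(law, law.reference_area, fluid)
        out = state
        for _ in range(20):
            out = step(out, law, fluid, dt, inlet_velocity=0.0)
        assert np.array_equal(out.area, state.area)
        assert np.array_equal(out.flow, state.flow)

    def test_rest_fixed_point_across_stiffness_jump(self, geometry, fluid):
        """Rest survives a 40x stiffness jump (well-balanced junction)."""
        laws = [tube_law_for(geometry, STIFF if i < 50 else COMPLIANT)
                for i in range(100)]
        state = _uniform_state(laws[0], n=100)
        c = wave_speed(laws[0], laws[0].reference_area, fluid)
        out, audit = advance(state, laws, fluid, 0.5 * 5e-4 / c, 50,
                             inlet_velocity=0.0)
        assert np.array_equal(out.area, state.area)
        assert np.array_equal(out.flow, state.flow)

    def test_gaussian_pulse_travels_at_tube_law_speed(self, geometry, fluid):
        """Centroid speed of a 1% right-going pulse within 2% of c(A0)."""
        law = tube_law_for(geometry, COMPLIANT)
        rho = fluid.density
        n, dx = 800, 5e-4
        x = (np.arange(n) + 0.5) * dx
        a0 = law.reference_area
        c0 = wave_speed(law, a0, fluid)
        area = a0 * (1 + 0.01 * np.exp(-((x - 0.08) ** 2) / (2 * 0.01**2)))
        c_loc = np.sqrt(law.stiffness_coefficient * np.sqrt(area) / (2 * rho))
        flow = area * 4.0 * (c_loc - c0)  # right-going simple wave
        state = PulseWaveState(x, area, flow)
        dt = 0.8 * dx / (1.1 * c0)
        n_steps = int(round(0.20 / c0 / dt))
        out, audit = advance(state, law, fluid, dt, n_steps)

        def centroid(s):
            w = s.area - a0
            return float(np.sum(s.x_grid * w) / np.sum(w))

        c_measured = (centroid(out) - centroid(state)) / (n_steps * dt)
        assert c_measured == pytest.approx(c0, rel=0.02)

    def test_volume_audit_closes(self, geometry, fluid, default_run):
        """Discrete volume balance <= 1e-8 relative, pulse and full runs."""
        law = tube_law_for(geometry, COMPLIANT)
        state = _uniform_state(law, n=200)
        c0 = wave_speed(law, law.reference_area, fluid)
        dt = 0.8 * 5e-4 / (1.1 * c0)
        u_in = 0.1 * np.sin(np.linspace(0, math.pi, 301)) ** 2
        out, audit = advance(state, law, fluid, dt, 300, inlet_velocity=u_in)
        assert audit["volume_residual_rel"] <= 1e-8
        assert audit["influx"] > 0
        assert default_run.diagnostics["volume_audit_rel"] <= 1e-8

    def test_cfl_violation_aborts_with_diagnostic(self, geometry, fluid):
        law = tube_law_for(geometry, STIFF)
        state = _uniform_state(law, n=100)
        c = wave_speed(law, law.reference_area, fluid)
        with pytest.raises(SolverError, match="CFL"):
            step(state, law, fluid, dt=5.0 * 5e-4 / c, inlet_velocity=0.0)

    def test_mismatched_law_count_rejected(self, geometry, fluid):
        law = tube_law_for(geometry, STIFF)
        state = _uniform_state(law, n=100)
        with pytest.raises(ValueError):
            step(state, [law] * 7, fluid, 1e-6, inlet_velocity=0.0)


class TestMeasuredReflection:
    def test_pressure_reflection_matches_linear_theory(self, geometry, fluid):
        """Reflected/incident amplitude at a 200->5 MPa junction within 5%."""
        law_s = tube_law_for(geometry, STIFF)
        law_c = tube_law_for(geometry, COMPLIANT)
        n, dx = 800, 5e-4
        x = (np.arange(n) + 0.5) * dx
        a0 = law_s.reference_area
        laws = [law_s if xi < 0.2 else law_c for xi in x]
        cs = wave_speed(law_s, a0, fluid)
        area = a0 * (1 + 1e-3 * np.exp(-((x - 0.06) ** 2) / (2 * 0.01**2)))
        beta = np.array([l.stiffness_coefficient for l in laws])
        c_loc = np.sqrt(beta * np.sqrt(area) / (2 * fluid.density))
        u = 4.0 * (c_loc - cs)
        u[x > 0.2] = 0.0
        state = PulseWaveState(x, area, area * u)
        dt = 0.8 * dx / (1.1 * cs)
        probe = int(np.argmin(np.abs(x - 0.12)))
        # incident pass, then reflection return, in two windows
        t_incident = (0.12 - 0.06) / cs + 4 * 0.01 / cs
        t_return = (0.2 - 0.06) / cs + (0.2 - 0.12) / cs
        n1 = int(t_incident / dt)
        n2 = int(1.6 * t_return / dt) - n1
        sqrt_a0 = math.sqrt(a0)

        def probe_pressure(s):
            return law_s.stiffness_coefficient * (
                math.sqrt(s.area[probe]) - sqrt_a0
            )

        p1 = []
        for _ in range(n1):
            state = step(state, laws, fluid, dt)
            p1.append(probe_pressure(state))
        p2 = []
        for _ in range(n2):
            state = step(state, laws, fluid, dt)
            p2.append(probe_pressure(state))
        p1, p2 = np.array(p1), np.array(p2)
        incident = p1[np.argmax(np.abs(p1))]
        reflected = p2[np.argmax(np.abs(p2))]
        measured = reflected / incident
        predicted = junction_reflection(law_s, law_c, fluid)
        assert measured == pytest.approx(predicted, rel=0.05)
        assert measured < 0


class TestSimulate:
    def test_zero_waveform_gives_zero_output(self, default_model, fluid):
        t = np.linspace(0.0, 1.0, 65)
        wf = MeanVelocitySeries(t, np.zeros(65))
        res = simulate(default_model, wf, fluid,
                       SolverSettings(dx=2e-3, cycles=1))
        for df in res.probes.values():
            assert np.allclose(df["pressure_Pa"], 0.0)
            assert np.allclose(df["flow_m3_per_s"], 0.0)
            assert np.allclose(df["wss_Pa"], 0.0)

    def test_steady_pressure_drop_is_poiseuille(self, steady_run, fluid):
        """Probe-to-probe drop matches 8 mu u L / R^2 within 5%."""
        tail = slice(-20, None)
        p70 = steady_run.probes[0.070]["pressure_Pa"].to_numpy()[tail].mean()
        p140 = steady_run.probes[0.140]["pressure_Pa"].to_numpy()[tail].mean()
        x = steady_run.diagnostics["probe_cell_positions_m"]
        expected = 8 * fluid.dynamic_viscosity * 0.2 / 0.004**2 * (x[2] - x[0])
        assert (p70 - p140) == pytest.approx(expected, rel=0.05)

    def test_steady_wss_is_poiseuille(self, steady_run):
        tail = slice(-20, None)
        wss = steady_run.probes[0.100]["wss_Pa"].to_numpy()[tail].mean()
        assert wss == pytest.approx(0.7, rel=0.05)

    def test_rigid_limit_wss_matches_womersley(self, rigid_run, fluid,
                                               geometry):
        """Near-rigid tube WSS vs the analytic oracle within 5%."""
        df = rigid_run.probes[0.100]
        dec = decompose(rigid_run.waveform, 12)
        field = solve_womersley(
            fluid, geometry, dec, radial_points=64,
            times=df["time_s"].to_numpy(),
        )
        scale = np.max(np.abs(field.wall_shear_stress))
        err = np.max(np.abs(df["wss_Pa"].to_numpy()
                            - field.wall_shear_stress))
        assert err <= 0.05 * scale

    def test_rigid_limit_has_no_probe_delay(self, rigid_run):
        """Flow waveforms at the probes are essentially simultaneous."""
        q70 = rigid_run.probes[0.070]["flow_m3_per_s"].to_numpy()
        q140 = rigid_run.probes[0.140]["flow_m3_per_s"].to_numpy()
        lag = np.argmax(np.correlate(
            q70 - q70.mean(), q140 - q140.mean(), mode="full",
        )) - (q70.size - 1)
        assert abs(lag) <= 1  # within one 10 ms output sample

    def test_three_cycle_convergence(self, default_run):
        """Final two cycles agree within 1% at every probe."""
        conv = default_run.diagnostics["cycle_convergence"]
        assert all(v <= 0.01 for v in conv.values())
        assert default_run.converged

    def test_grid_convergence_second_order(self, default_run, coarse_run):
        """Halving dx (and dt) changes probe pressures by < 1%."""
        for xp in (0.070, 0.100, 0.140):
            p_f = default_run.probes[xp]["pressure_Pa"].to_numpy()
            p_c = coarse_run.probes[xp]["pressure_Pa"].to_numpy()
            err = np.max(np.abs(p_f - p_c)) / np.max(np.abs(p_f))
            assert err < 0.01

    def test_compliant_probe_strains_most(self, default_run):
        """Cycle-max distension strain peaks at the 100 mm probe."""
        def strain_max(xp):
            a = default_run.probes[xp]["area_m2"].to_numpy()
            a0 = default_run.vessel.geometry.lumen_area
            return np.max((np.sqrt(a) - math.sqrt(a0)) / math.sqrt(a0))

        assert strain_max(0.100) > strain_max(0.070)
        assert strain_max(0.100) > strain_max(0.140)

    def test_output_cadence_and_length(self, default_run):
        df = default_run.probes[0.100]
        assert df["time_s"].iloc[0] == 0.0
        assert df["time_s"].iloc[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(df["time_s"]), 0.01)

    def test_single_cycle_flagged_unconverged(self, default_model, fluid):
        res = simulate(
            default_model, fluid=fluid,
            settings=SolverSettings(dx=2e-3, cycles=1),
        )
        assert not res.converged

    def test_wave_speed_diagnostics(self, default_run):
        speeds = default_run.diagnostics["wave_speeds_m_per_s"]
        assert speeds["segment_1"] == pytest.approx(28.15, abs=0.05)
        assert speeds["segment_0"] / speeds["segment_1"] == pytest.approx(
            math.sqrt(40), rel=1e-6
        )


def test_model_object_wraps_simulate(default_model, fluid):
    from artwave.pulsewave import PulseWaveModel

    model = PulseWaveModel(
        default_model, fluid=fluid,
        settings=SolverSettings(dx=2e-3, cycles=2),
    )
    res = model.run()
    assert set(res.probes) == {0.070, 0.100, 0.140}
    table = res.summary()
    assert table.shape[0] == 3
    assert (table["max_hoop_strain"] >= table["min_hoop_strain"]).all()
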