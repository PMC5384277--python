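import numpy as np
import pytest

from pharynxflow import (
    BoundaryConditions,
    FluidProps,
    NumericsConfig,
    Waveform,
    build_phantom,
    generate_grid,
    inlet_velocity,
    peak_flow_rate,
    solve_steady,
)
from pharynxflow.airway_metrics import probe_plane, slice_sweep, compute_metrics
from pharynxflow.synthetic_anatomy import uniform_tube_spec
from tests.conftest import POISEUILLE_RE, TUBE_LENGTH_MM, TUBE_RADIUS_MM


class TestWaveform:
    def test_zero_tidal(self):
        assert peak_flow_rate(0.0, 4.0, 1.0) == 0.0

    def test_printed_parameters_close_form(self):
        # 600 mL over a 2 s half-sine inspiration -> Q_peak = 150 pi mL/s
        q = peak_flow_rate(600.0, 4.0, 1.0)
        assert q == pytest.approx(150.0 * np.pi, rel=1e-12)
        assert q == pytest.approx(471.24, abs=0.01)

    def test_integral_recovers_tidal_volume(self):
        wf = Waveform(tidal_volume=600.0, period=4.0, ie_ratio=1.0)
        t = np.linspace(0.0, wf.t_insp, 20001)
        vol = np.trapezoid(wf.flow(t), t)
        assert vol == pytest.approx(600.0, rel=1e-6)

    def test_angular_frequency(self):
        wf = Waveform(tidal_volume=600.0, period=4.0, ie_ratio=1.0)
        assert wf.omega == pytest.approx(np.pi / 2.0)
        assert wf.t_insp == pytest.approx(2.0)

    def test_ie_ratio_shifts_inspiration(self):
        wf = Waveform(tidal_volume=500.0, period=3.0, ie_ratio=0.5)
        assert wf.t_insp == pytest.approx(1.0)
        t = np.linspace(0.0, wf.t_insp, 20001)
        assert np.trapezoid(wf.flow(t), t) == pytest.approx(500.0, rel=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            peak_flow_rate(600.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            Waveform(tidal_volume=-1.0)


class TestInletVelocity:
    def test_zero_flow(self):
        assert inlet_velocity(0.0, 2.0) == 0.0

    def test_unit_arithmetic(self):
        # 471.24 mL/s through 2 cm^2 -> 2.356 m/s
        assert inlet_velocity(471.24, 2.0) == pytest.approx(2.356, abs=1e-3)

    def test_halving_area_doubles_velocity(self):
        assert inlet_velocity(100.0, 1.0) == pytest.approx(2 * inlet_velocity(100.0, 2.0))

    def test_bad_area(self):
        with pytest.raises(ValueError):
            inlet_velocity(100.0, 0.0)


class TestConfigs:
    def test_underrelaxation_bounds(self):
        with pytest.raises(ValueError):
            NumericsConfig(alpha_u=0.0)
        with pytest.raises(ValueError):
            NumericsConfig(alpha_p=1.5)

    def test_scheme_names(self):
        with pytest.raises(ValueError):
            NumericsConfig(scheme="quick")

    def test_fluid_validation(self):
        with pytest.raises(ValueError):
            FluidProps(density=0.0)
        with pytest.raises(ValueError):
            FluidProps(viscosity=-1.0)

    def test_bc_validation(self):
        with pytest.raises(ValueError):
            BoundaryConditions(inlet_velocity=-1.0)
        with pytest.raises(ValueError):
            BoundaryConditions(inlet_velocity=1.0, inlet_profile="plug")


class TestPoiseuille:
    def test_hagen_poiseuille_pressure_drop(self, poiseuille_case, air):
        grid, field, v_mean = poiseuille_case
        r_m = TUBE_RADIUS_MM * 1e-3
        q = v_mean * np.pi * r_m**2
        p1, _ = probe_plane(grid, field, 180.0)
        p2, _ = probe_plane(grid, field, 280.0)
        analytic = 8.0 * air.viscosity * 0.1 * q / (np.pi * r_m**4)
        assert (p1 - p2) == pytest.approx(analytic, rel=0.03)

    def test_mass_conservation(self, poiseuille_case):
        _, field, _ = poiseuille_case
        assert field.mass_imbalance <= 1e-3

    def test_slice_flux_constant(self, poiseuille_case):
        _, field, _ = poiseuille_case
        flux = field.slice_flux()
        assert flux.max() - flux.min() <= 5e-3 * abs(flux.mean())

    def test_parabolic_profile_develops(self, poiseuille_case):
        grid, field, v_mean = poiseuille_case
        # centreline velocity approaches 2 V_mean in the developed region
        i = int(0.8 * grid.nz)
        assert field.u[i, 0] == pytest.approx(2.0 * v_mean, rel=0.03)

    def test_grid_convergence_monotone(self, tube_phantom, air):
        v_mean = POISEUILLE_RE * air.viscosity / (air.density * 2 * TUBE_RADIUS_MM * 1e-3)
        bc = BoundaryConditions(inlet_velocity=v_mean)
        r_m = TUBE_RADIUS_MM * 1e-3
        q = v_mean * np.pi * r_m**2
        analytic = 8.0 * air.viscosity * 0.1 * q / (np.pi * r_m**4)
        errs = []
        for nz, nr in ((40, 6), (80, 9), (120, 14)):
            grid = generate_grid(tube_phantom, nz=nz, nr=nr)
            field = solve_steady(grid, bc, air, NumericsConfig(max_iterations=800))
            p1, _ = probe_plane(grid, field, 180.0)
            p2, _ = probe_plane(grid, field, 280.0)
            errs.append(abs((p1 - p2) - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]


class TestSolverProperties:
    def test_determinism(self, tube_phantom, air):
        grid = generate_grid(tube_phantom, nz=40, nr=6)
        bc = BoundaryConditions(inlet_velocity=0.1)
        a = solve_steady(grid, bc, air, NumericsConfig(max_iterations=300))
        b = solve_steady(grid, bc, air, NumericsConfig(max_iterations=300))
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.p, b.p)

    def test_pressure_reference_invariance(self, tube_phantom, air):
        grid = generate_grid(tube_phantom, nz=40, nr=8)
        base = solve_steady(
            grid, BoundaryConditions(inlet_velocity=0.2), air, NumericsConfig(max_iterations=600)
        )
        shifted = solve_steady(
            grid,
            BoundaryConditions(inlet_velocity=0.2, outlet_pressure=10.0),
            air,
            NumericsConfig(max_iterations=600),
        )
        np.testing.assert_allclose(shifted.p - base.p, 10.0, atol=1e-6)
        np.testing.assert_allclose(shifted.u, base.u, atol=1e-8)

    def test_mirror_symmetry_low_re(self, mean_phantom, air):
        # mirror-image area profile with reversed flow: the interior
        # pressure drop agrees within 1% in the creeping-flow limit (Stokes
        # reversibility). A 5 mm margin excludes the plug-inflow/outflow
        # adjustment zones, whose entrance corrections do not mirror
        # because the two end areas differ.
        from pharynxflow.synthetic_anatomy import AirwayPhantom

        length = mean_phantom.length
        b1, b2 = mean_phantom.boundaries
        mirrored = AirwayPhantom(
            z=mean_phantom.z,
            radius=mean_phantom.radius[::-1].copy(),
            boundaries=(length - b2, length - b1),
        )
        margin = 5.0
        drops = []
        for ph in (mean_phantom, mirrored):
            grid = generate_grid(ph, nz=120, nr=14)
            inlet_area_cm2 = float(ph.area[-1]) * 1e-2
            bc = BoundaryConditions.from_flow(5.0, inlet_area_cm2)  # Re ~ 5
            field = solve_steady(grid, bc, air, NumericsConfig(max_iterations=2500))
            assert field.converged
            p_top, _ = probe_plane(grid, field, margin)
            p_bot, _ = probe_plane(grid, field, length - margin)
            drops.append(p_top - p_bot)
        assert drops[0] == pytest.approx(drops[1], rel=0.01)

    def test_laminar_guard_warns(self, mean_phantom):
        grid = generate_grid(mean_phantom, nz=24, nr=6)
        q = peak_flow_rate(600.0, 4.0, 1.0)
        bc = BoundaryConditions.from_flow(q, mean_phantom.spec.inlet_area)
        with pytest.warns(UserWarning, match="Reynolds"):
            solve_steady(
                grid, bc, FluidProps(), NumericsConfig(max_iterations=2, laminar_re_threshold=2300.0)
            )

    def test_reports_throat_reynolds(self, venturi_case, air):
        _, field, q = venturi_case
        # Re = rho V D / mu at the throat
        r_min = field.grid.wall_radius.min()
        v = q * 1e-6 / (np.pi * r_min**2)
        expected = air.density * v * 2 * r_min / air.viscosity
        assert field.throat_reynolds == pytest.approx(expected, rel=1e-9)


class TestVenturi:
    def test_min_pressure_at_throat(self, venturi_case, mean_phantom):
        _, field, q = venturi_case
        profs = slice_sweep(mean_phantom, field)
        z = np.array([s.z for s in profs])
        p = np.array([s.mean_pressure for s in profs])
        a = np.array([s.area for s in profs])
        z_throat = z[np.argmin(a)]
        z_pmin = z[np.argmin(p)]
        assert abs(z_pmin - z_throat) <= 6.0  # mm; min pressure at/near the throat

    def test_pressure_drop_exceeds_bernoulli(self, venturi_case, mean_phantom, air):
        # at moderate Re viscous losses dominate profile/curvature effects,
        # so the slice-mean Bernoulli estimate is a strict lower bound
        _, field, q = venturi_case
        profs = slice_sweep(mean_phantom, field)
        p = np.array([s.mean_pressure for s in profs])
        v = np.array([s.mean_velocity for s in profs])
        a = np.array([s.area for s in profs])
        i_t = int(np.argmin(a))
        bernoulli = 0.5 * air.density * (v[i_t] ** 2 - v[0] ** 2)
        assert (p[0] - p[i_t]) > bernoulli
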