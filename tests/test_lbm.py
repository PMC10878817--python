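import numpy as np
import pytest
from hypothesis import given, strategies as st

from stenoflow.errors import DivergenceError, StabilityError
from stenoflow.lattice import CS2, D2Q9
from stenoflow.lbm import (LatticeSpec, LBMState, PressureBC,
                           equilibrium_distribution, macroscopic_moments,
                           run_flow, step)
from stenoflow.metrics import peak_jet_velocity as peak_jet_velocity_helper
from stenoflow.scenario import FluidProperties, make_scenario


def _independent_equilibrium(rho, u):
    """Textbook second-order equilibrium, coded independently of the
    solver kernel (scalar loops, explicit constants)."""
    c = D2Q9.velocities.astype(float)
    w = D2Q9.weights
    out = np.empty(9)
    for i in range(9):
        cu = c[i, 0] * u[0] + c[i, 1] * u[1]
        uu = u[0] ** 2 + u[1] ** 2
        out[i] = w[i] * rho * (1 + 3 * cu + 4.5 * cu**2 - 1.5 * uu)
    return out


class TestEquilibrium:
    def test_zero_velocity_gives_weighted_density(self):
        feq = equilibrium_distribution(np.array(2.0), np.zeros(2))
        np.testing.assert_allclose(feq, 2.0 * D2Q9.weights, rtol=1e-15)

    @given(rho=st.floats(0.5, 2.0),
           ux=st.floats(-0.1, 0.1), uy=st.floats(-0.1, 0.1))
    def test_moments_recovered_exactly(self, rho, ux, uy):
        u = np.array([ux, uy])
        feq = equilibrium_distribution(np.array(rho), u)
        r, v = macroscopic_moments(feq)
        assert r == pytest.approx(rho, rel=1e-13)
        np.testing.assert_allclose(v, u, rtol=0, atol=1e-14)

    @given(rho=st.floats(0.5, 2.0),
           ux=st.floats(-0.15, 0.15), uy=st.floats(-0.15, 0.15))
    def test_matches_independent_formula(self, rho, ux, uy):
        ours = equilibrium_distribution(np.array(rho), np.array([ux, uy]))
        ref = _independent_equilibrium(rho, np.array([ux, uy]))
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_mach_limit_flagged(self):
        with pytest.raises(StabilityError):
            equilibrium_distribution(np.array(1.0), np.array([0.5, 0.0]),
                                     check_mach=True)


class TestMoments:
    def test_random_populations_match_summation_oracle(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.01, 1.0, size=(9, 5, 7))
        rho, u = macroscopic_moments(f)
        c = D2Q9.velocities
        rho_ref = sum(f[i] for i in range(9))
        ux_ref = sum(f[i] * c[i, 0] for i in range(9)) / rho_ref
        np.testing.assert_allclose(rho, rho_ref, rtol=1e-14)
        np.testing.assert_allclose(u[..., 0], ux_ref, rtol=1e-13)

    def test_all_zero_populations_error(self):
        with pytest.raises(DivergenceError):
            macroscopic_moments(np.zeros((9, 3, 3)))

    def test_nonfinite_population_named(self):
        f = equilibrium_distribution(np.ones((3, 3)), np.zeros((3, 3, 2)))
        f[2, 1, 1] = np.nan
        with pytest.raises(DivergenceError, match="non-finite"):
            macroscopic_moments(f)


class TestStep:
    def test_uniform_periodic_state_is_invariant(self):
        state = LBMState.at_rest(np.zeros((8, 8), bool), 0.9)
        f0 = state.f.copy()
        for _ in range(50):
            step(state)
        np.testing.assert_allclose(state.f, f0, rtol=1e-13, atol=1e-16)

    def test_mass_conserved_in_closed_periodic_domain(self):
        """Total density drift below 1e-10 relative over 1e4 steps."""
        state = LBMState.at_rest(np.zeros((16, 16), bool), 0.8)
        rng = np.random.default_rng(42)
        state.f *= 1.0 + 0.05 * rng.random(state.f.shape)
        m0 = state.f.sum()
        for _ in range(10_000):
            step(state)
        assert abs(state.f.sum() / m0 - 1.0) < 1e-10

    def test_poiseuille_profile_within_one_percent(self, poiseuille_33):
        ux, analytic, _, _ = poiseuille_33
        err = np.linalg.norm(ux - analytic) / np.linalg.norm(analytic)
        assert err < 0.01

    def test_grid_convergence_is_second_order(self, poiseuille_errors):
        """Error order >= 1.7 over three resolution doublings."""
        H = np.array(sorted(poiseuille_errors))
        e = np.array([poiseuille_errors[h] for h in H])
        assert np.all(np.diff(e) < 0)
        slope = np.polyfit(np.log2(H), np.log2(e), 1)[0]
        assert -slope >= 1.7

    def test_couette_linear_profile_and_wall_shear(self):
        """Moving-lid channel: linear profile; shear rate U/H within 1%."""
        H, U, tau = 16, 0.05, 0.8
        solid = np.zeros((H + 2, 4), bool)
        solid[0] = True
        solid[-1] = True
        state = LBMState.at_rest(solid, tau)
        nu = CS2 * (tau - 0.5)
        n = int(10 * H**2 / nu / np.pi**2)
        c = D2Q9.velocities
        for _ in range(n):
            step(state)
            # moving top lid: add momentum correction to the bounced
            # populations entering the top fluid row (standard
            # bounce-back with wall velocity)
            top = H  # last fluid row index
            for i in np.nonzero(c[:, 1] == -1)[0]:
                j = D2Q9.opposite[i]
                state.f[i, top, :] -= 6 * D2Q9.weights[j] * c[j, 0] * U
        _, u = state.moments()
        ux = u[1:-1, 0, 0]
        y = np.arange(H) + 0.5
        expect = U * y / H
        assert np.abs(ux - expect).max() / U < 0.01
        shear = np.gradient(ux)
        assert shear.mean() == pytest.approx(U / H, rel=0.01)

    def test_solid_cells_report_zero_velocity(self):
        sc = make_scenario("CAS_pre")
        flow = run_flow(sc, duration=0.1, output_stride=20, drive="peak_hold")
        for snap in flow.snapshots:
            assert np.all(snap.velocity[sc.geometry.occupancy] == 0.0)


class TestLatticeSpec:
    def test_relaxation_time_below_half_refused(self):
        with pytest.raises(StabilityError):
            LatticeSpec(1e-3, 1e-4, 0.5, FluidProperties())

    def test_physical_viscosity_mapping(self):
        fl = FluidProperties()
        spec = LatticeSpec.from_physical(2e-4, 0.9, fl)
        nu_lat = spec.lattice_viscosity
        assert nu_lat * spec.spacing**2 / spec.time_step == pytest.approx(
            fl.kinematic_viscosity, rel=1e-12)

    def test_time_step_roundtrip(self):
        fl = FluidProperties()
        a = LatticeSpec.from_physical(2e-4, 0.8, fl)
        b = LatticeSpec.from_time_step(a.spacing, a.time_step, fl)
        assert b.relaxation_time == pytest.approx(0.8, rel=1e-12)


class TestRunFlow:
    def test_zero_gradient_gives_zero_velocity(self):
        sc = make_scenario("CAS_pre")
        wf = sc.waveform
        zero = type(wf)(wf.times, np.zeros_like(wf.pressure_gradient),
                        wf.period, 0.0)
        sc2 = type(sc)(name="zero", geometry=sc.geometry, fluid=sc.fluid,
                       particles=sc.particles, waveform=zero,
                       measurement_planes=sc.measurement_planes,
                       rng_seed=0, gradient_scale=sc.gradient_scale)
        flow = run_flow(sc2, duration=0.8, output_stride=100,
                        warmup_periods=0)
        for snap in flow.snapshots:
            assert np.abs(snap.velocity).max() < 1e-12

    def test_open_channel_flux_matches_poiseuille(self):
        """Constant pressure difference across an unobstructed channel:
        steady volumetric flow within 1% of G H^3 W / (12 mu)."""
        from stenoflow.metrics import plane_flux
        from stenoflow.scenario import (GeometryMask, PlaneSection,
                                        ScenarioSpec, make_orifice_geometry)
        w = 4e-3
        geom = make_orifice_geometry(w, w * w, lattice_spacing=2e-4, depth=w)
        # relaxation time 0.6: fine time step, negligible compressibility
        sc = ScenarioSpec(name="open", geometry=geom,
                          fluid=FluidProperties(),
                          particles=make_scenario("CAS_pre").particles,
                          constant_pressure_pair_mmhg=(90.0, 0.0),
                          measurement_planes=[], rng_seed=0,
                          gradient_scale=1e-5, relaxation_time=0.6)
        flow = run_flow(sc, duration=4.0, output_stride=2000)
        snap = flow[-1]
        nx = geom.shape[1]
        L = (nx - 1) * geom.lattice_spacing  # between the two pressure planes
        dp = 90.0 * 133.322 * 1e-5
        G = dp / L
        mu = sc.fluid.dynamic_viscosity
        H = geom.n_across * geom.lattice_spacing
        q_expect = G * H**3 * geom.depth / (12 * mu)
        q = plane_flux(snap, PlaneSection(nx // 2, "mid"), geom)
        assert q == pytest.approx(q_expect, rel=0.01)

    def test_jet_speed_per_unit_flow_rises_as_orifice_shrinks(self):
        """The stenotic-jet mechanism is continuity: at matched flow
        rate a smaller orifice forces a faster jet, i.e. peak jet speed
        per unit volumetric flow rises strictly as the open area falls.
        (At fixed pressure drive alone the peak speed is
        area-insensitive — the Bernoulli limit — so the flux-normalised
        statement is the regime-independent one.)"""
        from stenoflow.metrics import plane_flux
        from stenoflow.scenario import (PlaneSection, ScenarioSpec,
                                        make_orifice_geometry)
        w = 5e-3
        ratios = []
        for frac in (0.6, 0.45, 0.35):
            geom = make_orifice_geometry(w, frac * w * w,
                                         lattice_spacing=2e-4, depth=w)
            sc = ScenarioSpec(name=f"o{frac}", geometry=geom,
                              fluid=FluidProperties(),
                              particles=make_scenario("CAS_pre").particles,
                              constant_pressure_pair_mmhg=(90.0, 0.0),
                              measurement_planes=[], rng_seed=0,
                              gradient_scale=1e-5)
            flow = run_flow(sc, duration=3.0, output_stride=2000)
            v = float(flow[-1].speed().max())
            q = plane_flux(flow[-1], PlaneSection(geom.shape[1] // 2, "m"),
                           geom)
            ratios.append(v / q)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_pulsatile_run_requires_full_period(self):
        sc = make_scenario("FAS_pre")
        with pytest.raises(StabilityError):
            run_flow(sc, duration=0.2, drive="waveform")

    def test_pulsatile_run_discards_warmup_and_flows_forward(self):
        """A full-cycle pulsatile run reports times relative to the end
        of the warm-up period and develops a forward systolic jet."""
        sc = make_scenario("FAS_pre")
        flow = run_flow(sc, duration=0.8, output_stride=100,
                        drive="waveform", warmup_periods=1)
        t = flow.times
        assert t[0] >= 0.0 and t[-1] <= 0.8 + 1e-9
        assert np.all(np.diff(t) > 0)
        v, t_peak, _ = peak_jet_velocity_helper(flow)
        assert v > 0
        # the peak arrives during or shortly after systole
        assert t_peak <= 0.6

    def test_healthy_preset_mild_gradient_and_wide_opening(self):
        healthy = make_scenario("healthy")
        cas = make_scenario("CAS_pre")
        assert healthy.waveform.peak_gradient < cas.waveform.peak_gradient
        assert (healthy.geometry.orifice_descriptor["slit_cells"]
                > cas.geometry.orifice_descriptor["slit_cells"])
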