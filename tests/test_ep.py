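"""Aliev-Panfilov kinetics, diffusion operator and monodomain integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiosynth import (
    Cable1D,
    EPParams,
    FiberField,
    Stimulus,
    activation_time,
    active_stress_rate,
    active_stress_tensor,
    assemble_diffusion,
    circumferential_fibers,
    conductivity_tensor,
    delay_function,
    dimensionalize_potential,
    electric_current,
    ionic_current,
    local_time_scale,
    loft_ellipses,
    recovery_rate,
    simulate_monodomain,
    stretch_current,
)
from cardiosynth.geometry import EllipseSection


class TestPointwiseKinetics:
    def test_dimensionalization_maps_rest_and_peak(self):
        assert dimensionalize_potential(0.0) == -80.0
        assert dimensionalize_potential(1.0) == 20.0
        assert dimensionalize_potential(0.5) == -30.0

    def test_activation_time_and_rescaling(self):
        p = EPParams()
        assert activation_time(80.0, 80.0, p.t_alpha) == 0.0   # apex activates first
        assert activation_time(0.0, 80.0, p.t_alpha) == p.t_alpha
        assert local_time_scale(p.t0, p) == pytest.approx(p.t_beta)
        with pytest.raises(ValueError):
            local_time_scale(1e9, p)

    def test_electric_current_nullclines_and_value(self):
        assert electric_current(0.0, 0.7) == 0.0
        assert electric_current(1.0, 0.0) == 0.0
        assert electric_current(EPParams().alpha, 0.0) == pytest.approx(0.0)
        # c phi (phi-alpha)(phi-1) at phi=0.5: 8*0.5*0.35*(-0.5) = -0.7
        assert electric_current(0.5, 0.0) == pytest.approx(-0.7)

    def test_recovery_rate_values(self):
        assert recovery_rate(0.0, 0.0) == 0.0
        assert recovery_rate(1.0, 0.0) == pytest.approx(0.002 * 8.0 * 0.15)
        assert recovery_rate(0.0, 0.5) == pytest.approx((0.002 + 0.2 * 0.5 / 0.3) * (-0.5))

    def test_stretch_current_tension_gate(self):
        p = EPParams(G_s=1.0)
        assert stretch_current(1.0, 0.3, p) == 0.0
        assert stretch_current(0.9, 0.3, p) == 0.0  # compression: channel closed
        assert stretch_current(1.1, 0.0, p) == pytest.approx(0.1 * (0.0 - 0.6))

    def test_ionic_current_scaling(self):
        p = EPParams()
        assert ionic_current(0.0, 0.0) == 0.0
        i1 = ionic_current(0.5, 0.0, beta_t=p.t_beta)
        i2 = ionic_current(0.5, 0.0, beta_t=2.0 * p.t_beta)
        assert i1 == pytest.approx(2.0 * i2)
        assert i1 == pytest.approx(p.C_m * p.beta_phi / p.t_beta * (-0.7))

    def test_delay_function_limits_and_midpoint(self):
        p = EPParams()
        assert delay_function(-1e6) == pytest.approx(p.eps0)
        assert delay_function(1e6) == pytest.approx(p.eps1)
        assert delay_function(p.Phi_t) == pytest.approx(p.eps0 + (p.eps1 - p.eps0) * np.exp(-1.0))
        # monotone increasing and bounded in [eps0, eps1]
        grid = np.linspace(-200.0, 200.0, 400)
        vals = delay_function(grid)
        assert np.all(np.diff(vals) >= 0)
        assert np.all(np.diff(delay_function(np.linspace(-25.0, 50.0, 200))) > 0)
        assert vals.min() >= p.eps0 and vals.max() <= p.eps1


class TestActiveStress:
    def test_double_fixed_point_at_rest(self):
        p = EPParams()
        assert active_stress_rate(p.Phi_r, 0.0) == 0.0
        steady = p.k_T * (20.0 - p.Phi_r)
        assert active_stress_rate(20.0, steady) == pytest.approx(0.0)

    def test_monotone_relaxation_to_steady_state(self):
        p = EPParams()
        sol = solve_ivp(
            lambda t, s: active_stress_rate(20.0, s, p), (0.0, 200.0), [0.0], max_step=0.5
        )
        s = sol.y[0]
        assert np.all(np.diff(s) >= -1e-12)
        assert s[-1] == pytest.approx(p.k_T * (20.0 - p.Phi_r), rel=1e-3)

    def test_tensor_addition_along_fibers(self):
        fibers = FiberField(
            a0=np.array([[1.0, 0, 0]]), s0=np.array([[0, 1.0, 0]]), n0=np.array([[0, 0, 1.0]])
        )
        p = EPParams(eta1=1.0, eta2=0.0, eta3=0.0)
        S = active_stress_tensor(np.zeros((3, 3)), 50.0, fibers, p)
        np.testing.assert_allclose(S, np.diag([50.0, 0.0, 0.0]))
        # eigenvalues of the added term are S_a * {eta1, eta2, eta3}
        p2 = EPParams(eta1=1.0, eta2=0.4, eta3=0.2)
        S2 = active_stress_tensor(np.zeros((3, 3)), 50.0, fibers, p2)
        np.testing.assert_allclose(sorted(np.linalg.eigvalsh(S2)), sorted([50.0, 20.0, 10.0]))
        # zero activation leaves the passive stress untouched
        passive = np.diag([1.0, 2.0, 3.0])
        np.testing.assert_allclose(active_stress_tensor(passive, 0.0, fibers, p2), passive)

    def test_non_orthonormal_fibers_rejected(self):
        with pytest.raises(ValueError, match="orthogonal|unit"):
            FiberField(
                a0=np.array([[1.0, 0, 0]]), s0=np.array([[0.5, 0.5, 0]]), n0=np.array([[0, 0, 1.0]])
            )


class TestDiffusionOperator:
    def test_element_tensor(self):
        p = EPParams(d_iso=1.0, d_ani=2.0, C_m=1.0, chi_m=1.0)
        D = conductivity_tensor(p, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(D, np.diag([3.0, 1.0, 1.0]))

    def test_symmetry_and_constant_annihilation(self):
        sections = [EllipseSection(z=z, ax=20.0 - 0.1 * z, ay=20.0 - 0.1 * z) for z in (0.0, 20.0, 40.0)]
        mesh = loft_ellipses(sections, n_theta=24)
        fibers = circumferential_fibers(mesh)
        op = assemble_diffusion(mesh, EPParams(), fibers)
        assert abs(op.K - op.K.T).max() == 0.0
        const = np.ones(mesh.n_vertices)
        assert np.abs(op.K @ const).max() < 1e-10
        # -K negative semidefinite: quadratic form non-negative
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.standard_normal(mesh.n_vertices)
            assert v @ (op.K @ v) >= -1e-10

    def test_cable_mass_conservation_pure_diffusion(self):
        cable = Cable1D(50.0, 101)
        rng = np.random.default_rng(1)
        phi0 = rng.uniform(0.0, 1.0, 101)
        op = assemble_diffusion(cable)
        res = simulate_monodomain(cable, phi0=phi0, pure_diffusion=True, T_end=20.0)
        m0 = float(op.mass @ phi0)
        m1 = float(op.mass @ res.phi[-1])
        assert abs(m1 - m0) / abs(m0) < 1e-10

    def test_fiber_field_orthonormal_on_lv_surface(self):
        sections = [EllipseSection(z=z, ax=25.0, ay=25.0) for z in (0.0, 30.0, 60.0)]
        mesh = loft_ellipses(sections, n_theta=32)
        fibers = circumferential_fibers(mesh, helix_angle=np.deg2rad(30.0))
        dots = np.einsum("ij,ij->i", fibers.a0, fibers.s0)
        assert np.abs(dots).max() < 1e-9


class TestMonodomain:
    def test_rest_state_is_stable(self):
        res = simulate_monodomain(Cable1D(20.0, 41), T_end=50.0)
        assert np.all(res.phi == 0.0)
        assert np.all(res.Phi == -80.0)
        assert np.all(res.S_a == 0.0)

    def test_stimulated_cable_activates_and_repolarizes(self):
        cable = Cable1D(30.0, 121)
        stim = Stimulus(nodes=np.flatnonzero(cable.x <= 2.0))
        res = simulate_monodomain(cable, stimulus=stim, T_end=2500.0, n_samples=26)
        # wave reaches the far end ...
        assert np.isfinite(res.activation_times[-1])
        # ... and after full repolarization the potential returns to rest
        assert np.abs(res.Phi[-1] + 80.0).max() < 2.0
        # active stress rose during the beat and decays afterwards
        assert res.S_a.max() > 1.0
        assert res.S_a[-1].max() < res.S_a.max()

    def test_trajectories_bit_identical(self):
        cable = Cable1D(30.0, 61)
        stim = Stimulus(nodes=np.array([0, 1, 2]))
        r1 = simulate_monodomain(cable, stimulus=stim, T_end=100.0)
        r2 = simulate_monodomain(cable, stimulus=stim, T_end=100.0)
        np.testing.assert_array_equal(r1.phi, r2.phi)
        np.testing.assert_array_equal(r1.S_a, r2.S_a)

    def test_unstable_dt_rejected(self):
        cable = Cable1D(30.0, 121)
        op = assemble_diffusion(cable)
        with pytest.raises(ValueError, match="stability"):
            simulate_monodomain(cable, dt=op.dt_stable * 3.0, T_end=1.0)

    def test_apex_rescaling_shortens_base_time_scale(self):
        cable = Cable1D(80.0, 41)
        res = simulate_monodomain(cable, T_end=1.0, z_coords=cable.x)
        # apex (Z = 80): t_a = 0 -> beta_t = t_beta; base (Z = 0): t_a = 40 ms
        p = EPParams()
        assert res.beta_t[-1] == pytest.approx(p.t_beta)
        assert res.beta_t[0] == pytest.approx(p.t_beta * (1 - p.tau0))
        assert np.all(np.diff(res.beta_t) > 0)
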