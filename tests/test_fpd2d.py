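"""2D fluid-particle-dynamics solver: spectral NS, profiles, colloid drag."""

import math

import numpy as np
import pytest

from netcoarse.sim_fpd2d import (FPDConfig, FPDSolver, FluidGrid,
                                 colloid_body_force, colloid_velocities,
                                 single_profiles_weights, smoothed_profile)


def make_fluid(cfg, viscosity=None):
    n = cfg.n_grid
    eta = cfg.eta_liquid if viscosity is None else viscosity
    return FluidGrid(velocity=np.zeros((2, n, n)), pressure=np.zeros((n, n)),
                     viscosity=np.full((n, n), eta), grid_spacing=cfg.grid_spacing)


def uniform_cfg(**kw):
    """Config with no viscosity contrast: the implicit step is exact."""
    kw.setdefault("viscosity_ratio", 1.0)
    kw.setdefault("n_grid", 64)
    kw.setdefault("dt", 0.002)
    return FPDConfig(**kw)


class TestConfig:
    def test_reynolds_rule_sets_lj_depth(self):
        cfg = FPDConfig()
        assert cfg.reynolds == pytest.approx(
            cfg.solvent_density * cfg.sigma ** 2 / (cfg.eta_liquid * cfg.tau_d),
            abs=1e-12)
        assert cfg.epsilon_lj == pytest.approx(3 * math.pi * 0.8, rel=1e-12)

    def test_interface_width_floor(self):
        with pytest.raises(ValueError):
            FPDConfig(interface_width=0.01)

    def test_radius_resolution_floor(self):
        with pytest.raises(ValueError):
            FPDConfig(points_per_sigma=4.0)


class TestSmoothedProfile:
    def test_value_at_center_and_interface(self):
        cfg = FPDConfig(n_grid=64)
        L = cfg.box_length
        a, xi = cfg.colloid_radius, cfg.interface_width
        phi = smoothed_profile(np.array([[L / 2, L / 2]]), a, xi,
                               cfg.n_grid, cfg.grid_spacing)
        assert phi.values.max() >= math.tanh(a / xi) * 0.999
        # phi = 1/2 exactly at |r - R| = a: check along a grid row
        x = phi.cell_centers()
        row = phi.values[:, np.argmin(np.abs(x - L / 2))]
        crossing = np.interp(0.5, row[np.argmax(row):][::-1],
                             x[np.argmax(row):][::-1])
        assert abs(abs(crossing - x[np.argmax(row)]) - a) < cfg.grid_spacing

    def test_area_integral_near_disk_area(self):
        cfg = FPDConfig(n_grid=64)
        L = cfg.box_length
        phi = smoothed_profile(np.array([[L / 2, L / 2]]), cfg.colloid_radius,
                               cfg.interface_width, cfg.n_grid, cfg.grid_spacing)
        area = phi.integral()
        expected = math.pi * cfg.colloid_radius ** 2
        assert area == pytest.approx(expected, rel=0.1)  # O(xi/a) correction

    def test_clipped_overlap(self):
        cfg = FPDConfig(n_grid=64)
        L = cfg.box_length
        two = np.array([[L / 2, L / 2], [L / 2 + 0.05, L / 2]])
        phi = smoothed_profile(two, cfg.colloid_radius, cfg.interface_width,
                               cfg.n_grid, cfg.grid_spacing)
        assert phi.values.max() <= 1.0


class TestNSStep:
    def test_rest_state_stays_at_rest(self):
        cfg = uniform_cfg()
        solver = FPDSolver(cfg)
        fluid = make_fluid(cfg)
        out = solver.ns_step(fluid, np.zeros((2, cfg.n_grid, cfg.n_grid)))
        assert np.abs(out.velocity).max() == 0.0

    def test_single_shear_mode_decays_at_viscous_rate(self):
        """One Fourier shear mode in a uniform fluid decays as
        exp(-(eta/rho) k^2 t) within 1%."""
        cfg = uniform_cfg()
        solver = FPDSolver(cfg)
        n, h, L = cfg.n_grid, cfg.grid_spacing, cfg.box_length
        x = (np.arange(n) + 0.5) * h
        k = 2 * np.pi / L * 2
        v = np.zeros((2, n, n))
        v[0] = np.sin(k * x)[None, :]  # vx(y): divergence-free
        fluid = make_fluid(cfg)
        fluid.velocity = v
        steps = 100
        for _ in range(steps):
            fluid = solver.ns_step(fluid, np.zeros((2, n, n)))
        nu = cfg.eta_liquid / cfg.solvent_density
        expected = math.exp(-nu * k * k * cfg.dt * steps)
        assert np.abs(fluid.velocity[0]).max() == pytest.approx(expected, rel=0.01)

    def test_taylor_green_decay(self):
        """Taylor-Green vortex: closed-form exponential decay within 1%."""
        cfg = uniform_cfg()
        solver = FPDSolver(cfg)
        n, h, L = cfg.n_grid, cfg.grid_spacing, cfg.box_length
        x = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(x, x, indexing="ij")
        k = 2 * np.pi / L
        amp = 1e-3  # small amplitude: nonlinear terms negligible
        v = np.stack([amp * np.cos(k * X) * np.sin(k * Y),
                      -amp * np.sin(k * X) * np.cos(k * Y)])
        fluid = make_fluid(cfg)
        fluid.velocity = v
        steps = 120
        for _ in range(steps):
            fluid = solver.ns_step(fluid, np.zeros((2, n, n)))
        nu = cfg.eta_liquid / cfg.solvent_density
        expected = amp * math.exp(-2 * nu * k * k * cfg.dt * steps)
        assert np.abs(fluid.velocity[0]).max() == pytest.approx(expected, rel=0.01)

    def test_divergence_free_after_projection(self, rng):
        cfg = FPDConfig(n_grid=64, dt=0.002)  # full viscosity contrast
        solver = FPDSolver(cfg)
        fluid = make_fluid(cfg)
        fluid.velocity = 0.01 * rng.standard_normal((2, 64, 64))
        fluid.velocity, _ = solver.project(fluid.velocity)
        out = solver.ns_step(fluid, np.zeros((2, 64, 64)))
        vmax = np.abs(out.velocity).max()
        assert out.divergence_norm() < 1e-8 * max(vmax / cfg.grid_spacing, 1.0)


class TestColloidCoupling:
    def test_no_force_quiescent_fluid_static_positions(self):
        cfg = FPDConfig(n_grid=64, dt=0.002)
        solver = FPDSolver(cfg)
        L = cfg.box_length
        pos = np.array([[L / 3, L / 2]])
        profiles, integrals = single_profiles_weights(
            pos, cfg.colloid_radius, cfg.interface_width, cfg.n_grid,
            cfg.grid_spacing)
        fluid = make_fluid(cfg)
        F = colloid_body_force(profiles, integrals, np.zeros((1, 2)), cfg.n_grid)
        fluid = solver.ns_step(fluid, F)
        V = colloid_velocities(profiles, integrals, fluid)
        assert np.abs(V).max() == 0.0

    def test_action_reaction_conserves_momentum(self):
        """Equal and opposite colloid forces: total fluid momentum stays
        zero to solver tolerance."""
        cfg = FPDConfig(n_grid=64, dt=0.002)
        solver = FPDSolver(cfg)
        L = cfg.box_length
        pos = np.array([[L / 3, L / 2], [2 * L / 3, L / 2]])
        forces = np.array([[0.4, 0.0], [-0.4, 0.0]])
        profiles, integrals = single_profiles_weights(
            pos, cfg.colloid_radius, cfg.interface_width, cfg.n_grid,
            cfg.grid_spacing)
        fluid = make_fluid(cfg)
        fluid.viscosity = (cfg.eta_liquid + (cfg.eta_colloid - cfg.eta_liquid)
                           * smoothed_profile(pos, cfg.colloid_radius,
                                              cfg.interface_width, cfg.n_grid,
                                              cfg.grid_spacing).values)
        for _ in range(40):
            F = colloid_body_force(profiles, integrals, forces, cfg.n_grid)
            fluid = solver.ns_step(fluid, F)
        p_tot = fluid.velocity.sum(axis=(1, 2)) * cfg.grid_spacing ** 2
        scale = np.abs(fluid.velocity).max() * cfg.box_length ** 2
        assert np.abs(p_tot).max() < 1e-10 * scale + 1e-14

    def test_terminal_velocity_matches_discrete_stokes_oracle(self):
        """Dragged colloid: the FPD terminal velocity agrees with an
        independent steady-Stokes solve (fixed-point iteration on the
        constant-viscosity periodic Green function) on the same grid."""
        cfg = FPDConfig(n_grid=64, dt=0.002, viscosity_ratio=5.0)
        solver = FPDSolver(cfg)
        n, h, L = cfg.n_grid, cfg.grid_spacing, cfg.box_length
        pos = np.array([[L / 2, L / 2]])
        Fext = np.array([[0.3, 0.0]])
        profiles, integrals = single_profiles_weights(
            pos, cfg.colloid_radius, cfg.interface_width, n, h)
        phi = smoothed_profile(pos, cfg.colloid_radius, cfg.interface_width,
                               n, h)
        eta = cfg.eta_liquid + (cfg.eta_colloid - cfg.eta_liquid) * phi.values
        # FPD: time-step to steady state at fixed colloid position
        fluid = make_fluid(cfg)
        fluid.viscosity = eta
        F = colloid_body_force(profiles, integrals, Fext, n)
        for _ in range(3000):
            fluid = solver.ns_step(fluid, F)
        v_fpd = colloid_velocities(profiles, integrals, fluid)[0, 0]

        # oracle: steady Stokes, under-relaxed fixed point in Fourier space
        k1 = 2 * np.pi * np.fft.fftfreq(n, d=h)
        k1[n // 2] = 0.0
        kx, ky = np.meshgrid(k1, k1, indexing="ij")
        k2 = kx ** 2 + ky ** 2
        k2s = np.where(k2 == 0, 1.0, k2)
        eta0 = 0.5 * (eta.max() + eta.min())
        de = eta - eta0

        def stokes_const(rhs):
            # solve eta0 lap v = -rhs with projection
            rx = np.fft.fft2(rhs[0])
            ry = np.fft.fft2(rhs[1])
            div = 1j * (kx * rx + ky * ry)
            rx -= kx * div / k2s * -1j * 1j  # keep explicit for clarity
            chi = div / (-k2s)
            rx = np.fft.fft2(rhs[0]) - 1j * kx * chi
            ry = np.fft.fft2(rhs[1]) - 1j * ky * chi
            vx = rx / (eta0 * k2s)
            vy = ry / (eta0 * k2s)
            vx[0, 0] = 0.0
            vy[0, 0] = 0.0
            return np.stack([np.fft.ifft2(vx).real, np.fft.ifft2(vy).real])

        def var_stress(v):
            vxh = np.fft.fft2(v[0])
            vyh = np.fft.fft2(v[1])
            dvx_dx = np.fft.ifft2(1j * kx * vxh).real
            dvx_dy = np.fft.ifft2(1j * ky * vxh).real
            dvy_dx = np.fft.ifft2(1j * kx * vyh).real
            dvy_dy = np.fft.ifft2(1j * ky * vyh).real
            sxx, sxy, syy = 2 * dvx_dx, dvx_dy + dvy_dx, 2 * dvy_dy
            tx = (np.fft.ifft2(1j * kx * np.fft.fft2(de * sxx)).real
                  + np.fft.ifft2(1j * ky * np.fft.fft2(de * sxy)).real)
            ty = (np.fft.ifft2(1j * kx * np.fft.fft2(de * sxy)).real
                  + np.fft.ifft2(1j * ky * np.fft.fft2(de * syy)).real)
            return np.stack([tx, ty])

        v = np.zeros((2, n, n))
        for _ in range(400):
            v_new = stokes_const(F + var_stress(v))
            v = 0.5 * v + 0.5 * v_new
        v_oracle = colloid_velocities(profiles, integrals,
                                      FluidGrid(v, np.zeros((n, n)), eta, h))[0, 0]
        assert v_fpd == pytest.approx(v_oracle, rel=0.05)

    def test_single_colloid_no_force_uniform_pressure(self):
        cfg = FPDConfig(n_grid=64, dt=0.002)
        solver = FPDSolver(cfg)
        L = cfg.box_length
        phi = smoothed_profile(np.array([[L / 2, L / 2]]), cfg.colloid_radius,
                               cfg.interface_width, cfg.n_grid, cfg.grid_spacing)
        fluid = make_fluid(cfg)
        fluid.viscosity = (cfg.eta_liquid
                           + (cfg.eta_colloid - cfg.eta_liquid) * phi.values)
        out = solver.ns_step(fluid, np.zeros((2, cfg.n_grid, cfg.n_grid)))
        assert np.ptp(out.pressure) < 1e-12


class TestPhaseSeparationEndToEnd:
    def test_isolated_pores_carry_distinct_pressures(self):
        """2D hydrodynamic phase separation: once the network divides the
        solvent into pores, pore-to-pore pressure differences dominate the
        within-pore variance (ratio > 1), and the hydrodynamics-starved
        2D coarsening stays slow (log-log slope well below 0.4)."""
        from netcoarse.experiments import fpd2d_experiment

        rep = fpd2d_experiment(seed=6, n_grid=96, steps=6000)
        assert rep["n_pores"] >= 2
        assert rep["pore_pressure_ratio"] > 1.0
        t = np.array(rep["times"])
        ell = np.array(rep["ell"])
        slope = np.polyfit(np.log(t[len(t) // 2:]), np.log(ell[len(t) // 2:]),
                           1)[0]
        assert abs(slope) < 0.4
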