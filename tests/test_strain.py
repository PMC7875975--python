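"""Strain fields: affine oracles, interpolation, ballistic/diffusive collapse."""

import numpy as np
import pytest

from netcoarse import strain
from netcoarse.state import ParticleState, Trajectory


def lattice_trajectory(disp_fn, L=12.0, spacing=0.75, times=(0.0, 1.0)):
    """Two-frame trajectory with displacements disp_fn(positions)."""
    n1 = int(L / spacing)
    axes = [np.arange(n1) * spacing + spacing / 2] * 3
    pos = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    N = len(pos)
    frames = []
    for i, t in enumerate(times):
        p = pos if i == 0 else pos + disp_fn(pos)
        st = ParticleState(p.copy(), np.zeros((N, 3)), np.zeros(N, np.int64),
                           L, time=t)
        frames.append(st)
    return Trajectory(frames=frames)


class TestDisplacementField:
    def test_rigid_translation_gives_constant_field(self):
        c = np.array([0.3, -0.2, 0.1])
        traj = lattice_trajectory(lambda p: np.broadcast_to(c, p.shape))
        sf = strain.displacement_field(traj, 0.0, 1.0, grid_spacing=0.5)
        for k in range(3):
            vals = sf.u[k][~sf.void]
            assert np.allclose(vals, c[k], atol=1e-12)

    def test_single_particle_constant_where_not_void(self):
        L = 10.0
        pos = np.array([[5.0, 5.0, 5.0]])
        u1 = np.array([[0.2, 0.0, -0.1]])
        frames = [ParticleState(pos, np.zeros((1, 3)), np.zeros(1, np.int64), L, 0.0),
                  ParticleState(pos + u1, np.zeros((1, 3)), np.zeros(1, np.int64), L, 1.0)]
        traj = Trajectory(frames=frames)
        sf = strain.displacement_field(traj, 0.0, 1.0, grid_spacing=0.5)
        assert not sf.void.all()
        for k in range(3):
            assert np.allclose(sf.u[k][~sf.void], u1[0, k], atol=1e-12)

    def test_linear_displacement_reproduced_with_small_bias(self):
        """u = s.(r - r_mid) on a dense lattice: kernel bias < 1e-3 rel."""
        s = 0.004
        L = 12.0
        traj = lattice_trajectory(lambda p: s * (p - L / 2), spacing=0.5)
        sf = strain.displacement_field(traj, 0.0, 1.0, grid_spacing=0.5,
                                       center_at_reference=True)
        n = sf.u.shape[1]
        x = (np.arange(n) + 0.5) * sf.grid_spacing
        # compare away from the periodic wrap discontinuity
        sel = slice(n // 4, 3 * n // 4)
        expected = s * (x - L / 2)
        got = sf.u[0][:, n // 2, n // 2]
        err = np.abs(got[sel] - expected[sel]).max()
        assert err < 1e-3 * np.abs(expected[sel]).max() + 1e-12

    def test_unwrapping_across_boundary(self):
        L = 10.0
        pos = np.array([[9.9, 5.0, 5.0]])
        frames = [ParticleState(pos.copy(), np.zeros((1, 3)), np.zeros(1, np.int64), L, 0.0),
                  ParticleState(np.array([[0.1, 5.0, 5.0]]), np.zeros((1, 3)),
                                np.zeros(1, np.int64), L, 1.0)]
        traj = Trajectory(frames=frames)
        unw = traj.unwrapped_positions()
        assert unw[1, 0, 0] == pytest.approx(10.1)


class TestStrainTensor:
    def test_rigid_translation_zero_strain(self):
        traj = lattice_trajectory(lambda p: np.broadcast_to([0.1, 0.2, 0.0], p.shape))
        sf = strain.strain_tensor(strain.displacement_field(traj, 0.0, 1.0, 0.5))
        assert np.abs(sf.eps_vol[~sf.void]).max() < 1e-10

    @staticmethod
    def _synthetic_field(u_fn, n=16, h=0.5):
        x = (np.arange(n) + 0.5) * h
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        u = np.stack(u_fn(X, Y, Z))
        return strain.StrainField(u=u, void=np.zeros((n, n, n), bool),
                                  grid_spacing=h, t0=0.0, tprime=1.0)

    def test_uniform_dilation_trace_exact(self):
        """u = s r: central differences of a linear field are exact, so
        eps = d s away from the periodic wrap rows."""
        s = 0.003
        sf = strain.strain_tensor(
            self._synthetic_field(lambda X, Y, Z: (s * X, s * Y, s * Z)))
        core = (slice(2, -2),) * 3
        np.testing.assert_allclose(sf.eps_vol[core], 3 * s, rtol=1e-6)

    def test_simple_shear_off_diagonal_exact(self):
        g = 0.004
        sf = strain.strain_tensor(
            self._synthetic_field(lambda X, Y, Z:
                                  (g * Y, np.zeros_like(Y), np.zeros_like(Z))))
        core = (slice(2, -2),) * 3
        np.testing.assert_allclose(sf.eps_tensor[0, 1][core], g / 2, rtol=1e-6)
        np.testing.assert_allclose(sf.eps_vol[core], 0.0, atol=1e-12)

    def test_dilation_through_displacement_field_pipeline(self):
        """End-to-end (particles -> kernel average -> derivatives): the
        sawtooth wrap and kernel bias limit accuracy to the percent level."""
        s = 0.003
        L = 12.0
        traj = lattice_trajectory(lambda p: s * (p - L / 2), spacing=0.5)
        sf = strain.strain_tensor(strain.displacement_field(traj, 0.0, 1.0, 0.5))
        n = sf.eps_vol.shape[0]
        core = sf.eps_vol[n // 3: 2 * n // 3, n // 3: 2 * n // 3, n // 3: 2 * n // 3]
        assert np.median(core) == pytest.approx(3 * s, rel=0.02)

    def test_symmetry_of_tensor(self):
        traj = lattice_trajectory(lambda p: 0.01 * np.sin(2 * np.pi * p / 12.0))
        sf = strain.strain_tensor(strain.displacement_field(traj, 0.0, 1.0, 0.5))
        np.testing.assert_allclose(sf.eps_tensor[0, 1], sf.eps_tensor[1, 0])


class TestPerParticleStrain:
    def test_uniform_field_constant(self):
        sf = strain.StrainField(u=np.zeros((3, 8, 8, 8)),
                                void=np.zeros((8, 8, 8), bool),
                                grid_spacing=0.5, t0=0.0, tprime=1.0,
                                eps_vol=np.full((8, 8, 8), 0.37))
        pos = np.random.default_rng(0).random((40, 3)) * 4.0
        vals = strain.per_particle_strain(sf, pos)
        assert np.allclose(vals, 0.37)

    def test_trilinear_exact_on_linear_field(self):
        n, h = 16, 0.5
        x = (np.arange(n) + 0.5) * h
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        field = 0.1 * X + 0.2 * Y - 0.05 * Z
        sf = strain.StrainField(u=np.zeros((3, n, n, n)),
                                void=np.zeros((n, n, n), bool),
                                grid_spacing=h, t0=0.0, tprime=1.0,
                                eps_vol=field)
        rng = np.random.default_rng(1)
        pos = rng.random((50, 3)) * (n - 2) * h + h  # away from the wrap
        vals = strain.per_particle_strain(sf, pos)
        expected = 0.1 * pos[:, 0] + 0.2 * pos[:, 1] - 0.05 * pos[:, 2]
        np.testing.assert_allclose(vals, expected, atol=1e-12)


class TestStrainCollapse:
    @staticmethod
    def _velocity_trajectory(motion, L=12.0, spacing=0.6,
                             times=(10.0, 10.01, 10.1, 10.2)):
        rng = np.random.default_rng(42)
        n1 = int(L / spacing)
        axes = [np.arange(n1) * spacing + spacing / 2] * 3
        pos = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        N = len(pos)
        v = 0.01 * rng.standard_normal((N, 3))
        frames = []
        for t in times:
            if motion == "ballistic":
                disp = v * (t - times[0])
            else:  # diffusive: |u| ~ sqrt(t), fixed per-particle direction
                disp = v * np.sqrt(t - times[0] + 1e-12) * 10
            st = ParticleState((pos + disp) % L, np.zeros((N, 3)),
                               np.zeros(N, np.int64), L, time=t)
            frames.append(st)
        return Trajectory(frames=frames)

    def test_ballistic_motion_collapses_exactly(self):
        """Constant velocities: eps is linear in t', so the (t'/t0)
        scaling at fixed t0 collapses to machine precision."""
        traj = self._velocity_trajectory("ballistic")
        out = strain.strain_collapse(traj, [10.0], [0.01, 0.1, 0.2],
                                     grid_spacing=0.6, dense_phase_only=False,
                                     center_at_reference=True)
        assert out["residual"] < 1e-6

    def test_diffusive_motion_fails_the_ballistic_scaling(self):
        """|u| ~ sqrt(t'): eps grows sublinearly in t', so the scaled
        distributions spread apart instead of collapsing."""
        bal = strain.strain_collapse(self._velocity_trajectory("ballistic"),
                                     [10.0], [0.01, 0.1, 0.2],
                                     grid_spacing=0.6, dense_phase_only=False,
                                     center_at_reference=True)
        dif = strain.strain_collapse(self._velocity_trajectory("diffusive"),
                                     [10.0], [0.01, 0.1, 0.2],
                                     grid_spacing=0.6, dense_phase_only=False,
                                     center_at_reference=True)
        assert dif["residual"] > 100 * max(bal["residual"], 1e-9)


class TestDistributionScaling:
    def test_scaled_form_preserves_normalization(self, rng):
        eps = rng.normal(0, 1e-3, 20000)
        d = strain.strain_distribution(eps, t0=10.0, tprime=0.1)
        x = np.linspace(-0.8, 0.8, 4001)
        scaled = d.scaled(x)
        assert np.trapezoid(scaled, x) == pytest.approx(1.0, abs=0.02)


class TestNetworkStrainCollapse:
    def test_late_stage_network_strain_collapses(self, standin_traj):
        """Aging colloid network: P(eps) at short lags t'/t0 in
        {0.001, 0.01, 0.02} for two reference times overlays onto one
        master curve under the (t'/t0) scaling — the signature of
        constant-velocity (mechanically limited) relaxation."""
        from netcoarse import strain

        t0s = standin_traj.metadata["t0s"]
        out = strain.strain_collapse(standin_traj, list(t0s),
                                     [0.001 * t0s[0], 0.01 * t0s[0],
                                      0.02 * t0s[0]],
                                     grid_spacing=0.5)
        assert out["residual"] < 0.1

    def test_strain_anticorrelates_with_density_change(self, standin_traj):
        """Volumetric strain eps = -delta(phi)/phi: where the network
        locally compacts, eps is negative, so corr(eps, -delta rho_g) > 0
        on matched grids."""
        import numpy as np
        from netcoarse import fields, strain

        t0 = standin_traj.metadata["t0s"][-1]
        tp = 0.02 * t0
        sf = strain.strain_tensor(
            strain.displacement_field(standin_traj, t0, tp, grid_spacing=0.5))
        times = standin_traj.times
        f0 = standin_traj.frames[int(np.argmin(np.abs(times - t0)))]
        f1 = standin_traj.frames[int(np.argmin(np.abs(times - (t0 + tp))))]
        g0 = fields.gaussian_density(f0, delta=1.0, grid_spacing=0.5)
        g1 = fields.gaussian_density(f1, delta=1.0, grid_spacing=0.5)
        drho = g1.values - g0.values
        mask = fields.binarize(
            fields.gaussian_density(f0, delta=0.5, grid_spacing=0.5), 0.5)
        sel = (~sf.void) & mask.values
        eps = sf.eps_vol[sel]
        target = -drho[sel]
        corr = np.corrcoef(eps, target)[0, 1]
        assert corr > 0.2
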