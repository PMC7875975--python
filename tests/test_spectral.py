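"""Structure factor, scaling collapses and growth-exponent estimation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from netcoarse import fields, spectral
from netcoarse.state import ParticleState


def cosine_field(n=64, L=16.0, mode=4, amp=0.1):
    h = L / n
    x = (np.arange(n) + 0.5) * h
    X = np.meshgrid(x, x, x, indexing="ij")[0]
    k = 2 * np.pi / L * mode
    return fields.ScalarField(1.0 + amp * np.cos(k * X), h), k


class TestStructureFactor:
    def test_single_cosine_peaks_in_one_bin(self):
        fld, k = cosine_field()
        sp = spectral.structure_factor(fld, n_particles=100)
        peak_bin = int(np.argmax(sp.s[:15]))
        assert sp.q[peak_bin] == pytest.approx(k)
        # away from the peak and q=0 the spectrum is empty
        off = np.delete(sp.s[:15], peak_bin)
        assert np.all(off < 1e-18 * sp.s[peak_bin])

    def test_ideal_gas_points_flat_near_one(self, rng):
        N, L = 150, 10.0
        st = ParticleState(rng.random((N, 3)) * L, np.zeros((N, 3)),
                           np.zeros(N, np.int64), L)
        sp = spectral.structure_factor_points(st, q_max=6.0)
        sel = np.isfinite(sp.s)
        assert sp.s[sel].mean() == pytest.approx(1.0, abs=3 / math.sqrt(sel.sum() * N))

    def test_mirror_image_has_identical_spectrum(self, rng):
        N, L = 40, 8.0
        pos = rng.random((N, 3)) * L
        st1 = ParticleState(pos, np.zeros((N, 3)), np.zeros(N, np.int64), L)
        st2 = ParticleState((L - pos) % L, np.zeros((N, 3)),
                            np.zeros(N, np.int64), L)
        f1 = fields.step_density(st1, 0.25)
        f2 = fields.step_density(st2, 0.25)
        s1 = spectral.structure_factor(f1, N)
        s2 = spectral.structure_factor(f2, N)
        np.testing.assert_allclose(s1.s, s2.s, rtol=1e-8, atol=1e-12)

    def test_parseval_against_direct_double_sum(self, rng):
        """Field S(q) summed over the reciprocal lattice equals the direct
        |rho_q|^2/N double sum over the same grid (N <= 200)."""
        N, L = 64, 6.0
        st = ParticleState(rng.random((N, 3)) * L, np.zeros((N, 3)),
                           np.zeros(N, np.int64), L)
        fld = fields.step_density(st, grid_spacing=0.25)
        rho = fld.values
        h = fld.grid_spacing
        n = rho.shape[0]
        # direct double sum for a handful of q vectors
        dq = 2 * np.pi / L
        x = (np.arange(n) + 0.5) * h
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        fft = np.fft.fftn(rho) * h ** 3
        for mvec in ([1, 0, 0], [2, 1, 0], [3, 2, 1]):
            qv = dq * np.asarray(mvec)
            direct = np.sum(rho * np.exp(-1j * (qv[0] * X + qv[1] * Y + qv[2] * Z))) * h ** 3
            # the FFT indexes cells from their corners, the direct sum from
            # cell centers: the moduli (hence S(q)) agree exactly
            assert abs(abs(fft[tuple(mvec)]) - abs(direct)) / max(abs(direct), 1.0) < 1e-8

    def test_amplitude_rescaling_leaves_qmean_invariant(self):
        fld, k = cosine_field()
        s1 = spectral.structure_factor(fld, 100)
        fld2 = fields.ScalarField(3.0 * fld.values, fld.grid_spacing)
        s2 = spectral.structure_factor(fld2, 100)
        sel = s1.s > 0
        assert (spectral.first_moment(s1.q, s1.s)
                == pytest.approx(spectral.first_moment(s2.q, s2.s), rel=1e-9))

    def test_non_cubic_grid_rejected(self):
        fld = fields.ScalarField(np.zeros((8, 16)), 0.5)
        with pytest.raises(ValueError):
            spectral.structure_factor(fld, 10)


class TestMoments:
    def test_flat_spectrum_moment_is_midpoint(self):
        q = np.linspace(1.0, 2.0, 21)
        s = np.ones_like(q)
        assert spectral.first_moment(q, s) == pytest.approx(1.5)

    def test_single_bin_spectrum(self):
        q = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        s = np.array([0.0, 0.0, 4.0, 0.0, 0.0])
        # trapezoid over the triangle centered at 1.5 is symmetric
        assert spectral.first_moment(q, s) == pytest.approx(1.5)

    def test_furukawa_moment_matches_quadrature(self):
        kappa = 4.0
        q = np.linspace(1e-3, 20.0, 40000)
        s = spectral.furukawa_form(q / 2.0, 1.0, kappa)
        got = spectral.first_moment(q, s, q.min(), q.max())
        num = quad(lambda x: x * spectral.furukawa_form(x / 2.0, 1.0, kappa),
                   q.min(), q.max(), limit=400)[0]
        den = quad(lambda x: spectral.furukawa_form(x / 2.0, 1.0, kappa),
                   q.min(), q.max(), limit=400)[0]
        assert got == pytest.approx(num / den, rel=1e-5)

    def test_empty_window_raises(self):
        q = np.linspace(1, 2, 10)
        with pytest.raises(ValueError):
            spectral.first_moment(q, np.ones_like(q), 5.0, 6.0)


class TestIntensity:
    def test_self_similar_family_gives_d_minus_1_slope(self):
        """I = int S dq with S = ell^d g(q ell) scales as ell^(d-1)."""
        d = 3
        x = np.linspace(0.05, 12.0, 4000)
        g = spectral.furukawa_form(x, 2.0, d + 1.0)
        ells = np.geomspace(2.0, 20.0, 8)
        intensities = []
        for ell in ells:
            q = x / ell
            s = ell ** d * g
            intensities.append(spectral.integrated_intensity(q, s, q.min(), q.max()))
        slope = np.polyfit(np.log(ells), np.log(intensities), 1)[0]
        assert slope == pytest.approx(d - 1, abs=0.01)

    def test_linearity_in_amplitude(self):
        q = np.linspace(0.1, 3.0, 50)
        s = np.exp(-q)
        i1 = spectral.integrated_intensity(q, s)
        i2 = spectral.integrated_intensity(q, 7.0 * s)
        assert i2 == pytest.approx(7.0 * i1)

    def test_intensity_linear_in_time_for_sqrt_coarsening(self):
        """<q> ~ t^(-1/2) self-similar family: I(t) ~ t (log-slope 1)."""
        d = 3
        x = np.linspace(0.05, 12.0, 4000)
        g = spectral.furukawa_form(x, 2.0, d + 1.0)
        times = np.geomspace(1.0, 100.0, 10)
        intensities = []
        for t in times:
            ell = 2.0 * math.sqrt(t)
            q = x / ell
            s = ell ** d * g
            intensities.append(spectral.integrated_intensity(q, s, q.min(), q.max()))
        slope = np.polyfit(np.log(times), np.log(intensities), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)


class TestFurukawa:
    def test_peak_at_x_equal_one(self):
        x = np.linspace(0.01, 5.0, 100001)
        for kappa in (3.0, 4.0):
            g = spectral.furukawa_form(x, 1.0, kappa)
            assert x[np.argmax(g)] == pytest.approx(1.0, abs=1e-3)

    def test_amplitude_recovered_exactly(self):
        q = np.linspace(0.05, 5.0, 200)
        qmean = 1.0
        d = 3
        s = spectral.furukawa_form(q / qmean, 2.0, d + 1.0)
        fit = spectral.furukawa_fit(q, s, qmean, d)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)
        assert fit.residual < 1e-10

    def test_porod_tail_exponent(self):
        d = 3
        x = np.array([50.0, 100.0])
        g = spectral.furukawa_form(x, 1.0, d + 1.0)
        slope = np.log(g[1] / g[0]) / np.log(2.0)
        assert slope == pytest.approx(-(d + 1), rel=1e-3)


class TestCollapse:
    def test_identical_rescaled_spectra_collapse_exactly(self):
        x = np.linspace(0.1, 4.0, 200)
        g = spectral.furukawa_form(x, 1.0, 4.0)
        curves = [g, g.copy(), g.copy()]
        assert spectral.collapse_residual(curves) == 0.0

    def test_self_similar_family_below_005(self, rng):
        d = 3
        x_master = np.linspace(0.01, 8.0, 2000)
        g = spectral.furukawa_form(x_master, 1.5, d + 1.0)
        series = []
        for ell in (4.0, 6.0, 9.0):
            q = x_master / ell
            s = ell ** d * g * (1 + 0.01 * rng.standard_normal(len(g)))
            series.append(spectral.Spectrum(q=q, s=s, time=ell, n_particles=1,
                                            box_length=100.0))
        ss = spectral.SpectrumSeries(series, q_min=None, q_max=None)
        assert spectral.scaling_collapse(ss, d) < 0.05

    def test_different_morphologies_have_larger_residual(self):
        x = np.linspace(0.4, 3.0, 40)
        fam1 = [spectral.furukawa_form(x, 1.0, 4.0)] * 2
        other = np.exp(-((x - 2.0) ** 2))
        other *= fam1[0].max() / other.max()
        within = spectral.collapse_residual(fam1)
        across = spectral.collapse_residual([fam1[0], other])
        assert across > within


class TestGrowthFit:
    def test_exact_power_law(self):
        t = np.geomspace(1, 300, 25)
        fit = spectral.fit_exponent(t, 2 * np.sqrt(t))
        assert fit.nu == pytest.approx(0.5, abs=1e-12)
        assert fit.stable_plateau

    def test_qmean_convention_flips_sign(self):
        t = np.geomspace(1, 300, 25)
        q = 5 * t ** -0.5
        fit = spectral.fit_exponent(t, q)
        assert fit.nu == pytest.approx(-0.5, abs=1e-12)

    def test_noisy_power_law_within_stated_error(self, rng):
        t = np.geomspace(1, 300, 30)
        nus = []
        for _ in range(20):
            q = 5 * t ** -0.5 * (1 + 0.01 * rng.standard_normal(len(t)))
            fit = spectral.fit_exponent(t, 2 * np.pi / q)
            nus.append(fit.nu)
        assert np.mean(nus) == pytest.approx(0.5, abs=0.01)

    def test_logarithmic_decay_has_no_stable_plateau(self):
        """Glassy logarithmic-like coarsening: the running exponent drifts
        and no plateau window is flagged."""
        t = np.geomspace(1, 1000, 30)
        q = 2.0 - 0.25 * np.log(t)
        fit = spectral.fit_exponent(t, 2 * np.pi / q)
        assert not fit.stable_plateau

    def test_finite_size_guard_excludes_frames(self):
        t = np.geomspace(1, 100, 20)
        ell = 2 * np.sqrt(t)
        fit = spectral.fit_exponent(t, ell, box_length=40.0)
        assert fit.guard_excluded == int((ell > 10.0).sum())

    def test_time_rescaling_shifts_intercept_only(self):
        t = np.geomspace(1, 300, 25)
        ell = 2 * t ** 0.5
        f1 = spectral.fit_exponent(t, ell)
        f2 = spectral.fit_exponent(7.0 * t, ell)
        assert f1.nu == pytest.approx(f2.nu, abs=1e-12)

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            spectral.fit_exponent(np.arange(1, 5), np.arange(1, 5.0))
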