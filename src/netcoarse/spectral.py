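"""Structure factor and dynamic-scaling analysis of coarsening patterns.

The structure factor S(q, t) = rho_q rho_-q / N is computed from the FFT of
the sharp-sphere density field (a point-particle variant exists for oracle
checks), radially averaged in bins of width 2 pi / L.  The characteristic
wavenumber <q> is the first moment of S over a configurable window, ell =
2 pi / <q> the pattern's dominant length, and I(t) the integrated intensity.
Self-similar coarsening implies <q>^d S(q,t) = g(q/<q>) with g close to the
Furukawa form A x^2 / (kappa/2 + x^(2+kappa)), kappa = d + 1, and the
growth law ell ~ t^nu with nu = 1/2 under mechanical-relaxation control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field  # noqa: F401
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .fields import ScalarField
from .state import ParticleState, Trajectory


@dataclass
class Spectrum:
    """Radially averaged structure factor of one frame."""

    q: np.ndarray
    s: np.ndarray
    time: float
    n_particles: int
    box_length: float

    def first_moment(self, q_min: Optional[float] = None,
                     q_max: Optional[float] = None) -> float:
        return first_moment(self.q, self.s, q_min, q_max)

    def integrated_intensity(self, q_min: Optional[float] = None,
                             q_max: Optional[float] = None) -> float:
        lo, hi = _window(self.q, q_min, q_max)
        sel = (self.q >= lo) & (self.q <= hi)
        return float(np.trapezoid(self.s[sel], self.q[sel]))


@dataclass
class SpectrumSeries:
    """Per-frame spectra plus derived <q>, ell and I series."""

    spectra: list
    q_min: Optional[float] = None
    q_max: Optional[float] = None

    @property
    def times(self) -> np.ndarray:
        return np.array([sp.time for sp in self.spectra])

    @property
    def qmean(self) -> np.ndarray:
        return np.array([sp.first_moment(self.q_min, self.q_max)
                         for sp in self.spectra])

    @property
    def ell(self) -> np.ndarray:
        return 2.0 * np.pi / self.qmean

    @property
    def intensity(self) -> np.ndarray:
        return np.array([sp.integrated_intensity(self.q_min, self.q_max)
                         for sp in self.spectra])


@dataclass
class FurukawaFit:
    amplitude: float
    kappa: float
    residual: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return furukawa_form(x, self.amplitude, self.kappa)


@dataclass
class GrowthFit:
    """Power-law exponent of ell(t) (or <q>(t), sign-flipped)."""

    nu: float
    nu_ci: Tuple[float, float]
    window: Tuple[float, float]
    n_used: int
    guard_excluded: int
    stable_plateau: bool
    running: Optional[np.ndarray] = None  # columns: t, local exponent
    info: dict = dataclass_field(default_factory=dict)


# ---------------------------------------------------------------------------
# structure factor


def _radial_average(power: np.ndarray, L: float) -> Tuple[np.ndarray, np.ndarray]:
    dims = power.ndim
    n = power.shape[0]
    dq = 2.0 * math.pi / L
    freqs = [np.fft.fftfreq(n, d=1.0 / n) for _ in range(dims)]
    grids = np.meshgrid(*freqs, indexing="ij")
    qmag = np.sqrt(sum(g.astype(float) ** 2 for g in grids))  # in units of dq
    bins = np.rint(qmag).astype(np.int64)
    nb = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=power.ravel(), minlength=nb)
    counts = np.bincount(bins.ravel(), minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = sums / counts
    q = np.arange(nb) * dq
    return q[1:], s[1:]  # q = 0 excluded


def structure_factor(field_or_state, n_particles: Optional[int] = None) -> Spectrum:
    """Radially averaged S(q) = |rho_q|^2 / N of a periodic field.

    Accepts a ScalarField (with meta or explicit n_particles for the
    normalization) built on a cubic grid.  The Fourier convention matches
    rho_q = integral rho(r) exp(-i q r) dr evaluated on the grid (FFT times
    cell volume), and the q bins have width 2 pi / L.
    """
    if isinstance(field_or_state, ParticleState):
        from .fields import step_density
        state = field_or_state
        fld = step_density(state)
        n_particles = state.n
    else:
        fld = field_or_state
    if n_particles is None:
        raise ValueError("n_particles required to normalize S(q)")
    shape = fld.values.shape
    if len(set(shape)) != 1:
        raise ValueError("non-cubic grids are not supported")
    h = fld.grid_spacing
    L = fld.box_length
    rho_q = np.fft.fftn(fld.values) * h ** fld.dims
    power = np.abs(rho_q) ** 2 / n_particles  # |rho_q|^2 / N
    q, s = _radial_average(power, L)
    return Spectrum(q=q, s=s, time=fld.time, n_particles=n_particles,
                    box_length=L)


def structure_factor_points(state: ParticleState, q_max: float) -> Spectrum:
    """Direct-sum point-particle S(q) = |sum_j exp(-i q R_j)|^2 / N.

    O(N * n_q); intended for oracle checks at small N.  Uses all reciprocal
    lattice vectors with 0 < |q| <= q_max.
    """
    L = state.box_length
    dq = 2.0 * math.pi / L
    mmax = int(q_max / dq)
    rng = np.arange(-mmax, mmax + 1)
    grids = np.meshgrid(*([rng] * state.dims), indexing="ij")
    mvecs = np.stack([g.ravel() for g in grids], axis=1)
    qmag2 = (mvecs ** 2).sum(axis=1)
    keep = (qmag2 > 0) & (qmag2 <= mmax ** 2)
    mvecs = mvecs[keep]
    qvecs = mvecs * dq
    phases = qvecs @ state.positions.T  # (n_q, N)
    amp = np.exp(-1j * phases).sum(axis=1)
    power = np.abs(amp) ** 2 / state.n
    bins = np.rint(np.sqrt((mvecs ** 2).sum(axis=1))).astype(np.int64)
    nb = bins.max() + 1
    sums = np.bincount(bins, weights=power, minlength=nb)
    counts = np.bincount(bins, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = sums / counts
    q = np.arange(nb) * dq
    return Spectrum(q=q[1:], s=s[1:], time=state.time, n_particles=state.n,
                    box_length=L)


# ---------------------------------------------------------------------------
# moments and intensity


def _window(q: np.ndarray, q_min: Optional[float], q_max: Optional[float]):
    lo = q[q > 0].min() if q_min is None else q_min
    hi = q.max() if q_max is None else q_max
    return lo, hi


def first_moment(q: np.ndarray, s: np.ndarray, q_min: Optional[float] = None,
                 q_max: Optional[float] = None) -> float:
    """<q> = int q S dq / int S dq (trapezoidal) over [q_min, q_max]."""
    lo, hi = _window(q, q_min, q_max)
    sel = (q >= lo) & (q <= hi) & np.isfinite(s)
    if sel.sum() < 3:
        raise ValueError("moment window contains fewer than 3 bins")
    qq, ss = q[sel], s[sel]
    denom = np.trapezoid(ss, qq)
    if denom <= 0:
        raise ValueError("empty spectrum in window")
    return float(np.trapezoid(qq * ss, qq) / denom)


def integrated_intensity(q: np.ndarray, s: np.ndarray,
                         q_min: Optional[float] = None,
                         q_max: Optional[float] = None) -> float:
    lo, hi = _window(q, q_min, q_max)
    sel = (q >= lo) & (q <= hi) & np.isfinite(s)
    return float(np.trapezoid(s[sel], q[sel]))


def spectrum_series(traj: Trajectory, sigma: float = 1.0,
                    grid_spacing: Optional[float] = None,
                    q_max: Optional[float] = None) -> SpectrumSeries:
    """Structure-factor series over trajectory frames.

    Default moment window: [2 pi / L, pi / sigma] — the upper cutoff
    excludes particle-scale correlations whose Porod tail would bias <q>.
    """
    from .fields import step_density
    spectra = []
    for f in traj.frames:
        fld = step_density(f, grid_spacing=grid_spacing, sigma=sigma)
        spectra.append(structure_factor(fld, n_particles=f.n))
    L = traj.frames[0].box_length
    return SpectrumSeries(spectra, q_min=2 * math.pi / L,
                          q_max=(math.pi / sigma if q_max is None else q_max))


# ---------------------------------------------------------------------------
# Furukawa form and collapses


def furukawa_form(x: np.ndarray, amplitude: float = 1.0,
                  kappa: float = 4.0) -> np.ndarray:
    """A x^2 / (kappa/2 + x^(2+kappa)); peaks at x = 1 for any kappa."""
    x = np.asarray(x, float)
    return amplitude * x ** 2 / (kappa / 2.0 + x ** (2.0 + kappa))


def furukawa_fit(q: np.ndarray, s: np.ndarray, qmean: float, dims: int,
                 sigma: float = 1.0) -> FurukawaFit:
    """Least-squares amplitude of the Furukawa form, kappa = d + 1 fixed.

    Fits (qmean sigma)^d S against the form in x = q / qmean; the amplitude
    is linear, so the fit is closed-form.
    """
    kappa = dims + 1.0
    x = q / qmean
    y = (qmean * sigma) ** dims * s
    sel = np.isfinite(y) & (x > 0)
    g = furukawa_form(x[sel], 1.0, kappa)
    a = float(np.dot(g, y[sel]) / np.dot(g, g))
    resid = float(np.sqrt(np.mean((y[sel] - a * g) ** 2)) / max(abs(a), 1e-300))
    return FurukawaFit(amplitude=a, kappa=kappa, residual=resid)


def scaling_collapse(series: SpectrumSeries, dims: int, sigma: float = 1.0,
                     frames: Optional[Sequence[int]] = None,
                     x_grid: Optional[np.ndarray] = None) -> float:
    """Residual of the dynamic-scaling collapse <q>^d S(q) vs q/<q>.

    All scaled spectra are interpolated to a common x grid; the residual is
    the median pairwise RMS deviation divided by the median amplitude.
    0 means a perfect collapse; self-similar families land well below 0.05.
    """
    idx = range(len(series.spectra)) if frames is None else frames
    if x_grid is None:
        x_grid = np.linspace(0.4, 3.0, 40)
    curves = []
    for i in idx:
        sp = series.spectra[i]
        qm = sp.first_moment(series.q_min, series.q_max)
        x = sp.q / qm
        y = (qm * sigma) ** dims * sp.s
        sel = np.isfinite(y)
        curves.append(np.interp(x_grid, x[sel], y[sel]))
    return collapse_residual(curves)


def collapse_residual(curves: Iterable[np.ndarray]) -> float:
    """Median pairwise RMS deviation / median amplitude of a curve family."""
    curves = [np.asarray(c, float) for c in curves]
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    devs = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            devs.append(np.sqrt(np.mean((curves[i] - curves[j]) ** 2)))
    amp = np.median([np.max(np.abs(c)) for c in curves])
    if amp == 0:
        return 0.0
    return float(np.median(devs) / amp)


# ---------------------------------------------------------------------------
# growth-exponent estimation


def running_exponent(t: np.ndarray, y: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Local log-log slope d ln y / d ln t by windowed least squares."""
    lt, ly = np.log(t), np.log(y)
    out = np.full(len(t), np.nan)
    for i in range(len(t)):
        lo, hi = max(0, i - half_window), min(len(t), i + half_window + 1)
        if hi - lo >= 3:
            out[i] = np.polyfit(lt[lo:hi], ly[lo:hi], 1)[0]
    return out


def fit_exponent(t: np.ndarray, ell: np.ndarray, box_length: Optional[float] = None,
                 guard_fraction: float = 0.25, min_frames: int = 8,
                 drift_tol: float = 0.1, plateau_decades: float = 0.8,
                 t_min: Optional[float] = None,
                 ell_min: Optional[float] = None) -> GrowthFit:
    """Growth exponent nu of ell ~ t^nu by guarded log-log least squares.

    Frames with ell > guard_fraction * L are excluded (finite-size guard),
    as are frames with ell < ell_min (initial-transient guard: until the
    pattern has coarsened well beyond its initial scale, the offset ell(0)
    depresses the log-log slope).
    The fit window is the largest contiguous run of frames whose running
    exponent stays within drift_tol of its window median; a window spanning
    at least plateau_decades decades marks a stable plateau.  Without one,
    the fit falls back to all guarded frames and stable_plateau = False
    (the signature of, e.g., logarithmic-like glassy coarsening).

    To fit <q>(t), pass ell = 2 pi / <q> (or 1 / <q>): nu flips sign only
    through the data, never through the code.
    """
    t = np.asarray(t, float)
    ell = np.asarray(ell, float)
    sel = np.isfinite(ell) & (t > 0)
    if t_min is not None:
        sel &= t >= t_min
    if ell_min is not None:
        sel &= ell >= ell_min
    guard_excluded = 0
    if box_length is not None:
        guard = ell <= guard_fraction * box_length
        guard_excluded = int((sel & ~guard).sum())
        sel &= guard
    t, ell = t[sel], ell[sel]
    if len(t) < min_frames:
        raise ValueError(f"only {len(t)} frames in window; need {min_frames}")
    run = running_exponent(t, ell)

    # largest contiguous window with bounded drift of the running exponent
    best = (0, 0)
    i = 0
    ok = np.isfinite(run)
    while i < len(t):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(t) and ok[j]:
            w = run[i:j + 1]
            if np.max(w) - np.min(w) > 2 * drift_tol:
                break
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
        i += 1
    i0, i1 = best
    span_decades = (math.log10(t[i1 - 1] / t[i0])
                    if i1 - i0 >= 2 and t[i0] > 0 else 0.0)
    stable = (i1 - i0 >= min_frames) and (span_decades >= plateau_decades)
    if stable:
        # curvature test: a quadratic fit in log-log space measures the
        # drift of the local exponent across the window; a systematic
        # drift beyond drift_tol (and beyond twice its standard error)
        # marks logarithmic-like rather than power-law growth
        u = np.log(t[i0:i1])
        w = np.log(ell[i0:i1])
        coefs, cov = np.polyfit(u, w, 2, cov=True)
        delta_u = u[-1] - u[0]
        drift = 2.0 * coefs[0] * delta_u
        drift_se = 2.0 * math.sqrt(max(cov[0, 0], 0.0)) * delta_u
        if abs(drift) > drift_tol and abs(drift) > 2.0 * drift_se:
            stable = False
    if stable:
        tw, ew = t[i0:i1], ell[i0:i1]
        window = (float(tw[0]), float(tw[-1]))
    else:
        tw, ew = t, ell
        window = (float(t[0]), float(t[-1]))
    res = stats.linregress(np.log(tw), np.log(ew))
    dof = max(len(tw) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return GrowthFit(nu=float(res.slope), nu_ci=(float(ci[0]), float(ci[1])),
                     window=window, n_used=len(tw),
                     guard_excluded=guard_excluded, stable_plateau=bool(stable),
                     running=np.column_stack([t, run]),
                     info={"r2": float(res.rvalue ** 2),
                           "span_decades": span_decades})
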