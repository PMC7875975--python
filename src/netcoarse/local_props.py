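"""Local packing and kinetic-energy statistics.

The per-particle local volume fraction is phi_vor = pi sigma^3 / (6 V_vor)
in 3D (pi sigma^2 / (4 A_vor) in 2D), with V_vor the periodic Voronoi cell
volume.  In the late stage of network-forming phase separation the dense
phase settles at the zero-pressure random packing, phi_vor ~ 0.54, which
this module extracts as the modal phi_vor of particles inside the rich
mask.  Per-particle kinetic energies K_i map the effective-temperature
heterogeneity; their spatial autocorrelation length tracks the network's
characteristic length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, Voronoi

from .fields import BinaryMask, particles_in_mask
from .state import ParticleState, Trajectory


@dataclass
class VoronoiResult:
    volumes: np.ndarray        # per-particle cell volume (area in 2D)
    phi_vor: np.ndarray
    box_length: float
    dims: int

    def histogram(self, bin_width: float = 0.01) -> Tuple[np.ndarray, np.ndarray]:
        """P(phi_vor) on fixed bins [0, 1]; values above 1 are clipped."""
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        h, _ = np.histogram(np.clip(self.phi_vor, 0, 1 - 1e-12), bins=edges,
                            density=True)
        return edges, h


def voronoi_phi(state: ParticleState, sigma: float = 1.0,
                jitter: float = 1e-9, seed: int = 0) -> VoronoiResult:
    """Periodic Voronoi tessellation volumes and phi_vor per particle.

    Periodicity is realized by tessellating with the full 3^d set of ghost
    images, so arbitrarily large cells (dilute-phase particles) are exact;
    the partition property sum V_vor = L^d holds to round-off and is
    asserted on every call.  Degenerate (co-spherical/co-planar) inputs are
    defused by a seeded 1e-9 sigma jitter.
    """
    d = state.dims
    n = state.n
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} particles for a tessellation")
    L = state.box_length
    rng = np.random.default_rng(seed)
    pos = state.positions + jitter * rng.standard_normal((n, d))
    shifts = np.array(np.meshgrid(*([[-L, 0.0, L]] * d), indexing="ij"))
    shifts = shifts.reshape(d, -1).T
    # center image first so region indices 0..n-1 are the originals
    order = np.argsort((shifts ** 2).sum(axis=1), kind="stable")
    shifts = shifts[order]
    tiled = (pos[None, :, :] + shifts[:, None, :]).reshape(-1, d)
    # ghosts beyond half a box from the boundary cannot bound a central
    # cell unless a cell spans > L/2 (the partition check below would
    # catch that); cropping them cuts the tessellation cost ~3x
    shell = 0.5 * L
    keep = np.all((tiled > -shell) & (tiled < L + shell), axis=1)
    keep[:n] = True
    tiled = tiled[keep]
    vor = Voronoi(tiled)
    vols = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell for a central particle")
        verts = vor.vertices[region]
        vols[i] = ConvexHull(verts).volume
    total = vols.sum()
    if not math.isclose(total, L ** d, rel_tol=1e-8):
        raise RuntimeError(f"Voronoi cells sum to {total}, box volume {L ** d}")
    if d == 3:
        phi = math.pi * sigma ** 3 / (6.0 * vols)
    else:
        phi = math.pi * sigma ** 2 / (4.0 * vols)
    return VoronoiResult(volumes=vols, phi_vor=phi, box_length=L, dims=d)


def half_sample_mode(values: np.ndarray) -> float:
    """Robust mode by the half-sample method (recursive shortest half)."""
    x = np.sort(np.asarray(values, float))
    while len(x) > 3:
        m = (len(x) + 1) // 2
        widths = x[m - 1:] - x[: len(x) - m + 1]
        i = int(np.argmin(widths))
        x = x[i: i + m]
    return float(np.mean(x))


def distribution_peak(values: np.ndarray, bin_width: float = 0.01,
                      smooth_bins: float = 1.5,
                      prominence_frac: float = 0.08) -> float:
    """Location of the rightmost prominent peak of a [0, 1] distribution.

    Histogram on fixed 0.01 bins, lightly smoothed; peaks below
    prominence_frac of the maximum are ignored.  Falls back to the global
    maximum bin when no interior peak exists (e.g. a delta-like spike).
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    h, _ = np.histogram(np.clip(values, 0, 1 - 1e-12), bins=edges)
    hs = gaussian_filter1d(h.astype(float), smooth_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = find_peaks(hs, prominence=prominence_frac * hs.max())
    if len(peaks) == 0:
        return float(centers[int(np.argmax(hs))])
    return float(centers[peaks[-1]])


def dense_phase_mode(result: VoronoiResult, mask: BinaryMask,
                     positions: np.ndarray) -> Tuple[float, float]:
    """Modal phi_vor of the dense phase: rightmost peak of P(phi_vor)
    restricted to particles inside the rich mask.

    In a thin-stranded network, particles on strand surfaces have Voronoi
    cells leaking into the pores, adding a broad low-phi_vor component to
    P(phi_vor); the dense-phase packing shows up as the sharp high-phi
    peak (near the zero-pressure packing ~0.54 in the late stage), so the
    estimator locates the rightmost prominent peak rather than the global
    mode.  Returns (mode, halfwidth) with halfwidth the half-width of the
    central 68% interval of the phi_vor values within +-0.1 of the peak.
    """
    inside = particles_in_mask(mask, positions)
    if not inside.any():
        raise ValueError("no particles inside the rich mask")
    phi = result.phi_vor[inside]
    mode = distribution_peak(phi)
    near = phi[np.abs(phi - mode) <= 0.1]
    if len(near) >= 4:
        lo, hi = np.percentile(near, [16, 84])
        halfwidth = float((hi - lo) / 2)
    else:
        halfwidth = float("nan")
    return mode, halfwidth


# ---------------------------------------------------------------------------
# kinetic-energy maps


def kinetic_energy_map(traj: Trajectory, t: float, window: float = 1.0,
                       grid_spacing: float = 1.0, kernel_sigma: float = 1.0
                       ) -> dict:
    """Per-particle K_i plus the correlation length of the K field.

    K_i comes from the windowed velocity average; the field is the
    Gaussian-kernel average of K_i on a grid, and the correlation length is
    the e-folding distance of its radial autocorrelation (fluctuations
    about the mean), quantifying how far effective-temperature
    heterogeneity extends.
    """
    from .sim_particles import kinetic_energy_per_particle
    from .strain import _kernel_average

    ki = kinetic_energy_per_particle(traj, t, window=window)
    times = traj.times
    frame = traj.frames[int(np.argmin(np.abs(times - t)))]
    L = frame.box_length
    n = int(round(L / grid_spacing))
    h = L / n
    d = frame.dims
    usum, wsum = _kernel_average(np.ascontiguousarray(frame.positions),
                                 np.ascontiguousarray(ki[:, None] * np.ones((1, d))),
                                 L, h, n, kernel_sigma,
                                 min(4.0 * kernel_sigma, L / 2), d)
    if d == 2:
        usum, wsum = usum[..., 0], wsum[..., 0]
    valid = wsum > 1e-3 * wsum.mean()
    kfield = np.where(valid, usum[0] / np.where(wsum > 0, wsum, 1.0), np.nan)
    corr_len = field_correlation_length(np.where(valid, kfield, np.nanmean(kfield)), h)
    return {"K": ki, "field": kfield, "grid_spacing": h,
            "correlation_length": corr_len, "valid": valid}


def field_correlation_length(values: np.ndarray, grid_spacing: float) -> float:
    """e-folding length of the radial autocorrelation of a periodic field."""
    f = values - values.mean()
    power = np.abs(np.fft.fftn(f)) ** 2
    corr = np.fft.ifftn(power).real
    corr /= corr.flat[0]
    n = values.shape[0]
    dims = values.ndim
    idx = [np.minimum(np.arange(n), n - np.arange(n)) for _ in range(dims)]
    grids = np.meshgrid(*idx, indexing="ij")
    r = np.sqrt(sum(g.astype(float) ** 2 for g in grids)) * grid_spacing
    rbins = np.arange(0, r.max() + grid_spacing, grid_spacing)
    which = np.digitize(r.ravel(), rbins)
    prof = np.bincount(which, weights=corr.ravel()) / np.maximum(
        np.bincount(which), 1)
    rs = 0.5 * (rbins[:-1] + rbins[1:])
    prof = prof[1:len(rbins)]
    below = np.where(prof < math.exp(-1.0))[0]
    if len(below) == 0:
        return float(rs[-1])
    i = below[0]
    if i == 0:
        return float(rs[0])
    # linear interpolation to the 1/e crossing
    x0, x1, y0, y1 = rs[i - 1], rs[i], prof[i - 1], prof[i]
    return float(x0 + (math.exp(-1.0) - y0) * (x1 - x0) / (y1 - y0))
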