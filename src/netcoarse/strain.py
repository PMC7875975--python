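"""Coarse-grained displacement and strain fields from particle trajectories.

The displacement of particle i between a reference time t0 and t0 + t' is
u_i = R_i(t0 + t') - R_i(t0) with positions unwrapped across the periodic
boundary.  The field is the Gaussian-kernel weighted average

    u(r) = sum_i u_i G(r - R_i) / sum_i G(r - R_i),
    G(r) = exp(-r^2 / sigma^2) / (sqrt(pi) sigma)^d,

with the kernel centered at the later-time positions R_i(t0 + t') (a flag
moves it to the reference time).  Grid points with sum_i G below a floor
(10^-3 of the bulk mean) are void and excluded.  The linear strain tensor
eps_ab = (du_a/dr_b + du_b/dr_a) / 2 follows by central differences, and
the volumetric strain eps = tr(eps) is the quantity whose distribution
P(eps; t0, t') collapses as (t'/t0) P vs t0 eps / t' when the dense phase
deforms elastically at constant velocity over short lags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .fields import binarize, gaussian_density
from .state import Trajectory


@dataclass
class StrainField:
    """Displacement/strain fields on a uniform grid; void-aware."""

    u: np.ndarray               # (d, n, n[, n]) displacement components
    void: np.ndarray            # boolean, True where kernel weight below floor
    grid_spacing: float
    t0: float
    tprime: float
    eps_tensor: Optional[np.ndarray] = None   # (d, d, ...) symmetric
    eps_vol: Optional[np.ndarray] = None      # trace

    @property
    def dims(self) -> int:
        return self.u.shape[0]


@dataclass
class StrainDistribution:
    """P(eps) histogram at one (t0, t')."""

    t0: float
    tprime: float
    bin_edges: np.ndarray
    density: np.ndarray
    n: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def scaled(self, x_grid: np.ndarray) -> np.ndarray:
        """(t'/t0) P interpolated on x = t0 eps / t'."""
        r = self.tprime / self.t0
        return np.interp(x_grid, self.bin_centers / r, self.density * r,
                         left=0.0, right=0.0)


@njit(cache=True, fastmath=True)
def _kernel_average(pos, disp, L, h, n, sigma, cut, dims):
    """Accumulate sum_i u_i G and sum_i G on the grid (truncated kernel)."""
    inv_s2 = 1.0 / (sigma * sigma)
    m = int(cut / h) + 1
    c2 = cut * cut
    if dims == 3:
        wsum = np.zeros((n, n, n))
        usum = np.zeros((3, n, n, n))
    else:
        wsum = np.zeros((n, n, 1))
        usum = np.zeros((2, n, n, 1))
    for p in range(pos.shape[0]):
        cx = int(pos[p, 0] / h)
        cy = int(pos[p, 1] / h)
        cz = int(pos[p, 2] / h) if dims == 3 else 0
        zmax = cz + m if dims == 3 else 0
        zmin = cz - m if dims == 3 else 0
        for ax in range(cx - m, cx + m + 1):
            x = (ax + 0.5) * h - pos[p, 0]
            ia = ax % n
            for ay in range(cy - m, cy + m + 1):
                y = (ay + 0.5) * h - pos[p, 1]
                ib = ay % n
                xy2 = x * x + y * y
                if xy2 > c2:
                    continue
                for az in range(zmin, zmax + 1):
                    if dims == 3:
                        z = (az + 0.5) * h - pos[p, 2]
                        r2 = xy2 + z * z
                        ic = az % n
                    else:
                        r2 = xy2
                        ic = 0
                    if r2 <= c2:
                        g = np.exp(-r2 * inv_s2)
                        wsum[ia, ib, ic] += g
                        for k in range(dims):
                            usum[k, ia, ib, ic] += g * disp[p, k]
    return usum, wsum


def displacement_field(traj: Trajectory, t0: float, tprime: float,
                       grid_spacing: float = 0.5, sigma: float = 1.0,
                       center_at_reference: bool = False,
                       void_floor: float = 1e-3) -> StrainField:
    """Coarse-grained displacement field between frames t0 and t0 + t'.

    Displacements are unwrapped by accumulated minimum image across the
    intervening frames.  Raises ValueError if every grid point is void.
    """
    times = traj.times
    i0 = int(np.argmin(np.abs(times - t0)))
    i1 = int(np.argmin(np.abs(times - (t0 + tprime))))
    if i0 == i1:
        raise ValueError("t0 and t0 + t' select the same frame")
    unwrapped = traj.unwrapped_positions()
    disp = unwrapped[i1] - unwrapped[i0]
    anchor = traj.frames[i0 if center_at_reference else i1].positions
    L = traj.frames[0].box_length
    n = int(round(L / grid_spacing))
    h = L / n
    dims = traj.frames[0].dims
    usum, wsum = _kernel_average(np.ascontiguousarray(anchor),
                                 np.ascontiguousarray(disp), L, h, n, sigma,
                                 min(4.0 * sigma, L / 2), dims)
    if dims == 2:
        usum, wsum = usum[..., 0], wsum[..., 0]
    void = wsum < void_floor * wsum.mean()
    if void.all():
        raise ValueError("all grid points are void (no particles near grid)")
    u = np.where(void[None], 0.0, usum / np.where(wsum > 0, wsum, 1.0))
    return StrainField(u=u, void=void, grid_spacing=h,
                       t0=float(times[i0]), tprime=float(times[i1] - times[i0]))


def strain_tensor(sf: StrainField) -> StrainField:
    """Symmetric strain tensor and volumetric strain by central differences.

    Differences touching a void cell fall back one-sided; cells with no
    valid neighbor on an axis are marked void.
    """
    u = sf.u
    d = sf.dims
    h = sf.grid_spacing
    grads = np.empty((d, d) + u.shape[1:])
    valid = ~sf.void
    extra_void = np.zeros_like(sf.void)
    for a in range(d):
        for b in range(d):
            fwd = np.roll(u[a], -1, axis=b)
            bwd = np.roll(u[a], 1, axis=b)
            vf = np.roll(valid, -1, axis=b)
            vb = np.roll(valid, 1, axis=b)
            both = vf & vb
            only_f = vf & ~vb
            only_b = vb & ~vf
            g = np.zeros_like(u[a])
            g[both] = (fwd[both] - bwd[both]) / (2 * h)
            g[only_f] = (fwd[only_f] - u[a][only_f]) / h
            g[only_b] = (u[a][only_b] - bwd[only_b]) / h
            extra_void |= valid & ~(vf | vb)
            grads[a, b] = g
    eps = 0.5 * (grads + np.swapaxes(grads, 0, 1))
    vol = np.einsum("aa...->...", eps)
    out = StrainField(u=sf.u, void=sf.void | extra_void, grid_spacing=h,
                      t0=sf.t0, tprime=sf.tprime, eps_tensor=eps, eps_vol=vol)
    return out


def per_particle_strain(sf: StrainField, positions: np.ndarray) -> np.ndarray:
    """Volumetric strain interpolated (tri/bi-linearly) at particle positions."""
    if sf.eps_vol is None:
        raise ValueError("run strain_tensor first")
    vals = sf.eps_vol
    n = vals.shape[0]
    h = sf.grid_spacing
    d = sf.dims
    # cell-centered grid: value at ((i + 0.5) h); fractional index
    f = positions[:, :d] / h - 0.5
    i0 = np.floor(f).astype(np.int64)
    w = f - i0
    out = np.zeros(len(positions))
    for corner in range(2 ** d):
        idx = []
        weight = np.ones(len(positions))
        for axis in range(d):
            bit = (corner >> axis) & 1
            idx.append((i0[:, axis] + bit) % n)
            weight *= w[:, axis] if bit else (1.0 - w[:, axis])
        out += weight * vals[tuple(idx)]
    return out


def strain_distribution(eps_values: np.ndarray, t0: float, tprime: float,
                        bins: int = 80,
                        range_sigmas: float = 5.0) -> StrainDistribution:
    """Normalized histogram of volumetric strain values."""
    eps_values = np.asarray(eps_values, float)
    eps_values = eps_values[np.isfinite(eps_values)]
    spread = max(np.std(eps_values), 1e-12)
    lo = eps_values.mean() - range_sigmas * spread
    hi = eps_values.mean() + range_sigmas * spread
    density, edges = np.histogram(eps_values, bins=bins, range=(lo, hi),
                                  density=True)
    return StrainDistribution(t0=t0, tprime=tprime, bin_edges=edges,
                              density=density, n=len(eps_values))


def strain_collapse(traj: Trajectory, t0_list: Sequence[float],
                    tprime_list: Sequence[float], grid_spacing: float = 0.5,
                    sigma: float = 1.0, delta: float = 1.0, rho_th: float = 0.5,
                    dense_phase_only: bool = True,
                    center_at_reference: bool = False,
                    x_grid: Optional[np.ndarray] = None) -> dict:
    """P(eps) for all (t0, t') pairs and the (t'/t0)-scaling residual.

    Distributions are taken over non-void grid points, restricted to the
    dense phase (rich mask at t0) by default.  The scaled overlay is
    (t'/t0) P vs t0 eps / t'; exact collapse means eps ∝ t' at fixed t0
    (constant-velocity, mechanically controlled deformation).
    """
    dists = []
    for t0 in t0_list:
        mask = None
        if dense_phase_only:
            f0 = traj.frames[int(np.argmin(np.abs(traj.times - t0)))]
            mask = binarize(gaussian_density(f0, delta, grid_spacing))
        for tp in tprime_list:
            sf = strain_tensor(displacement_field(
                traj, t0, tp, grid_spacing, sigma,
                center_at_reference=center_at_reference))
            sel = ~sf.void
            if mask is not None:
                sel &= mask.values
            dists.append(strain_distribution(sf.eps_vol[sel], sf.t0, sf.tprime))
    if x_grid is None:
        spans = [np.abs(d.bin_centers / (d.tprime / d.t0)).max() for d in dists]
        lim = np.median(spans)
        x_grid = np.linspace(-lim, lim, 101)
    curves = [d.scaled(x_grid) for d in dists]
    from .spectral import collapse_residual
    return {"distributions": dists, "residual": collapse_residual(curves),
            "x_grid": x_grid, "curves": np.array(curves)}
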