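"""2D fluid-particle dynamics (FPD) for colloidal phase separation.

Colloids are represented as smooth high-viscosity regions of an
incompressible Navier-Stokes solvent on a periodic grid:

    rho (dv/dt + v . grad v) = -grad p + div[eta(r) (grad v + grad v^T)] + F,
    div v = 0,

with the viscosity field eta(r) = eta_l + (eta_c - eta_l) phi(r) built from
tanh colloid profiles phi_i = {tanh[(a - |r - R_i|)/xi] + 1}/2.  Colloids
move with the local fluid average V_i = int phi_i v / int phi_i, and their
LJ interactions enter the fluid as smooth body forces.  Thermal noise is
absent (deep-quench limit); the LJ depth is set from the Reynolds-number
rule Re = rho sigma^2 / (eta tau_d) = 0.8.

Time stepping: explicit advection and variable-viscosity stress about the
mid viscosity eta0 = (eta_max + eta_min)/2, implicit spectral treatment of
eta0 and of the pressure projection.  With the mid-viscosity split the
frozen-coefficient amplification factor is below one for any viscosity
ratio, so dt is limited by advection and colloid displacement only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .fields import ScalarField
from .state import ParticleState, Trajectory


@dataclass
class FPDConfig:
    """Grid, colloid and solvent parameters of the 2D FPD solver."""

    n_grid: int = 128
    points_per_sigma: float = 8.0
    colloid_radius: float = 0.5       # a = sigma / 2
    interface_width: Optional[float] = None   # xi; default = grid spacing
    viscosity_ratio: float = 50.0
    eta_liquid: float = 1.0
    solvent_density: float = 1.0
    reynolds: float = 0.8
    epsilon_lj: Optional[float] = None  # default from the Re rule
    dt: float = 0.005
    rc: float = 2.5

    def __post_init__(self):
        if self.interface_width is None:
            self.interface_width = self.grid_spacing
        if self.epsilon_lj is None:
            self.epsilon_lj = (3.0 * math.pi * self.eta_liquid ** 2
                               * self.sigma * self.reynolds
                               / self.solvent_density)
        if self.interface_width < self.grid_spacing - 1e-12:
            raise ValueError("interface width must be at least one grid cell")
        if self.colloid_radius < 3 * self.grid_spacing:
            raise ValueError("colloid radius must span at least 3 grid cells")
        re = (self.solvent_density * self.sigma ** 2
              / (self.eta_liquid * self.tau_d))
        if abs(re - self.reynolds) > 1e-9:
            raise ValueError(f"Re={re} inconsistent with configured {self.reynolds}")

    @property
    def sigma(self) -> float:
        return 2.0 * self.colloid_radius

    @property
    def grid_spacing(self) -> float:
        return self.sigma / self.points_per_sigma

    @property
    def box_length(self) -> float:
        return self.n_grid * self.grid_spacing

    @property
    def eta_colloid(self) -> float:
        return self.eta_liquid * self.viscosity_ratio

    @property
    def tau_d(self) -> float:
        return (3.0 * math.pi * self.eta_liquid * self.sigma ** 3
                / self.epsilon_lj)


@dataclass
class FluidGrid:
    """Velocity, pressure and viscosity fields of the solvent."""

    velocity: np.ndarray       # (2, n, n)
    pressure: np.ndarray       # (n, n)
    viscosity: np.ndarray      # (n, n)
    grid_spacing: float

    def divergence_norm(self) -> float:
        n = self.velocity.shape[1]
        k1 = 2.0 * np.pi * np.fft.fftfreq(n, d=self.grid_spacing)
        if n % 2 == 0:
            k1[n // 2] = 0.0  # Nyquist carries no odd derivative
        kx, ky = np.meshgrid(k1, k1, indexing="ij")
        div = (np.fft.ifft2(1j * kx * np.fft.fft2(self.velocity[0]))
               + np.fft.ifft2(1j * ky * np.fft.fft2(self.velocity[1]))).real
        return float(np.max(np.abs(div)))


def smoothed_profile(positions: np.ndarray, a: float, xi: float,
                     n_grid: int, grid_spacing: float) -> ScalarField:
    """Sum of tanh colloid profiles, clipped to [0, 1].

    phi_i(r) = {tanh[(a - |r - R_i|)/xi] + 1}/2; each colloid carries area
    ~ pi a^2 up to O(xi/a) interface corrections.
    """
    n = n_grid
    h = grid_spacing
    L = n * h
    phi = np.zeros((n, n))
    cut = a + 6.0 * xi
    m = int(cut / h) + 1
    centers = (np.arange(n) + 0.5) * h
    for p in range(len(positions)):
        cx = int(positions[p, 0] / h)
        cy = int(positions[p, 1] / h)
        ax = np.arange(cx - m, cx + m + 1)
        ay = np.arange(cy - m, cy + m + 1)
        x = (ax + 0.5) * h - positions[p, 0]
        y = (ay + 0.5) * h - positions[p, 1]
        r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
        patch = 0.5 * (np.tanh((a - r) / xi) + 1.0)
        ia = ax % n
        ib = ay % n
        np.add.at(phi, (ia[:, None], ib[None, :]), patch)
    np.clip(phi, 0.0, 1.0, out=phi)
    return ScalarField(phi, h, meta={"kind": "smoothed_profile", "a": a, "xi": xi})


def single_profiles_weights(positions: np.ndarray, a: float, xi: float,
                            n_grid: int, grid_spacing: float):
    """Per-colloid profile patches used for velocity averages and forces.

    Returns a list of (index_x, index_y, patch) with patch the unclipped
    phi_i on its local stencil, plus each colloid's integral int phi_i dr.
    """
    n = n_grid
    h = grid_spacing
    cut = a + 6.0 * xi
    m = int(cut / h) + 1
    out = []
    integrals = np.empty(len(positions))
    for p in range(len(positions)):
        cx = int(positions[p, 0] / h)
        cy = int(positions[p, 1] / h)
        ax = np.arange(cx - m, cx + m + 1)
        ay = np.arange(cy - m, cy + m + 1)
        x = (ax + 0.5) * h - positions[p, 0]
        y = (ay + 0.5) * h - positions[p, 1]
        r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
        patch = 0.5 * (np.tanh((a - r) / xi) + 1.0)
        out.append((ax % n, ay % n, patch))
        integrals[p] = patch.sum() * h * h
    return out, integrals


class FPDSolver:
    """Semi-implicit spectral solver for the 2D FPD equations."""

    def __init__(self, config: FPDConfig):
        self.config = config
        n = config.n_grid
        h = config.grid_spacing
        k1 = 2.0 * np.pi * np.fft.fftfreq(n, d=h)
        # full |k|^2 for the (even, dissipative) implicit operator; for odd
        # derivative operators the Nyquist mode must be zeroed to keep real
        # fields real (its coefficient has no Hermitian partner)
        kd = k1.copy()
        if n % 2 == 0:
            kd[n // 2] = 0.0
        self.kx, self.ky = np.meshgrid(kd, kd, indexing="ij")
        kxf, kyf = np.meshgrid(k1, k1, indexing="ij")
        self.k2 = kxf ** 2 + kyf ** 2
        k2d = self.kx ** 2 + self.ky ** 2
        self.k2_safe = np.where(k2d == 0, 1.0, k2d)
        self.eta0 = 0.5 * (config.eta_colloid + config.eta_liquid)

    def _ddx(self, fhat, axis):
        k = self.kx if axis == 0 else self.ky
        return np.fft.ifft2(1j * k * fhat).real

    def project(self, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Leray projection; returns (solenoidal v, pressure-like potential).

        The potential chi satisfies grad chi = v - P v; the physical
        pressure of one step is rho * chi / dt.
        """
        vx_hat = np.fft.fft2(v[0])
        vy_hat = np.fft.fft2(v[1])
        div_hat = 1j * (self.kx * vx_hat + self.ky * vy_hat)
        chi_hat = div_hat / (-self.k2_safe)
        chi_hat[0, 0] = 0.0
        vx_hat = vx_hat - 1j * self.kx * chi_hat
        vy_hat = vy_hat - 1j * self.ky * chi_hat
        return (np.stack([np.fft.ifft2(vx_hat).real,
                          np.fft.ifft2(vy_hat).real]),
                np.fft.ifft2(chi_hat).real)

    def ns_step(self, fluid: FluidGrid, body_force: np.ndarray,
                div_tol: float = 1e-8) -> FluidGrid:
        """Advance one dt; raises RuntimeError if projection leaves residual
        divergence above div_tol (relative to max velocity / h)."""
        cfg = self.config
        rho = cfg.solvent_density
        dt = cfg.dt
        v = fluid.velocity
        eta = fluid.viscosity
        vx_hat = np.fft.fft2(v[0])
        vy_hat = np.fft.fft2(v[1])

        # velocity gradients (spectral)
        dvx_dx = self._ddx(vx_hat, 0)
        dvx_dy = self._ddx(vx_hat, 1)
        dvy_dx = self._ddx(vy_hat, 0)
        dvy_dy = self._ddx(vy_hat, 1)

        # advection
        adv_x = -(v[0] * dvx_dx + v[1] * dvx_dy)
        adv_y = -(v[0] * dvy_dx + v[1] * dvy_dy)

        # variable-viscosity stress about eta0: div[(eta - eta0) S]
        de = eta - self.eta0
        sxx = 2.0 * dvx_dx
        sxy = dvx_dy + dvy_dx
        syy = 2.0 * dvy_dy
        tx = (self._ddx(np.fft.fft2(de * sxx), 0)
              + self._ddx(np.fft.fft2(de * sxy), 1))
        ty = (self._ddx(np.fft.fft2(de * sxy), 0)
              + self._ddx(np.fft.fft2(de * syy), 1))

        # a net body force in a periodic box is balanced by a mean pressure
        # gradient (otherwise the k = 0 mode accelerates without bound)
        fx = body_force[0] - body_force[0].mean()
        fy = body_force[1] - body_force[1].mean()
        rhs_x = v[0] + dt * (adv_x + (tx + fx) / rho)
        rhs_y = v[1] + dt * (adv_y + (ty + fy) / rho)

        # implicit mid viscosity
        denom = 1.0 + dt * (self.eta0 / rho) * self.k2
        vx_new = np.fft.ifft2(np.fft.fft2(rhs_x) / denom).real
        vy_new = np.fft.ifft2(np.fft.fft2(rhs_y) / denom).real

        v_new, chi = self.project(np.stack([vx_new, vy_new]))
        pressure = rho * chi / dt
        out = FluidGrid(velocity=v_new, pressure=pressure, viscosity=eta,
                        grid_spacing=fluid.grid_spacing)
        vmax = np.max(np.abs(v_new)) + 1e-300
        if out.divergence_norm() > div_tol * max(vmax / fluid.grid_spacing, 1.0):
            raise RuntimeError("projection failed: residual divergence")
        return out


def colloid_body_force(profiles, integrals, forces, n_grid) -> np.ndarray:
    """Body force density F(r) = sum_i F_i phi_i(r) / int phi_i dr."""
    F = np.zeros((2, n_grid, n_grid))
    for (ia, ib, patch), Ii, fi in zip(profiles, integrals, forces):
        w = patch / Ii
        np.add.at(F[0], (ia[:, None], ib[None, :]), fi[0] * w)
        np.add.at(F[1], (ia[:, None], ib[None, :]), fi[1] * w)
    return F


def colloid_velocities(profiles, integrals, fluid: FluidGrid) -> np.ndarray:
    """V_i = int phi_i v dr / int phi_i dr."""
    h2 = fluid.grid_spacing ** 2
    out = np.empty((len(profiles), 2))
    for p, ((ia, ib, patch), Ii) in enumerate(zip(profiles, integrals)):
        vx = fluid.velocity[0][ia[:, None], ib[None, :]]
        vy = fluid.velocity[1][ia[:, None], ib[None, :]]
        out[p, 0] = (patch * vx).sum() * h2 / Ii
        out[p, 1] = (patch * vy).sum() * h2 / Ii
    return out


def lj_colloid_forces(positions: np.ndarray, L: float, epsilon: float,
                      rc: float) -> Tuple[np.ndarray, float]:
    """Pairwise LJ forces between colloid centers (sigma = 2a = 1 unit)."""
    pos = np.ascontiguousarray(positions)
    pi, pj = _kernels.build_pairs(pos, L, rc + 0.3)
    f = np.zeros_like(pos)
    species = np.zeros(len(pos), np.int64)
    eps_table = np.array([[epsilon]])
    epot, _ = _kernels.lj_forces(pos, L, pi, pj, species, eps_table, rc, f)
    return f, epot


def run_fpd_phase_separation(config: FPDConfig, phi_area: float, steps: int,
                             seed: int = 0,
                             sample_every: Optional[int] = None,
                             max_disp_factor: float = 1.0) -> Tuple[Trajectory, list]:
    """Phase separation of a 2D colloidal suspension with hydrodynamics.

    Colloids start from RSA placement (the only use of the seed); the fluid
    starts at rest.  Returns the colloid trajectory and the list of
    per-frame solvent pressure ScalarFields.  Raises RuntimeError if any
    colloid moves more than max_disp_factor grid cells in one step.
    """
    n = config.n_grid
    h = config.grid_spacing
    L = config.box_length
    sigma = config.sigma
    n_coll = int(round(phi_area * L ** 2 / (math.pi * config.colloid_radius ** 2)))
    pos, got = _kernels.rsa_insert(L / sigma, 2, n_coll, 0.9, 4000 * n_coll,
                                   seed % (2 ** 31))
    if got < n_coll:
        raise RuntimeError(f"RSA placed only {got}/{n_coll} colloids")
    pos = np.ascontiguousarray(pos[:, :2]) * sigma

    solver = FPDSolver(config)
    fluid = FluidGrid(velocity=np.zeros((2, n, n)), pressure=np.zeros((n, n)),
                      viscosity=np.full((n, n), config.eta_liquid),
                      grid_spacing=h)
    if sample_every is None:
        sample_every = max(1, steps // 20)
    frames = []
    pressure_frames = []
    thermo = []
    a, xi = config.colloid_radius, config.interface_width
    for step in range(steps):
        profiles, integrals = single_profiles_weights(pos, a, xi, n, h)
        # total profile assembled from the same per-colloid patches
        phi_vals = np.zeros((n, n))
        for ia, ib, patch in profiles:
            np.add.at(phi_vals, (ia[:, None], ib[None, :]), patch)
        np.clip(phi_vals, 0.0, 1.0, out=phi_vals)
        fluid.viscosity = (config.eta_liquid
                           + (config.eta_colloid - config.eta_liquid) * phi_vals)
        # LJ forces act between centers, in units where sigma is the LJ length
        forces, epot = lj_colloid_forces(pos / sigma, L / sigma,
                                         config.epsilon_lj, config.rc)
        forces /= sigma  # d/dR = (1/sigma) d/d(R/sigma)
        F = colloid_body_force(profiles, integrals, forces, n)
        fluid = solver.ns_step(fluid, F)
        vel = colloid_velocities(profiles, integrals, fluid)
        disp = vel * config.dt
        if np.max(np.abs(disp)) > max_disp_factor * h:
            raise RuntimeError(
                f"colloid displacement {np.max(np.abs(disp)):.3g} exceeds a "
                f"grid cell at step {step}; reduce dt")
        pos = (pos + disp) % L
        if (step + 1) % sample_every == 0 or step == steps - 1:
            t = (step + 1) * config.dt
            frames.append(ParticleState(pos.copy() / sigma,
                                        vel.copy() * config.tau_d / sigma,
                                        np.zeros(len(pos), np.int64), L / sigma,
                                        time=t / config.tau_d))
            pf = ScalarField(fluid.pressure.copy(), h, time=t / config.tau_d,
                             meta={"kind": "solvent_pressure"})
            pressure_frames.append(pf)
            thermo.append([t / config.tau_d, 0.0, epot, float(np.abs(fluid.velocity).max())])
    traj = Trajectory(frames=frames, thermo=np.array(thermo))
    traj.metadata.update(config=config.__dict__.copy(), phi_area=phi_area,
                         seed=seed, units="sigma, tau_d")
    return traj, pressure_frames
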