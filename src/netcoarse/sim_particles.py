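"""Particle simulators for phase-separating LJ systems.

Four dynamics share the numba pair kernels:

* NVT molecular dynamics (Nose-Hoover chain) for the one-component fluid and
  the symmetric binary mixture, with an instantaneous-quench protocol;
* NVE molecular dynamics (thermostat off);
* zero-temperature overdamped colloid dynamics, dR/dt = F/(3 pi eta sigma),
  a non-hydrodynamic stand-in used for desk-scale 3D colloid morphology;
* FIRE energy minimization at fixed density, with the virial pressure of the
  minimized packing.

Everything is in reduced units (sigma = m = k_B = 1); the binary mixture
enters via a species-pair well-depth table.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .state import ParticleState, QuenchProtocol, Trajectory

_ONE = np.array([[1.0]])

HARD_FLOOR = 1e-6  # pair separations below this (in sigma) are rejected


class OverlapError(ValueError):
    """Raised for pathological, effectively overlapping configurations."""


class EquilibrationError(RuntimeError):
    """Raised when a prepared liquid misses its temperature band."""


class IntegratorError(RuntimeError):
    """Raised on NaN coordinates / diverging temperature."""


def lj_pair(r: float, depth: float = 1.0, sigma: float = 1.0,
            rc: Optional[float] = 2.5) -> Tuple[float, float, float]:
    """Energy, force magnitude and virial of a single LJ pair.

    Energy is cut-and-shifted at rc (rc=None -> untruncated).  The force
    magnitude is -dU/dr of the unshifted potential (positive = repulsive);
    the virial contribution is r * f(r).
    """
    if r <= HARD_FLOOR * sigma:
        raise OverlapError(f"pair distance {r} below hard floor")
    if rc is not None and r >= rc * sigma:
        return 0.0, 0.0, 0.0
    sr6 = (sigma / r) ** 6
    u = 4.0 * depth * (sr6 * sr6 - sr6)
    if rc is not None:
        src6 = (1.0 / rc) ** 6
        u -= 4.0 * depth * (src6 * src6 - src6)
    f = 24.0 * depth * (2.0 * sr6 * sr6 - sr6) / r
    return u, f, r * f


def compute_forces(state: ParticleState, eps_table: Optional[np.ndarray] = None,
                   rc: float = 2.5, skin: float = 0.3):
    """Forces, potential energy and pair virial of a configuration."""
    eps_table = _ONE if eps_table is None else np.asarray(eps_table, float)
    pos = state.positions
    pi, pj = _kernels.build_pairs(pos, state.box_length, rc + skin)
    if pi.shape[0] and _kernels.min_pair_distance(pos, state.box_length, pi, pj) < HARD_FLOOR:
        raise OverlapError("overlapping configuration")
    forces = np.zeros_like(pos)
    epot, virial = _kernels.lj_forces(pos, state.box_length, pi, pj,
                                      state.species, eps_table, rc, forces)
    return forces, epot, virial


def virial_pressure(state: ParticleState, epot_virial: Optional[Tuple[float, float]] = None,
                    eps_table: Optional[np.ndarray] = None, rc: float = 2.5,
                    kinetic: bool = True) -> float:
    """P = (N k_B T_kin + W/d) / V with W the pair virial sum_ij r.f."""
    d = state.dims
    V = state.box_length ** d
    if epot_virial is None:
        _, _, w = compute_forces(state, eps_table, rc)
    else:
        w = epot_virial[1]
    nkt = float(np.sum(state.velocities ** 2)) if kinetic else 0.0
    return (nkt / d + w / d) / V


# ---------------------------------------------------------------------------
# initial conditions


def lattice_positions(n: int, L: float, dims: int, rng: np.random.Generator) -> np.ndarray:
    """Simple-cubic (square) lattice of >= n sites, n of them kept at random."""
    per_side = int(math.ceil(n ** (1.0 / dims)))
    axes = [np.arange(per_side) * (L / per_side)] * dims
    grids = np.meshgrid(*axes, indexing="ij")
    sites = np.stack([g.ravel() for g in grids], axis=1)
    keep = rng.choice(sites.shape[0], size=n, replace=False)
    return sites[np.sort(keep)] + 0.5 * L / per_side


def fcc_positions(n_cells: int, L: float) -> np.ndarray:
    """FCC lattice with 4 * n_cells^3 particles in a cubic box of side L."""
    a = L / n_cells
    base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    cells = np.arange(n_cells)
    gx, gy, gz = np.meshgrid(cells, cells, cells, indexing="ij")
    origins = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    pos = (origins[:, None, :] + base[None, :, :]).reshape(-1, 3) * a
    return pos + 0.25 * a


def maxwell_velocities(n: int, dims: int, T: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(0.0, math.sqrt(T), size=(n, dims))
    v -= v.mean(axis=0)
    # rescale to the exact target kinetic temperature
    nfree = n * dims - dims
    k2 = float(np.sum(v ** 2))
    if k2 > 0:
        v *= math.sqrt(nfree * T / k2)
    return v


def random_nonoverlapping(n: int, L: float, dims: int, rmin: float = 0.85,
                          seed: int = 0) -> np.ndarray:
    """Random sequential addition with minimum separation rmin (in sigma)."""
    pos, got = _kernels.rsa_insert(L, dims, n, rmin, 2000 * n, seed % (2 ** 31))
    if got < n:
        raise RuntimeError(f"RSA placed only {got}/{n} particles at rmin={rmin}")
    return np.ascontiguousarray(pos)


# ---------------------------------------------------------------------------
# MD driver


def _check_finite(state: ParticleState, step: int, dt: float) -> None:
    if not np.all(np.isfinite(state.positions)) or not np.all(np.isfinite(state.velocities)):
        raise IntegratorError(f"NaN coordinates at step {step} (dt={dt})")


def _run_md(state: ParticleState, eps_table: np.ndarray, dt: float, nsteps: int,
            sample_times: Sequence[float], rc: float, skin: float,
            thermostat: bool, T_target: float, tdamp: float,
            chain: Optional[np.ndarray] = None,
            thermo_every: int = 50) -> Tuple[Trajectory, np.ndarray]:
    """Integrate nsteps from state, saving frames at the requested times.

    sample_times are offsets from state.time, snapped to whole steps.
    """
    chain = np.zeros(6) if chain is None else chain
    t0 = state.time
    save_steps = sorted({int(round(ts / dt)) for ts in sample_times if ts > 0})
    save_steps = [s for s in save_steps if s <= nsteps]
    frames = []
    thermo_rows = []
    done = 0
    for target in save_steps + ([nsteps] if (not save_steps or save_steps[-1] != nsteps) else []):
        chunk = target - done
        if chunk > 0:
            th, epot, virial = _kernels.md_chunk(
                state.positions, state.velocities, state.species, eps_table,
                state.box_length, rc, skin, dt, chunk,
                1 if thermostat else 0, T_target, tdamp, chain,
                max(1, min(thermo_every, chunk)))
            th = th.copy()
            th[:, 0] = t0 + (done + th[:, 0]) * dt
            thermo_rows.append(th)
            done = target
        state.time = t0 + done * dt
        _check_finite(state, done, dt)
        if target in save_steps:
            frames.append(state.copy())
    thermo = np.vstack(thermo_rows) if thermo_rows else np.zeros((0, 4))
    # convert raw (t, K, Epot, W) -> (t, T_kin, E_pot, P)
    N, d = state.positions.shape
    nfree = N * d - d
    V = state.box_length ** d
    out = np.column_stack([
        thermo[:, 0],
        2.0 * thermo[:, 1] / nfree,
        thermo[:, 2],
        (2.0 * thermo[:, 1] / d + thermo[:, 3] / d) / V,
    ]) if thermo.size else thermo
    traj = Trajectory(frames=frames, thermo=out)
    return traj, chain


def prepare_equilibrium_liquid(protocol: QuenchProtocol,
                               temperature_band: float = 0.03) -> ParticleState:
    """Equilibrate a liquid at (rho, T_init) with the NH-chain thermostat.

    Starts from a diluted lattice with Maxwell velocities and zero total
    momentum; raises EquilibrationError if the mean kinetic temperature over
    the final quarter of the run misses T_init by more than temperature_band
    (relative).
    """
    rng = np.random.default_rng(protocol.seed)
    L = protocol.box_length
    n = protocol.n_particles
    pos = lattice_positions(n, L, protocol.dims, rng)
    vel = maxwell_velocities(n, protocol.dims, protocol.T_init, rng)
    if protocol.mixture == "symmetric_binary":
        species = np.zeros(n, np.int64)
        species[rng.permutation(n)[: n // 2]] = 1
    else:
        species = np.zeros(n, np.int64)
    state = ParticleState(pos, vel, species, L, time=0.0)
    traj, _ = _run_md(state, protocol.eps_table(), protocol.dt_equil,
                      protocol.equilibration_steps, [], protocol.rc, protocol.skin,
                      True, protocol.T_init, protocol.thermostat_damping)
    th = traj.thermo
    tail = th[3 * len(th) // 4:, 1]
    # small systems cannot beat the canonical T_kin fluctuation floor
    floor = 3.0 * math.sqrt(2.0 / (protocol.dims * n))
    temperature_band = max(temperature_band, floor)
    if abs(tail.mean() - protocol.T_init) > temperature_band * protocol.T_init:
        raise EquilibrationError(
            f"T_kin={tail.mean():.4f} outside {temperature_band:.0%} band of "
            f"T_init={protocol.T_init}")
    state.time = 0.0
    return state


def run_nvt(state: ParticleState, protocol: QuenchProtocol,
            sample_times: Optional[Sequence[float]] = None,
            thermo_every: int = 50) -> Trajectory:
    """Quench to protocol.T_target and run NVT production.

    The quench is instantaneous: one velocity rescale to T_target plus a
    thermostat retarget.  Frames are stored at sample_times (offsets from
    the quench, in tau_lj); default is 20 log-spaced times.
    """
    state = state.copy()
    nfree = state.n * state.dims - state.dims
    k2 = float(np.sum(state.velocities ** 2))
    if k2 > 0:
        state.velocities *= math.sqrt(nfree * protocol.T_target / k2)
    t_total = protocol.production_steps * protocol.dt
    if sample_times is None:
        sample_times = np.geomspace(max(10 * protocol.dt, t_total / 200), t_total, 20)
    traj, _ = _run_md(state, protocol.eps_table(), protocol.dt,
                      protocol.production_steps, sample_times, protocol.rc,
                      protocol.skin, True, protocol.T_target,
                      protocol.thermostat_damping, thermo_every=thermo_every)
    if traj.thermo is not None and len(traj.thermo):
        tmax = np.nanmax(traj.thermo[:, 1])
        if not np.isfinite(tmax) or tmax > 50 * max(protocol.T_target, protocol.T_init):
            raise IntegratorError(f"temperature divergence (max T_kin={tmax}); reduce dt")
    traj.metadata.update(protocol.to_dict(), rc=protocol.rc)
    return traj


def run_nve(state: ParticleState, dt: float, nsteps: int,
            sample_times: Optional[Sequence[float]] = None, rc: float = 2.5,
            skin: float = 0.3, eps_table: Optional[np.ndarray] = None,
            thermo_every: int = 10) -> Trajectory:
    """Constant-energy MD (velocity Verlet, no thermostat)."""
    state = state.copy()
    eps_table = _ONE if eps_table is None else np.asarray(eps_table, float)
    if sample_times is None:
        sample_times = np.arange(1, nsteps + 1) * dt
    traj, _ = _run_md(state, eps_table, dt, nsteps, sample_times, rc, skin,
                      False, 0.0, 1.0, thermo_every=thermo_every)
    traj.metadata.update(dt=dt, rc=rc, ensemble="NVE")
    return traj


# ---------------------------------------------------------------------------
# overdamped colloid stand-in


def run_overdamped_colloids(state: ParticleState, steps: int, dt: float,
                            seed: int = 0,
                            sample_times: Optional[Sequence[float]] = None,
                            mobility: Optional[float] = None, eta: float = 1.0,
                            rc: float = 4.0, skin: float = 0.5,
                            max_disp: float = 0.05,
                            energy_tol: float = 1e-8) -> Trajectory:
    """Zero-noise overdamped dynamics dR/dt = F / (3 pi eta sigma).

    Time is in units of tau_d.  This is a non-hydrodynamic stand-in for the
    3D colloid suspension: it reproduces the T = 0 network morphology but
    makes no claim about hydrodynamic transport.  Total energy must be
    non-increasing between uncapped frames; an increase beyond energy_tol
    (per particle) raises IntegratorError (dt too large).

    The default cutoff is 4 sigma: the colloid attraction is long-ranged,
    and truncating at 2.5 shifts the zero-pressure packing of the dense
    phase (and hence its Voronoi volume fraction) down by ~0.04.
    """
    state = state.copy()
    mob = mobility if mobility is not None else 1.0 / (3.0 * math.pi * eta)
    t0 = state.time
    t_total = steps * dt
    if sample_times is None:
        sample_times = np.geomspace(max(dt, t_total / 100), t_total, 15)
    save_steps = sorted({int(round(ts / dt)) for ts in sample_times if ts > 0})
    save_steps = [s for s in save_steps if s <= steps]
    if not save_steps or save_steps[-1] != steps:
        save_steps.append(steps)
    frames = []
    thermo_rows = []
    done = 0
    prev_epot = None
    for target in save_steps:
        chunk = target - done
        epot, virial = _kernels.overdamped_chunk(
            state.positions, state.species, _ONE, state.box_length, rc, skin,
            dt, mob, chunk, max_disp)
        done = target
        state.time = t0 + done * dt
        _check_finite(state, done, dt)
        if prev_epot is not None and epot > prev_epot + energy_tol * state.n:
            raise IntegratorError(
                f"energy increased by {(epot - prev_epot)/state.n:.3e} per "
                f"particle at t={state.time}; reduce dt")
        prev_epot = epot
        frames.append(state.copy())
        d, V = state.dims, state.box_length ** state.dims
        thermo_rows.append([state.time, 0.0, epot, virial / d / V])
    traj = Trajectory(frames=frames, thermo=np.array(thermo_rows))
    traj.metadata.update(dt=dt, rc=rc, mobility=mob, seed=seed,
                         dynamics="overdamped")
    return traj


def colloid_standin_initial(phi: float, n: int, dims: int = 3,
                            seed: int = 0) -> ParticleState:
    """Random non-overlapping colloids at volume fraction phi, zero velocity.

    The RSA minimum separation shrinks with phi so that the effective hard
    packing stays below the RSA saturation limit (~0.38 in 3D, ~0.55 in 2D).
    """
    if dims == 3:
        L = (math.pi * n / (6.0 * phi)) ** (1.0 / 3.0)
        rmin = min(0.9, (0.28 / phi) ** (1.0 / 3.0))
    else:
        L = (math.pi * n / (4.0 * phi)) ** 0.5
        rmin = min(0.9, (0.40 / phi) ** 0.5)
    pos = random_nonoverlapping(n, L, dims, rmin=rmin, seed=seed)
    return ParticleState(pos, np.zeros_like(pos), np.zeros(n, np.int64), L)


# ---------------------------------------------------------------------------
# minimization / packing pressure


def minimize_at_fixed_density(positions: np.ndarray, box_length: float,
                              dims: int = 3, ftol: float = 1e-8,
                              max_steps: int = 200000, dt0: float = 0.005,
                              rc: float = 2.5, skin: float = 0.3
                              ) -> Tuple[ParticleState, float]:
    """FIRE-minimize a configuration at fixed box; return (state, pressure).

    Pressure is the T = 0 virial pressure P = W / (d V).  Non-convergence
    (max|F| >= ftol after max_steps) raises RuntimeError.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64).copy()
    n, d = pos.shape
    species = np.zeros(n, np.int64)
    if n == 1:
        state = ParticleState(pos, np.zeros_like(pos), species, box_length)
        return state, 0.0
    epot, virial, fmax, used = _kernels.fire_minimize(
        pos, species, _ONE, box_length, rc, skin, dt0, ftol, max_steps)
    if fmax >= ftol:
        raise RuntimeError(f"FIRE did not converge: max|F|={fmax:.2e} after {used} steps")
    state = ParticleState(pos, np.zeros((n, d)), species, box_length)
    pressure = virial / d / box_length ** d
    return state, pressure


def packing_pressure_scan(phi_values: Sequence[float], n: int = 2000,
                          seeds: Sequence[int] = (0, 1, 2, 3, 4),
                          ftol: float = 0.05, dims: int = 3,
                          presteps: int = 300, rc_minimize: float = 2.5,
                          rc_pressure: float = 4.0):
    """Pressure of energy-minimized random packings across volume fractions.

    For each (phi, seed): RSA placement, a short capped-descent pre-relax to
    defuse steep contacts, then FIRE at rc_minimize down to max|F| < ftol.
    The virial pressure is evaluated at rc_pressure on the minimized
    structure: colloid LJ attraction is long-ranged, and a 2.5-sigma cutoff
    biases the pressure by about -1 near close packing, shifting the
    zero-pressure fraction by ~0.04.  The mild residual forces at the loose
    ftol move the pressure by < 0.05, far below the phi resolution of the
    scan (see the tolerance study in the methods note).

    Returns a dict with per-run pressures, the mean curve, and the zero
    crossing of mean P(phi) located by linear interpolation.
    """
    phi_values = np.asarray(list(phi_values), float)
    pressures = np.zeros((len(phi_values), len(seeds)))
    for a, phi in enumerate(phi_values):
        for b, seed in enumerate(seeds):
            st = colloid_standin_initial(phi, n, dims=dims, seed=int(seed) + 7919 * a)
            _kernels.overdamped_chunk(st.positions, st.species, _ONE,
                                      st.box_length, rc_minimize, 0.5, 0.002,
                                      1.0 / (3 * math.pi), presteps, 0.02)
            stmin, _ = minimize_at_fixed_density(st.positions, st.box_length,
                                                 dims=dims, ftol=ftol,
                                                 rc=rc_minimize)
            _, _, w = compute_forces(stmin, rc=rc_pressure, skin=0.1)
            pressures[a, b] = w / dims / st.box_length ** dims
    mean_p = pressures.mean(axis=1)
    phi_zero = zero_crossing(phi_values, mean_p)
    return {"phi": phi_values, "pressures": pressures, "mean_pressure": mean_p,
            "phi_zero": phi_zero, "rc_minimize": rc_minimize,
            "rc_pressure": rc_pressure, "ftol": ftol}


def zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """First sign change of y(x), located by linear interpolation."""
    s = np.sign(y)
    idx = np.where(np.diff(s) != 0)[0]
    if len(idx) == 0:
        raise ValueError("no zero crossing in range")
    i = idx[0]
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


# ---------------------------------------------------------------------------
# per-particle kinetic energy


def kinetic_energy_per_particle(traj: Trajectory, t: float,
                                window: float = 1.0, mass: float = 1.0) -> np.ndarray:
    """K_i(t) = (1/2) m <V_i^2> averaged over frames in [t - w/2, t + w/2].

    The default window is one LJ time.  Raises ValueError if the window
    extends beyond the trajectory.
    """
    times = traj.times
    lo, hi = t - window / 2.0, t + window / 2.0
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        # degenerate window: a single frame exactly at t is acceptable
        try:
            f = traj.frame_at(t)
            return 0.5 * mass * np.sum(f.velocities ** 2, axis=1)
        except KeyError:
            raise ValueError("window exceeds trajectory bounds")
    sel = [f for f in traj.frames if lo - 1e-9 <= f.time <= hi + 1e-9]
    if not sel:
        raise ValueError("no frames in window")
    v2 = np.mean([np.sum(f.velocities ** 2, axis=1) for f in sel], axis=0)
    return 0.5 * mass * v2
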