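"""Numba kernels for Lennard-Jones particle dynamics.

All kernels work in reduced units (sigma = m = k_B = 1); the pair well depth
enters through a per-species-pair table so the symmetric binary mixture
(cross depth eps/2) shares the same code path as the one-component fluid.
Positions are (N, d) arrays with d in {2, 3}, wrapped into [0, L)^d.

Neighbor handling: cell-binned half pair lists built at radius rc + skin,
rebuilt whenever any particle has moved more than skin/2 since the last
build.  Energies are cut-and-shifted at rc; forces keep the (small)
discontinuity at the cutoff.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# pair lists


@njit(cache=True)
def _count_cells(L, rlist, d):
    nc = int(L / rlist)
    if nc < 3:
        nc = 1  # fall back to O(N^2) all-pairs
    return nc


@njit(cache=True, fastmath=True)
def build_pairs(pos, L, rlist):
    """Half pair list (i < j by construction) within rlist, minimum image.

    Returns (pi, pj, npairs); pi/pj are sized to the pair count.
    """
    N, d = pos.shape
    nc = _count_cells(L, rlist, d)
    r2max = rlist * rlist

    if nc == 1:
        # all-pairs fallback for small boxes
        cap = N * (N - 1) // 2
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        n = 0
        for i in range(N):
            for j in range(i + 1, N):
                r2 = 0.0
                for k in range(d):
                    dx = pos[i, k] - pos[j, k]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    r2 += dx * dx
                if r2 < r2max:
                    pi[n] = i
                    pj[n] = j
                    n += 1
        return pi[:n], pj[:n]

    # small cells (target width ~1.3 sigma) with a half stencil of radius m;
    # scanning a (2m+1)^d block oversamples the cutoff sphere far less than
    # cells of width rlist would
    target = 1.3
    nc = max(3, int(L / min(target, rlist)))
    cw = L / nc
    m = int(np.ceil(rlist / cw))
    if 2 * m + 1 > nc:
        # box too small for the stencil: fall back to all pairs
        cap = N * (N - 1) // 2
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        n = 0
        for i in range(N):
            for j in range(i + 1, N):
                r2 = 0.0
                for k in range(d):
                    dx = pos[i, k] - pos[j, k]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    r2 += dx * dx
                if r2 < r2max:
                    pi[n] = i
                    pj[n] = j
                    n += 1
        return pi[:n], pj[:n]

    ncell = nc ** d
    cell_of = np.empty(N, np.int64)
    for i in range(N):
        c = 0
        for k in range(d):
            ck = int(pos[i, k] / cw)
            if ck >= nc:
                ck = nc - 1
            if ck < 0:
                ck = 0
            c = c * nc + ck
        cell_of[i] = c
    start = np.zeros(ncell + 1, np.int64)
    for i in range(N):
        start[cell_of[i] + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(N, np.int64)
    fill = start[:ncell].copy()
    for i in range(N):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # half stencil: offsets with positive lexicographic key
    span = 2 * m + 1
    noff_max = span ** d // 2
    offs = np.empty((noff_max, 3), np.int64)
    s = 0
    for ox in range(-m, m + 1):
        for oy in range(-m, m + 1):
            if d == 3:
                for oz in range(-m, m + 1):
                    key = (ox * span + oy) * span + oz
                    if key > 0:
                        offs[s, 0] = ox
                        offs[s, 1] = oy
                        offs[s, 2] = oz
                        s += 1
            else:
                key = ox * span + oy
                if key > 0:
                    offs[s, 0] = ox
                    offs[s, 1] = oy
                    offs[s, 2] = 0
                    s += 1
    noff = s

    cap = N * 40 + int(2.6 * N * rlist ** d) + 1024
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    n = 0
    half = 0.5 * L
    for cx in range(nc):
        for cy in range(nc):
            czmax = nc if d == 3 else 1
            for cz in range(czmax):
                if d == 3:
                    c = (cx * nc + cy) * nc + cz
                else:
                    c = cx * nc + cy
                a0, a1 = start[c], start[c + 1]
                # within-cell pairs
                for a in range(a0, a1):
                    i = order[a]
                    for b in range(a + 1, a1):
                        j = order[b]
                        r2 = 0.0
                        for k in range(d):
                            dx = pos[i, k] - pos[j, k]
                            if dx > half:
                                dx -= L
                            elif dx < -half:
                                dx += L
                            r2 += dx * dx
                        if r2 < r2max:
                            if n >= cap:
                                raise RuntimeError("pair list capacity exceeded")
                            pi[n] = i
                            pj[n] = j
                            n += 1
                # neighbor-cell pairs (half stencil)
                for s in range(noff):
                    nx = cx + offs[s, 0]
                    if nx >= nc:
                        nx -= nc
                    elif nx < 0:
                        nx += nc
                    ny = cy + offs[s, 1]
                    if ny >= nc:
                        ny -= nc
                    elif ny < 0:
                        ny += nc
                    if d == 3:
                        nz = cz + offs[s, 2]
                        if nz >= nc:
                            nz -= nc
                        elif nz < 0:
                            nz += nc
                        c2 = (nx * nc + ny) * nc + nz
                    else:
                        c2 = nx * nc + ny
                    b0, b1 = start[c2], start[c2 + 1]
                    for a in range(a0, a1):
                        i = order[a]
                        xi0 = pos[i, 0]
                        xi1 = pos[i, 1]
                        xi2 = pos[i, 2] if d == 3 else 0.0
                        for b in range(b0, b1):
                            j = order[b]
                            dx0 = xi0 - pos[j, 0]
                            if dx0 > half:
                                dx0 -= L
                            elif dx0 < -half:
                                dx0 += L
                            dx1 = xi1 - pos[j, 1]
                            if dx1 > half:
                                dx1 -= L
                            elif dx1 < -half:
                                dx1 += L
                            r2 = dx0 * dx0 + dx1 * dx1
                            if d == 3:
                                dx2 = xi2 - pos[j, 2]
                                if dx2 > half:
                                    dx2 -= L
                                elif dx2 < -half:
                                    dx2 += L
                                r2 += dx2 * dx2
                            if r2 < r2max:
                                if n >= cap:
                                    raise RuntimeError("pair list capacity exceeded")
                                pi[n] = i
                                pj[n] = j
                                n += 1
    return pi[:n], pj[:n]


@njit(cache=True, fastmath=True)
def lj_forces(pos, L, pi, pj, species, eps_table, rc, forces):
    """LJ forces/energy/virial from a half pair list.

    Energy is cut-and-shifted at rc.  Returns (epot, virial) with
    virial = sum_pairs r_ij . f_ij (pair virial, used as W in
    P = (N k_B T + W/d) / V).
    """
    N, d = pos.shape
    rc2 = rc * rc
    forces[:] = 0.0
    epot = 0.0
    virial = 0.0
    # per-pair-type shift so U(rc) = 0
    sr6c = 1.0 / rc2 ** 3
    ushift_unit = 4.0 * (sr6c * sr6c - sr6c)
    half = 0.5 * L
    if d == 3:
        for p in range(pi.shape[0]):
            i = pi[p]
            j = pj[p]
            dx0 = pos[i, 0] - pos[j, 0]
            if dx0 > half:
                dx0 -= L
            elif dx0 < -half:
                dx0 += L
            dx1 = pos[i, 1] - pos[j, 1]
            if dx1 > half:
                dx1 -= L
            elif dx1 < -half:
                dx1 += L
            dx2 = pos[i, 2] - pos[j, 2]
            if dx2 > half:
                dx2 -= L
            elif dx2 < -half:
                dx2 += L
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 >= rc2:
                continue
            eps = eps_table[species[i], species[j]]
            inv_r2 = 1.0 / r2
            sr6 = inv_r2 * inv_r2 * inv_r2
            sr12 = sr6 * sr6
            epot += 4.0 * eps * (sr12 - sr6) - eps * ushift_unit
            fr = eps * (48.0 * sr12 - 24.0 * sr6) * inv_r2
            virial += fr * r2
            forces[i, 0] += fr * dx0
            forces[j, 0] -= fr * dx0
            forces[i, 1] += fr * dx1
            forces[j, 1] -= fr * dx1
            forces[i, 2] += fr * dx2
            forces[j, 2] -= fr * dx2
    else:
        for p in range(pi.shape[0]):
            i = pi[p]
            j = pj[p]
            dx0 = pos[i, 0] - pos[j, 0]
            if dx0 > half:
                dx0 -= L
            elif dx0 < -half:
                dx0 += L
            dx1 = pos[i, 1] - pos[j, 1]
            if dx1 > half:
                dx1 -= L
            elif dx1 < -half:
                dx1 += L
            r2 = dx0 * dx0 + dx1 * dx1
            if r2 >= rc2:
                continue
            eps = eps_table[species[i], species[j]]
            inv_r2 = 1.0 / r2
            sr6 = inv_r2 * inv_r2 * inv_r2
            sr12 = sr6 * sr6
            epot += 4.0 * eps * (sr12 - sr6) - eps * ushift_unit
            fr = eps * (48.0 * sr12 - 24.0 * sr6) * inv_r2
            virial += fr * r2
            forces[i, 0] += fr * dx0
            forces[j, 0] -= fr * dx0
            forces[i, 1] += fr * dx1
            forces[j, 1] -= fr * dx1
    return epot, virial


@njit(cache=True, fastmath=True)
def min_pair_distance(pos, L, pi, pj):
    dmin = 1.0e300
    d = pos.shape[1]
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        r2 = 0.0
        for k in range(d):
            dx = pos[i, k] - pos[j, k]
            if dx > 0.5 * L:
                dx -= L
            elif dx < -0.5 * L:
                dx += L
            r2 += dx * dx
        if r2 < dmin:
            dmin = r2
    return np.sqrt(dmin)


# ---------------------------------------------------------------------------
# integrators


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        r2 = 0.0
        for k in range(pos.shape[1]):
            dx = pos[i, k] - ref[i, k]
            r2 += dx * dx
        if r2 > m:
            m = r2
    return m


@njit(cache=True, fastmath=True)
def _nhc_half(vel, chain, T, tdamp, dt, nfree):
    """Half-step update of a length-3 Nose-Hoover chain; rescales velocities.

    chain = [vxi1, vxi2, vxi3, xi1, xi2, xi3] (xi kept for bookkeeping).
    """
    q1 = nfree * T * tdamp * tdamp
    q2 = T * tdamp * tdamp
    q3 = q2
    dt2 = 0.5 * dt
    dt4 = 0.25 * dt
    dt8 = 0.125 * dt
    k2 = 0.0
    for i in range(vel.shape[0]):
        for k in range(vel.shape[1]):
            k2 += vel[i, k] * vel[i, k]
    # k2 = 2*K (m = 1)
    g3 = (q2 * chain[1] * chain[1] - T) / q3
    chain[2] += g3 * dt4
    chain[1] *= np.exp(-chain[2] * dt8)
    g2 = (q1 * chain[0] * chain[0] - T) / q2
    chain[1] += g2 * dt4
    chain[1] *= np.exp(-chain[2] * dt8)
    chain[0] *= np.exp(-chain[1] * dt8)
    g1 = (k2 - nfree * T) / q1
    chain[0] += g1 * dt4
    chain[0] *= np.exp(-chain[1] * dt8)
    s = np.exp(-chain[0] * dt2)
    for i in range(vel.shape[0]):
        for k in range(vel.shape[1]):
            vel[i, k] *= s
    k2 *= s * s
    chain[3] += chain[0] * dt2
    chain[4] += chain[1] * dt2
    chain[5] += chain[2] * dt2
    chain[0] *= np.exp(-chain[1] * dt8)
    g1 = (k2 - nfree * T) / q1
    chain[0] += g1 * dt4
    chain[0] *= np.exp(-chain[1] * dt8)
    chain[1] *= np.exp(-chain[2] * dt8)
    g2 = (q1 * chain[0] * chain[0] - T) / q2
    chain[1] += g2 * dt4
    chain[1] *= np.exp(-chain[2] * dt8)
    g3 = (q2 * chain[1] * chain[1] - T) / q3
    chain[2] += g3 * dt4


@njit(cache=True, fastmath=True)
def md_chunk(pos, vel, species, eps_table, L, rc, skin, dt, nsteps,
             thermostat, T_target, tdamp, chain, sample_every):
    """Velocity-Verlet MD for nsteps; NH-chain NVT when thermostat != 0.

    Mutates pos/vel/chain in place.  Returns thermo samples
    (time_index, K, Epot, virial) taken every sample_every steps,
    plus the final (epot, virial).
    """
    N, d = pos.shape
    nfree = float(N * d - d)  # zero total momentum
    rlist = rc + skin
    forces = np.zeros_like(pos)
    pi, pj = build_pairs(pos, L, rlist)
    ref = pos.copy()
    epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
    nsamp = nsteps // sample_every + 1
    thermo = np.zeros((nsamp, 4))
    isamp = 0
    half_skin2 = (0.5 * skin) ** 2
    for step in range(nsteps):
        if thermostat != 0:
            _nhc_half(vel, chain, T_target, tdamp, dt, nfree)
        for i in range(N):
            for k in range(d):
                vel[i, k] += 0.5 * dt * forces[i, k]
                pos[i, k] += dt * vel[i, k]
                if pos[i, k] >= L:
                    pos[i, k] -= L
                elif pos[i, k] < 0.0:
                    pos[i, k] += L
        # rebuild check (reference positions move with wrapping; compare
        # unwrapped drift via accumulated displacement instead)
        drift = 0.0
        for i in range(N):
            r2 = 0.0
            for k in range(d):
                dx = pos[i, k] - ref[i, k]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                r2 += dx * dx
            if r2 > drift:
                drift = r2
        if drift > half_skin2:
            pi, pj = build_pairs(pos, L, rlist)
            ref = pos.copy()
        epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
        for i in range(N):
            for k in range(d):
                vel[i, k] += 0.5 * dt * forces[i, k]
        if thermostat != 0:
            _nhc_half(vel, chain, T_target, tdamp, dt, nfree)
        if (step + 1) % sample_every == 0:
            k2 = 0.0
            for i in range(N):
                for k in range(d):
                    k2 += vel[i, k] * vel[i, k]
            thermo[isamp, 0] = step + 1
            thermo[isamp, 1] = 0.5 * k2
            thermo[isamp, 2] = epot
            thermo[isamp, 3] = virial
            isamp += 1
    return thermo[:isamp], epot, virial


@njit(cache=True, fastmath=True)
def overdamped_chunk(pos, species, eps_table, L, rc, skin, dt, mobility,
                     nsteps, max_disp):
    """Overdamped (zero-noise) dynamics dR/dt = mobility * F.

    Per-step particle displacements are capped at max_disp to survive steep
    repulsive starts; the cap only ever shortens a downhill move.
    Returns (epot, virial) at the final configuration.
    """
    N, d = pos.shape
    rlist = rc + skin
    forces = np.zeros_like(pos)
    pi, pj = build_pairs(pos, L, rlist)
    ref = pos.copy()
    half_skin2 = (0.5 * skin) ** 2
    epot = 0.0
    virial = 0.0
    for step in range(nsteps):
        epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
        for i in range(N):
            f2 = 0.0
            for k in range(d):
                f2 += forces[i, k] * forces[i, k]
            s = mobility * dt
            disp = s * np.sqrt(f2)
            if disp > max_disp:
                s *= max_disp / disp
            for k in range(d):
                pos[i, k] += s * forces[i, k]
                if pos[i, k] >= L:
                    pos[i, k] -= L
                elif pos[i, k] < 0.0:
                    pos[i, k] += L
        drift = 0.0
        for i in range(N):
            r2 = 0.0
            for k in range(d):
                dx = pos[i, k] - ref[i, k]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                r2 += dx * dx
            if r2 > drift:
                drift = r2
        if drift > half_skin2:
            pi, pj = build_pairs(pos, L, rlist)
            ref = pos.copy()
    epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
    return epot, virial


@njit(cache=True, fastmath=True)
def fire_minimize(pos, species, eps_table, L, rc, skin, dt0, ftol, max_steps):
    """FIRE energy minimization at fixed box.

    Returns (epot, virial, fmax, nsteps_used); converged when fmax < ftol.
    """
    N, d = pos.shape
    rlist = rc + skin
    forces = np.zeros_like(pos)
    vel = np.zeros_like(pos)
    pi, pj = build_pairs(pos, L, rlist)
    ref = pos.copy()
    half_skin2 = (0.5 * skin) ** 2

    dt = dt0
    dt_max = 10.0 * dt0
    alpha0 = 0.1
    alpha = alpha0
    n_pos = 0
    n_min = 5
    f_inc = 1.1
    f_dec = 0.5
    f_alpha = 0.99

    epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
    fmax = 0.0
    step_used = 0
    for step in range(max_steps):
        step_used = step
        # P = F . v
        power = 0.0
        for i in range(N):
            for k in range(d):
                power += forces[i, k] * vel[i, k]
        if power > 0.0:
            n_pos += 1
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
            # mix velocity toward the force direction
            vnorm = 0.0
            fnorm = 0.0
            for i in range(N):
                for k in range(d):
                    vnorm += vel[i, k] * vel[i, k]
                    fnorm += forces[i, k] * forces[i, k]
            vnorm = np.sqrt(vnorm)
            fnorm = np.sqrt(fnorm)
            if fnorm > 0.0:
                cf = alpha * vnorm / fnorm
                for i in range(N):
                    for k in range(d):
                        vel[i, k] = (1.0 - alpha) * vel[i, k] + cf * forces[i, k]
        else:
            vel[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_pos = 0
        # semi-implicit Euler with displacement cap
        for i in range(N):
            for k in range(d):
                vel[i, k] += dt * forces[i, k]
            disp2 = 0.0
            for k in range(d):
                disp2 += (dt * vel[i, k]) ** 2
            s = 1.0
            if disp2 > 0.01:  # cap at 0.1 sigma
                s = 0.1 / np.sqrt(disp2)
            for k in range(d):
                pos[i, k] += s * dt * vel[i, k]
                if pos[i, k] >= L:
                    pos[i, k] -= L
                elif pos[i, k] < 0.0:
                    pos[i, k] += L
        drift = 0.0
        for i in range(N):
            r2 = 0.0
            for k in range(d):
                dx = pos[i, k] - ref[i, k]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                r2 += dx * dx
            if r2 > drift:
                drift = r2
        if drift > half_skin2:
            pi, pj = build_pairs(pos, L, rlist)
            ref = pos.copy()
        epot, virial = lj_forces(pos, L, pi, pj, species, eps_table, rc, forces)
        fmax = 0.0
        for i in range(N):
            f2 = 0.0
            for k in range(d):
                f2 += forces[i, k] * forces[i, k]
            if f2 > fmax:
                fmax = f2
        fmax = np.sqrt(fmax)
        if fmax < ftol:
            break
    return epot, virial, fmax, step_used + 1


@njit(cache=True, fastmath=True)
def rsa_insert(L, d, n_target, rmin, max_tries, seed):
    """Random sequential addition of points with minimum separation rmin."""
    np.random.seed(seed)
    pos = np.zeros((n_target, 3))
    rmin2 = rmin * rmin
    n = 0
    tries = 0
    while n < n_target and tries < max_tries:
        tries += 1
        ok = True
        cand = np.random.random(d) * L
        for i in range(n):
            r2 = 0.0
            for k in range(d):
                dx = cand[k] - pos[i, k]
                dx -= L * np.rint(dx / L)
                r2 += dx * dx
            if r2 < rmin2:
                ok = False
                break
        if ok:
            for k in range(d):
                pos[n, k] = cand[k]
            n += 1
    return pos[:n, :d], n
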