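"""Numba kernels for the bead-spring Langevin engine.

Everything here works in LJ units on plain float64 arrays; the friendly
interface lives in :mod:`transloc.md_engine`.  The integrator is BAOAB
(velocity half-kick, half-drift, exact Ornstein-Uhlenbeck update of the
velocity with variance matching the fluctuation-dissipation relation
<xi(t) xi(t')> = 2 eta kBT delta(t-t'), half-drift, half-kick), one force
evaluation per step.

Force field: WCA excluded volume between all chain bead pairs and between
chain beads and the 16 static pore beads; FENE bonds; discrete bending
penalty kappa_b (1 - cos theta) on consecutive bond pairs; a purely
repulsive 9-3 wall on |x| (truncated and shifted at its minimum
3^{1/6} sigma) felt by beads radially outside the pore lumen; a constant
driving force +f x_hat on beads inside the pore (|x| <= sigma/2).

Status codes returned by the force routine / run loops:
0 = ok; > 0 = FENE bond (status-1) reached its maximum extension
(time step too large or force field inconsistent); -1 = non-finite
coordinate encountered.
"""

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
WALL_CUT = 3.0 ** (1.0 / 6.0)
# value of the raw 9-3 potential at its minimum; subtracted so the
# truncated potential is continuous (and purely repulsive)
WALL_SHIFT = -4.0 * (3.0 ** -1.5 - 3.0 ** -0.5)


@njit(cache=True)
def forces(pos, pore, eps, sigma, fene_k, fene_r0, kappa_b,
           wall_on, lumen_radius, drive_f, pore_half_thickness,
           tether_k, out):
    """Accumulate all forces into ``out``; return a status code."""
    n = pos.shape[0]
    out[:] = 0.0
    sig2 = sigma * sigma
    rc2 = WCA_CUT * WCA_CUT * sig2
    r02 = fene_r0 * fene_r0

    # WCA between chain beads (all pairs, bonded included)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 1e-12:
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                out[i, 0] += fr * dx; out[i, 1] += fr * dy; out[i, 2] += fr * dz
                out[j, 0] -= fr * dx; out[j, 1] -= fr * dy; out[j, 2] -= fr * dz

    # WCA between chain beads and static pore beads
    for i in range(n):
        for j in range(pore.shape[0]):
            dx = pos[i, 0] - pore[j, 0]
            dy = pos[i, 1] - pore[j, 1]
            dz = pos[i, 2] - pore[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 1e-12:
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                out[i, 0] += fr * dx; out[i, 1] += fr * dy; out[i, 2] += fr * dz

    # FENE bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return i + 1
        fr = -fene_k / (1.0 - r2 / r02)  # attractive
        out[i, 0] -= fr * dx; out[i, 1] -= fr * dy; out[i, 2] -= fr * dz
        out[i + 1, 0] += fr * dx; out[i + 1, 1] += fr * dy; out[i + 1, 2] += fr * dz

    # bending: kappa_b (1 - cos theta) on consecutive bond pairs
    if kappa_b > 0.0:
        for i in range(1, n - 1):
            ux = pos[i, 0] - pos[i - 1, 0]
            uy = pos[i, 1] - pos[i - 1, 1]
            uz = pos[i, 2] - pos[i - 1, 2]
            vx = pos[i + 1, 0] - pos[i, 0]
            vy = pos[i + 1, 1] - pos[i, 1]
            vz = pos[i + 1, 2] - pos[i, 2]
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = np.sqrt(lu2)
            lv = np.sqrt(lv2)
            inv = 1.0 / (lu * lv)
            c = (ux * vx + uy * vy + uz * vz) * inv
            # dc/du and dc/dv
            dcux = vx * inv - c * ux / lu2
            dcuy = vy * inv - c * uy / lu2
            dcuz = vz * inv - c * uz / lu2
            dcvx = ux * inv - c * vx / lv2
            dcvy = uy * inv - c * vy / lv2
            dcvz = uz * inv - c * vz / lv2
            # F_k = kappa * dc/dr_k
            out[i - 1, 0] -= kappa_b * dcux
            out[i - 1, 1] -= kappa_b * dcuy
            out[i - 1, 2] -= kappa_b * dcuz
            out[i, 0] += kappa_b * (dcux - dcvx)
            out[i, 1] += kappa_b * (dcuy - dcvy)
            out[i, 2] += kappa_b * (dcuz - dcvz)
            out[i + 1, 0] += kappa_b * dcvx
            out[i + 1, 1] += kappa_b * dcvy
            out[i + 1, 2] += kappa_b * dcvz

    # 9-3 wall on |x|, beads radially outside the pore lumen only
    if wall_on:
        lum2 = lumen_radius * lumen_radius
        xcut = WALL_CUT * sigma
        for i in range(n):
            rho2 = pos[i, 1] * pos[i, 1] + pos[i, 2] * pos[i, 2]
            if rho2 > lum2:
                ax = abs(pos[i, 0])
                if ax < xcut:
                    if ax < 0.4 * sigma:  # unreachable in practice; cap
                        ax = 0.4 * sigma
                    s1 = sigma / ax
                    s3 = s1 * s1 * s1
                    s9 = s3 * s3 * s3
                    fmag = 4.0 * eps * (9.0 * s9 - 3.0 * s3) / ax
                    if pos[i, 0] >= 0.0:
                        out[i, 0] += fmag
                    else:
                        out[i, 0] -= fmag

    # driving force inside the pore
    if drive_f != 0.0:
        for i in range(n):
            if abs(pos[i, 0]) <= pore_half_thickness:
                out[i, 0] += drive_f

    # harmonic tether of bead 0 to the pore center (equilibration only)
    if tether_k > 0.0:
        out[0, 0] -= tether_k * pos[0, 0]
        out[0, 1] -= tether_k * pos[0, 1]
        out[0, 2] -= tether_k * pos[0, 2]

    for i in range(n):
        for d in range(3):
            if not np.isfinite(out[i, d]):
                return -1
    return 0


@njit(cache=True)
def baoab_run(pos, vel, pore, nsteps, dt, eps, sigma, fene_k, fene_r0,
              kappa_b, eta, kbt, mass, wall_on, lumen_radius, drive_f,
              pore_half_thickness, tether_k, seed,
              sample_every, samples):
    """Run ``nsteps`` BAOAB steps; optionally sample [R_ee^2, KE] rows.

    ``samples`` must be shaped (nsteps // sample_every + 1, 2) when
    ``sample_every > 0`` (pass shape (1, 2) otherwise).  Returns
    (status, n_samples_written).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    status = forces(pos, pore, eps, sigma, fene_k, fene_r0, kappa_b,
                    wall_on, lumen_radius, drive_f, pore_half_thickness,
                    tether_k, f)
    if status != 0:
        return status, 0
    gamma = eta / mass
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    half = 0.5 * dt
    written = 0
    for step in range(nsteps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d] / mass
                pos[i, d] += half * vel[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
                pos[i, d] += half * vel[i, d]
        status = forces(pos, pore, eps, sigma, fene_k, fene_r0, kappa_b,
                        wall_on, lumen_radius, drive_f, pore_half_thickness,
                        tether_k, f)
        if status != 0:
            return status, written
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d] / mass
        if sample_every > 0 and (step + 1) % sample_every == 0:
            dx = pos[n - 1, 0] - pos[0, 0]
            dy = pos[n - 1, 1] - pos[0, 1]
            dz = pos[n - 1, 2] - pos[0, 2]
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                    + vel[i, 2] ** 2)
            samples[written, 0] = dx * dx + dy * dy + dz * dz
            samples[written, 1] = ke / n
            written += 1
    return 0, written


@njit(cache=True)
def translocate_run(pos, vel, pore, max_steps, dt, eps, sigma, fene_k,
                    fene_r0, kappa_b, eta, kbt, mass, lumen_radius,
                    drive_f, pore_half_thickness, seed, escape_x,
                    last_below, first_above, trans_extent):
    """Drive the chain until it fully translocates, escapes or times out.

    ``last_below[k]`` (k = 1..N) records the last time at which fewer than
    k beads were on the trans side and ``first_above[k]`` the first time
    at which at least k were; waiting times from the former are
    last-passage filtered (recrossings not double counted).  Returns
    (outcome, status, t_final) with outcome 1 = translocated, 2 = escaped
    to the cis side, 0 = step limit reached.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    status = forces(pos, pore, eps, sigma, fene_k, fene_r0, kappa_b,
                    True, lumen_radius, drive_f, pore_half_thickness,
                    0.0, f)
    if status != 0:
        return 0, status, 0.0
    gamma = eta / mass
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    half = 0.5 * dt
    last_below[:] = 0.0
    first_above[:] = -1.0
    first_above[0] = 0.0
    t = 0.0
    for step in range(max_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d] / mass
                pos[i, d] += half * vel[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
                pos[i, d] += half * vel[i, d]
        status = forces(pos, pore, eps, sigma, fene_k, fene_r0, kappa_b,
                        True, lumen_radius, drive_f, pore_half_thickness,
                        0.0, f)
        if status != 0:
            return 0, status, t
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d] / mass
        t += dt
        s = 0
        max_x = -1.0e30
        for i in range(n):
            if pos[i, 0] > 0.0:
                s += 1
            if pos[i, 0] > max_x:
                max_x = pos[i, 0]
        for k in range(s + 1, n + 1):
            last_below[k] = t
        for k in range(1, s + 1):
            if first_above[k] < 0.0:
                first_above[k] = t
                trans_extent[k] = max_x  # trans-side reach when bead k arrives
        if s == n:
            return 1, 0, t
        if s == 0 and max_x < escape_x:
            return 2, 0, t
    return 0, 0, t
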