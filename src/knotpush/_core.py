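"""Numba kernels: forces, the Langevin loop, and the Gauss writhe sum.

Everything here is plain-array nopython code; the friendly dataclass
surfaces live in :mod:`knotpush.forcefield` and :mod:`knotpush.dynamics`.
The python-level force implementations in ``forcefield.py`` are the readable
reference; the kernels below are cross-checked against them in the tests.

Status codes returned by :func:`run_segment`:
    0  completed
    1  non-finite coordinate (blow-up); info = (step, bead)
    2  bead escaped the channel tube;  info = (step, bead)
    3  neighbour-list overflow;        info = (step, capacity)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
WCA_CUT2 = WCA_CUT * WCA_CUT


# ---------------------------------------------------------------- helix ----

@njit(cache=True, inline="always")
def _helix_f_fp_fpp(px, py, pz, R_H, k, w, t):
    c = math.cos(w * t)
    s = math.sin(w * t)
    dx = px - k * t
    dy = py - R_H * c
    dz = pz - R_H * s
    f = dx * dx + dy * dy + dz * dz
    fp = -2.0 * k * dx + 2.0 * R_H * w * (py * s - pz * c)
    fpp = 2.0 * k * k + 2.0 * R_H * (py * c + pz * s)
    return f, fp, fpp


@njit(cache=True)
def helix_newton(px, py, pz, R_H, k, w, t0, iters):
    """Local refinement of the nearest-point parameter from a warm start."""
    t = t0
    lo = t0 - math.pi
    hi = t0 + math.pi
    for _ in range(iters):
        f, fp, fpp = _helix_f_fp_fpp(px, py, pz, R_H, k, w, t)
        if abs(fp) < 1e-13 * (1.0 + abs(f)):
            break
        if fp > 0.0:
            hi = t
        else:
            lo = t
        if fpp > 0.0:
            tn = t - fp / fpp
        else:
            tn = 0.5 * (lo + hi)
        if tn <= lo or tn >= hi:
            tn = 0.5 * (lo + hi)
        t = tn
    return t


@njit(cache=True)
def helix_multistart(px, py, pz, R_H, k, w, n_half_turns):
    """Global nearest-point parameter: Newton from every half-turn start."""
    tc = px / k
    best_t = tc
    best_f = 1.0e300
    for j in range(-n_half_turns, n_half_turns + 1):
        t = helix_newton(px, py, pz, R_H, k, w, tc + j * math.pi, 60)
        f, _, _ = _helix_f_fp_fpp(px, py, pz, R_H, k, w, t)
        if f < best_f:
            best_f = f
            best_t = t
    return best_t


# --------------------------------------------------------------- forces ----

@njit(cache=True)
def _add_wall_force(forces, i, px, py, pz, R_ch, R_H, k, w, t_warm, refresh,
                    iters):
    """Wall contribution for bead i; returns (gap, new_t_warm)."""
    if R_H == 0.0:
        d = math.sqrt(py * py + pz * pz)
        g = R_ch - d
        if g <= 0.0:
            return g, 0.0
        if g < WCA_CUT and d > 1e-12:
            inv = 1.0 / g
            sr6 = inv ** 6
            dU_dg = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv
            fac = dU_dg / d
            forces[i, 1] += fac * py
            forces[i, 2] += fac * pz
        return g, 0.0
    t = helix_newton(px, py, pz, R_H, k, w, t_warm, iters)
    if refresh:
        f0, _, _ = _helix_f_fp_fpp(px, py, pz, R_H, k, w, t)
        for j in (-1, 1):
            ta = helix_newton(px, py, pz, R_H, k, w, t + 2.0 * math.pi * j, 8)
            fa, _, _ = _helix_f_fp_fpp(px, py, pz, R_H, k, w, ta)
            if fa < f0:
                f0 = fa
                t = ta
    f, _, _ = _helix_f_fp_fpp(px, py, pz, R_H, k, w, t)
    d = math.sqrt(f)
    g = R_ch - d
    if g <= 0.0:
        return g, t
    if g < WCA_CUT and d > 1e-12:
        inv = 1.0 / g
        sr6 = inv ** 6
        dU_dg = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv
        fx = px - k * t
        fy = py - R_H * math.cos(w * t)
        fz = pz - R_H * math.sin(w * t)
        fac = dU_dg / d
        forces[i, 0] += fac * fx
        forces[i, 1] += fac * fy
        forces[i, 2] += fac * fz
    return g, t


@njit(cache=True)
def build_neighbor_list(pos, n_chain, r_list2, exclude_bonded, nbr, nbr_count):
    """Half neighbour list (j > i) over chain beads.  Returns 0 or overflow."""
    cap = nbr.shape[1]
    for i in range(n_chain):
        nbr_count[i] = 0
    for i in range(n_chain - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        j0 = i + 2 if exclude_bonded else i + 1
        for j in range(j0, n_chain):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            if dx * dx + dy * dy + dz * dz < r_list2:
                c = nbr_count[i]
                if c >= cap:
                    return 1
                nbr[i, c] = j
                nbr_count[i] = c + 1
    return 0


@njit(cache=True)
def compute_forces(
    pos,
    forces,
    n_chain,
    K_s,
    r0,
    K_b,
    has_channel,
    R_ch,
    R_H,
    k_pitch,
    w_sign,
    t_warm,
    refresh,
    has_piston,
    sigma_c,
    F_ext,
    nbr,
    nbr_count,
    wall_gap,
    wall_ref,
):
    """Total forces on chain beads (+ piston last row when present).

    Returns (status, bad_bead): status 0 ok, 2 escaped bead.
    Excluded volume uses the prebuilt neighbour list.  ``wall_gap`` and
    ``wall_ref`` cache the last computed wall gap and the bead position it
    was computed at: a bead whose displacement since then cannot have
    brought it within the wall cutoff skips the distance solve entirely.
    """
    n_tot = forces.shape[0]
    for i in range(n_tot):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    # bonds: U = K_s * (|b| - r0)^2
    for i in range(n_chain - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return 2, i
        fac = 2.0 * K_s * (r - r0) / r
        forces[i, 0] += fac * dx
        forces[i, 1] += fac * dy
        forces[i, 2] += fac * dz
        forces[i + 1, 0] -= fac * dx
        forces[i + 1, 1] -= fac * dy
        forces[i + 1, 2] -= fac * dz

    # angles: U = (K_b/2) * (theta - pi)^2, theta at bead i between bonds
    for i in range(1, n_chain - 1):
        ax = pos[i - 1, 0] - pos[i, 0]
        ay = pos[i - 1, 1] - pos[i, 1]
        az = pos[i - 1, 2] - pos[i, 2]
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        bz = pos[i + 1, 2] - pos[i, 2]
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            return 2, i
        ia = 1.0 / la
        ib = 1.0 / lb
        ax *= ia
        ay *= ia
        az *= ia
        bx *= ib
        by *= ib
        bz *= ib
        ct = ax * bx + ay * by + az * bz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        st = math.sqrt(1.0 - ct * ct)
        # q = (theta - pi)/sin(theta); finite limit -1 as theta -> pi
        if st > 1e-8:
            q = (theta - math.pi) / st
        else:
            q = -1.0 if theta > 1.5 else (theta - math.pi) / 1e-8
        # F_{i-1} = K_b*q*(b_hat - ct*a_hat)/la ; F_{i+1} symmetric
        f1x = K_b * q * (bx - ct * ax) * ia
        f1y = K_b * q * (by - ct * ay) * ia
        f1z = K_b * q * (bz - ct * az) * ia
        f3x = K_b * q * (ax - ct * bx) * ib
        f3y = K_b * q * (ay - ct * by) * ib
        f3z = K_b * q * (az - ct * bz) * ib
        forces[i - 1, 0] += f1x
        forces[i - 1, 1] += f1y
        forces[i - 1, 2] += f1z
        forces[i + 1, 0] += f3x
        forces[i + 1, 1] += f3y
        forces[i + 1, 2] += f3z
        forces[i, 0] -= f1x + f3x
        forces[i, 1] -= f1y + f3y
        forces[i, 2] -= f1z + f3z

    # excluded volume (WCA, sigma = 1) over the neighbour list
    for i in range(n_chain):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for jj in range(nbr_count[i]):
            j = nbr[i, jj]
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < WCA_CUT2:
                if r2 < 0.09:  # r < 0.3 sigma: clip to avoid overflow
                    r2 = 0.09
                inv2 = 1.0 / r2
                sr6 = inv2 * inv2 * inv2
                fac = 4.0 * (12.0 * sr6 * sr6 - 6.0 * sr6) * inv2
                forces[i, 0] -= fac * dx
                forces[i, 1] -= fac * dy
                forces[i, 2] -= fac * dz
                forces[j, 0] += fac * dx
                forces[j, 1] += fac * dy
                forces[j, 2] += fac * dz

    # piston: WCA with contact scale sigma_c, plus external force along -x
    if has_piston:
        ip = n_tot - 1
        px = pos[ip, 0]
        cut2 = WCA_CUT2 * sigma_c * sigma_c
        for i in range(n_chain):
            dx = pos[i, 0] - px
            dy = pos[i, 1]
            dz = pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                s2 = sigma_c * sigma_c / r2
                if s2 > 11.12:  # r < 0.3*sigma_c
                    s2 = 11.12
                sr6 = s2 * s2 * s2
                fac = 4.0 * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
                forces[i, 0] += fac * dx
                forces[i, 1] += fac * dy
                forces[i, 2] += fac * dz
                forces[ip, 0] -= fac * dx
                forces[ip, 1] -= fac * dy
                forces[ip, 2] -= fac * dz
        forces[ip, 0] -= F_ext

    # channel wall (lazy: skip beads provably outside the cutoff zone)
    if has_channel:
        for i in range(n_chain):
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            dx = px - wall_ref[i, 0]
            dy = py - wall_ref[i, 1]
            dz = pz - wall_ref[i, 2]
            moved2 = dx * dx + dy * dy + dz * dz
            budget = wall_gap[i] - WCA_CUT
            if budget > 0.0 and moved2 < budget * budget:
                continue
            # axial drift shifts the nearest-point parameter by dx/k
            t0 = t_warm[i] + dx / k_pitch if R_H > 0.0 else t_warm[i]
            stale = moved2 > 0.01
            g, t = _add_wall_force(
                forces, i, px, py, pz,
                R_ch, R_H, k_pitch, w_sign, t0,
                refresh or stale,
                8 if stale else 3,
            )
            t_warm[i] = t
            wall_gap[i] = g
            wall_ref[i, 0] = px
            wall_ref[i, 1] = py
            wall_ref[i, 2] = pz
            if g <= 0.0:
                return 2, i
    return 0, -1


# ------------------------------------------------------------ integrator ---

@njit(cache=True)
def run_segment(
    pos,
    vel,
    n_chain,
    dt,
    n_steps,
    sample_every,
    K_s,
    r0,
    K_b,
    exclude_bonded,
    gamma,
    mass,
    gamma_p,
    mass_p,
    has_channel,
    R_ch,
    R_H,
    k_pitch,
    w_sign,
    t_warm,
    has_piston,
    sigma_c,
    F_ext,
    kT,
    rng,
    frames,
    frame_times,
    t_start,
    refresh_every,
    list_skin,
):
    """BAOAB Langevin integration of ``n_steps`` steps, sampling frames.

    ``pos``/``vel`` hold chain beads and, when ``has_piston``, the piston as
    the last row (constrained to the x axis).  Frames are written every
    ``sample_every`` steps.  Returns (status, info_step, info_bead).
    """
    n_tot = pos.shape[0]
    forces = np.zeros((n_tot, 3))
    nbr = np.zeros((n_chain, 64), dtype=np.int64)
    nbr_count = np.zeros(n_chain, dtype=np.int64)
    pos_at_build = np.zeros((n_chain, 3))
    wall_gap = np.full(n_chain, -1.0)  # force a fresh wall solve first
    wall_ref = pos[:n_chain].copy()

    r_list = WCA_CUT + list_skin
    r_list2 = r_list * r_list
    half_skin2 = 0.25 * list_skin * list_skin

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1) / mass)
    c1p = math.exp(-gamma_p * dt)
    c2p = math.sqrt(kT * (1.0 - c1p * c1p) / mass_p)

    if build_neighbor_list(pos, n_chain, r_list2, exclude_bonded, nbr, nbr_count):
        return 3, 0, 64
    for i in range(n_chain):
        pos_at_build[i, 0] = pos[i, 0]
        pos_at_build[i, 1] = pos[i, 1]
        pos_at_build[i, 2] = pos[i, 2]

    status, bad = compute_forces(
        pos, forces, n_chain, K_s, r0, K_b,
        has_channel, R_ch, R_H, k_pitch, w_sign, t_warm, True,
        has_piston, sigma_c, F_ext, nbr, nbr_count, wall_gap, wall_ref,
    )
    if status != 0:
        return status, 0, bad

    half_dt = 0.5 * dt
    for step in range(n_steps):
        # B: half kick
        for i in range(n_tot):
            m = mass_p if (has_piston and i == n_tot - 1) else mass
            inv_m = 1.0 / m
            vel[i, 0] += half_dt * forces[i, 0] * inv_m
            vel[i, 1] += half_dt * forces[i, 1] * inv_m
            vel[i, 2] += half_dt * forces[i, 2] * inv_m
        # A: half drift
        for i in range(n_tot):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O: Ornstein-Uhlenbeck
        for i in range(n_tot):
            if has_piston and i == n_tot - 1:
                a, b = c1p, c2p
            else:
                a, b = c1, c2
            vel[i, 0] = a * vel[i, 0] + b * rng.standard_normal()
            vel[i, 1] = a * vel[i, 1] + b * rng.standard_normal()
            vel[i, 2] = a * vel[i, 2] + b * rng.standard_normal()
        # A: half drift
        for i in range(n_tot):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # piston constraint: x axis only
        if has_piston:
            ip = n_tot - 1
            pos[ip, 1] = 0.0
            pos[ip, 2] = 0.0
            vel[ip, 1] = 0.0
            vel[ip, 2] = 0.0

        # neighbour list refresh when any bead moved half the skin
        need = False
        for i in range(n_chain):
            dx = pos[i, 0] - pos_at_build[i, 0]
            dy = pos[i, 1] - pos_at_build[i, 1]
            dz = pos[i, 2] - pos_at_build[i, 2]
            if dx * dx + dy * dy + dz * dz > half_skin2:
                need = True
                break
        if need:
            if build_neighbor_list(
                pos, n_chain, r_list2, exclude_bonded, nbr, nbr_count
            ):
                return 3, step, 64
            for i in range(n_chain):
                pos_at_build[i, 0] = pos[i, 0]
                pos_at_build[i, 1] = pos[i, 1]
                pos_at_build[i, 2] = pos[i, 2]

        refresh = (step % refresh_every) == 0
        status, bad = compute_forces(
            pos, forces, n_chain, K_s, r0, K_b,
            has_channel, R_ch, R_H, k_pitch, w_sign, t_warm, refresh,
            has_piston, sigma_c, F_ext, nbr, nbr_count, wall_gap, wall_ref,
        )
        if status != 0:
            return status, step, bad
        # B: half kick
        for i in range(n_tot):
            m = mass_p if (has_piston and i == n_tot - 1) else mass
            inv_m = 1.0 / m
            vel[i, 0] += half_dt * forces[i, 0] * inv_m
            vel[i, 1] += half_dt * forces[i, 1] * inv_m
            vel[i, 2] += half_dt * forces[i, 2] * inv_m
        if has_piston:
            vel[n_tot - 1, 1] = 0.0
            vel[n_tot - 1, 2] = 0.0

        if (step + 1) % sample_every == 0:
            j = (step + 1) // sample_every - 1
            ok = True
            for i in range(n_tot):
                for d in range(3):
                    v = pos[i, d]
                    if not np.isfinite(v):
                        ok = False
            if not ok:
                return 1, step, -1
            for i in range(n_tot):
                frames[j, i, 0] = pos[i, 0]
                frames[j, i, 1] = pos[i, 1]
                frames[j, i, 2] = pos[i, 2]
            frame_times[j] = t_start + (step + 1) * dt

    return 0, n_steps, -1


# ---------------------------------------------------------------- writhe ---

@njit(cache=True)
def writhe_segments(verts, closed):
    """Gauss-integral writhe of a polygonal curve.

    Exact analytic solid-angle contribution for every pair of non-adjacent
    segments (Gauss map quadrilateral).  ``closed`` appends the segment from
    the last vertex back to the first.
    """
    n = verts.shape[0]
    n_seg = n if closed else n - 1
    total = 0.0
    for i in range(n_seg - 1):
        p1x = verts[i, 0]
        p1y = verts[i, 1]
        p1z = verts[i, 2]
        i2 = (i + 1) % n
        p2x = verts[i2, 0]
        p2y = verts[i2, 1]
        p2z = verts[i2, 2]
        for j in range(i + 2, n_seg):
            if closed and i == 0 and j == n_seg - 1:
                continue  # adjacent through the closure
            p3x = verts[j, 0]
            p3y = verts[j, 1]
            p3z = verts[j, 2]
            j2 = (j + 1) % n
            p4x = verts[j2, 0]
            p4y = verts[j2, 1]
            p4z = verts[j2, 2]

            r13x = p3x - p1x
            r13y = p3y - p1y
            r13z = p3z - p1z
            r14x = p4x - p1x
            r14y = p4y - p1y
            r14z = p4z - p1z
            r23x = p3x - p2x
            r23y = p3y - p2y
            r23z = p3z - p2z
            r24x = p4x - p2x
            r24y = p4y - p2y
            r24z = p4z - p2z

            n1x = r13y * r14z - r13z * r14y
            n1y = r13z * r14x - r13x * r14z
            n1z = r13x * r14y - r13y * r14x
            n2x = r14y * r24z - r14z * r24y
            n2y = r14z * r24x - r14x * r24z
            n2z = r14x * r24y - r14y * r24x
            n3x = r24y * r23z - r24z * r23y
            n3y = r24z * r23x - r24x * r23z
            n3z = r24x * r23y - r24y * r23x
            n4x = r23y * r13z - r23z * r13y
            n4y = r23z * r13x - r23x * r13z
            n4z = r23x * r13y - r23y * r13x

            l1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            l2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            l3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            l4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if l1 < 1e-14 or l2 < 1e-14 or l3 < 1e-14 or l4 < 1e-14:
                continue  # coplanar pair contributes zero

            i1 = 1.0 / l1
            i2n = 1.0 / l2
            i3 = 1.0 / l3
            i4 = 1.0 / l4
            d12 = (n1x * n2x + n1y * n2y + n1z * n2z) * i1 * i2n
            d23 = (n2x * n3x + n2y * n3y + n2z * n3z) * i2n * i3
            d34 = (n3x * n4x + n3y * n4y + n3z * n4z) * i3 * i4
            d41 = (n4x * n1x + n4y * n1y + n4z * n1z) * i4 * i1
            if d12 > 1.0:
                d12 = 1.0
            elif d12 < -1.0:
                d12 = -1.0
            if d23 > 1.0:
                d23 = 1.0
            elif d23 < -1.0:
                d23 = -1.0
            if d34 > 1.0:
                d34 = 1.0
            elif d34 < -1.0:
                d34 = -1.0
            if d41 > 1.0:
                d41 = 1.0
            elif d41 < -1.0:
                d41 = -1.0
            omega = (
                math.asin(d12) + math.asin(d23) + math.asin(d34) + math.asin(d41)
            )

            r12x = p2x - p1x
            r12y = p2y - p1y
            r12z = p2z - p1z
            r34x = p4x - p3x
            r34y = p4y - p3y
            r34z = p4z - p3z
            cx = r34y * r12z - r34z * r12y
            cy = r34z * r12x - r34x * r12z
            cz = r34x * r12y - r34y * r12x
            sgn = cx * r13x + cy * r13y + cz * r13z
            if sgn > 0.0:
                total += omega
            elif sgn < 0.0:
                total -= omega
    return total / (2.0 * math.pi)
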