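"""Numba-compiled Brownian-dynamics core.

Everything in the system is represented as a rigid body of one or more
disks: a free membrane disk is a single-disk body without rotational degree
of freedom, a rod is an m-disk body obeying the rotational equation of
motion, and in rigid-kink mode the kink triplet is a three-disk body.
Disk indexing matches the reference implementation: membrane ring disks
0..N_v-1 first, then rod constituent disks in rod order, so the bonded
(FENE/angle) index lists can address membrane disks directly even when some
of them belong to a rigid body.

The pair loop runs over a Verlet list (cutoff + skin) rebuilt whenever any
disk has moved more than skin/2 since the last build; the list must agree
with an all-pairs sweep to roundoff, which the test suite checks against
:func:`kinkvesicle.forcefield.evaluate_forces`.

Noise is pre-generated per chunk as standard normals (numpy SFC64 stream,
one stream per replica) and scaled inside the kernel, which keeps the
trajectory bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# error codes returned by run_chunk
ERR_OK = 0
ERR_OVERSTRETCH = 1
ERR_NONFINITE = 2
ERR_OVERLAP = 3

RC = 2.0 ** (1.0 / 6.0)


@njit(cache=False, fastmath=True)
def _build_pairs(pos, disk_body, r_list2, pair_i, pair_j):
    nd = pos.shape[0]
    n = 0
    for i in range(nd - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        bi = disk_body[i]
        for j in range(i + 1, nd):
            if disk_body[j] == bi:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 < r_list2:
                if n >= pair_i.shape[0]:
                    return -1
                pair_i[n] = i
                pair_j[n] = j
                n += 1
    return n


@njit(cache=False, fastmath=True)
def run_chunk(
    # bodies
    cen, theta, img, gam_t, gam_r, rotates, f_act,
    # disks
    disk_body, loc, pos, pos_ref,
    # bonded terms (disk indices)
    bond_i, bond_j, kappa_b, r0,
    ang_i, ang_k, ang_l, ang_theta0, ang_kappa, kink_aidx, dtheta_step,
    # parameters
    eps, sigma, box, dt, kT,
    # noise: (nsteps, 2*nb + nrot) standard normals, or (1,1) when kT == 0
    noise, rot_body,
    # workspaces
    pair_i, pair_j, forces,
    nsteps,
):
    """Advance the packed system by ``nsteps`` Euler-Maruyama steps.

    Returns (err_code, err_index, n_pairs, e_wca, e_fene, e_angle,
    n_capped) where the
    energies are those of the final evaluated step. The box is periodic:
    body centres are wrapped into [0, box) with image counts in ``img``;
    disk positions are kept unwrapped relative to their body centre so that
    rigid-body offsets are exact, and pair terms use the minimum image.
    """
    nb = cen.shape[0]
    nd = pos.shape[0]
    nrot = rot_body.shape[0]
    use_noise = kT > 0.0
    half_box = 0.5 * box
    r_list2 = 0.0
    skin = 0.4 * sigma
    rcut = RC * sigma
    r_list = rcut + skin
    r_list2 = r_list * r_list
    rc2 = rcut * rcut
    half_skin2 = (0.5 * skin) * (0.5 * skin)
    r02 = r0 * r0

    n_pairs = -1  # force initial build
    e_wca = 0.0
    e_fene = 0.0
    e_angle = 0.0
    cap = 0.05 * sigma
    cap2 = cap * cap
    cap_rot = 0.05
    n_capped = 0
    guard = 0.92 * r0  # capped steps move a bond at most +0.1 sigma, staying < r0
    guard2 = guard * guard

    amp_t = np.empty(nb)
    amp_r = np.empty(nrot)
    for b in range(nb):
        amp_t[b] = np.sqrt(2.0 * kT * dt / gam_t[b])
    for k in range(nrot):
        amp_r[k] = np.sqrt(2.0 * kT * dt / gam_r[rot_body[k]])

    bfx = np.zeros(nb)
    bfy = np.zeros(nb)
    btq = np.zeros(nb)

    for step in range(nsteps):
        want_energy = step == nsteps - 1
        # ---- disk positions from body coordinates -----------------------
        for d in range(nd):
            b = disk_body[d]
            if rotates[b] == 1:
                c = np.cos(theta[b])
                s = np.sin(theta[b])
                pos[d, 0] = cen[b, 0] + c * loc[d, 0] - s * loc[d, 1]
                pos[d, 1] = cen[b, 1] + s * loc[d, 0] + c * loc[d, 1]
            else:
                pos[d, 0] = cen[b, 0] + loc[d, 0]
                pos[d, 1] = cen[b, 1] + loc[d, 1]

        # ---- neighbour list maintenance ---------------------------------
        rebuild = n_pairs < 0
        if not rebuild:
            for d in range(nd):
                dx = pos[d, 0] - pos_ref[d, 0]
                dy = pos[d, 1] - pos_ref[d, 1]
                # min-image: a wrap jump just forces a harmless rebuild
                if dx > half_box:
                    dx -= box
                elif dx < -half_box:
                    dx += box
                if dy > half_box:
                    dy -= box
                elif dy < -half_box:
                    dy += box
                if dx * dx + dy * dy > half_skin2:
                    rebuild = True
                    break
        if rebuild:
            n_pairs = _build_pairs(pos, disk_body, r_list2, pair_i, pair_j)
            if n_pairs < 0:
                return ERR_NONFINITE, -1, 0, 0.0, 0.0, 0.0, n_capped
            for d in range(nd):
                pos_ref[d, 0] = pos[d, 0]
                pos_ref[d, 1] = pos[d, 1]

        # ---- forces ------------------------------------------------------
        for d in range(nd):
            forces[d, 0] = 0.0
            forces[d, 1] = 0.0
        if want_energy:
            e_wca = 0.0
            e_fene = 0.0
            e_angle = 0.0

        # WCA over the pair list
        for p in range(n_pairs):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx > half_box:
                dx -= box
            elif dx < -half_box:
                dx += box
            if dy > half_box:
                dy -= box
            elif dy < -half_box:
                dy += box
            r2 = dx * dx + dy * dy
            if r2 < rc2:
                if r2 < 1.0e-24:
                    return ERR_OVERLAP, i, n_pairs, 0.0, 0.0, 0.0, n_capped
                s2 = sigma * sigma / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                if want_energy:
                    e_wca += 4.0 * eps * (s6 * s6 - s6) + eps

        # FENE bonds
        for p in range(bond_i.shape[0]):
            i = bond_i[p]
            j = bond_j[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx > half_box:
                dx -= box
            elif dx < -half_box:
                dx += box
            if dy > half_box:
                dy -= box
            elif dy < -half_box:
                dy += box
            r2 = dx * dx + dy * dy
            if r2 >= r02:
                return ERR_OVERSTRETCH, p, n_pairs, 0.0, 0.0, 0.0, n_capped
            x2 = r2 / r02
            fr = -kappa_b / (1.0 - x2)
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            if want_energy:
                e_fene += -0.5 * kappa_b * r02 * np.log(1.0 - x2)

        # harmonic angle terms
        for p in range(ang_i.shape[0]):
            i = ang_i[p]
            k = ang_k[p]
            l = ang_l[p]
            ax = pos[i, 0] - pos[k, 0]
            ay = pos[i, 1] - pos[k, 1]
            bx = pos[l, 0] - pos[k, 0]
            by = pos[l, 1] - pos[k, 1]
            if ax > half_box:
                ax -= box
            elif ax < -half_box:
                ax += box
            if ay > half_box:
                ay -= box
            elif ay < -half_box:
                ay += box
            if bx > half_box:
                bx -= box
            elif bx < -half_box:
                bx += box
            if by > half_box:
                by -= box
            elif by < -half_box:
                by += box
            ra = np.sqrt(ax * ax + ay * ay)
            rb = np.sqrt(bx * bx + by * by)
            cosq = (ax * bx + ay * by) / (ra * rb)
            if cosq > 1.0:
                cosq = 1.0
            elif cosq < -1.0:
                cosq = -1.0
            th = np.arccos(cosq)
            th0 = ang_theta0[p]
            kap = ang_kappa[p]
            sinq = np.sqrt(max(0.0, 1.0 - cosq * cosq))
            if sinq >= 1.0e-8:
                coeff = kap * (th - th0) / sinq
            elif abs(th - th0) < 1.0e-6:
                coeff = -kap if cosq < 0.0 else kap
            else:
                coeff = kap * (th - th0) / 1.0e-8
            iax = ax / ra
            iay = ay / ra
            ibx = bx / rb
            iby = by / rb
            fix = coeff * (ibx - cosq * iax) / ra
            fiy = coeff * (iby - cosq * iay) / ra
            flx = coeff * (iax - cosq * ibx) / rb
            fly = coeff * (iay - cosq * iby) / rb
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[l, 0] += flx
            forces[l, 1] += fly
            forces[k, 0] -= fix + flx
            forces[k, 1] -= fiy + fly
            if want_energy:
                e_angle += 0.5 * kap * (th - th0) * (th - th0)

        # ---- reduce to bodies and integrate ------------------------------
        for b in range(nb):
            bfx[b] = 0.0
            bfy[b] = 0.0
            btq[b] = 0.0
        for d in range(nd):
            b = disk_body[d]
            fx = forces[d, 0]
            fy = forces[d, 1]
            bfx[b] += fx
            bfy[b] += fy
            if rotates[b] == 1:
                ox = pos[d, 0] - cen[b, 0]
                oy = pos[d, 1] - cen[b, 1]
                btq[b] += ox * fy - oy * fx
        for b in range(nb):
            if rotates[b] == 1 and f_act[b] != 0.0:
                bfx[b] += f_act[b] * np.cos(theta[b])
                bfy[b] += f_act[b] * np.sin(theta[b])

        for b in range(nb):
            dx = bfx[b] / gam_t[b] * dt
            dy = bfy[b] / gam_t[b] * dt
            if use_noise:
                dx += amp_t[b] * noise[step, 2 * b]
                dy += amp_t[b] * noise[step, 2 * b + 1]
            # displacement cap: typical steps are ~1e-3 sigma; a step beyond
            # 0.05 sigma can only come from a numerical force spike (deep
            # collision overlap) and would blow through the FENE barrier
            d2 = dx * dx + dy * dy
            if d2 > cap2:
                scale_cap = cap / np.sqrt(d2)
                dx *= scale_cap
                dy *= scale_cap
                n_capped += 1
            nx = cen[b, 0] + dx
            ny = cen[b, 1] + dy
            if not (np.isfinite(nx) and np.isfinite(ny)):
                return ERR_NONFINITE, b, n_pairs, 0.0, 0.0, 0.0, n_capped
            if nx >= box:
                nx -= box
                img[b, 0] += 1
            elif nx < 0.0:
                nx += box
                img[b, 0] -= 1
            if ny >= box:
                ny -= box
                img[b, 1] += 1
            elif ny < 0.0:
                ny += box
                img[b, 1] -= 1
            cen[b, 0] = nx
            cen[b, 1] = ny
        for k in range(nrot):
            b = rot_body[k]
            dth = btq[b] / gam_r[b] * dt
            if use_noise:
                dth += amp_r[k] * noise[step, 2 * nb + k]
            if dth > cap_rot:
                dth = cap_rot
                n_capped += 1
            elif dth < -cap_rot:
                dth = -cap_rot
                n_capped += 1
            theta[b] += dth

        # FENE guard: the continuum bond can never reach r0 (the potential
        # diverges), but the Euler step is unstable near the divergence and
        # can jump across it. Project over-stretched bonds back to the
        # guard length (both endpoints symmetrically, free disks only).
        for p in range(bond_i.shape[0]):
            i = bond_i[p]
            j = bond_j[p]
            bi = disk_body[i]
            bj = disk_body[j]
            if rotates[bi] == 1 or rotates[bj] == 1:
                continue        # rigid-body junction bonds are not projected
            dx = cen[bi, 0] - cen[bj, 0]
            dy = cen[bi, 1] - cen[bj, 1]
            if dx > half_box:
                dx -= box
            elif dx < -half_box:
                dx += box
            if dy > half_box:
                dy -= box
            elif dy < -half_box:
                dy += box
            r2 = dx * dx + dy * dy
            if r2 > guard2:
                r = np.sqrt(r2)
                pull = 0.5 * (r - guard) / r
                cen[bi, 0] -= pull * dx
                cen[bi, 1] -= pull * dy
                cen[bj, 0] += pull * dx
                cen[bj, 1] += pull * dy
                n_capped += 1

        # kink-angle ramp (rest angle moves every step during a ramp)
        if kink_aidx >= 0 and dtheta_step != 0.0:
            ang_theta0[kink_aidx] += dtheta_step

    return ERR_OK, -1, n_pairs, e_wca, e_fene, e_angle, n_capped
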