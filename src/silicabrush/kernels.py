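"""Numba kernels: cell-list neighbour search, forces, Brownian updates.

These mirror the scalar reference model in :mod:`silicabrush.forcefield`
exactly (same WCA / screened-Coulomb / switched-attraction forms); the test
suite cross-checks the two paths to 1e-10 relative on random systems.

Conventions baked into the kernels:

* orthorhombic box anchored at the origin; per-axis flag selects periodic
  (minimum image + wrap) or reflecting walls;
* the pair list stores every pair within cutoff + skin involving at least
  one mobile bead (optionally all pairs), excluding directly bonded pairs;
* rebuilds are triggered when any mobile bead has moved more than skin/2
  since the last build.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ROOT6_2 = 2.0 ** (1.0 / 6.0)

# status codes returned by advance()
STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_OVERFLOW = 2


@njit(cache=True, inline="always")
def _switch(r, r_on, r_off):
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    r2 = r * r
    on2 = r_on * r_on
    off2 = r_off * r_off
    denom = (off2 - on2) ** 3
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / denom
    ds = 12.0 * r * (off2 - r2) * (on2 - r2) / denom
    return s, ds


@njit(cache=True, inline="always")
def _pair_u_du(r, qq, contact, att_eps, wca_eps, lb, ld, cutoff, switch_frac, att_range):
    """Nonbonded energy and dU/dr for one pair (mirrors forcefield reference)."""
    if r >= cutoff:
        return 0.0, 0.0
    u = 0.0
    du = 0.0
    if wca_eps > 0.0 and r < contact:
        sigma = contact / _ROOT6_2
        sr6 = (sigma / r) ** 6
        u += 4.0 * wca_eps * (sr6 * sr6 - sr6) + wca_eps
        du += -24.0 * wca_eps * (2.0 * sr6 * sr6 - sr6) / r
    if qq != 0.0:
        u0 = lb * qq * np.exp(-r / ld) / r
        du0 = -u0 * (1.0 / r + 1.0 / ld)
        s, ds = _switch(r, switch_frac * cutoff, cutoff)
        u += u0 * s
        du += du0 * s + u0 * ds
    if att_eps > 0.0:
        r_off = contact + att_range
        if r < r_off:
            if r <= contact:
                u += -att_eps
            else:
                sigma = contact / _ROOT6_2
                sr6 = (sigma / r) ** 6
                u0 = 4.0 * att_eps * (sr6 * sr6 - sr6)
                du0 = -24.0 * att_eps * (2.0 * sr6 * sr6 - sr6) / r
                r_on = contact + switch_frac * att_range
                s, ds = _switch(r, r_on, r_off)
                u += u0 * s
                du += du0 * s + u0 * ds
    return u, du


@njit(cache=True, inline="always")
def _min_image(d, box_l, periodic, ax):
    # branch form: valid because |d| < 1.5 L for in-box coordinates
    if periodic[ax]:
        L = box_l[ax]
        if d > 0.5 * L:
            d -= L
        elif d < -0.5 * L:
            d += L
    return d


@njit(cache=True)
def _excluded(excl_code, code):
    """Binary search for code in the sorted exclusion array."""
    lo = 0
    hi = excl_code.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        v = excl_code[mid]
        if v == code:
            return True
        if v < code:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True, fastmath=True)
def build_pairs(pos, box_l, periodic, rlist, mobile, include_fixed_pairs,
                excl_code, charge, radius, species, att_mat,
                pair_i, pair_j, pair_qq, pair_contact, pair_att):
    """Fill pair arrays with all pairs within rlist; return count or -1 on overflow.

    Besides the indices, per-pair charge products, contact distances and
    attraction depths are cached so the force loop reads positions only.
    Uses a linked-cell grid when the box supports it, otherwise falls back to
    an all-pairs scan (small systems).
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    rlist2 = rlist * rlist

    nc = np.empty(3, dtype=np.int64)
    for ax in range(3):
        nc[ax] = max(1, int(box_l[ax] / rlist)) if rlist > 0.0 else 1
    use_cells = n > 256 and rlist > 0.0
    for ax in range(3):
        if periodic[ax] and nc[ax] < 3:
            use_cells = False

    count = 0
    if not use_cells:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if not include_fixed_pairs and not (mobile[i] or mobile[j]):
                    continue
                r2 = 0.0
                for ax in range(3):
                    d = _min_image(pos[i, ax] - pos[j, ax], box_l, periodic, ax)
                    r2 += d * d
                if r2 < rlist2 and not _excluded(excl_code, i * n + j):
                    if count >= cap:
                        return -1
                    pair_i[count] = i
                    pair_j[count] = j
                    pair_qq[count] = charge[i] * charge[j]
                    pair_contact[count] = radius[i] + radius[j]
                    pair_att[count] = att_mat[species[i], species[j]]
                    count += 1
        return count

    ncells = nc[0] * nc[1] * nc[2]
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_ix = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        for ax in range(3):
            c = int(pos[i, ax] / box_l[ax] * nc[ax])
            if c < 0:
                c = 0
            if c >= nc[ax]:
                c = nc[ax] - 1
            cell_ix[i, ax] = c
        cid = (cell_ix[i, 0] * nc[1] + cell_ix[i, 1]) * nc[2] + cell_ix[i, 2]
        nxt[i] = head[cid]
        head[cid] = i

    for i in range(n):
        # when fixed-fixed pairs are not wanted, traverse from mobile beads
        # only: pair (i mobile, j fixed) is kept for any j, (i, j) both
        # mobile deduplicated by j > i
        if not include_fixed_pairs and not mobile[i]:
            continue
        cx = cell_ix[i, 0]
        cy = cell_ix[i, 1]
        cz = cell_ix[i, 2]
        for dx in range(-1, 2):
            gx = cx + dx
            if periodic[0]:
                gx %= nc[0]
            elif gx < 0 or gx >= nc[0]:
                continue
            for dy in range(-1, 2):
                gy = cy + dy
                if periodic[1]:
                    gy %= nc[1]
                elif gy < 0 or gy >= nc[1]:
                    continue
                for dz in range(-1, 2):
                    gz = cz + dz
                    if periodic[2]:
                        gz %= nc[2]
                    elif gz < 0 or gz >= nc[2]:
                        continue
                    cid = (gx * nc[1] + gy) * nc[2] + gz
                    j = head[cid]
                    while j >= 0:
                        if include_fixed_pairs:
                            take = j > i
                        elif mobile[j]:
                            take = j > i
                        else:
                            take = True  # i mobile, j fixed: unique traversal
                        if take:
                            r2 = 0.0
                            for ax in range(3):
                                d = _min_image(pos[i, ax] - pos[j, ax],
                                               box_l, periodic, ax)
                                r2 += d * d
                            if r2 < rlist2:
                                a = i if i < j else j
                                b = j if i < j else i
                                if not _excluded(excl_code, a * n + b):
                                    if count >= cap:
                                        return -1
                                    pair_i[count] = a
                                    pair_j[count] = b
                                    pair_qq[count] = charge[a] * charge[b]
                                    pair_contact[count] = radius[a] + radius[b]
                                    pair_att[count] = att_mat[species[a], species[b]]
                                    count += 1
                        j = nxt[j]
    return count


@njit(cache=True)
def compute_forces(pos, box_l, periodic,
                   wca_eps, lb, ld, cutoff, switch_frac, att_range,
                   pair_i, pair_j, pair_qq, pair_contact, pair_att, n_pairs,
                   bond_i, bond_j, bond_r0, bond_k,
                   ang_i, ang_j, ang_k, ang_t0, ang_kap,
                   forces):
    """Accumulate all forces into `forces` (zeroed here); returns total energy."""
    n = pos.shape[0]
    for i in range(n):
        for ax in range(3):
            forces[i, ax] = 0.0
    energy = 0.0
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = _min_image(pos[i, 0] - pos[j, 0], box_l, periodic, 0)
        dy = _min_image(pos[i, 1] - pos[j, 1], box_l, periodic, 1)
        dz = _min_image(pos[i, 2] - pos[j, 2], box_l, periodic, 2)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff or r2 <= 0.0:
            continue
        r = np.sqrt(r2)
        u, du = _pair_u_du(r, pair_qq[p], pair_contact[p], pair_att[p],
                           wca_eps, lb, ld, cutoff, switch_frac, att_range)
        energy += u
        f = -du / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = _min_image(pos[i, 0] - pos[j, 0], box_l, periodic, 0)
        dy = _min_image(pos[i, 1] - pos[j, 1], box_l, periodic, 1)
        dz = _min_image(pos[i, 2] - pos[j, 2], box_l, periodic, 2)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += 0.5 * bond_k[b] * dr * dr
        f = -bond_k[b] * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        u1x = _min_image(pos[i, 0] - pos[j, 0], box_l, periodic, 0)
        u1y = _min_image(pos[i, 1] - pos[j, 1], box_l, periodic, 1)
        u1z = _min_image(pos[i, 2] - pos[j, 2], box_l, periodic, 2)
        u2x = _min_image(pos[k, 0] - pos[j, 0], box_l, periodic, 0)
        u2y = _min_image(pos[k, 1] - pos[j, 1], box_l, periodic, 1)
        u2z = _min_image(pos[k, 2] - pos[j, 2], box_l, periodic, 2)
        n1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
        n2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
        c = (u1x * u2x + u1y * u2y + u1z * u2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - ang_t0[a]
        energy += 0.5 * ang_kap[a] * dth * dth
        s2 = 1.0 - c * c
        if s2 < 1e-12:
            s2 = 1e-12
        coef = ang_kap[a] * dth / np.sqrt(s2)
        fix = coef * (u2x / (n1 * n2) - c * u1x / (n1 * n1))
        fiy = coef * (u2y / (n1 * n2) - c * u1y / (n1 * n1))
        fiz = coef * (u2z / (n1 * n2) - c * u1z / (n1 * n1))
        fkx = coef * (u1x / (n1 * n2) - c * u2x / (n2 * n2))
        fky = coef * (u1y / (n1 * n2) - c * u2y / (n2 * n2))
        fkz = coef * (u1z / (n1 * n2) - c * u2z / (n2 * n2))
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return energy


@njit(cache=True)
def advance(pos, box_l, periodic, charge, radius, species, att_mat,
            wca_eps, lb, ld, cutoff, switch_frac, att_range,
            bond_i, bond_j, bond_r0, bond_k,
            ang_i, ang_j, ang_k, ang_t0, ang_kap,
            mobile, mobile_idx, inv_gamma, noise, dt, skin,
            excl_code, pair_i, pair_j, pair_qq, pair_contact, pair_att,
            state_npairs, ref_pos, forces, max_step_disp, max_force_disp):
    """Run len(noise) Brownian steps in place; returns (steps_done, status).

    ``state_npairs`` is a 1-element array carrying the current pair count
    (−1 forces a rebuild); ``ref_pos`` holds positions at the last rebuild.
    """
    n_steps = noise.shape[0]
    n_mob = mobile_idx.shape[0]
    rlist = cutoff + skin
    half_skin2 = (0.5 * skin) ** 2
    sqrt2dt = np.sqrt(2.0 * dt)
    for step in range(n_steps):
        # displacement-triggered rebuild
        need = state_npairs[0] < 0
        if not need:
            for m in range(n_mob):
                i = mobile_idx[m]
                d2 = 0.0
                for ax in range(3):
                    d = _min_image(pos[i, ax] - ref_pos[i, ax], box_l, periodic, ax)
                    d2 += d * d
                if d2 > half_skin2:
                    need = True
                    break
        if need:
            cnt = build_pairs(pos, box_l, periodic, rlist, mobile, False,
                              excl_code, charge, radius, species, att_mat,
                              pair_i, pair_j, pair_qq, pair_contact, pair_att)
            if cnt < 0:
                return step, STATUS_OVERFLOW
            state_npairs[0] = cnt
            for i in range(pos.shape[0]):
                for ax in range(3):
                    ref_pos[i, ax] = pos[i, ax]
        compute_forces(pos, box_l, periodic,
                       wca_eps, lb, ld, cutoff, switch_frac, att_range,
                       pair_i, pair_j, pair_qq, pair_contact, pair_att,
                       state_npairs[0],
                       bond_i, bond_j, bond_r0, bond_k,
                       ang_i, ang_j, ang_k, ang_t0, ang_kap, forces)
        for m in range(n_mob):
            i = mobile_idx[m]
            ig = inv_gamma[m]
            amp = sqrt2dt * np.sqrt(ig)
            for ax in range(3):
                # the deterministic displacement is clamped: the clamp can
                # only engage deep inside an excluded-volume core, where the
                # equilibrium weight is negligible, and prevents Euler
                # overshoot through the steep repulsion
                dxf = dt * ig * forces[i, ax]
                if dxf > max_force_disp:
                    dxf = max_force_disp
                elif dxf < -max_force_disp:
                    dxf = -max_force_disp
                dxm = dxf + amp * noise[step, m, ax]
                if dxm > max_step_disp or dxm < -max_step_disp:
                    return step, STATUS_UNSTABLE
                x = pos[i, ax] + dxm
                L = box_l[ax]
                if periodic[ax]:
                    if x >= L:
                        x -= L
                    elif x < 0.0:
                        x += L
                else:
                    if x < 0.0:
                        x = -x
                    if x > L:
                        x = 2.0 * L - x
                pos[i, ax] = x
    return n_steps, STATUS_OK
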