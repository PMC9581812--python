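"""Numba kernels: neighbor search, forces, and the Langevin integrator.

All kernels work in reduced units on flat numpy arrays; the object layer in
:mod:`engine` prepares the arrays and owns the preallocated workspaces.
Error signalling is via integer codes (0 ok, 1 FENE overextension,
2 pair-buffer overflow) because numba cannot raise rich exceptions.

Pair distances are clamped at ``r_floor_frac * b`` before evaluating the
r^-12 repulsion so that transient overlaps during the ramped-timestep
equilibration produce a large-but-finite push instead of an overflow.

The neighbor list is a Verlet list (cutoff + skin) filled either by a cell
decomposition or an all-pairs scan; per-pair WCA diameters and attraction
widths are precomputed at build time so the force loop reads contiguous
arrays.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ERR_OK = 0
ERR_FENE = 1
ERR_OVERFLOW = 2

_RT2 = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _is_excluded(i, j, mol_ids, excl_intra):
    # nonbonded exclusions: all pairs within the same near-rigid molecule
    # (the peptide); lipid intramolecular WCA stays on (FENE + WCA bonds)
    return excl_intra[i] == 1 and mol_ids[i] == mol_ids[j]


@njit(cache=True, fastmath=True)
def build_pairs_n2(pos, box, rlist, mol_ids, excl_intra,
                   types, b_tab, wc_tab, pi, pj, pb, pwc):
    """All-pairs candidate list under minimum image.

    Fills the preallocated buffers and returns the pair count, or -1 on
    overflow.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    cap = pi.shape[0]
    k = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx > 0.5 * box:
                dx -= box
            elif dx < -0.5 * box:
                dx += box
            if dy > 0.5 * box:
                dy -= box
            elif dy < -0.5 * box:
                dy += box
            if dz > 0.5 * box:
                dz -= box
            elif dz < -0.5 * box:
                dz += box
            if dx * dx + dy * dy + dz * dz <= rl2:
                if not _is_excluded(i, j, mol_ids, excl_intra):
                    if k >= cap:
                        return -1
                    pi[k] = i
                    pj[k] = j
                    pb[k] = b_tab[types[i], types[j]]
                    pwc[k] = wc_tab[types[i], types[j]]
                    k += 1
    return k


@njit(cache=True, fastmath=True)
def build_pairs_cell(pos, box, rlist, mol_ids, excl_intra,
                     types, b_tab, wc_tab,
                     cell_counts, cell_order, cell_of,
                     pi, pj, pb, pwc):
    """Cell-list candidate pairs; requires box >= 3 * rlist.

    ``cell_counts`` must have at least m^3 + 1 entries for m = box // rlist.
    Returns the pair count, or -1 on overflow.
    """
    n = pos.shape[0]
    m = int(box / rlist)
    rl2 = rlist * rlist
    ncell = m * m * m
    for c in range(ncell + 1):
        cell_counts[c] = 0
    for i in range(n):
        x = pos[i, 0] - box * math.floor(pos[i, 0] / box)
        y = pos[i, 1] - box * math.floor(pos[i, 1] / box)
        z = pos[i, 2] - box * math.floor(pos[i, 2] / box)
        ix = min(int(x / box * m), m - 1)
        iy = min(int(y / box * m), m - 1)
        iz = min(int(z / box * m), m - 1)
        c = (ix * m + iy) * m + iz
        cell_of[i] = c
        cell_counts[c + 1] += 1
    for c in range(ncell):
        cell_counts[c + 1] += cell_counts[c]
    fill = np.zeros(ncell, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        cell_order[cell_counts[c] + fill[c]] = i
        fill[c] += 1

    cap = pi.shape[0]
    k = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        c = cell_of[i]
        cz = c % m
        cy = (c // m) % m
        cx = c // (m * m)
        for ox in range(-1, 2):
            jx = (cx + ox) % m
            for oy in range(-1, 2):
                jy = (cy + oy) % m
                for oz in range(-1, 2):
                    jz = (cz + oz) % m
                    cc = (jx * m + jy) * m + jz
                    for s in range(cell_counts[cc], cell_counts[cc + 1]):
                        j = cell_order[s]
                        if j <= i:
                            continue
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        if dx > 0.5 * box:
                            dx -= box
                        elif dx < -0.5 * box:
                            dx += box
                        if dy > 0.5 * box:
                            dy -= box
                        elif dy < -0.5 * box:
                            dy += box
                        if dz > 0.5 * box:
                            dz -= box
                        elif dz < -0.5 * box:
                            dz += box
                        if dx * dx + dy * dy + dz * dz <= rl2:
                            if not _is_excluded(i, j, mol_ids,
                                                excl_intra):
                                if k >= cap:
                                    return -1
                                pi[k] = i
                                pj[k] = j
                                pb[k] = b_tab[types[i], types[j]]
                                pwc[k] = wc_tab[types[i], types[j]]
                                k += 1
    return k


@njit(cache=True, fastmath=True)
def compute_forces(pos, box, eps, pi, pj, pb, pwc, npairs,
                   fene_i, fene_j, k_fene, r_inf,
                   harm_i, harm_j, harm_r0, harm_k,
                   r_floor_frac, forces):
    """Total potential energy and per-bead forces (overwrites ``forces``)."""
    forces[:] = 0.0
    energy = 0.0
    err = ERR_OK

    # nonbonded: WCA + broadened cosine^2 attraction
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * box:
            dx -= box
        elif dx < -0.5 * box:
            dx += box
        if dy > 0.5 * box:
            dy -= box
        elif dy < -0.5 * box:
            dy += box
        if dz > 0.5 * box:
            dz -= box
        elif dz < -0.5 * box:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        b = pb[p]
        wc = pwc[p]
        rc = _RT2 * b
        outer = rc + wc
        if r2 > outer * outer:
            continue
        r = math.sqrt(r2)
        rf = r_floor_frac * b
        if r < rf:
            r = rf
        if r <= rc:
            x2 = (b / r) * (b / r)
            x6 = x2 * x2 * x2
            energy += 4.0 * eps * (x6 * x6 - x6 + 0.25)
            dvdr = 4.0 * eps * (6.0 * x6 - 12.0 * x6 * x6) / r
            if wc > 0.0:
                energy -= eps
        else:
            u = math.pi * (r - rc) / (2.0 * wc)
            c = math.cos(u)
            energy -= eps * c * c
            dvdr = eps * math.pi / (2.0 * wc) * math.sin(2.0 * u)
        g = -dvdr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # FENE bonds
    for p in range(fene_i.shape[0]):
        i = fene_i[p]
        j = fene_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * box:
            dx -= box
        elif dx < -0.5 * box:
            dx += box
        if dy > 0.5 * box:
            dy -= box
        elif dy < -0.5 * box:
            dy += box
        if dz > 0.5 * box:
            dz -= box
        elif dz < -0.5 * box:
            dz += box
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = r / r_inf
        if x >= 1.0:
            err = ERR_FENE
            continue
        energy += -0.5 * k_fene * r_inf * r_inf * math.log(1.0 - x * x)
        dvdr = k_fene * r / (1.0 - x * x)
        g = -dvdr / r if r > 1e-12 else 0.0
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # harmonic bonds (lipid straightening + peptide elastic network)
    for p in range(harm_i.shape[0]):
        i = harm_i[p]
        j = harm_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * box:
            dx -= box
        elif dx < -0.5 * box:
            dx += box
        if dy > 0.5 * box:
            dy -= box
        elif dy < -0.5 * box:
            dy += box
        if dz > 0.5 * box:
            dz -= box
        elif dz < -0.5 * box:
            dz += box
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - harm_r0[p]
        energy += 0.5 * harm_k[p] * dr * dr
        g = -harm_k[p] * dr / r if r > 1e-12 else 0.0
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    return energy, err


@njit(cache=True, fastmath=True)
def integrate_chunk(pos, vel, forces, pos0, box, types, b_tab, wc_tab, eps,
                    pi, pj, pb, pwc, npairs,
                    fene_i, fene_j, k_fene, r_inf,
                    harm_i, harm_j, harm_r0, harm_k,
                    mol_ids, excl_intra,
                    cell_counts, cell_order, cell_of,
                    noise, dt, c1, c2, mass, rlist, skin,
                    r_floor_frac, use_cell,
                    ke_out, pe_out):
    """BAOAB Langevin steps, updating ``pos``/``vel``/``forces`` in place.

    ``pos0`` holds positions at the last neighbor-list build; the list is
    rebuilt (and positions wrapped) whenever any bead has moved more than
    ``skin / 2`` since then.  ``noise`` has shape (nsteps, n, 3); with the
    thermostat off (c1 = 1, c2 = 0) the scheme reduces to velocity Verlet.
    Returns (pair count, error code, number of rebuilds).
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt
    inv_m = 1.0 / mass
    err = ERR_OK
    rebuilds = 0
    thresh2 = 0.25 * skin * skin
    thermostat = c2 != 0.0 or c1 != 1.0

    for s in range(nsteps):
        # B (half kick) + A (half drift)
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            vel[i, 2] += half * forces[i, 2] * inv_m
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # O (Ornstein-Uhlenbeck) + A (half drift)
        if thermostat:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[s, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[s, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[s, i, 2]
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # refresh neighbor list if any bead moved more than skin/2
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos0[i, 0]
            dy = pos[i, 1] - pos0[i, 1]
            dz = pos[i, 2] - pos0[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > thresh2:
            for i in range(n):
                pos[i, 0] -= box * math.floor(pos[i, 0] / box)
                pos[i, 1] -= box * math.floor(pos[i, 1] / box)
                pos[i, 2] -= box * math.floor(pos[i, 2] / box)
            if use_cell:
                npairs = build_pairs_cell(
                    pos, box, rlist, mol_ids, excl_intra, types,
                    b_tab, wc_tab, cell_counts, cell_order, cell_of,
                    pi, pj, pb, pwc)
            else:
                npairs = build_pairs_n2(
                    pos, box, rlist, mol_ids, excl_intra, types,
                    b_tab, wc_tab, pi, pj, pb, pwc)
            if npairs < 0:
                return npairs, ERR_OVERFLOW, rebuilds
            pos0[:] = pos
            rebuilds += 1
        # force at new positions, then B: half kick (+ KE tally)
        pe, ferr = compute_forces(pos, box, eps, pi, pj, pb, pwc, npairs,
                                  fene_i, fene_j, k_fene, r_inf,
                                  harm_i, harm_j, harm_r0, harm_k,
                                  r_floor_frac, forces)
        if ferr != ERR_OK:
            err = ferr
        ke = 0.0
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            vel[i, 2] += half * forces[i, 2] * inv_m
            ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        ke_out[s] = 0.5 * mass * ke
        pe_out[s] = pe
    return npairs, err, rebuilds
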