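"""Numba kernels for the dynamic Monte-Carlo evolution of the chain ensemble.

All chains carry explicit coordinates; interactions with the other chains and
the solvent enter through shell-binned mean fields that are rebuilt once per
cycle from the instantaneous bead counts, so every chain inside one cycle
sees the same fields (one SCMF field update per cycle).  Each bead couples to
the fields through its *available* square-well volume -- the well volume not
blocked by the chain's own beads -- which is what makes crumpled (hairpin)
conformations pay a smaller dehydration penalty than extended ones.  Per-bead
potentials on shell j:

    u_X(j) = avail_i * Omega (e_XP c_P + e_Xs c_s)(j) + v_p pi(j)

with Omega the full well volume and c_s, pi from the exact incompressibility
closure.  Moves are the same symmetric set as the equilibrium sampler:
sub-chain pivots about a random free joint and rigid whole-chain
translations; acceptance follows Metropolis in the energy difference
(intramolecular part exact, intermolecular part mean-field).
"""

import numpy as np
from numba import njit

HC_TOL = 1.0 - 1e-9


@njit(cache=True)
def _shell_index(r, shell_width, n_shells, r_inner):
    if r >= r_inner:
        return n_shells - 1
    j = int(r / shell_width)
    if j > n_shells - 2:
        j = n_shells - 2
    return j


@njit(cache=True)
def _lens(R, a, d):
    """Sphere-sphere intersection volume."""
    if d >= R + a:
        return 0.0
    if d <= abs(R - a):
        m = R if R < a else a
        return 4.18879020478639098 * m * m * m  # 4 pi / 3
    return (
        np.pi * (R + a - d) ** 2 * (d * d + 2.0 * d * (a + R) - 3.0 * (a - R) ** 2) / (12.0 * d)
    )


@njit(cache=True)
def _well_ball_overlap(d, well_outer, hard_core, excl):
    return _lens(well_outer, excl, d) - _lens(hard_core, excl, d)


@njit(cache=True)
def _chain_pair_scan(p, is_po, hard_core2, well_outer2, well_outer, hard_core, excl, blocked):
    """Exact intra-chain scan.

    Returns (overlap flag, EO-PO contact count); fills ``blocked`` with the
    per-bead well volume blocked by non-bonded *and* bonded chain beads.
    """
    nb = p.shape[0]
    reach = well_outer + excl
    reach2 = reach * reach
    contacts = 0
    for i in range(nb):
        blocked[i] = 0.0
    for i in range(nb):
        for j in range(i + 1, nb):
            dx = p[i, 0] - p[j, 0]
            dy = p[i, 1] - p[j, 1]
            dz = p[i, 2] - p[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if j > i + 1:
                if d2 < hard_core2:
                    return True, 0
                if d2 <= well_outer2 and (is_po[i] != is_po[j]):
                    contacts += 1
            if d2 < reach2:
                ov = _well_ball_overlap(np.sqrt(d2), well_outer, hard_core, excl)
                blocked[i] += ov
                blocked[j] += ov
    return False, contacts


@njit(cache=True)
def _field_potentials(
    counts_eo, counts_po, phi_eo, phi_po, volumes,
    omega, e_ep, e_es, e_ps, v_p, v_s,
    u_eo, u_po, u_pi,
):
    """Per-shell coupling potentials (to be scaled by each bead's available
    fraction) and the common pressure term."""
    J = counts_eo.shape[0]
    for j in range(J):
        c_eo = counts_eo[j] / volumes[j]
        c_po = counts_po[j] / volumes[j]
        phi_s = 1.0 - v_p * (c_eo + c_po)
        if phi_s < 1e-12:
            phi_s = 1e-12
        c_s = phi_s / v_s
        m_eo = omega * phi_eo[j] / volumes[j]
        m_po = omega * phi_po[j] / volumes[j]
        pi = -(np.log(phi_s) + e_es * m_eo + e_ps * m_po) / v_s
        u_eo[j] = omega * (e_ep * c_po + e_es * c_s)
        u_po[j] = omega * (e_ep * c_eo + e_ps * c_s)
        u_pi[j] = v_p * pi


@njit(cache=True)
def _chain_field_energy(p, is_po, avail, u_eo, u_po, u_pi, shell_width, n_shells, r_inner):
    e = 0.0
    for i in range(p.shape[0]):
        r = np.sqrt(p[i, 0] ** 2 + p[i, 1] ** 2 + p[i, 2] ** 2)
        j = _shell_index(r, shell_width, n_shells, r_inner)
        if is_po[i]:
            e += avail[i] * u_po[j] + u_pi[j]
        else:
            e += avail[i] * u_eo[j] + u_pi[j]
    return e


@njit(cache=True)
def _propose(p_old, p_new, seg_stops, amplitude):
    """Symmetric proposal: pivot about a random free joint or a rigid
    whole-chain translation (uniform in a ball of radius ``amplitude``)."""
    nb = p_old.shape[0]
    nseg = seg_stops.shape[0]
    for i in range(nb):
        for k in range(3):
            p_new[i, k] = p_old[i, k]
    if np.random.random() < 0.5 and nseg > 1:
        joint = np.random.randint(0, nseg - 1)
        pivot_end = seg_stops[joint]
        tail_side = np.random.random() < 0.5
        angle = (2.0 * np.random.random() - 1.0) * amplitude
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        an = np.sqrt(ax * ax + ay * ay + az * az)
        ax, ay, az = ax / an, ay / an, az / an
        c = np.cos(angle)
        s = np.sin(angle)
        C = 1.0 - c
        if tail_side:
            pidx = pivot_end - 1
            lo, hi = pivot_end, nb
        else:
            pidx = pivot_end
            lo, hi = 0, pivot_end
        px, py, pz = p_old[pidx, 0], p_old[pidx, 1], p_old[pidx, 2]
        for i in range(lo, hi):
            x = p_old[i, 0] - px
            y = p_old[i, 1] - py
            z = p_old[i, 2] - pz
            rx = (c + ax * ax * C) * x + (ax * ay * C - az * s) * y + (ax * az * C + ay * s) * z
            ry = (ay * ax * C + az * s) * x + (c + ay * ay * C) * y + (ay * az * C - ax * s) * z
            rz = (az * ax * C - ay * s) * x + (az * ay * C + ax * s) * y + (c + az * az * C) * z
            p_new[i, 0] = px + rx
            p_new[i, 1] = py + ry
            p_new[i, 2] = pz + rz
    else:
        dx = np.random.normal()
        dy = np.random.normal()
        dz = np.random.normal()
        dn = np.sqrt(dx * dx + dy * dy + dz * dz)
        step = amplitude * np.random.random() ** (1.0 / 3.0)
        dx, dy, dz = dx / dn * step, dy / dn * step, dz / dn * step
        for i in range(nb):
            p_new[i, 0] = p_old[i, 0] + dx
            p_new[i, 1] = p_old[i, 1] + dy
            p_new[i, 2] = p_old[i, 2] + dz


@njit(cache=True)
def _po_com_radius(p, is_po):
    x = 0.0
    y = 0.0
    z = 0.0
    n = 0
    for i in range(p.shape[0]):
        if is_po[i]:
            x += p[i, 0]
            y += p[i, 1]
            z += p[i, 2]
            n += 1
    return np.sqrt(x * x + y * y + z * z) / n


@njit(cache=True)
def run_dynamics(
    pos,  # (Nc, nb, 3), modified in place
    is_po,  # (nb,) bool
    seg_stops,  # (nseg,) int64
    e_contact_ep,
    e_ep,
    e_es,
    e_ps,
    v_p,
    v_s,
    omega,
    well_outer,
    hard_core,
    excl_radius,
    volumes,  # (J,)
    shell_width,
    r_inner,
    amplitude,
    r_wall,
    n_cycles,
    record_at,  # (nrec,) sorted int64 cycle indices
    tagged,  # (Nc,) bool
    inside,  # (Nc,) bool, updated with hysteresis
    r_bound,
    hysteresis,
    seed,
    prof_stride,
    prof_r,
    prof_rg,
    prof_angle,
    n_head,
    n_po,
    freeze_fields,
    u_eo,
    u_po,
    u_pi,  # (J,) work arrays; frozen potentials on entry when freeze_fields
):
    np.random.seed(seed)
    Nc, nb = pos.shape[0], pos.shape[1]
    J = volumes.shape[0]
    n_shells = J
    hard_core2 = (hard_core * HC_TOL) ** 2
    well_outer2 = well_outer * well_outer

    avail = np.empty((Nc, nb))
    blocked = np.empty(nb)
    blocked_new = np.empty(nb)
    contacts = np.zeros(Nc, dtype=np.int64)
    counts_eo = np.zeros(J)
    counts_po = np.zeros(J)
    phi_eo = np.zeros(J)  # available-fraction weighted counts
    phi_po = np.zeros(J)
    for c in range(Nc):
        ov, ct = _chain_pair_scan(
            pos[c], is_po, hard_core2, well_outer2, well_outer, hard_core, excl_radius, blocked
        )
        contacts[c] = ct
        for i in range(nb):
            a = 1.0 - blocked[i] / omega
            if a < 0.0:
                a = 0.0
            avail[c, i] = a
            r = np.sqrt(pos[c, i, 0] ** 2 + pos[c, i, 1] ** 2 + pos[c, i, 2] ** 2)
            j = _shell_index(r, shell_width, n_shells, r_inner)
            if is_po[i]:
                counts_po[j] += 1.0
                phi_po[j] += a
            else:
                counts_eo[j] += 1.0
                phi_eo[j] += a
    if not freeze_fields:
        _field_potentials(
            counts_eo, counts_po, phi_eo, phi_po, volumes,
            omega, e_ep, e_es, e_ps, v_p, v_s, u_eo, u_po, u_pi,
        )

    p_new = np.empty((nb, 3))
    avail_new = np.empty(nb)
    f_out = np.empty(record_at.shape[0], dtype=np.float64)
    rec_i = 0
    n_acc = 0
    prof_count = 0
    max_prof = prof_r.shape[0]

    for cyc in range(1, n_cycles + 1):
        for c in range(Nc):
            _propose(pos[c], p_new, seg_stops, amplitude)
            ovl, ct_new = _chain_pair_scan(
                p_new, is_po, hard_core2, well_outer2, well_outer, hard_core, excl_radius, blocked_new
            )
            if ovl:
                continue
            if _po_com_radius(p_new, is_po) > r_wall:
                continue
            for i in range(nb):
                a = 1.0 - blocked_new[i] / omega
                if a < 0.0:
                    a = 0.0
                avail_new[i] = a
            e_old = contacts[c] * e_contact_ep + _chain_field_energy(
                pos[c], is_po, avail[c], u_eo, u_po, u_pi, shell_width, n_shells, r_inner
            )
            e_new = ct_new * e_contact_ep + _chain_field_energy(
                p_new, is_po, avail_new, u_eo, u_po, u_pi, shell_width, n_shells, r_inner
            )
            dE = e_new - e_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                for i in range(nb):
                    r_old = np.sqrt(
                        pos[c, i, 0] ** 2 + pos[c, i, 1] ** 2 + pos[c, i, 2] ** 2
                    )
                    j_old = _shell_index(r_old, shell_width, n_shells, r_inner)
                    r_nw = np.sqrt(p_new[i, 0] ** 2 + p_new[i, 1] ** 2 + p_new[i, 2] ** 2)
                    j_new = _shell_index(r_nw, shell_width, n_shells, r_inner)
                    if is_po[i]:
                        counts_po[j_old] -= 1.0
                        counts_po[j_new] += 1.0
                        phi_po[j_old] -= avail[c, i]
                        phi_po[j_new] += avail_new[i]
                    else:
                        counts_eo[j_old] -= 1.0
                        counts_eo[j_new] += 1.0
                        phi_eo[j_old] -= avail[c, i]
                        phi_eo[j_new] += avail_new[i]
                    pos[c, i, 0] = p_new[i, 0]
                    pos[c, i, 1] = p_new[i, 1]
                    pos[c, i, 2] = p_new[i, 2]
                    avail[c, i] = avail_new[i]
                contacts[c] = ct_new
                n_acc += 1
        if not freeze_fields:
            _field_potentials(
                counts_eo, counts_po, phi_eo, phi_po, volumes,
                omega, e_ep, e_es, e_ps, v_p, v_s, u_eo, u_po, u_pi,
            )
        for c in range(Nc):
            r = _po_com_radius(pos[c], is_po)
            if inside[c]:
                if r > r_bound + hysteresis:
                    inside[c] = False
            else:
                if r < r_bound:
                    inside[c] = True
        if rec_i < record_at.shape[0] and cyc == record_at[rec_i]:
            f = 0.0
            for c in range(Nc):
                if tagged[c] and inside[c]:
                    f += 1.0
            f_out[rec_i] = f
            rec_i += 1
        if prof_stride > 0 and cyc % prof_stride == 0:
            for c in range(Nc):
                if prof_count >= max_prof:
                    break
                x = 0.0
                y = 0.0
                z = 0.0
                for i in range(n_head, n_head + n_po):
                    x += pos[c, i, 0]
                    y += pos[c, i, 1]
                    z += pos[c, i, 2]
                x /= n_po
                y /= n_po
                z /= n_po
                rg2 = 0.0
                for i in range(n_head, n_head + n_po):
                    rg2 += (
                        (pos[c, i, 0] - x) ** 2
                        + (pos[c, i, 1] - y) ** 2
                        + (pos[c, i, 2] - z) ** 2
                    )
                rg2 /= n_po
                hx = 0.0
                hy = 0.0
                hz = 0.0
                for i in range(0, n_head):
                    hx += pos[c, i, 0]
                    hy += pos[c, i, 1]
                    hz += pos[c, i, 2]
                hx, hy, hz = hx / n_head - x, hy / n_head - y, hz / n_head - z
                tx = 0.0
                ty = 0.0
                tz = 0.0
                n_tail = nb - n_head - n_po
                for i in range(n_head + n_po, nb):
                    tx += pos[c, i, 0]
                    ty += pos[c, i, 1]
                    tz += pos[c, i, 2]
                tx, ty, tz = tx / n_tail - x, ty / n_tail - y, tz / n_tail - z
                hn = np.sqrt(hx * hx + hy * hy + hz * hz)
                tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                if hn > 0.0 and tn > 0.0:
                    ca = (hx * tx + hy * ty + hz * tz) / (hn * tn)
                    if ca > 1.0:
                        ca = 1.0
                    if ca < -1.0:
                        ca = -1.0
                    ang = np.degrees(np.arccos(ca))
                else:
                    ang = np.nan
                prof_r[prof_count] = np.sqrt(x * x + y * y + z * z)
                prof_rg[prof_count] = np.sqrt(rg2)
                prof_angle[prof_count] = ang
                prof_count += 1
    return f_out, n_acc, prof_count


@njit(cache=True)
def free_diffusion(
    pos,  # (Nc, nb, 3)
    is_po,
    seg_stops,
    e_contact_ep,
    amplitude,
    n_cycles,
    stride,
    seed,
):
    """Zero-field evolution; returns chain centre-of-mass tracks (for MSD)."""
    np.random.seed(seed)
    Nc, nb = pos.shape[0], pos.shape[1]
    hard_core2 = HC_TOL * HC_TOL
    well_outer2 = 1.62 * 1.62
    scratch = np.empty(nb)
    n_rec = n_cycles // stride + 1
    coms = np.zeros((n_rec, Nc, 3))
    contacts = np.zeros(Nc, dtype=np.int64)
    for c in range(Nc):
        ov, ct = _chain_pair_scan(pos[c], is_po, hard_core2, well_outer2, 1.62, 1.0, 0.5, scratch)
        contacts[c] = ct
    p_new = np.empty((nb, 3))
    rec = 0
    for c in range(Nc):
        for i in range(nb):
            coms[0, c, 0] += pos[c, i, 0] / nb
            coms[0, c, 1] += pos[c, i, 1] / nb
            coms[0, c, 2] += pos[c, i, 2] / nb
    n_acc = 0
    for cyc in range(1, n_cycles + 1):
        for c in range(Nc):
            _propose(pos[c], p_new, seg_stops, amplitude)
            ov, ct_new = _chain_pair_scan(
                p_new, is_po, hard_core2, well_outer2, 1.62, 1.0, 0.5, scratch
            )
            if ov:
                continue
            dE = (ct_new - contacts[c]) * e_contact_ep
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                for i in range(nb):
                    pos[c, i, 0] = p_new[i, 0]
                    pos[c, i, 1] = p_new[i, 1]
                    pos[c, i, 2] = p_new[i, 2]
                contacts[c] = ct_new
                n_acc += 1
        if cyc % stride == 0:
            rec += 1
            for c in range(Nc):
                for i in range(nb):
                    coms[rec, c, 0] += pos[c, i, 0] / nb
                    coms[rec, c, 1] += pos[c, i, 1] / nb
                    coms[rec, c, 2] += pos[c, i, 2] / nb
    return coms, n_acc
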