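"""Overdamped Langevin (Brownian) dynamics and equilibrium Metropolis Monte
Carlo for compiled diabody systems.

Both samplers target the same Boltzmann measure.  Free beads follow the
Euler--Maruyama update x <- x + (F/gamma) dt + sqrt(2 kT dt / gamma) xi; rigid
groups translate with the net force and rotate with the net torque about their
centre of mass, with Stokes-scaled drags (translational ~ diameter, rotational
~ diameter^3).  Rigid-group positions are always reconstructed from stored
body-frame coordinates and a unit quaternion, so internal distances are
preserved to machine precision along any trajectory.

The Monte Carlo sampler mixes single-bead displacements, rigid-group
translations/rotations and crankshaft rotations of linker sub-chains (which
preserve all chain bond lengths, the efficient move for a stiff-bonded chain).

Times are in Brownian units tau_B = gamma sigma^2 / kT of a unit-drag bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .topology import DiabodySystem
from .forcefield import (
    CompiledFF,
    compile_forcefield,
    total_energy_forces,
    partial_energy,
)

__all__ = [
    "SimState",
    "Trajectory",
    "UmbrellaBias",
    "run_trajectory",
    "sample_equilibrium_mc",
    "step_brownian",
    "compute_forces_state",
    "bead_height_distribution",
    "HeightDistribution",
]


# ---------------------------------------------------------------------------
# quaternion helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _quat_mult(a, b):
    w = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    x = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    y = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    z = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
    out = np.empty(4)
    out[0], out[1], out[2], out[3] = w, x, y, z
    return out


@njit(cache=True)
def _quat_from_rotvec(v):
    out = np.empty(4)
    ang = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if ang < 1e-14:
        out[0] = 1.0
        out[1] = 0.5 * v[0]
        out[2] = 0.5 * v[1]
        out[3] = 0.5 * v[2]
    else:
        s = np.sin(0.5 * ang) / ang
        out[0] = np.cos(0.5 * ang)
        out[1] = s * v[0]
        out[2] = s * v[1]
        out[3] = s * v[2]
    n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    return out / n


@njit(cache=True)
def _quat_rotate(q, v):
    """Rotate vector v by unit quaternion q."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    tx = 2.0 * (y * v[2] - z * v[1])
    ty = 2.0 * (z * v[0] - x * v[2])
    tz = 2.0 * (x * v[1] - y * v[0])
    out = np.empty(3)
    out[0] = v[0] + w * tx + (y * tz - z * ty)
    out[1] = v[1] + w * ty + (z * tx - x * tz)
    out[2] = v[2] + w * tz + (x * ty - y * tx)
    return out


@njit(cache=True)
def _rebuild_group(pos, idx, ref, com, q):
    for a in range(len(idx)):
        r = _quat_rotate(q, ref[a])
        pos[idx[a], 0] = com[0] + r[0]
        pos[idx[a], 1] = com[1] + r[1]
        pos[idx[a], 2] = com[2] + r[2]


# ---------------------------------------------------------------------------
# umbrella bias
# ---------------------------------------------------------------------------


@dataclass
class UmbrellaBias:
    """Harmonic bias on a collective variable of the free nanobody COM.

    ``rho_z`` biases the height of the nbd-1 centre of mass; ``rho_xy`` biases
    the in-plane distance from the tethering point to the nbd-1 COM and adds a
    harmonic restraint holding the COM height at ``z_center``.
    """

    kind: str  # "rho_z" | "rho_xy"
    spring: float
    center: float
    z_spring: float = 50.0
    z_center: float = 5.0

    def code(self) -> int:
        return {"none": 0, "rho_z": 1, "rho_xy": 2}[self.kind]


@njit(cache=True)
def _bias_energy(pos, kind, kb, c, kz, cz, g_idx, g_w, tx, ty, lx, ly):
    if kind == 0:
        return 0.0
    cx = cy = czm = 0.0
    for a in range(len(g_idx)):
        cx += g_w[a] * pos[g_idx[a], 0]
        cy += g_w[a] * pos[g_idx[a], 1]
        czm += g_w[a] * pos[g_idx[a], 2]
    if kind == 1:
        d = czm - c
        return 0.5 * kb * d * d
    dx = cx - tx
    dy = cy - ty
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    rho = np.sqrt(dx * dx + dy * dy)
    d = rho - c
    dz = czm - cz
    return 0.5 * kb * d * d + 0.5 * kz * dz * dz


@njit(cache=True)
def _bias_force(pos, F, kind, kb, c, kz, cz, g_idx, g_w, tx, ty, lx, ly):
    if kind == 0:
        return
    cx = cy = czm = 0.0
    for a in range(len(g_idx)):
        cx += g_w[a] * pos[g_idx[a], 0]
        cy += g_w[a] * pos[g_idx[a], 1]
        czm += g_w[a] * pos[g_idx[a], 2]
    if kind == 1:
        fz = -kb * (czm - c)
        for a in range(len(g_idx)):
            F[g_idx[a], 2] += g_w[a] * fz
        return
    dx = cx - tx
    dy = cy - ty
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    rho = np.sqrt(dx * dx + dy * dy)
    if rho > 1e-12:
        f = -kb * (rho - c) / rho
        for a in range(len(g_idx)):
            F[g_idx[a], 0] += g_w[a] * f * dx
            F[g_idx[a], 1] += g_w[a] * f * dy
    fz = -kz * (czm - cz)
    for a in range(len(g_idx)):
        F[g_idx[a], 2] += g_w[a] * fz


@njit(cache=True)
def collective_variable(pos, kind, g_idx, g_w, tx, ty, lx, ly):
    """Evaluate rho_z (kind 1) or rho_xy (kind 2) at a configuration."""
    cx = cy = cz = 0.0
    for a in range(len(g_idx)):
        cx += g_w[a] * pos[g_idx[a], 0]
        cy += g_w[a] * pos[g_idx[a], 1]
        cz += g_w[a] * pos[g_idx[a], 2]
    if kind == 1:
        return cz
    dx = cx - tx
    dy = cy - ty
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    return np.sqrt(dx * dx + dy * dy)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _bd_kernel(
    pos, quat, g_com, n_steps, dt, sample_every, seed, kT,
    free_idx, gamma_free,
    g_start, g_idx, g_ref, g_gt, g_gr,
    bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w, tx, ty,
    out, out_e,
    lx, ly, lz,
    bi, bj, bk, br0,
    ai, aj, ak, akf, at0, astyle,
    di, dj, dk, dl, dkf, dp0,
    pi, pj, peps, ps, prcut, pshift,
    wlo_s, wlo_rcut, wlo_eps, wlo_shift,
    whi_s, whi_rcut, whi_eps, whi_shift,
):
    np.random.seed(seed)
    n = pos.shape[0]
    F = np.zeros((n, 3))
    ngr = len(g_start) - 1
    sq = np.sqrt(2.0 * kT * dt)
    max_disp = 0.25  # per-step displacement clamp (sigma); inactive when stable
    frame = 0
    for step in range(n_steps):
        e = total_energy_forces(
            pos, F, True,
            lx, ly, lz, bi, bj, bk, br0, ai, aj, ak, akf, at0, astyle,
            di, dj, dk, dl, dkf, dp0, pi, pj, peps, ps, prcut, pshift,
            wlo_s, wlo_rcut, wlo_eps, wlo_shift, whi_s, whi_rcut, whi_eps, whi_shift,
        )
        _bias_force(pos, F, bias_kind, bias_k, bias_c, bias_zk, bias_zc,
                    cvg_idx, cvg_w, tx, ty, lx, ly)
        for a in range(len(free_idx)):
            b = free_idx[a]
            g = gamma_free[a]
            for d in range(3):
                dx = F[b, d] * dt / g + sq / np.sqrt(g) * np.random.normal()
                if dx > max_disp:
                    dx = max_disp
                elif dx < -max_disp:
                    dx = -max_disp
                pos[b, d] += dx
            if pos[b, 2] < 0.0:
                pos[b, 2] = -pos[b, 2]
            elif pos[b, 2] > lz:
                pos[b, 2] = 2.0 * lz - pos[b, 2]
        for g in range(ngr):
            i0, i1 = g_start[g], g_start[g + 1]
            fx = fy = fz = 0.0
            t0 = t1 = t2 = 0.0
            for a in range(i0, i1):
                b = g_idx[a]
                fx += F[b, 0]
                fy += F[b, 1]
                fz += F[b, 2]
                rx = pos[b, 0] - g_com[g, 0]
                ry = pos[b, 1] - g_com[g, 1]
                rz = pos[b, 2] - g_com[g, 2]
                t0 += ry * F[b, 2] - rz * F[b, 1]
                t1 += rz * F[b, 0] - rx * F[b, 2]
                t2 += rx * F[b, 1] - ry * F[b, 0]
            gt, gr = g_gt[g], g_gr[g]
            for d in range(3):
                fd = fx if d == 0 else (fy if d == 1 else fz)
                dx = fd * dt / gt + sq / np.sqrt(gt) * np.random.normal()
                if dx > max_disp:
                    dx = max_disp
                elif dx < -max_disp:
                    dx = -max_disp
                g_com[g, d] += dx
            rot = np.empty(3)
            rot[0] = t0 * dt / gr + sq / np.sqrt(gr) * np.random.normal()
            rot[1] = t1 * dt / gr + sq / np.sqrt(gr) * np.random.normal()
            rot[2] = t2 * dt / gr + sq / np.sqrt(gr) * np.random.normal()
            dq = _quat_from_rotvec(rot)
            qn = _quat_mult(dq, quat[g])
            qn /= np.sqrt(qn[0] ** 2 + qn[1] ** 2 + qn[2] ** 2 + qn[3] ** 2)
            quat[g] = qn
            _rebuild_group(pos, g_idx[i0:i1], g_ref[i0:i1], g_com[g], quat[g])
        if (step + 1) % sample_every == 0 and frame < out.shape[0]:
            out[frame] = pos
            out_e[frame] = e
            frame += 1
    return frame


@njit(cache=True)
def _mc_kernel(
    pos, quat, g_com, n_sweeps, sample_every, seed, kT,
    free_idx, chain_idx, tail_idx, tail_group,
    anchor_idx, all_mobile, n_tilt,
    g_start, g_idx, g_ref, g_m,
    amp_free, amp_trans, amp_rot, n_crank, n_pivot,
    bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w, tx, ty,
    out, acc,
    lx, ly, lz,
    bi, bj, bk, br0,
    ai, aj, ak, akf, at0, astyle,
    di, dj, dk, dl, dkf, dp0,
    pi, pj, peps, ps, prcut, pshift,
    wlo_s, wlo_rcut, wlo_eps, wlo_shift,
    whi_s, whi_rcut, whi_eps, whi_shift,
):
    np.random.seed(seed)
    n = pos.shape[0]
    moved = np.zeros(n, dtype=np.bool_)
    trial = pos.copy()
    ngr = len(g_start) - 1
    nch = len(chain_idx)
    beta = 1.0 / kT if kT > 0 else np.inf
    frame = 0

    def_args = (lx, ly, lz, bi, bj, bk, br0, ai, aj, ak, akf, at0, astyle,
                di, dj, dk, dl, dkf, dp0, pi, pj, peps, ps, prcut, pshift,
                wlo_s, wlo_rcut, wlo_eps, wlo_shift, whi_s, whi_rcut, whi_eps, whi_shift)

    for sweep in range(n_sweeps):
        # single-bead displacements
        for a in range(len(free_idx)):
            b = free_idx[a]
            moved[b] = True
            e_old = partial_energy(pos, moved, *def_args) + _bias_energy(
                pos, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            for d in range(3):
                trial[b, d] = pos[b, d] + amp_free * (2.0 * np.random.random() - 1.0)
            e_new = partial_energy(trial, moved, *def_args) + _bias_energy(
                trial, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            de = e_new - e_old
            if de <= 0.0 or (kT > 0 and np.random.random() < np.exp(-beta * de)):
                for d in range(3):
                    pos[b, d] = trial[b, d]
                acc[0] += 1
            else:
                for d in range(3):
                    trial[b, d] = pos[b, d]
            acc[1] += 1
            moved[b] = False
        # rigid-group translations / rotations
        for g in range(ngr):
            i0, i1 = g_start[g], g_start[g + 1]
            for a in range(i0, i1):
                moved[g_idx[a]] = True
            e_old = partial_energy(pos, moved, *def_args) + _bias_energy(
                pos, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            com_new = np.empty(3)
            for d in range(3):
                com_new[d] = g_com[g, d]
            q_new = quat[g].copy()
            u_move = np.random.random()
            if u_move < 1.0 / 3.0:
                for d in range(3):
                    com_new[d] += amp_trans * (2.0 * np.random.random() - 1.0)
            else:
                rv = np.empty(3)
                for d in range(3):
                    rv[d] = np.random.normal()
                nrm = np.sqrt(rv[0] ** 2 + rv[1] ** 2 + rv[2] ** 2)
                ang = amp_rot * (2.0 * np.random.random() - 1.0)
                for d in range(3):
                    rv[d] *= ang / nrm
                dq = _quat_from_rotvec(rv)
                if u_move >= 2.0 / 3.0:
                    # rotate about the group's first bead (the anchored
                    # paratope for the tethered nanobody): samples tilt
                    # without fighting the tether
                    pvt = pos[g_idx[i0]]
                    for d in range(3):
                        rv[d] = g_com[g, d] - pvt[d]
                    r = _quat_rotate(dq, rv)
                    for d in range(3):
                        com_new[d] = pvt[d] + r[d]
                q_new = _quat_mult(dq, quat[g])
                q_new /= np.sqrt(q_new[0] ** 2 + q_new[1] ** 2 + q_new[2] ** 2 + q_new[3] ** 2)
            _rebuild_group(trial, g_idx[i0:i1], g_ref[i0:i1], com_new, q_new)
            e_new = partial_energy(trial, moved, *def_args) + _bias_energy(
                trial, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            de = e_new - e_old
            if de <= 0.0 or (kT > 0 and np.random.random() < np.exp(-beta * de)):
                for a in range(i0, i1):
                    b = g_idx[a]
                    for d in range(3):
                        pos[b, d] = trial[b, d]
                for d in range(3):
                    g_com[g, d] = com_new[d]
                quat[g] = q_new
                acc[2] += 1
            else:
                for a in range(i0, i1):
                    b = g_idx[a]
                    for d in range(3):
                        trial[b, d] = pos[b, d]
            acc[3] += 1
            for a in range(i0, i1):
                moved[g_idx[a]] = False
        # crankshaft rotations of linker sub-chains
        for _ in range(n_crank):
            if nch < 3:
                break
            a0 = np.random.randint(0, nch - 2)
            b0 = np.random.randint(a0 + 2, nch)
            ia, ib = chain_idx[a0], chain_idx[b0]
            axis = np.empty(3)
            for d in range(3):
                axis[d] = pos[ib, d] - pos[ia, d]
            nrm = np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
            if nrm < 1e-10:
                continue
            ang = np.pi * (2.0 * np.random.random() - 1.0)
            for d in range(3):
                axis[d] *= ang / nrm
            dq = _quat_from_rotvec(axis)
            for c0 in range(a0 + 1, b0):
                moved[chain_idx[c0]] = True
            e_old = partial_energy(pos, moved, *def_args) + _bias_energy(
                pos, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            v = np.empty(3)
            for c0 in range(a0 + 1, b0):
                b = chain_idx[c0]
                for d in range(3):
                    v[d] = pos[b, d] - pos[ia, d]
                r = _quat_rotate(dq, v)
                for d in range(3):
                    trial[b, d] = pos[ia, d] + r[d]
            e_new = partial_energy(trial, moved, *def_args) + _bias_energy(
                trial, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            de = e_new - e_old
            if de <= 0.0 or (kT > 0 and np.random.random() < np.exp(-beta * de)):
                for c0 in range(a0 + 1, b0):
                    b = chain_idx[c0]
                    for d in range(3):
                        pos[b, d] = trial[b, d]
                acc[4] += 1
            else:
                for c0 in range(a0 + 1, b0):
                    b = chain_idx[c0]
                    for d in range(3):
                        trial[b, d] = pos[b, d]
            acc[5] += 1
            for c0 in range(a0 + 1, b0):
                moved[chain_idx[c0]] = False
        # pivot rotations: rotate the chain tail (and the free-nanobody beads
        # hanging off it) about a random axis through a pivot bead
        for _ in range(n_pivot):
            if nch < 1:
                break
            p0 = np.random.randint(0, nch)
            ip = chain_idx[p0]
            nmv = (nch - 1 - p0) + len(tail_idx)
            if nmv < 1:
                continue
            axis = np.empty(3)
            for d in range(3):
                axis[d] = np.random.normal()
            nrm = np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
            ang = np.pi * (2.0 * np.random.random() - 1.0)
            for d in range(3):
                axis[d] *= ang / nrm
            dq = _quat_from_rotvec(axis)
            for c0 in range(p0 + 1, nch):
                moved[chain_idx[c0]] = True
            for a in range(len(tail_idx)):
                moved[tail_idx[a]] = True
            e_old = partial_energy(pos, moved, *def_args) + _bias_energy(
                pos, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            v = np.empty(3)
            for b in range(pos.shape[0]):
                if moved[b]:
                    for d in range(3):
                        v[d] = pos[b, d] - pos[ip, d]
                    r = _quat_rotate(dq, v)
                    for d in range(3):
                        trial[b, d] = pos[ip, d] + r[d]
            e_new = partial_energy(trial, moved, *def_args) + _bias_energy(
                trial, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            de = e_new - e_old
            if de <= 0.0 or (kT > 0 and np.random.random() < np.exp(-beta * de)):
                for b in range(pos.shape[0]):
                    if moved[b]:
                        for d in range(3):
                            pos[b, d] = trial[b, d]
                if tail_group >= 0:
                    for d in range(3):
                        v[d] = g_com[tail_group, d] - pos[ip, d]
                    r = _quat_rotate(dq, v)
                    for d in range(3):
                        g_com[tail_group, d] = pos[ip, d] + r[d]
                    qn = _quat_mult(dq, quat[tail_group])
                    qn /= np.sqrt(qn[0] ** 2 + qn[1] ** 2 + qn[2] ** 2 + qn[3] ** 2)
                    quat[tail_group] = qn
                acc[6] += 1
            else:
                for b in range(pos.shape[0]):
                    if moved[b]:
                        for d in range(3):
                            trial[b, d] = pos[b, d]
            acc[7] += 1
            for c0 in range(p0 + 1, nch):
                moved[chain_idx[c0]] = False
            for a in range(len(tail_idx)):
                moved[tail_idx[a]] = False
        # base-tilt moves: rotate the whole molecule about the anchored
        # paratope position (tether energy unchanged); decorrelates the slow
        # global tilt of the tethered nanobody
        for _ in range(n_tilt):
            if anchor_idx < 0:
                break
            pvx = pos[anchor_idx, 0]
            pvy = pos[anchor_idx, 1]
            pvz = pos[anchor_idx, 2]
            axis = np.empty(3)
            for d in range(3):
                axis[d] = np.random.normal()
            nrm = np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
            ang = 0.4 * (2.0 * np.random.random() - 1.0)
            for d in range(3):
                axis[d] *= ang / nrm
            dq = _quat_from_rotvec(axis)
            for a in range(len(all_mobile)):
                moved[all_mobile[a]] = True
            e_old = partial_energy(pos, moved, *def_args) + _bias_energy(
                pos, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            v = np.empty(3)
            for a in range(len(all_mobile)):
                b = all_mobile[a]
                v[0] = pos[b, 0] - pvx
                v[1] = pos[b, 1] - pvy
                v[2] = pos[b, 2] - pvz
                r = _quat_rotate(dq, v)
                trial[b, 0] = pvx + r[0]
                trial[b, 1] = pvy + r[1]
                trial[b, 2] = pvz + r[2]
            e_new = partial_energy(trial, moved, *def_args) + _bias_energy(
                trial, bias_kind, bias_k, bias_c, bias_zk, bias_zc, cvg_idx, cvg_w,
                tx, ty, lx, ly)
            de = e_new - e_old
            if de <= 0.0 or (kT > 0 and np.random.random() < np.exp(-beta * de)):
                for a in range(len(all_mobile)):
                    b = all_mobile[a]
                    for d in range(3):
                        pos[b, d] = trial[b, d]
                for g in range(ngr):
                    v[0] = g_com[g, 0] - pvx
                    v[1] = g_com[g, 1] - pvy
                    v[2] = g_com[g, 2] - pvz
                    r = _quat_rotate(dq, v)
                    g_com[g, 0] = pvx + r[0]
                    g_com[g, 1] = pvy + r[1]
                    g_com[g, 2] = pvz + r[2]
                    qn = _quat_mult(dq, quat[g])
                    qn /= np.sqrt(qn[0] ** 2 + qn[1] ** 2 + qn[2] ** 2 + qn[3] ** 2)
                    quat[g] = qn
                acc[8] += 1
            else:
                for a in range(len(all_mobile)):
                    b = all_mobile[a]
                    for d in range(3):
                        trial[b, d] = pos[b, d]
            acc[9] += 1
            for a in range(len(all_mobile)):
                moved[all_mobile[a]] = False
        if (sweep + 1) % sample_every == 0 and frame < out.shape[0]:
            out[frame] = pos
            frame += 1
    return frame


# ---------------------------------------------------------------------------
# python-side state, compilation and drivers
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Positions plus rigid-group orientations and time."""

    positions: np.ndarray
    quaternions: np.ndarray
    group_coms: np.ndarray
    time: float = 0.0


@dataclass
class Trajectory:
    """Uniformly sampled frames of bead coordinates."""

    frames: np.ndarray  # (n_frames, n_beads, 3)
    names: list[str]
    frame_interval: float
    box: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)
    energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no bead named {name!r}") from None

    def z_series(self, name: str) -> np.ndarray:
        return self.frames[:, self.index(name), 2].copy()

    def positions_of(self, name: str) -> np.ndarray:
        return self.frames[:, self.index(name), :]


class CompiledSystem:
    """System compiled to flat arrays for the kernels (cached per system)."""

    def __init__(self, system: DiabodySystem):
        self.system = system
        self.ff = compile_forcefield(system)
        grouped = set()
        g_start = [0]
        g_idx: list[int] = []
        g_ref_rows = []
        g_gt, g_gr = [], []
        for grp in system.rigid_groups:
            g_idx.extend(grp.bead_ids)
            g_ref_rows.append(grp.reference)
            grouped.update(grp.bead_ids)
            g_start.append(len(g_idx))
            dia = max(system.beads[i].diameter for i in grp.bead_ids)
            g_gt.append(dia)
            g_gr.append(dia**3)
        self.g_start = np.array(g_start, dtype=np.int64)
        self.g_idx = np.array(g_idx, dtype=np.int64)
        self.g_ref = (
            np.vstack(g_ref_rows) if g_ref_rows else np.zeros((0, 3))
        )
        self.g_gt = np.array(g_gt, dtype=float)
        self.g_gr = np.array(g_gr, dtype=float)
        free = [
            b.id
            for b in system.beads
            if b.id not in grouped and not system.fixed[b.id]
        ]
        self.free_idx = np.array(free, dtype=np.int64)
        self.gamma_free = np.ones(len(free))
        # linker chain (ordered by L index) for crankshaft moves
        lbeads = sorted(
            (
                b
                for b in system.beads
                if b.group == "linker" and b.name[:1] == "L" and b.name[1:].isdigit()
            ),
            key=lambda b: int(b.name[1:]),
        )
        self.chain_idx = np.array([b.id for b in lbeads], dtype=np.int64)
        # beads topologically past the linker's free end (the nbd-1 arm),
        # rotated together with the chain tail by pivot moves
        try:
            tail = [int(i) for i in system.free_nanobody_indices()]
        except KeyError:
            tail = []
        self.tail_idx = np.array(sorted(tail), dtype=np.int64)
        self.tail_group = -1
        for gi, grp in enumerate(system.rigid_groups):
            if set(grp.bead_ids) & set(tail):
                self.tail_group = gi
        mob = sorted(set(free) | set(g_idx))
        self.all_mobile = np.array(mob, dtype=np.int64)
        self.anchor_idx = int(system.tether.paratope) if system.tether is not None else -1
        # collective-variable group: nbd-1 beads, mass weights
        try:
            cvg = system.free_nanobody_indices()
        except KeyError:
            cvg = np.zeros(0, dtype=np.int64)
        self.cvg_idx = cvg
        m = system.masses[cvg] if len(cvg) else np.zeros(0)
        self.cvg_w = m / m.sum() if len(cvg) else m
        if system.tether is not None:
            self.tx, self.ty = system.tether_point_xy()
        else:
            self.tx = self.ty = 0.0

    def initial_state(self) -> SimState:
        pos = self.system.positions.copy()
        ngr = len(self.system.rigid_groups)
        quat = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (ngr, 1))
        coms = np.zeros((ngr, 3))
        for g, grp in enumerate(self.system.rigid_groups):
            m = np.array([self.system.beads[i].mass for i in grp.bead_ids])
            coms[g] = (m[:, None] * pos[grp.bead_ids]).sum(axis=0) / m.sum()
        return SimState(pos, quat, coms)

    def bias_args(self, bias: UmbrellaBias | None):
        if bias is None:
            return (0, 0.0, 0.0, 0.0, 0.0, self.cvg_idx, self.cvg_w, self.tx, self.ty)
        return (
            bias.code(), float(bias.spring), float(bias.center),
            float(bias.z_spring), float(bias.z_center),
            self.cvg_idx, self.cvg_w, self.tx, self.ty,
        )

    def cv_value(self, pos: np.ndarray, kind: str) -> float:
        code = {"rho_z": 1, "rho_xy": 2}[kind]
        return float(
            collective_variable(pos, code, self.cvg_idx, self.cvg_w, self.tx, self.ty,
                                self.ff.lx, self.ff.ly)
        )


_COMPILED_CACHE: dict[int, CompiledSystem] = {}


def compiled(system: DiabodySystem) -> CompiledSystem:
    key = id(system)
    cs = _COMPILED_CACHE.get(key)
    if cs is None or cs.system is not system:
        cs = CompiledSystem(system)
        _COMPILED_CACHE[key] = cs
    return cs


class StabilityError(RuntimeError):
    """Raised when the BD timestep exceeds the stiffest-term stability bound."""


DEFAULT_DT = 1e-4


def _check_dt(system: DiabodySystem, dt: float) -> None:
    if dt <= 0:
        raise StabilityError("timestep must be positive")
    kmax = max((t.k for t in system.bonds), default=0.0)
    if kmax > 0 and dt > 2.0 / kmax:
        raise StabilityError(
            f"dt = {dt} exceeds the overdamped stability bound 2 gamma / k_bond "
            f"= {2.0 / kmax:.2e} for the stiffest bond"
        )


def run_trajectory(
    system: DiabodySystem,
    n_steps: int,
    dt: float = DEFAULT_DT,
    sample_every: int = 1000,
    seed: int = 0,
    kT: float = 1.0,
    bias: UmbrellaBias | None = None,
    burn_in: int = 0,
    state: SimState | None = None,
) -> Trajectory:
    """Brownian-dynamics trajectory; reproducible bitwise for a given seed.

    ``burn_in`` steps are run (and discarded) before production.  With
    ``n_steps = 0`` the trajectory contains the single initial frame.
    """
    _check_dt(system, dt)
    cs = compiled(system)
    st = state if state is not None else cs.initial_state()
    names = [b.name for b in system.beads]
    prov = {
        "sampler": "brownian",
        "seed": seed,
        "dt": dt,
        "n_steps": n_steps,
        "sample_every": sample_every,
        "burn_in": burn_in,
        "model": system.metadata.get("model"),
    }
    if n_steps == 0:
        return Trajectory(st.positions[None, :, :].copy(), names, dt * sample_every,
                          system.box, prov)
    if burn_in > 0:
        dump = np.zeros((0, system.n_beads, 3))
        dump_e = np.zeros(0)
        _bd_kernel(
            st.positions, st.quaternions, st.group_coms, burn_in, dt, burn_in + 1,
            seed + 1_000_003, kT,
            cs.free_idx, cs.gamma_free,
            cs.g_start, cs.g_idx, cs.g_ref, cs.g_gt, cs.g_gr,
            *cs.bias_args(bias), dump, dump_e, *cs.ff.args(),
        )
    n_frames = n_steps // sample_every
    if n_frames < 1:
        n_frames = 1
        sample_every = n_steps
    out = np.zeros((n_frames, system.n_beads, 3))
    out_e = np.zeros(n_frames)
    got = _bd_kernel(
        st.positions, st.quaternions, st.group_coms, n_steps, dt, sample_every,
        seed, kT,
        cs.free_idx, cs.gamma_free,
        cs.g_start, cs.g_idx, cs.g_ref, cs.g_gt, cs.g_gr,
        *cs.bias_args(bias), out, out_e, *cs.ff.args(),
    )
    st.time += (burn_in + n_steps) * dt
    if not np.isfinite(out_e[:got]).all():
        raise StabilityError("non-finite energy encountered; reduce dt")
    return Trajectory(out[:got], names, dt * sample_every, system.box, prov,
                      energies=out_e[:got])


def step_brownian(
    system: DiabodySystem,
    state: SimState,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    kT: float = 1.0,
) -> SimState:
    """Advance a state by one Euler--Maruyama step (in place) and return it."""
    _check_dt(system, dt)
    cs = compiled(system)
    out = np.zeros((0, system.n_beads, 3))
    out_e = np.zeros(0)
    _bd_kernel(
        state.positions, state.quaternions, state.group_coms, 1, dt, 2, seed, kT,
        cs.free_idx, cs.gamma_free,
        cs.g_start, cs.g_idx, cs.g_ref, cs.g_gt, cs.g_gr,
        *cs.bias_args(None), out, out_e, *cs.ff.args(),
    )
    state.time += dt
    return state


def compute_forces_state(system: DiabodySystem, state: SimState | None = None):
    from .forcefield import compute_forces

    pos = state.positions if state is not None else None
    return compute_forces(system, pos, compiled(system).ff)


def sample_equilibrium_mc(
    system: DiabodySystem,
    n_sweeps: int,
    seed: int = 0,
    sample_every: int = 10,
    kT: float = 1.0,
    bias: UmbrellaBias | None = None,
    burn_in: int = 0,
    amp_free: float = 0.12,
    amp_trans: float = 0.4,
    amp_rot: float = 0.35,
    state: SimState | None = None,
) -> Trajectory:
    """Metropolis sampling of the equilibrium (Boltzmann) configuration measure.

    One sweep attempts a displacement per free bead, a translation/rotation per
    rigid group and ~n_linker/2 crankshaft rotations.  Returns a
    configuration-only trajectory with ``frame_interval`` in sweeps; the
    acceptance counters are stored in the provenance dictionary.
    """
    cs = compiled(system)
    st = state if state is not None else cs.initial_state()
    names = [b.name for b in system.beads]
    n_crank = max(len(cs.chain_idx) // 2, 1) if len(cs.chain_idx) >= 3 else 0
    n_pivot = max(len(cs.chain_idx) // 4, 2) if len(cs.chain_idx) >= 1 else 0
    n_tilt = 2 if cs.anchor_idx >= 0 else 0
    acc = np.zeros(10, dtype=np.int64)
    if burn_in > 0:
        dump = np.zeros((0, system.n_beads, 3))
        _mc_kernel(
            st.positions, st.quaternions, st.group_coms, burn_in, burn_in + 1,
            seed + 1_000_003, kT,
            cs.free_idx, cs.chain_idx, cs.tail_idx, cs.tail_group,
            cs.anchor_idx, cs.all_mobile, n_tilt,
            cs.g_start, cs.g_idx, cs.g_ref,
            np.ones(len(cs.g_idx)),
            amp_free, amp_trans, amp_rot, n_crank, n_pivot,
            *cs.bias_args(bias), dump, acc, *cs.ff.args(),
        )
    n_frames = max(n_sweeps // sample_every, 1)
    out = np.zeros((n_frames, system.n_beads, 3))
    got = _mc_kernel(
        st.positions, st.quaternions, st.group_coms, n_sweeps, sample_every, seed, kT,
        cs.free_idx, cs.chain_idx, cs.tail_idx, cs.tail_group,
        cs.anchor_idx, cs.all_mobile, n_tilt,
        cs.g_start, cs.g_idx, cs.g_ref,
        np.ones(len(cs.g_idx)),
        amp_free, amp_trans, amp_rot, n_crank, n_pivot,
        *cs.bias_args(bias), out, acc, *cs.ff.args(),
    )
    prov = {
        "sampler": "mc",
        "seed": seed,
        "n_sweeps": n_sweeps,
        "sample_every": sample_every,
        "burn_in": burn_in,
        "acc_bead": _ratio(acc[0], acc[1]),
        "acc_rigid": _ratio(acc[2], acc[3]),
        "acc_crank": _ratio(acc[4], acc[5]),
        "acc_pivot": _ratio(acc[6], acc[7]),
        "acc_tilt": _ratio(acc[8], acc[9]),
        "model": system.metadata.get("model"),
    }
    return Trajectory(out[: max(got, 1)], names, float(sample_every), system.box, prov)


def _ratio(a: int, b: int) -> float:
    return float(a) / float(b) if b else float("nan")


# ---------------------------------------------------------------------------
# height distributions
# ---------------------------------------------------------------------------


@dataclass
class HeightDistribution:
    """Normalized histogram of a bead's height above the tethering wall."""

    density: np.ndarray
    edges: np.ndarray
    mean: float
    quantiles: dict[float, float]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bead_height_distribution(
    trajectory: Trajectory,
    bead: str,
    bins: int = 60,
    z_range: tuple[float, float] | None = None,
) -> HeightDistribution:
    """Density of z for one bead, plus its mean and (5, 25, 50, 75, 95)% quantiles."""
    z = trajectory.z_series(bead)
    density, edges = np.histogram(z, bins=bins, range=z_range, density=True)
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return HeightDistribution(
        density=density,
        edges=edges,
        mean=float(z.mean()),
        quantiles={q: float(v) for q, v in zip(qs, np.quantile(z, qs))},
    )
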