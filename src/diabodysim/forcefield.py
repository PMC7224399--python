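"""Numba kernels for energies and forces of compiled diabody systems.

All terms use minimum-image displacements in x and y (the box is periodic in
the plane only), so the energy is exactly invariant under lattice translations
of the whole molecule.  Pair and wall LJ terms are cut and shifted to zero at
their cutoffs; below ``CAP_FRACTION * s`` the force is capped at its value at
the capping radius and the energy continued linearly, so rare overlaps after
system construction cannot produce unbounded forces.

The tether (paratope-epitope attraction) is appended to the pair table at
compile time; its energy is reported separately in the component breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .topology import DiabodySystem

#: force capping radius as a fraction of the pair repulsive length
CAP_FRACTION = 0.3

_STYLE = {"harmonic": 0, "cosine": 1}


@dataclass
class CompiledFF:
    """Flat numeric view of a DiabodySystem for the numba kernels."""

    lx: float
    ly: float
    lz: float
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_kf: np.ndarray
    ang_t0: np.ndarray
    ang_style: np.ndarray
    dih_i: np.ndarray
    dih_j: np.ndarray
    dih_k: np.ndarray
    dih_l: np.ndarray
    dih_kf: np.ndarray
    dih_p0: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_eps: np.ndarray
    pair_s: np.ndarray
    pair_rcut: np.ndarray
    pair_shift: np.ndarray
    wlo_s: np.ndarray
    wlo_rcut: np.ndarray
    wlo_eps: np.ndarray
    wlo_shift: np.ndarray
    whi_s: np.ndarray
    whi_rcut: np.ndarray
    whi_eps: np.ndarray
    whi_shift: np.ndarray
    n_pairs_nonbonded: int

    def args(self) -> tuple:
        return (
            self.lx, self.ly, self.lz,
            self.bond_i, self.bond_j, self.bond_k, self.bond_r0,
            self.ang_i, self.ang_j, self.ang_k, self.ang_kf, self.ang_t0, self.ang_style,
            self.dih_i, self.dih_j, self.dih_k, self.dih_l, self.dih_kf, self.dih_p0,
            self.pair_i, self.pair_j, self.pair_eps, self.pair_s, self.pair_rcut,
            self.pair_shift,
            self.wlo_s, self.wlo_rcut, self.wlo_eps, self.wlo_shift,
            self.whi_s, self.whi_rcut, self.whi_eps, self.whi_shift,
        )


def _lj_shift(eps: np.ndarray, s: np.ndarray, rcut: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s)
    ok = rcut > 0
    sr6 = (s[ok] / rcut[ok]) ** 6
    out[ok] = 4.0 * eps[ok] * (sr6 * sr6 - sr6)
    return out


def compile_forcefield(system: DiabodySystem) -> CompiledFF:
    ia = lambda seq: np.array(seq, dtype=np.int64)
    fa = lambda seq: np.array(seq, dtype=np.float64)

    bonds, angles, dihedrals = system.bonds, system.angles, system.dihedrals
    pi = list(system.pairs.i)
    pj = list(system.pairs.j)
    peps = list(system.pairs.epsilon)
    ps = list(system.pairs.s)
    prc = list(system.pairs.r_cut)
    n_nb = len(pi)
    if system.tether is not None:
        t = system.tether
        pi.append(t.paratope)
        pj.append(t.epitope)
        peps.append(t.epsilon)
        ps.append(t.s)
        prc.append(t.r_cut)
    peps, ps, prc = fa(peps), fa(ps), fa(prc)

    return CompiledFF(
        lx=float(system.box[0]),
        ly=float(system.box[1]),
        lz=float(system.box[2]),
        bond_i=ia([t.i for t in bonds]),
        bond_j=ia([t.j for t in bonds]),
        bond_k=fa([t.k for t in bonds]),
        bond_r0=fa([t.r0 for t in bonds]),
        ang_i=ia([t.i for t in angles]),
        ang_j=ia([t.j for t in angles]),
        ang_k=ia([t.k_idx for t in angles]),
        ang_kf=fa([t.k for t in angles]),
        ang_t0=fa([np.radians(t.theta0_deg) for t in angles]),
        ang_style=np.array([_STYLE[t.style] for t in angles], dtype=np.int8),
        dih_i=ia([t.i for t in dihedrals]),
        dih_j=ia([t.j for t in dihedrals]),
        dih_k=ia([t.k_idx for t in dihedrals]),
        dih_l=ia([t.l for t in dihedrals]),
        dih_kf=fa([t.k for t in dihedrals]),
        dih_p0=fa([np.radians(t.phi0_deg) for t in dihedrals]),
        pair_i=ia(pi),
        pair_j=ia(pj),
        pair_eps=peps,
        pair_s=ps,
        pair_rcut=prc,
        pair_shift=_lj_shift(peps, ps, prc),
        wlo_s=fa([w.s_wall for w in system.wall_lower]),
        wlo_rcut=fa([w.r_cut for w in system.wall_lower]),
        wlo_eps=fa([w.epsilon for w in system.wall_lower]),
        wlo_shift=_lj_shift(
            fa([w.epsilon for w in system.wall_lower]),
            fa([w.s_wall for w in system.wall_lower]),
            fa([w.r_cut for w in system.wall_lower]),
        ),
        whi_s=fa([w.s_wall for w in system.wall_upper]),
        whi_rcut=fa([w.r_cut for w in system.wall_upper]),
        whi_eps=fa([w.epsilon for w in system.wall_upper]),
        whi_shift=_lj_shift(
            fa([w.epsilon for w in system.wall_upper]),
            fa([w.s_wall for w in system.wall_upper]),
            fa([w.r_cut for w in system.wall_upper]),
        ),
        n_pairs_nonbonded=n_nb,
    )


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mi(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def _disp(pos, a, b, lx, ly):
    """Minimum-image displacement pos[a] - pos[b]."""
    dx = _mi(pos[a, 0] - pos[b, 0], lx)
    dy = _mi(pos[a, 1] - pos[b, 1], ly)
    dz = pos[a, 2] - pos[b, 2]
    return dx, dy, dz


@njit(cache=True, inline="always")
def _lj_e_f(r, eps, s, rcut, shift):
    """Shifted, capped LJ: returns (energy, f_over_r) at separation r."""
    if r >= rcut or eps == 0.0:
        return 0.0, 0.0
    rcap = CAP_FRACTION * s
    if r < rcap:
        sr6 = (s / rcap) ** 6
        e_cap = 4.0 * eps * (sr6 * sr6 - sr6) - shift
        f_cap = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / rcap
        e = e_cap + f_cap * (rcap - r)
        rr = r if r > 1e-12 else 1e-12
        return e, f_cap / rr
    sr6 = (s / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6) - shift
    f_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / (r * r)
    return e, f_over_r


@njit(cache=True)
def _e_bonds(pos, F, do_force, lx, ly, bi, bj, bk, br0):
    e = 0.0
    for t in range(len(bi)):
        dx, dy, dz = _disp(pos, bi[t], bj[t], lx, ly)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[t]
        e += 0.5 * bk[t] * dr * dr
        if do_force and r > 1e-12:
            f = -bk[t] * dr / r
            F[bi[t], 0] += f * dx
            F[bi[t], 1] += f * dy
            F[bi[t], 2] += f * dz
            F[bj[t], 0] -= f * dx
            F[bj[t], 1] -= f * dy
            F[bj[t], 2] -= f * dz
    return e


@njit(cache=True)
def _e_angles(pos, F, do_force, lx, ly, ai, aj, ak, akf, at0, astyle):
    e = 0.0
    for t in range(len(ai)):
        ux, uy, uz = _disp(pos, ai[t], aj[t], lx, ly)
        vx, vy, vz = _disp(pos, ak[t], aj[t], lx, ly)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        th = np.arccos(ct)
        if astyle[t] == 0:
            dth = th - at0[t]
            e += 0.5 * akf[t] * dth * dth
            h = akf[t] * dth  # dE/dtheta
        else:
            e += akf[t] * (1.0 + ct)
            h = -akf[t] * np.sqrt(max(1.0 - ct * ct, 0.0))
        if do_force:
            st = np.sqrt(max(1.0 - ct * ct, 1e-16))
            g = h / st
            if astyle[t] == 0 and st < 1e-7 and at0[t] > 3.14:
                # theta -> pi limit of k (theta - pi) / sin(theta)
                g = -akf[t]
            elif astyle[t] == 1:
                g = -akf[t]
            # F_i = g * d cos(theta) / d r_i
            fi_x = g * (vx / (nu * nv) - ct * ux / (nu * nu))
            fi_y = g * (vy / (nu * nv) - ct * uy / (nu * nu))
            fi_z = g * (vz / (nu * nv) - ct * uz / (nu * nu))
            fk_x = g * (ux / (nu * nv) - ct * vx / (nv * nv))
            fk_y = g * (uy / (nu * nv) - ct * vy / (nv * nv))
            fk_z = g * (uz / (nu * nv) - ct * vz / (nv * nv))
            F[ai[t], 0] += fi_x
            F[ai[t], 1] += fi_y
            F[ai[t], 2] += fi_z
            F[ak[t], 0] += fk_x
            F[ak[t], 1] += fk_y
            F[ak[t], 2] += fk_z
            F[aj[t], 0] -= fi_x + fk_x
            F[aj[t], 1] -= fi_y + fk_y
            F[aj[t], 2] -= fi_z + fk_z
    return e


@njit(cache=True)
def _e_dihedrals(pos, F, do_force, lx, ly, di, dj, dk, dl, dkf, dp0):
    e = 0.0
    for t in range(len(di)):
        b1x, b1y, b1z = _disp(pos, dj[t], di[t], lx, ly)
        b2x, b2y, b2z = _disp(pos, dk[t], dj[t], lx, ly)
        b3x, b3y, b3z = _disp(pos, dl[t], dk[t], lx, ly)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if nb2 < 1e-12:
            continue
        # phi via atan2 for full range
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sin_term = (mx * b2x + my * b2y + mz * b2z) / nb2
        cos_term = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sin_term, cos_term)
        dphi = phi - dp0[t]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi < -np.pi:
            dphi += 2.0 * np.pi
        e += 0.5 * dkf[t] * dphi * dphi
        if do_force:
            h = dkf[t] * dphi  # dE/dphi
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if n1sq < 1e-14 or n2sq < 1e-14:
                continue
            # dphi/dr for the end atoms, then the middle atoms by the
            # standard chain-rule identities; F = -h dphi/dr
            c1 = -nb2 / n1sq
            c2 = nb2 / n2sq
            dix, diy, diz = c1 * n1x, c1 * n1y, c1 * n1z
            dlx, dly, dlz = c2 * n2x, c2 * n2y, c2 * n2z
            sv = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            sw = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            djx = -(1.0 + sv) * dix + sw * dlx
            djy = -(1.0 + sv) * diy + sw * dly
            djz = -(1.0 + sv) * diz + sw * dlz
            dkx = sv * dix - (1.0 + sw) * dlx
            dky = sv * diy - (1.0 + sw) * dly
            dkz = sv * diz - (1.0 + sw) * dlz
            fix, fiy, fiz = -h * dix, -h * diy, -h * diz
            flx, fly, flz = -h * dlx, -h * dly, -h * dlz
            fjx, fjy, fjz = -h * djx, -h * djy, -h * djz
            fkx, fky, fkz = -h * dkx, -h * dky, -h * dkz
            F[di[t], 0] += fix
            F[di[t], 1] += fiy
            F[di[t], 2] += fiz
            F[dj[t], 0] += fjx
            F[dj[t], 1] += fjy
            F[dj[t], 2] += fjz
            F[dk[t], 0] += fkx
            F[dk[t], 1] += fky
            F[dk[t], 2] += fkz
            F[dl[t], 0] += flx
            F[dl[t], 1] += fly
            F[dl[t], 2] += flz
    return e


@njit(cache=True)
def _e_pairs(pos, F, do_force, lx, ly, pi, pj, peps, ps, prcut, pshift, t0, t1):
    """Pair LJ energy for table rows [t0, t1)."""
    e = 0.0
    for t in range(t0, t1):
        dx, dy, dz = _disp(pos, pi[t], pj[t], lx, ly)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ei, f_over_r = _lj_e_f(r, peps[t], ps[t], prcut[t], pshift[t])
        e += ei
        if do_force and f_over_r != 0.0:
            F[pi[t], 0] += f_over_r * dx
            F[pi[t], 1] += f_over_r * dy
            F[pi[t], 2] += f_over_r * dz
            F[pj[t], 0] -= f_over_r * dx
            F[pj[t], 1] -= f_over_r * dy
            F[pj[t], 2] -= f_over_r * dz
    return e


@njit(cache=True)
def _e_walls(pos, F, do_force, lz, wlo_s, wlo_rcut, wlo_eps, wlo_shift,
             whi_s, whi_rcut, whi_eps, whi_shift):
    e = 0.0
    n = pos.shape[0]
    for b in range(n):
        z = pos[b, 2]
        if wlo_eps[b] != 0.0:
            ei, f_over_r = _lj_e_f(z, wlo_eps[b], wlo_s[b], wlo_rcut[b], wlo_shift[b])
            e += ei
            if do_force:
                F[b, 2] += f_over_r * z
        if whi_eps[b] != 0.0:
            zu = lz - z
            ei, f_over_r = _lj_e_f(zu, whi_eps[b], whi_s[b], whi_rcut[b], whi_shift[b])
            e += ei
            if do_force:
                F[b, 2] -= f_over_r * zu
    return e


@njit(cache=True)
def total_energy_forces(
    pos, F, do_force,
    lx, ly, lz,
    bi, bj, bk, br0,
    ai, aj, ak, akf, at0, astyle,
    di, dj, dk, dl, dkf, dp0,
    pi, pj, peps, ps, prcut, pshift,
    wlo_s, wlo_rcut, wlo_eps, wlo_shift,
    whi_s, whi_rcut, whi_eps, whi_shift,
):
    if do_force:
        F[:, :] = 0.0
    e = _e_bonds(pos, F, do_force, lx, ly, bi, bj, bk, br0)
    e += _e_angles(pos, F, do_force, lx, ly, ai, aj, ak, akf, at0, astyle)
    e += _e_dihedrals(pos, F, do_force, lx, ly, di, dj, dk, dl, dkf, dp0)
    e += _e_pairs(pos, F, do_force, lx, ly, pi, pj, peps, ps, prcut, pshift, 0, len(pi))
    e += _e_walls(pos, F, do_force, lz, wlo_s, wlo_rcut, wlo_eps, wlo_shift,
                  whi_s, whi_rcut, whi_eps, whi_shift)
    return e


@njit(cache=True)
def partial_energy(
    pos, moved,
    lx, ly, lz,
    bi, bj, bk, br0,
    ai, aj, ak, akf, at0, astyle,
    di, dj, dk, dl, dkf, dp0,
    pi, pj, peps, ps, prcut, pshift,
    wlo_s, wlo_rcut, wlo_eps, wlo_shift,
    whi_s, whi_rcut, whi_eps, whi_shift,
):
    """Energy of all terms touching at least one bead with moved[b] = True."""
    F = np.empty((0, 3))
    e = 0.0
    for t in range(len(bi)):
        if moved[bi[t]] or moved[bj[t]]:
            dx, dy, dz = _disp(pos, bi[t], bj[t], lx, ly)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - br0[t]
            e += 0.5 * bk[t] * dr * dr
    for t in range(len(ai)):
        if moved[ai[t]] or moved[aj[t]] or moved[ak[t]]:
            ux, uy, uz = _disp(pos, ai[t], aj[t], lx, ly)
            vx, vy, vz = _disp(pos, ak[t], aj[t], lx, ly)
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            if nu < 1e-12 or nv < 1e-12:
                continue
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            if astyle[t] == 0:
                dth = np.arccos(ct) - at0[t]
                e += 0.5 * akf[t] * dth * dth
            else:
                e += akf[t] * (1.0 + ct)
    for t in range(len(di)):
        if moved[di[t]] or moved[dj[t]] or moved[dk[t]] or moved[dl[t]]:
            sub_i = np.empty(1, np.int64); sub_i[0] = di[t]
            sub_j = np.empty(1, np.int64); sub_j[0] = dj[t]
            sub_k = np.empty(1, np.int64); sub_k[0] = dk[t]
            sub_l = np.empty(1, np.int64); sub_l[0] = dl[t]
            sub_kf = np.empty(1, np.float64); sub_kf[0] = dkf[t]
            sub_p0 = np.empty(1, np.float64); sub_p0[0] = dp0[t]
            e += _e_dihedrals(pos, F, False, lx, ly, sub_i, sub_j, sub_k, sub_l,
                              sub_kf, sub_p0)
    for t in range(len(pi)):
        if moved[pi[t]] or moved[pj[t]]:
            dx, dy, dz = _disp(pos, pi[t], pj[t], lx, ly)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            ei, _ = _lj_e_f(r, peps[t], ps[t], prcut[t], pshift[t])
            e += ei
    for b in range(pos.shape[0]):
        if moved[b]:
            z = pos[b, 2]
            if wlo_eps[b] != 0.0:
                ei, _ = _lj_e_f(z, wlo_eps[b], wlo_s[b], wlo_rcut[b], wlo_shift[b])
                e += ei
            if whi_eps[b] != 0.0:
                ei, _ = _lj_e_f(lz - z, whi_eps[b], whi_s[b], whi_rcut[b], whi_shift[b])
                e += ei
    return e


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def compute_forces(system: DiabodySystem, positions=None, ff: CompiledFF | None = None):
    """Forces (exact negative gradients of the potential) and total energy.

    Returns ``(forces, energy)``; ``energy_components`` gives the per-term
    breakdown for logging.
    """
    if ff is None:
        ff = compile_forcefield(system)
    pos = np.asarray(system.positions if positions is None else positions, dtype=float)
    F = np.zeros_like(pos)
    e = total_energy_forces(pos, F, True, *ff.args())
    return F, float(e)


def total_energy(system: DiabodySystem, positions=None, ff: CompiledFF | None = None) -> float:
    if ff is None:
        ff = compile_forcefield(system)
    pos = np.asarray(system.positions if positions is None else positions, dtype=float)
    F = np.zeros((0, 3))
    return float(
        total_energy_forces(pos, F, False, *ff.args())
    )


def energy_components(system: DiabodySystem, positions=None, ff: CompiledFF | None = None) -> dict:
    """Energy decomposed by term: bond, angle, dihedral, pair, tether, wall."""
    if ff is None:
        ff = compile_forcefield(system)
    pos = np.asarray(system.positions if positions is None else positions, dtype=float)
    F = np.zeros((0, 3))
    a = ff
    out = {
        "bond": _e_bonds(pos, F, False, a.lx, a.ly, a.bond_i, a.bond_j, a.bond_k, a.bond_r0),
        "angle": _e_angles(pos, F, False, a.lx, a.ly, a.ang_i, a.ang_j, a.ang_k,
                           a.ang_kf, a.ang_t0, a.ang_style),
        "dihedral": _e_dihedrals(pos, F, False, a.lx, a.ly, a.dih_i, a.dih_j, a.dih_k,
                                 a.dih_l, a.dih_kf, a.dih_p0),
        "pair": _e_pairs(pos, F, False, a.lx, a.ly, a.pair_i, a.pair_j, a.pair_eps,
                         a.pair_s, a.pair_rcut, a.pair_shift, 0, a.n_pairs_nonbonded),
        "tether": _e_pairs(pos, F, False, a.lx, a.ly, a.pair_i, a.pair_j, a.pair_eps,
                           a.pair_s, a.pair_rcut, a.pair_shift, a.n_pairs_nonbonded,
                           len(a.pair_i)),
        "wall": _e_walls(pos, F, False, a.lz, a.wlo_s, a.wlo_rcut, a.wlo_eps, a.wlo_shift,
                         a.whi_s, a.whi_rcut, a.whi_eps, a.whi_shift),
    }
    return {k: float(v) for k, v in out.items()}
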