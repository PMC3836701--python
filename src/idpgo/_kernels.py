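"""Numba kernels: energy/force evaluation, SHAKE/RATTLE, BAOAB integrator.

All kernels work in kcal/mol, Angstrom, ps, Da.  Coordinates are kept
unwrapped; the minimum-image convention is applied per interaction, which is
exact for a cubic box with edge > 2 x cutoff.  Energy components are indexed
by the ``E_*`` constants below.
"""

import numpy as np
from numba import njit

from .constants import KCAL_TO_DA_A2_PS2

E_BOND, E_ANGLE, E_DIHEDRAL, E_CONTACT_INTRA, E_CONTACT_INTER, \
    E_EXCLUDED, E_ELEC, E_RESTRAINT = range(8)
N_COMPONENTS = 8


@njit(cache=True)
def _mi(d, box):
    return d - box * np.rint(d / box)


@njit(cache=True)
def energy_forces(
    pos, box,
    bonds, bond_r0, k_bond, bond_energy_on,
    angles, theta0, k_theta,
    dihedrals, phi0, k_dih1, k_dih3,
    cpairs, c_rnat, c_eps, c_inter,
    nn_pairs, sigma_rep, eps_rep,
    e_pairs, e_qq, kappa, coul_pref, cutoff,
    zn_pairs, zn_r0, zn_k,
    forces,
):
    """Potential energy components and forces (-gradient).

    ``coul_pref`` is k_C / eps_r; ``kappa`` = 1/Debye length (0 for no salt).
    Contact, excluded-volume and electrostatic terms are shifted to zero at
    the cutoff.  Returns the (8,) component array; ``forces`` is filled in
    place.  Raises no exceptions; overlap detection is the caller's job.
    """
    comp = np.zeros(N_COMPONENTS)
    forces[:] = 0.0

    # bonds (harmonic; zero when SHAKE maintains the lengths)
    if bond_energy_on:
        for b in range(bonds.shape[0]):
            i, j = bonds[b, 0], bonds[b, 1]
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - bond_r0[b]
            comp[E_BOND] += k_bond * dr * dr
            f = -2.0 * k_bond * dr / r
            forces[i, 0] += f * dx; forces[i, 1] += f * dy; forces[i, 2] += f * dz
            forces[j, 0] -= f * dx; forces[j, 1] -= f * dy; forces[j, 2] -= f * dz

    # angles
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = _mi(pos[i, 0] - pos[j, 0], box)
        uy = _mi(pos[i, 1] - pos[j, 1], box)
        uz = _mi(pos[i, 2] - pos[j, 2], box)
        vx = _mi(pos[k, 0] - pos[j, 0], box)
        vy = _mi(pos[k, 1] - pos[j, 1], box)
        vz = _mi(pos[k, 2] - pos[j, 2], box)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosq = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = np.arccos(cosq)
        sinq = np.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            sinq = 1e-8
        dth = theta - theta0[a]
        comp[E_ANGLE] += k_theta * dth * dth
        coef = -2.0 * k_theta * dth
        # dtheta/dri = (cos * u_hat - v_hat) / (|u| sin)
        gix = (cosq * ux / nu - vx / nv) / (nu * sinq)
        giy = (cosq * uy / nu - vy / nv) / (nu * sinq)
        giz = (cosq * uz / nu - vz / nv) / (nu * sinq)
        gkx = (cosq * vx / nv - ux / nu) / (nv * sinq)
        gky = (cosq * vy / nv - uy / nu) / (nv * sinq)
        gkz = (cosq * vz / nv - uz / nu) / (nv * sinq)
        forces[i, 0] += coef * gix; forces[i, 1] += coef * giy; forces[i, 2] += coef * giz
        forces[k, 0] += coef * gkx; forces[k, 1] += coef * gky; forces[k, 2] += coef * gkz
        forces[j, 0] -= coef * (gix + gkx)
        forces[j, 1] -= coef * (giy + gky)
        forces[j, 2] -= coef * (giz + gkz)

    # dihedrals: U = k1 (1 - cos(phi - phi0)) + k3 (1 - cos(3 (phi - phi0)))
    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x = _mi(pos[j, 0] - pos[i, 0], box)
        b1y = _mi(pos[j, 1] - pos[i, 1], box)
        b1z = _mi(pos[j, 2] - pos[i, 2], box)
        b2x = _mi(pos[k, 0] - pos[j, 0], box)
        b2y = _mi(pos[k, 1] - pos[j, 1], box)
        b2z = _mi(pos[k, 2] - pos[j, 2], box)
        b3x = _mi(pos[l, 0] - pos[k, 0], box)
        b3y = _mi(pos[l, 1] - pos[k, 1], box)
        b3z = _mi(pos[l, 2] - pos[k, 2], box)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        y = (cx * b2x + cy * b2y + cz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        dphi = phi - phi0[d]
        comp[E_DIHEDRAL] += k_dih1 * (1.0 - np.cos(dphi)) + k_dih3 * (1.0 - np.cos(3.0 * dphi))
        dudphi = k_dih1 * np.sin(dphi) + 3.0 * k_dih3 * np.sin(3.0 * dphi)
        # dphi/dri = -(|b2|/|n1|^2) n1 ; dphi/drl = (|b2|/|n2|^2) n2
        six = -nb2 / n1sq * n1x
        siy = -nb2 / n1sq * n1y
        siz = -nb2 / n1sq * n1z
        slx = nb2 / n2sq * n2x
        sly = nb2 / n2sq * n2y
        slz = nb2 / n2sq * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        sjx = -(1.0 + c12) * six + c32 * slx
        sjy = -(1.0 + c12) * siy + c32 * sly
        sjz = -(1.0 + c12) * siz + c32 * slz
        skx = -six - sjx - slx
        sky = -siy - sjy - sly
        skz = -siz - sjz - slz
        forces[i, 0] -= dudphi * six; forces[i, 1] -= dudphi * siy; forces[i, 2] -= dudphi * siz
        forces[j, 0] -= dudphi * sjx; forces[j, 1] -= dudphi * sjy; forces[j, 2] -= dudphi * sjz
        forces[k, 0] -= dudphi * skx; forces[k, 1] -= dudphi * sky; forces[k, 2] -= dudphi * skz
        forces[l, 0] -= dudphi * slx; forces[l, 1] -= dudphi * sly; forces[l, 2] -= dudphi * slz

    # native contacts: 12-10 well, shifted to zero at the cutoff
    for c in range(cpairs.shape[0]):
        i, j = cpairs[c, 0], cpairs[c, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        r = np.sqrt(r2)
        xr = c_rnat[c] / r
        x10 = xr ** 10
        x12 = x10 * xr * xr
        xc = c_rnat[c] / cutoff
        shift = 5.0 * xc ** 12 - 6.0 * xc ** 10
        u = c_eps[c] * (5.0 * x12 - 6.0 * x10 - shift)
        if c_inter[c]:
            comp[E_CONTACT_INTER] += u
        else:
            comp[E_CONTACT_INTRA] += u
        # dU/dr = 60 eps (rnat^10/r^11) (1 - (rnat/r)^2); F = -dU/dr * rhat
        dudr = 60.0 * c_eps[c] * x10 / r * (1.0 - xr * xr)
        f = -dudr / r
        forces[i, 0] += f * dx; forces[i, 1] += f * dy; forces[i, 2] += f * dz
        forces[j, 0] -= f * dx; forces[j, 1] -= f * dy; forces[j, 2] -= f * dz

    # non-native excluded volume: eps_rep (sigma/r)^12, shifted
    sc12 = (sigma_rep / cutoff) ** 12
    for p in range(nn_pairs.shape[0]):
        i, j = nn_pairs[p, 0], nn_pairs[p, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        r = np.sqrt(r2)
        s12 = (sigma_rep / r) ** 12
        comp[E_EXCLUDED] += eps_rep * (s12 - sc12)
        f = 12.0 * eps_rep * s12 / r2
        forces[i, 0] += f * dx; forces[i, 1] += f * dy; forces[i, 2] += f * dz
        forces[j, 0] -= f * dx; forces[j, 1] -= f * dy; forces[j, 2] -= f * dz

    # Debye-Hueckel electrostatics, shifted
    for p in range(e_pairs.shape[0]):
        i, j = e_pairs[p, 0], e_pairs[p, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        r = np.sqrt(r2)
        a = coul_pref * e_qq[p]
        u = a * np.exp(-kappa * r) / r
        ushift = a * np.exp(-kappa * cutoff) / cutoff
        comp[E_ELEC] += u - ushift
        # dU/dr = -A e^{-kr} (k r + 1)/r^2
        dudr = -a * np.exp(-kappa * r) * (kappa * r + 1.0) / r2
        f = -dudr / r
        forces[i, 0] += f * dx; forces[i, 1] += f * dy; forces[i, 2] += f * dz
        forces[j, 0] -= f * dx; forces[j, 1] -= f * dy; forces[j, 2] -= f * dz

    # harmonic metal-site restraints (not cut off, not shifted)
    for p in range(zn_pairs.shape[0]):
        i, j = zn_pairs[p, 0], zn_pairs[p, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - zn_r0[p]
        comp[E_RESTRAINT] += zn_k * dr * dr
        f = -2.0 * zn_k * dr / r
        forces[i, 0] += f * dx; forces[i, 1] += f * dy; forces[i, 2] += f * dz
        forces[j, 0] -= f * dx; forces[j, 1] -= f * dy; forces[j, 2] -= f * dz

    return comp


@njit(cache=True)
def shake(pos, ref, bonds, bond_r0, invm, tol, max_iter):
    """Iteratively project positions onto the bond-length constraints.

    ``ref`` holds the pre-drift positions (constraint directions).
    Relative tolerance ``tol`` on |r - r0|/r0.  Returns the number of
    iterations used, or -1 on non-convergence.
    """
    nb = bonds.shape[0]
    if nb == 0:
        return 0
    for it in range(max_iter):
        worst = 0.0
        for b in range(nb):
            i, j = bonds[b, 0], bonds[b, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r0 = bond_r0[b]
            diff = r2 - r0 * r0
            rel = abs(np.sqrt(r2) - r0) / r0
            if rel > worst:
                worst = rel
            rx = ref[i, 0] - ref[j, 0]
            ry = ref[i, 1] - ref[j, 1]
            rz = ref[i, 2] - ref[j, 2]
            dot = rx * dx + ry * dy + rz * dz
            if abs(dot) < 1e-12:
                dot = 1e-12
            g = diff / (2.0 * (invm[i] + invm[j]) * dot)
            pos[i, 0] -= g * invm[i] * rx
            pos[i, 1] -= g * invm[i] * ry
            pos[i, 2] -= g * invm[i] * rz
            pos[j, 0] += g * invm[j] * rx
            pos[j, 1] += g * invm[j] * ry
            pos[j, 2] += g * invm[j] * rz
        if worst < tol:
            return it + 1
    return -1


@njit(cache=True)
def rattle(pos, vel, bonds, invm, tol, max_iter):
    """Project out velocity components along the constrained bonds."""
    nb = bonds.shape[0]
    if nb == 0:
        return 0
    for it in range(max_iter):
        worst = 0.0
        for b in range(nb):
            i, j = bonds[b, 0], bonds[b, 1]
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            rv = rx * vx + ry * vy + rz * vz
            rel = abs(rv) / r2
            if rel > worst:
                worst = rel
            kfac = rv / ((invm[i] + invm[j]) * r2)
            vel[i, 0] -= kfac * invm[i] * rx
            vel[i, 1] -= kfac * invm[i] * ry
            vel[i, 2] -= kfac * invm[i] * rz
            vel[j, 0] += kfac * invm[j] * rx
            vel[j, 1] += kfac * invm[j] * ry
            vel[j, 2] += kfac * invm[j] * rz
        if worst < tol:
            return it + 1
    return -1


@njit(cache=True)
def integrate(
    pos, vel, masses, box,
    bonds, bond_r0,
    angles, theta0, k_theta,
    dihedrals, phi0, k_dih1, k_dih3,
    cpairs, c_rnat, c_eps, c_inter,
    nn_pairs, sigma_rep, eps_rep,
    e_pairs, e_qq, kappa, coul_pref, cutoff,
    zn_pairs, zn_r0, zn_k,
    dt, gamma, kt, n_steps, save_every, seed,
    shake_tol, shake_max_iter,
    out_pos, out_pe, out_ke,
):
    """BAOAB Langevin integrator with SHAKE-constrained virtual bonds.

    Saves a frame every ``save_every`` steps into the pre-allocated outputs.
    Returns (status, step): status 0 = ok, 1 = SHAKE failure,
    2 = non-finite coordinates.  Bit-reproducible for fixed inputs and seed.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    invm = 1.0 / masses
    half = 0.5 * dt
    c1 = np.exp(-gamma * dt)
    forces = np.zeros((n, 3))
    ref = np.zeros((n, 3))
    comp = energy_forces(
        pos, box, bonds, bond_r0, 0.0, False,
        angles, theta0, k_theta, dihedrals, phi0, k_dih1, k_dih3,
        cpairs, c_rnat, c_eps, c_inter, nn_pairs, sigma_rep, eps_rep,
        e_pairs, e_qq, kappa, coul_pref, cutoff, zn_pairs, zn_r0, zn_k,
        forces,
    )
    frame = 0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            f = half * KCAL_TO_DA_A2_PS2 * invm[i]
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        # A: half drift + SHAKE
        for i in range(n):
            ref[i, 0] = pos[i, 0]; ref[i, 1] = pos[i, 1]; ref[i, 2] = pos[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if shake(pos, ref, bonds, bond_r0, invm, shake_tol, shake_max_iter) < 0:
            return 1, step
        for i in range(n):
            vel[i, 0] = (pos[i, 0] - ref[i, 0]) / half
            vel[i, 1] = (pos[i, 1] - ref[i, 1]) / half
            vel[i, 2] = (pos[i, 2] - ref[i, 2]) / half
        # O: exact Ornstein-Uhlenbeck step + RATTLE
        if gamma > 0.0:
            for i in range(n):
                sig = np.sqrt(kt * KCAL_TO_DA_A2_PS2 * invm[i] * (1.0 - c1 * c1))
                vel[i, 0] = c1 * vel[i, 0] + sig * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + sig * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + sig * np.random.standard_normal()
            rattle(pos, vel, bonds, invm, 1e-10, shake_max_iter)
        # A: half drift + SHAKE
        for i in range(n):
            ref[i, 0] = pos[i, 0]; ref[i, 1] = pos[i, 1]; ref[i, 2] = pos[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if shake(pos, ref, bonds, bond_r0, invm, shake_tol, shake_max_iter) < 0:
            return 1, step
        for i in range(n):
            vel[i, 0] = (pos[i, 0] - ref[i, 0]) / half
            vel[i, 1] = (pos[i, 1] - ref[i, 1]) / half
            vel[i, 2] = (pos[i, 2] - ref[i, 2]) / half
        # B: half kick with fresh forces, then RATTLE
        comp = energy_forces(
            pos, box, bonds, bond_r0, 0.0, False,
            angles, theta0, k_theta, dihedrals, phi0, k_dih1, k_dih3,
            cpairs, c_rnat, c_eps, c_inter, nn_pairs, sigma_rep, eps_rep,
            e_pairs, e_qq, kappa, coul_pref, cutoff, zn_pairs, zn_r0, zn_k,
            forces,
        )
        for i in range(n):
            f = half * KCAL_TO_DA_A2_PS2 * invm[i]
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        rattle(pos, vel, bonds, invm, 1e-10, shake_max_iter)

        if (step + 1) % save_every == 0:
            pe = 0.0
            for c in range(N_COMPONENTS):
                pe += comp[c]
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                ) / KCAL_TO_DA_A2_PS2
            if not (np.isfinite(pe) and np.isfinite(pos[0, 0])):
                return 2, step
            out_pe[frame] = pe
            out_ke[frame] = ke
            for i in range(n):
                out_pos[frame, i, 0] = pos[i, 0]
                out_pos[frame, i, 1] = pos[i, 1]
                out_pos[frame, i, 2] = pos[i, 2]
            frame += 1
    return 0, n_steps
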