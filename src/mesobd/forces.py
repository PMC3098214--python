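"""Pairwise and external force/energy evaluation.

All energies are handled in units of kT and forces in kT/nm, so the
propagation step ``dx = D * F * dt`` needs no further conversion.  Fixed
structures exert forces on mobile gestalten but never on each other, so
with ``N_p`` mobile particles and ``N_o`` fixed spheres the number of pair
interactions per step is ``N_p (N_p - 1) / 2 + N_p N_o``.

The three pair kernels (screened Coulomb, colour-indexed Lennard-Jones in
the surface-surface distance, harmonic/quartic bonds) are implemented once
in vectorised form; the scalar functions exposed for single pairs wrap the
same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundaries import minimum_image
from .model import Bond, ColourPair, quat_rotate

__all__ = [
    "ForceAccumulator", "SingularConfigurationError", "COULOMB_KDA_NM3_PS2",
    "accumulate", "bond_forces", "coulomb_constant_kT_nm",
    "electrostatic_pair", "external_forces", "pair_interaction_count",
    "vdw_pair",
]

#: e^2 / (4 pi eps_0) in kDa nm^3 ps^-2 (multiply by 1/(eps_r r) for energy)
COULOMB_KDA_NM3_PS2 = 0.1389355


class SingularConfigurationError(ValueError):
    """Two interaction sites coincide; the pair force direction is undefined."""


def coulomb_constant_kT_nm(kT: float) -> float:
    """Coulomb prefactor e^2/(4 pi eps_0) expressed in kT nm at thermal
    energy ``kT`` (kDa nm^2 ps^-2).  Dividing by eps_r gives the Bjerrum
    length in nm."""
    return COULOMB_KDA_NM3_PS2 / kT


@dataclass
class ForceAccumulator:
    """Per-gestalt force (kT/nm) and torque (kT) about the gestalt origin,
    with the running pair count and potential energy.  A fresh accumulator
    is created (i.e. reset to zero) at the start of every timestep."""

    force: np.ndarray     # (M, G, 3)
    torque: np.ndarray    # (M, G, 3)
    energy: np.ndarray    # (M,)
    n_int: np.ndarray     # (M,)


def pair_interaction_count(n_mobile, n_fixed) -> np.ndarray:
    """Pairwise interactions per step: mobile-mobile pairs once each plus
    mobile-fixed pairs; fixed-fixed pairs are never evaluated."""
    n_mobile = np.asarray(n_mobile)
    return n_mobile * (n_mobile - 1) // 2 + n_mobile * n_fixed


# ---------------------------------------------------------------------------
# kernels (vectorised; r arrays may carry any shape)


def _coulomb_kernel(r, qq_eff, kappa, B):
    """Energy (kT) and radial derivative dU/dr for U = qq_eff
    exp(-kappa (r - B)) / r.  ``qq_eff`` absorbs the Coulomb constant,
    1/eps_r and the charge product."""
    U = qq_eff * np.exp(-kappa * (r - B)) / r
    dUdr = -U * (kappa + 1.0 / r)
    return U, dUdr


def _vdw_kernel(r12, eps, sigma, attractive, r_lin):
    """Energy and dU/dr12 of the colour potential with linearised core.

    Attractive pairs: U = eps ((sigma/r)^12 - 2 (sigma/r)^6), minimum -eps
    at r12 = sigma.  Repulsive-only pairs keep the (sigma/r)^12 branch.
    Below ``r_lin`` the force is held constant and the energy continued
    linearly, which keeps insertion overlaps and hard collisions finite.
    """
    x = np.maximum(r12, r_lin)
    t = sigma / x
    t2 = t * t
    s6 = t2 * t2 * t2
    s12 = s6 * s6
    U0 = np.where(attractive, eps * (s12 - 2.0 * s6), eps * s12)
    dU0 = np.where(attractive,
                   -12.0 * eps * (s12 - s6) / x,
                   -12.0 * eps * s12 / x)
    below = r12 < r_lin
    U = np.where(below, U0 + dU0 * (r12 - r_lin), U0)
    return U, dU0  # dU/dr12 is dU0 everywhere (constant below the joint)


def _bond_kernel(d, k2, k4, l0):
    x = d - l0
    U = 0.5 * k2 * x * x + 0.25 * k4 * x ** 4
    dUdd = k2 * x + k4 * x ** 3
    return U, dUdd


# ---------------------------------------------------------------------------
# scalar pair API


def electrostatic_pair(pos_i, q_i, b_i, pos_k, q_k, b_k,
                       kappa: float = 0.0, eps_r: float = 80.0,
                       kT: float = 2.4361e-3):
    """Screened Coulomb interaction of two world-frame point charges.

    Returns ``(energy_kT, force_on_i)``.  The summed burial depths
    ``B = b_i + b_k`` are exempted from screening (the stretch of the
    separation buried inside the low-dielectric particles sees no counter
    ions).  Beyond ``r = B + 5/kappa`` the interaction is cut off (< 1% of
    its contact value).
    """
    rvec = np.asarray(pos_i, dtype=float) - np.asarray(pos_k, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r < 1e-12:
        raise SingularConfigurationError("coincident point charges")
    if q_i == 0.0 or q_k == 0.0:
        return 0.0, np.zeros(3)
    B = b_i + b_k
    if kappa > 0.0 and r > B + 5.0 / kappa:
        return 0.0, np.zeros(3)
    qq_eff = coulomb_constant_kT_nm(kT) * q_i * q_k / eps_r
    U, dUdr = _coulomb_kernel(r, qq_eff, kappa, B)
    return float(U), -dUdr * rvec / r


def vdw_pair(pos_i, radius_i, pos_k, radius_k, params: ColourPair):
    """Colour-potential interaction of two vdW spheres at world positions.

    Returns ``(energy_kT, force_on_i)``; zero beyond the surface-distance
    cutoff."""
    rvec = np.asarray(pos_i, dtype=float) - np.asarray(pos_k, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r < 1e-12:
        raise SingularConfigurationError("coincident vdW spheres")
    r12 = r - radius_i - radius_k
    if r12 > params.cutoff_value:
        return 0.0, np.zeros(3)
    r_lin = params.r_lin_value(radius_i, radius_k)
    U, dUdr = _vdw_kernel(r12, params.epsilon, params.sigma,
                          params.attractive, r_lin)
    return float(U), -float(dUdr) * rvec / r


def bond_forces(bond: Bond, pos_a, quat_a, pos_b, quat_b):
    """Forces and torques a harmonic/quartic bond exerts on its gestalten.

    Hook world positions are gestalt position plus rotated hook offset;
    the bond force applied at an eccentric hook exerts the torque
    ``offset x force`` about the gestalt origin.  Returns
    ``(energy, f_a, torque_a, f_b, torque_b)``.
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    off_a = quat_rotate(np.asarray(quat_a, dtype=float), np.asarray(bond.hook_a))
    off_b = quat_rotate(np.asarray(quat_b, dtype=float), np.asarray(bond.hook_b))
    dvec = (pos_a + off_a) - (pos_b + off_b)
    d = float(np.linalg.norm(dvec))
    if d < 1e-12:
        # direction undefined at exactly zero extension; documented tie-break
        dhat = np.array([1.0, 0.0, 0.0])
    else:
        dhat = dvec / d
    U, dUdd = _bond_kernel(d, bond.k2, bond.k4, bond.length)
    f_a = -dUdd * dhat
    f_b = -f_a
    return float(U), f_a, np.cross(off_a, f_a), f_b, np.cross(off_b, f_b)


def external_forces(pos, harmonic=None, constant=None):
    """Force contribution of external restraints at a gestalt position."""
    pos = np.asarray(pos, dtype=float)
    f = np.zeros(3)
    U = 0.0
    if harmonic is not None:
        dx = pos - np.asarray(harmonic.center)
        f += -harmonic.k * dx
        U += 0.5 * harmonic.k * float(dx @ dx)
    if constant is not None:
        f += np.asarray(constant.f)
    return U, f


# ---------------------------------------------------------------------------
# system-wide accumulation


def accumulate(system, state) -> ForceAccumulator:
    """Evaluate all pair and external interactions for every replica.

    Mobile-mobile pairs are looped once each (Newton's third law is exact
    by construction), mobile-fixed pairs once, fixed-fixed never.  Under
    periodic boundary modes the minimum-image separation is used.
    """
    M, G = state.pos.shape[:2]
    box = system.box
    force = np.zeros((M, G, 3))
    torque = np.zeros((M, G, 3)) if system.needs_torque else None
    energy = np.zeros(M)

    # ---- vdW spheres (dense masked arithmetic; pair lists do not pay off
    # at the system sizes this engine targets).  With interface-managed
    # populations most capacity slots are dormant, so the pair work is
    # compacted to spheres active in at least one replica.
    if system.n_sphere:
        P_full = system.sphere_world_positions(state)      # (M, S, 3)
        if state.active.all():
            sub = None
            P = P_full
            act = None
            pv, pc2, prs, pcu = (system.pp_valid, system.pp_cut2,
                                 system.pp_rsum, system.pp_cut)
            pe, ps, pa, pl = (system.pp_eps, system.pp_sig, system.pp_att,
                              system.pp_rlin)
        else:
            act_s = state.active[:, system.sph_owner]
            sub = np.flatnonzero(act_s.any(axis=0))
            P = P_full[:, sub]
            act = act_s[:, sub]
            ix = np.ix_(sub, sub)
            pv, pc2, prs, pcu = (system.pp_valid[ix], system.pp_cut2[ix],
                                 system.pp_rsum[ix], system.pp_cut[ix])
            pe, ps, pa, pl = (system.pp_eps[ix], system.pp_sig[ix],
                              system.pp_att[ix], system.pp_rlin[ix])

        dvec = P[:, :, None, :] - P[:, None, :, :]
        minimum_image(dvec, box)
        r2 = (dvec[..., 0] ** 2 + dvec[..., 1] ** 2 + dvec[..., 2] ** 2)
        mask = pv[None] & (r2 < pc2[None])
        if act is not None:
            mask = mask & act[:, :, None] & act[:, None, :]
        r = np.sqrt(np.where(mask, r2, 1.0))
        r12 = np.where(mask, r - prs[None], pcu[None])
        U, dUdr = _vdw_kernel(r12, pe[None], ps[None], pa[None], pl[None])
        w = np.where(mask, -dUdr / r, 0.0)
        energy += np.sum(np.where(mask, U, 0.0), axis=(1, 2))
        fmat = w[..., None] * dvec                         # force on i from k
        f_sub = fmat.sum(axis=2) - fmat.sum(axis=1)

        # mobile vs fixed spheres
        if system.n_wall_sphere:
            pw = slice(None) if sub is None else sub
            dw = P[:, :, None, :] - system.wall_sph_pos[None, None, :, :]
            minimum_image(dw, box)
            rw2 = dw[..., 0] ** 2 + dw[..., 1] ** 2 + dw[..., 2] ** 2
            wmask = rw2 < system.pw_cut2[pw][None]
            if act is not None:
                wmask = wmask & act[:, :, None]
            rw = np.sqrt(np.where(wmask, rw2, 1.0))
            rw12 = np.where(wmask, rw - system.pw_rsum[pw][None],
                            system.pw_cut[pw][None])
            Uw, dUwdr = _vdw_kernel(rw12, system.pw_eps[pw][None],
                                    system.pw_sig[pw][None],
                                    system.pw_att[pw][None],
                                    system.pw_rlin[pw][None])
            ww = np.where(wmask, -dUwdr / rw, 0.0)
            energy += np.sum(np.where(wmask, Uw, 0.0), axis=(1, 2))
            f_sub += (ww[..., None] * dw).sum(axis=2)

        if sub is None:
            f_sph = f_sub
        else:
            f_sph = np.zeros((M, system.n_sphere, 3))
            f_sph[:, sub] = f_sub
        force += f_sph if system.sph_identity else np.matmul(
            system.sph_incidence, f_sph)
        if torque is not None and system.sph_has_offsets:
            lever = P_full - state.pos[:, system.sph_owner, :]
            tq = np.cross(lever, f_sph)
            torque += tq if system.sph_identity else np.matmul(
                system.sph_incidence, tq)

    # ---- point charges
    if system.n_charge:
        _accumulate_charges(system, state, force, torque, energy)

    # ---- bonds
    if system.n_bond:
        qa = state.quat[:, system.bond_a, :]
        qb = state.quat[:, system.bond_b, :]
        ha = quat_rotate(qa, system.bond_hook_a) if system.bond_eccentric else 0.0
        hb = quat_rotate(qb, system.bond_hook_b) if system.bond_eccentric else 0.0
        dvec = (state.pos[:, system.bond_a, :] + ha
                - state.pos[:, system.bond_b, :] - hb)
        minimum_image(dvec, box)
        d = np.linalg.norm(dvec, axis=-1)
        degenerate = d < 1e-12
        if degenerate.any():
            dvec[degenerate] = (1.0, 0.0, 0.0)
            d = np.where(degenerate, 1.0, d)
        U, dUdd = _bond_kernel(d, system.bond_k2, system.bond_k4, system.bond_l0)
        energy += U.sum(axis=1)
        f_a = (-dUdd / d)[..., None] * dvec                  # (M, B, 3)
        force += np.matmul(system.bond_inc_a, f_a)
        force -= np.matmul(system.bond_inc_b, f_a)
        if torque is not None and system.bond_eccentric:
            torque += np.matmul(system.bond_inc_a, np.cross(ha, f_a))
            torque += np.matmul(system.bond_inc_b, np.cross(hb, -f_a))

    # ---- external restraints
    if system.has_restraints:
        dx = state.pos - system.harm_c[None]
        fh = -system.harm_k[None, :, None] * dx
        energy += 0.5 * np.einsum(
            "mgd,mgd->m", system.harm_k[None, :, None] * dx, dx * state.active[..., None])
        force += (fh + system.const_f[None]) * state.active[..., None]

    force *= state.active[..., None]
    n_mobile = state.active.sum(axis=1)
    acc = ForceAccumulator(
        force=force,
        torque=torque if torque is not None else np.zeros((M, G, 3)),
        energy=energy,
        n_int=pair_interaction_count(n_mobile, system.n_wall_sphere),
    )
    return acc


def _accumulate_charges(system, state, force, torque, energy):
    box = system.box
    base = state.pos[:, system.chg_owner, :]
    if system.chg_has_offsets:
        P = base + quat_rotate(state.quat[:, system.chg_owner, :], system.chg_offset)
    else:
        P = base
    act = state.active[:, system.chg_owner]
    dvec = P[:, :, None, :] - P[:, None, :, :]
    minimum_image(dvec, box)
    r2 = np.einsum("mikd,mikd->mik", dvec, dvec)
    kT, kappa, eps_r = system.kT, system.kappa, system.eps_r
    qq = (coulomb_constant_kT_nm(kT) / eps_r
          * system.chg_q[:, None] * system.chg_q[None, :])
    B = system.chg_b[:, None] + system.chg_b[None, :]
    cut = B + (5.0 / kappa if kappa > 0 else np.inf)
    mask = (system.cc_valid[None] & act[:, :, None] & act[:, None, :]
            & (r2 < cut[None] ** 2) & (qq[None] != 0.0))
    f_chg = np.zeros_like(P)
    if mask.any():
        mi, ii, kk = np.nonzero(mask)
        r = np.sqrt(r2[mi, ii, kk])
        U, dUdr = _coulomb_kernel(r, qq[ii, kk], kappa, B[ii, kk])
        np.add.at(energy, mi, U)
        fpair = (-dUdr / r)[:, None] * dvec[mi, ii, kk]
        np.add.at(f_chg, (mi, ii), fpair)
        np.add.at(f_chg, (mi, kk), -fpair)
    # mobile charges vs fixed wall charges
    if len(system.wall_chg_q):
        dw = P[:, :, None, :] - system.wall_chg_pos[None, None, :, :]
        minimum_image(dw, box)
        rw = np.sqrt(np.einsum("miwd,miwd->miw", dw, dw))
        qqw = (coulomb_constant_kT_nm(kT) / eps_r
               * system.chg_q[:, None] * system.wall_chg_q[None, :])
        Bw = system.chg_b[:, None] + system.wall_chg_b[None, :]
        cutw = Bw + (5.0 / kappa if kappa > 0 else np.inf)
        wmask = act[:, :, None] & (rw < cutw[None]) & (qqw[None] != 0.0)
        if wmask.any():
            mi, ii, ww = np.nonzero(wmask)
            U, dUdr = _coulomb_kernel(rw[mi, ii, ww], qqw[ii, ww], kappa,
                                      Bw[ii, ww])
            np.add.at(energy, mi, U)
            fw = (-dUdr / rw[mi, ii, ww])[:, None] * dw[mi, ii, ww]
            np.add.at(f_chg, (mi, ii), fw)
    force += np.matmul(system.chg_incidence, f_chg)
    if torque is not None and system.chg_has_offsets:
        lever = P - state.pos[:, system.chg_owner, :]
        torque += np.matmul(system.chg_incidence, np.cross(lever, f_chg))
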