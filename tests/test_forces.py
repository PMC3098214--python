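"""Pair potentials, bonds, restraints and the system-wide accumulator."""

import numpy as np
import pytest
import scipy.constants as const

from mesobd import (Bond, ColourPair, ColourTable, ConstantForce, GeomSpec,
                    GestaltTemplate, HarmonicRestraint, PointCharge,
                    ProteinTemplate, SimulationBox, SystemBuilder, VdWSphere)
from mesobd.forces import (SingularConfigurationError, accumulate,
                           bond_forces, electrostatic_pair, external_forces,
                           pair_interaction_count, vdw_pair)
from mesobd.model import (quat_identity, quat_multiply, quat_normalize,
                          quat_rotate)

from conftest import FREE_BOX

KT = 2.4361e-3
KDA_NM2_PS2_IN_J = 1.66053906660e-18


# ---------------------------------------------------------------------------
# screened Coulomb


def test_zero_charge_is_inert():
    U, f = electrostatic_pair((0, 0, 0), 1.0, 0.0, (1, 0, 0), 0.0, 0.0)
    assert U == 0.0 and np.all(f == 0.0)


def test_unit_charges_at_bjerrum_length_cost_one_kT():
    """The Bjerrum length computed from physical constants must give an
    interaction energy of exactly 1 kT (independent oracle for the
    Coulomb prefactor and unit system)."""
    eps_r = 80.0
    kT_joule = KT * KDA_NM2_PS2_IN_J
    l_b_m = const.e ** 2 / (4 * np.pi * const.epsilon_0 * eps_r * kT_joule)
    l_b_nm = l_b_m * 1e9
    U, f = electrostatic_pair((0, 0, 0), 1.0, 0.0, (l_b_nm, 0, 0), 1.0, 0.0,
                              kappa=0.0, eps_r=eps_r, kT=KT)
    assert U == pytest.approx(1.0, rel=2e-5)
    # repulsive: force on i points away from k
    assert f[0] < 0


def test_coincident_charges_raise():
    with pytest.raises(SingularConfigurationError):
        electrostatic_pair((0, 0, 0), 1.0, 0.0, (0, 0, 0), 1.0, 0.0)


def test_screening_and_burial():
    # burial depth exempts part of the separation from screening
    U_bare, _ = electrostatic_pair((0, 0, 0), 1, 0.0, (2, 0, 0), 1, 0.0,
                                   kappa=1.0)
    U_buried, _ = electrostatic_pair((0, 0, 0), 1, 0.5, (2, 0, 0), 1, 0.5,
                                     kappa=1.0)
    assert U_buried == pytest.approx(U_bare * np.exp(1.0))
    # beyond B + 5/kappa the interaction is cut off
    U_far, _ = electrostatic_pair((0, 0, 0), 1, 0.0, (6.0, 0, 0), 1, 0.0,
                                  kappa=1.0)
    assert U_far == 0.0


def test_electrostatic_force_is_minus_gradient(rng):
    """Central-difference oracle over random configurations."""
    h = 1e-5
    for _ in range(100):
        p_i = rng.uniform(-2, 2, 3)
        p_k = rng.uniform(-2, 2, 3)
        if np.linalg.norm(p_i - p_k) < 0.3:
            continue
        q_i, q_k = rng.uniform(-3, 3, 2)
        b_i, b_k = rng.uniform(0, 0.5, 2)
        kappa = rng.uniform(0, 2)
        _, f = electrostatic_pair(p_i, q_i, b_i, p_k, q_k, b_k, kappa=kappa)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            Up, _ = electrostatic_pair(p_i + dp, q_i, b_i, p_k, q_k, b_k,
                                       kappa=kappa)
            Um, _ = electrostatic_pair(p_i - dp, q_i, b_i, p_k, q_k, b_k,
                                       kappa=kappa)
            grad = (Up - Um) / (2 * h)
            assert -grad == pytest.approx(f[ax], rel=1e-5, abs=1e-9)


# ---------------------------------------------------------------------------
# colour potential


ATT = ColourPair(epsilon=2.0, sigma=0.5, attractive=True)
REP = ColourPair(epsilon=2.0, sigma=0.5, attractive=False)


def test_vdw_zero_beyond_cutoff():
    r = 1.0 + 1.0 + ATT.cutoff_value + 0.1
    U, f = vdw_pair((0, 0, 0), 1.0, (r, 0, 0), 1.0, ATT)
    assert U == 0.0 and np.all(f == 0.0)


def test_vdw_minimum_at_sigma():
    r = 1.0 + 1.0 + ATT.sigma
    U, f = vdw_pair((0, 0, 0), 1.0, (r, 0, 0), 1.0, ATT)
    assert U == pytest.approx(-ATT.epsilon)
    assert np.linalg.norm(f) == pytest.approx(0.0, abs=1e-10)


def test_vdw_repulsive_branch_only():
    r = 2.0 + REP.sigma          # at sigma the r^-12 branch equals epsilon
    U, _ = vdw_pair((0, 0, 0), 1.0, (r, 0, 0), 1.0, REP)
    assert U == pytest.approx(REP.epsilon)
    # strictly repulsive at any separation inside the cutoff
    for rr in (2.3, 2.6, 3.0, 3.4):
        _, f = vdw_pair((0, 0, 0), 1.0, (rr, 0, 0), 1.0, REP)
        assert f[0] <= 0.0


def test_vdw_force_matches_numerical_gradient(rng):
    """FD oracle everywhere except at the non-smooth linearization joint."""
    h = 1e-6
    r_lin = ATT.r_lin_value(1.0, 1.0)
    for _ in range(100):
        params = ATT if rng.random() < 0.5 else REP
        r = rng.uniform(r_lin + 0.05, 1.4)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p_k = (2.0 + r) * direction
        if abs(r - r_lin) < 5 * h:
            continue
        _, f = vdw_pair((0, 0, 0), 1.0, p_k, 1.0, params)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            Up, _ = vdw_pair(dp, 1.0, p_k, 1.0, params)
            Um, _ = vdw_pair(-dp, 1.0, p_k, 1.0, params)
            assert -(Up - Um) / (2 * h) == pytest.approx(f[ax], rel=2e-4,
                                                         abs=1e-7)


def test_vdw_linearized_core_is_continuous_with_constant_force():
    r_lin = REP.r_lin_value(1.0, 1.0)
    centre_at = lambda r12: (2.0 + r12, 0, 0)
    U_joint, f_joint = vdw_pair((0, 0, 0), 1.0, centre_at(r_lin), 1.0, REP)
    U_in, f_in = vdw_pair((0, 0, 0), 1.0, centre_at(r_lin - 0.05), 1.0, REP)
    U_deep, f_deep = vdw_pair((0, 0, 0), 1.0, centre_at(-0.2), 1.0, REP)
    # force constant below the joint, even for overlapping spheres
    assert np.linalg.norm(f_in) == pytest.approx(np.linalg.norm(f_joint))
    assert np.linalg.norm(f_deep) == pytest.approx(np.linalg.norm(f_joint))
    # energy continues linearly
    assert U_in == pytest.approx(U_joint + np.linalg.norm(f_joint) * 0.05)
    eps = 1e-7
    U_above, _ = vdw_pair((0, 0, 0), 1.0, centre_at(r_lin + eps), 1.0, REP)
    assert U_above == pytest.approx(U_joint, rel=1e-5)


# ---------------------------------------------------------------------------
# bonds


def test_bond_at_rest_length_is_inert():
    b = Bond(0, 1, k2=1000.0, length=2.5)
    U, fa, ta, fb, tb = bond_forces(b, (0, 0, 0), quat_identity(),
                                    (2.5, 0, 0), quat_identity())
    assert U == 0.0
    assert np.allclose(fa, 0) and np.allclose(ta, 0)


def test_bond_closed_form_force():
    # k2 = 1000 kT/nm^2 stretched by 0.1 nm -> 100 kT/nm along the axis
    b = Bond(0, 1, k2=1000.0, length=2.5)
    U, fa, _, fb, _ = bond_forces(b, (0, 0, 0), quat_identity(),
                                  (2.6, 0, 0), quat_identity())
    assert np.linalg.norm(fa) == pytest.approx(100.0)
    assert fa[0] > 0                     # pulled towards the partner
    assert np.allclose(fa, -fb)
    assert U == pytest.approx(0.5 * 1000 * 0.1 ** 2)


def test_quartic_term():
    b = Bond(0, 1, k2=0.0, k4=16.0, length=1.0)
    U, fa, *_ = bond_forces(b, (0, 0, 0), quat_identity(),
                            (1.5, 0, 0), quat_identity())
    assert U == pytest.approx(0.25 * 16 * 0.5 ** 4)
    assert np.linalg.norm(fa) == pytest.approx(16 * 0.5 ** 3)


def test_centered_hooks_never_torque(rng):
    b = Bond(0, 1, k2=50.0, length=1.0)
    for _ in range(20):
        qa = quat_normalize(rng.normal(size=4))
        qb = quat_normalize(rng.normal(size=4))
        _, _, ta, _, tb = bond_forces(b, rng.normal(size=3), qa,
                                      rng.normal(size=3), qb)
        assert np.allclose(ta, 0) and np.allclose(tb, 0)


def test_eccentric_hook_torque_is_lever_cross_force(rng):
    hook = (0.0, 0.4, 0.0)
    b = Bond(0, 1, k2=50.0, length=1.0, hook_a=hook)
    qa = quat_normalize(rng.normal(size=4))
    _, fa, ta, _, _ = bond_forces(b, (0, 0, 0), qa, (2.0, 0, 0),
                                  quat_identity())
    lever = quat_rotate(qa, np.asarray(hook))
    assert np.allclose(ta, np.cross(lever, fa))


def test_degenerate_bond_direction_tie_break():
    b = Bond(0, 1, k2=10.0, length=1.0)
    _, fa, *_ = bond_forces(b, (0, 0, 0), quat_identity(),
                            (0, 0, 0), quat_identity())
    # compressed by the full rest length; force along +x by convention
    assert fa[0] == pytest.approx(10.0)
    assert fa[1] == fa[2] == 0.0


# ---------------------------------------------------------------------------
# external restraints


def test_external_forces():
    harm = HarmonicRestraint(k=10.0, center=(1.0, 0.0, 0.0))
    U, f = external_forces((1.0, 0.0, 0.0), harmonic=harm)
    assert U == 0.0 and np.all(f == 0.0)
    U, f = external_forces((1.5, 0.0, 0.0), harmonic=harm)
    assert np.linalg.norm(f) == pytest.approx(5.0)
    const_r = ConstantForce((0.0, 0.0, -1.0))
    for pos in ((0, 0, 0), (5, 5, 5)):
        _, f = external_forces(pos, constant=const_r)
        assert np.allclose(f, (0, 0, -1))


# ---------------------------------------------------------------------------
# system accumulation


def test_pair_interaction_count_formula():
    assert pair_interaction_count(2, 0) == 1
    assert pair_interaction_count(20, 18) == 190 + 360
    # brute force oracle
    for n_p in (0, 1, 3, 7):
        for n_o in (0, 2, 9):
            brute = sum(1 for i in range(n_p) for j in range(i + 1, n_p))
            brute += n_p * n_o
            assert pair_interaction_count(n_p, n_o) == brute


def _random_cluster_system(rng, with_charges=True):
    colours = ColourTable({(0, 0): ColourPair(epsilon=1.0, sigma=0.3,
                                              attractive=True)})
    g = []
    for i in range(3):
        charges = (PointCharge(tuple(rng.uniform(-0.2, 0.2, 3)),
                               rng.uniform(-2, 2), 0.1),) if with_charges else ()
        g.append(GestaltTemplate(
            geom=GeomSpec(d_tr=1.0, d_rot=1e-3),
            position=tuple(rng.uniform(0, 4, 3)),
            vdw=(VdWSphere(tuple(rng.uniform(-0.3, 0.3, 3)), 1.0, 0),),
            charges=charges))
    bonds = (Bond(0, 1, k2=5.0, length=2.0, hook_a=(0.2, 0, 0)),
             Bond(1, 2, k2=5.0, length=2.0),)
    return ProteinTemplate("cluster", tuple(g), bonds), colours


def test_mobile_forces_sum_to_zero(rng):
    tpl, colours = _random_cluster_system(rng)
    builder = SystemBuilder(FREE_BOX, colours, kappa=0.5)
    builder.instantiate(tpl, position=(10, 10, 10))
    builder.instantiate(tpl, position=(12.5, 10.5, 10.2))
    system = builder.compile()
    state = system.initial_state()
    acc = accumulate(system, state)
    assert np.linalg.norm(acc.force.sum(axis=1)) < 1e-10
    assert acc.n_int[0] == pair_interaction_count(6, 0)


def test_energy_invariant_under_rigid_motion(rng):
    """Global translation + rotation of all positions and orientations
    leaves the total energy unchanged (no periodic images)."""
    tpl, colours = _random_cluster_system(rng)
    builder = SystemBuilder(FREE_BOX, colours, kappa=0.3)
    builder.instantiate(tpl, position=(10, 10, 10))
    builder.instantiate(tpl, position=(13, 11, 10))
    system = builder.compile()
    state = system.initial_state()
    e0 = accumulate(system, state).energy[0]
    assert e0 != 0.0

    rot = quat_normalize(rng.normal(size=4))
    shift = rng.uniform(-5, 5, 3)
    centre = state.pos[0].mean(axis=0)
    state.pos[0] = quat_rotate(rot, state.pos[0] - centre) + centre + shift
    state.quat[0] = quat_normalize(quat_multiply(rot, state.quat[0]))
    e1 = accumulate(system, state).energy[0]
    assert e1 == pytest.approx(e0, rel=1e-9)


def test_wall_interactions_counted_and_fixed_pairs_skipped():
    from mesobd import WallTemplate
    colours = ColourTable({(0, 0): ColourPair(1.0, 0.5),
                           (0, 1): ColourPair(1.0, 0.5),
                           (1, 1): ColourPair(1.0, 0.5)})
    box = SimulationBox((30, 20, 20), ("reflecting", "periodic", "periodic"))
    builder = SystemBuilder(box, colours)
    wall = WallTemplate("obst", tuple(
        VdWSphere((15.0, 3.0 + 6.0 * i, 10.0), 5.0, 1) for i in range(3)))
    builder.add_wall(wall)
    bead = ProteinTemplate("bead", (GestaltTemplate(
        geom=GeomSpec(d_tr=1e-4), vdw=(VdWSphere((0, 0, 0), 2.0, 0),)),))
    builder.instantiate(bead, position=(7.4, 3.0, 10.0))
    system = builder.compile()
    state = system.initial_state()
    acc = accumulate(system, state)
    assert acc.n_int[0] == pair_interaction_count(1, 3)
    # the wall pushes the nearby bead away (repulsive, overlapping range)
    assert acc.force[0, 0, 0] < 0.0


def test_missing_colour_pair_is_a_configuration_error():
    from mesobd.boundaries import ConfigurationError
    colours = ColourTable({(0, 0): ColourPair(1.0, 0.5)})
    builder = SystemBuilder(FREE_BOX, colours)
    bead = ProteinTemplate("two", (GestaltTemplate(
        geom=GeomSpec(d_tr=1.0),
        vdw=(VdWSphere((0, 0, 0), 1.0, 0), VdWSphere((1, 0, 0), 1.0, 7))),))
    builder.instantiate(bead)
    with pytest.raises(ConfigurationError, match="7"):
        builder.compile()
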