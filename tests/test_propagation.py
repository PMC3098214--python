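"""Brownian and Langevin stepping, rotation, and the main integrator."""

import numpy as np
import pytest

from mesobd import (DEFAULT_KT, GeomSpec, GestaltTemplate, HarmonicRestraint,
                    ProteinTemplate, StepContext, SystemBuilder, integrate)
from mesobd.analysis import apparent_diffusion, msd_curve
from mesobd.model import quat_identity, quat_rotate
from mesobd.propagation import (PropagationDivergedError, bd_step,
                                displacement_to_force, ld_step,
                                random_displacement, rotation_step,
                                validate_bd_timestep)

from conftest import FREE_BOX, make_free_system


def test_random_displacement_moments(rng):
    d, dt = 0.7, 0.05
    draws = random_displacement(d, dt, rng, size=(300_000,))
    var = draws.var(axis=(0, 1)).mean()
    assert var == pytest.approx(2 * d * dt, rel=0.005)
    se = np.sqrt(2 * d * dt / draws.size)
    assert abs(draws.mean()) < 4 * se
    assert np.all(random_displacement(0.0, dt, rng, size=(10,)) == 0.0)


def test_displacement_to_force_roundtrip(rng):
    d, dt, kT = 1.2e-4, 10.0, DEFAULT_KT
    R = rng.normal(size=3)
    f = displacement_to_force(R, d, dt, kT)
    # friction coefficient for a 2 nm particle at the default thermal
    # energy: gamma = kT / D = 20.3 kDa/ps
    assert kT / d == pytest.approx(20.3, rel=1e-3)
    # propagating the effective force overdampedly reproduces R exactly
    # (force converted back to kT/nm units for the step)
    assert np.allclose(bd_step(np.zeros(3), f / kT, d, dt), R)
    assert np.all(displacement_to_force(np.zeros(3), d, dt, kT) == 0.0)


def test_bd_step_deterministic_part_linear_in_dt():
    f = np.array([1.0, -2.0, 0.5])
    dx1 = bd_step(np.zeros(3), f, 0.3, 0.01)
    dx2 = bd_step(np.zeros(3), f, 0.3, 0.02)
    assert np.allclose(dx2, 2 * dx1)
    assert np.all(bd_step(np.zeros(3), np.zeros(3), 0.3, 0.01) == 0.0)


def test_ld_step_closed_form_value():
    """tau = 1, dt = 1, F/gamma = 1 nm/ps, v0 = 0:
    dx = 1 - (1 - e^-1) = 0.367879 nm."""
    d_self, kT = 1.0, 1.0
    f = np.array([1.0, 0.0, 0.0])     # F/gamma = D * f = 1 nm/ps
    new_pos, new_vel = ld_step(np.zeros(3), np.zeros(3), f, d_self,
                               tau=1.0, dt=1.0)
    assert new_pos[0] == pytest.approx(1.0 - (1.0 - np.exp(-1.0)), rel=1e-12)
    assert new_vel[0] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)
    # F = 0, v0 = 0 stays put
    p, v = ld_step(np.zeros(3), np.zeros(3), np.zeros(3), 1.0, 1.0, 1.0)
    assert np.all(p == 0) and np.all(v == 0)


def test_ld_reduces_to_bd_for_long_timesteps(rng):
    tau = 0.01
    dt = 100 * tau
    f = rng.normal(size=3)
    R = rng.normal(size=3) * 0.1
    bd = bd_step(np.zeros(3), f, 1.0, dt, R)
    ld, _ = ld_step(np.zeros(3), np.zeros(3), f, 1.0, tau, dt, R)
    assert np.linalg.norm(ld - bd) / np.linalg.norm(bd) <= 0.0101


def ld_msd_closed_form(t, d, tau):
    """Inertial free-particle MSD: 6 D (t - tau (1 - e^(-t/tau)))."""
    return 6.0 * d * (t - tau * (1.0 - np.exp(-t / tau)))


def test_free_ld_msd_matches_inertial_closed_form():
    """Ensemble of free Langevin particles against the analytic MSD,
    after a burn-in that thermalises the velocities."""
    kT = DEFAULT_KT
    d, mass = 1.2e-4, 20.0
    tau = mass * d / kT              # about 1 ps
    dt = tau / 10
    tpl = ProteinTemplate("inertial", (GestaltTemplate(
        geom=GeomSpec(d_tr=d, mass=mass)),))
    system, state = make_free_system(tpl, replicas=4000)
    ctx = StepContext(dt=dt, kT=kT, seed=42)
    burn = integrate(system, state, ctx, 200, stride=200)
    traj = integrate(system, state, ctx, 400, stride=2)
    series = msd_curve(traj.pos, traj.times,
                       lags=[1, 2, 5, 10, 25, 50, 100, 150])
    expected = ld_msd_closed_form(series.lags, d, tau)
    assert np.allclose(series.msd, expected, rtol=0.05)
    # and the apparent short-time D is strongly suppressed below D
    assert apparent_diffusion(series)[0] < 0.25 * d


def test_free_bd_msd_is_6Dt():
    tpl = ProteinTemplate("free", (GestaltTemplate(geom=GeomSpec(d_tr=1.0)),))
    system, state = make_free_system(tpl, replicas=2000)
    ctx = StepContext(dt=0.01, seed=7)
    traj = integrate(system, state, ctx, 50, stride=1)
    series = msd_curve(traj.pos, traj.times, lags=[1, 5, 10, 25])
    # 1e5 particle-steps at the single-step lag; longer lags have fewer
    # independent windows and get a correspondingly wider band
    assert series.msd[0] == pytest.approx(6.0 * series.lags[0], rel=0.01)
    assert np.allclose(series.msd, 6.0 * series.lags, rtol=0.03)


def test_mixed_bd_ld_in_one_simulation():
    """Massless and massive particles in the same run: at dt ~ tau the
    inertial particles show a strongly reduced single-step MSD while the
    overdamped ones diffuse at full speed."""
    kT = DEFAULT_KT
    d, mass = 1.2e-4, 20.0
    tau = mass * d / kT
    bd_tpl = ProteinTemplate("bd", (GestaltTemplate(geom=GeomSpec(d_tr=d)),))
    ld_tpl = ProteinTemplate("ld", (GestaltTemplate(
        geom=GeomSpec(d_tr=d, mass=mass)),))
    builder = SystemBuilder(FREE_BOX)
    builder.instantiate(bd_tpl)
    builder.instantiate(ld_tpl, position=(100.0, 0, 0))
    system = builder.compile()
    state = system.initial_state(3000)
    ctx = StepContext(dt=tau, kT=kT, seed=3)
    integrate(system, state, ctx, 100, stride=100)   # thermalise velocities
    traj = integrate(system, state, ctx, 60, stride=1)
    msd_bd = msd_curve(traj.pos[:, :, :1], traj.times, lags=[1]).msd[0]
    msd_ld = msd_curve(traj.pos[:, :, 1:], traj.times, lags=[1]).msd[0]
    assert msd_bd == pytest.approx(6 * d * tau, rel=0.05)
    assert msd_ld < 0.55 * msd_bd


def test_harmonic_restraint_reaches_boltzmann_variance():
    """Positional variance in a harmonic well is kT/k, i.e. 1/k nm^2 with
    the spring constant expressed in kT/nm^2."""
    k = 10.0
    tpl = ProteinTemplate("trapped", (GestaltTemplate(
        geom=GeomSpec(d_tr=1.0),
        restraints=(HarmonicRestraint(k=k, center=(0.0, 0.0, 0.0)),)),))
    system, state = make_free_system(tpl, replicas=3000)
    ctx = StepContext(dt=0.002, seed=11)
    integrate(system, state, ctx, 500, stride=500)    # equilibrate ~10 tau
    traj = integrate(system, state, ctx, 500, stride=10)
    var = traj.pos.var(axis=(0, 1, 2)).mean()
    # Euler discretisation bias is ~ D k dt / 2 = 1%
    assert var == pytest.approx(1.0 / k, rel=0.05)


def test_free_rotor_orientation_correlation(rng):
    """<u(0).u(t)> = exp(-2 D_rot t) for a freely rotating body axis."""
    d_rot = 0.01
    dt = 1.0
    n = 4000
    q = quat_identity((n,))
    u0 = np.tile([0.0, 0.0, 1.0], (n, 1))
    corr = []
    steps = 120
    for _ in range(steps):
        phi = rng.standard_normal((n, 3)) * np.sqrt(2 * d_rot * dt)
        from mesobd.model import quat_from_rotvec, quat_multiply, quat_normalize
        q = quat_normalize(quat_multiply(quat_from_rotvec(phi), q))
        corr.append(np.mean(np.sum(quat_rotate(q, u0) * u0, axis=1)))
    t = dt * np.arange(1, steps + 1)
    expected = np.exp(-2 * d_rot * t)
    assert np.allclose(corr, expected, atol=0.03)


def test_rotation_step_stokes_einstein_consistency():
    """D_rot = 3 D_tr / (4 a^2) for a 2 nm sphere with
    D_tr = 1.2e-4 nm^2/ps gives 2.25e-5 ps^-1, matching the tabulated
    2.26e-5 ps^-1 within rounding."""
    d_rot = 3.0 * 1.2e-4 / (4.0 * 2.0 ** 2)
    assert d_rot == pytest.approx(2.26e-5, rel=0.005)
    # zero diffusion and zero torque leave the orientation untouched
    q = rotation_step((1.0, 0, 0, 0), np.zeros(3), 0.0, 1.0,
                      np.random.default_rng(0))
    assert np.allclose(q, (1, 0, 0, 0))


def test_zero_steps_returns_initial_state(free_bead):
    system, state = make_free_system(free_bead)
    ctx = StepContext(dt=1.0, seed=0)
    traj = integrate(system, state, ctx, 0, stride=1)
    assert traj.n_frames == 1
    assert np.allclose(traj.pos[0], state.pos)


def test_identical_seeds_are_bitwise_identical(free_bead):
    runs = []
    for _ in range(2):
        system, state = make_free_system(free_bead, replicas=5)
        ctx = StepContext(dt=0.5, seed=123)
        runs.append(integrate(system, state, ctx, 200, stride=10))
    assert np.array_equal(runs[0].pos, runs[1].pos)
    system, state = make_free_system(free_bead, replicas=5)
    other = integrate(system, state, StepContext(dt=0.5, seed=124), 200,
                      stride=10)
    assert not np.array_equal(runs[0].pos, other.pos)


def test_single_particle_hi_equals_no_hi():
    """For one hydrodynamic sphere the tensor is diagonal and the HI code
    path must reproduce the plain path draw for draw."""
    from mesobd.model import HydroSphere
    tpl = ProteinTemplate("hydro", (GestaltTemplate(
        geom=GeomSpec(d_tr=1.0), hydro=HydroSphere(1.0, 1.0)),))
    trajs = []
    for hi in (False, True):
        system, state = make_free_system(tpl, replicas=4)
        ctx = StepContext(dt=0.1, seed=9, hi=hi)
        trajs.append(integrate(system, state, ctx, 100, stride=10))
    assert np.allclose(trajs[0].pos, trajs[1].pos)


def test_divergence_is_reported_with_context(free_bead):
    tpl = ProteinTemplate("unstable", (GestaltTemplate(
        geom=GeomSpec(d_tr=1.0),
        restraints=(HarmonicRestraint(k=1e12, center=(0, 0, 0)),)),))
    system, state = make_free_system(tpl)
    ctx = StepContext(dt=1.0, seed=0)
    with pytest.raises(PropagationDivergedError) as exc:
        integrate(system, state, ctx, 2000, stride=100)
    assert exc.value.gestalt == 0


def test_bd_timestep_guard_warns():
    with pytest.warns(RuntimeWarning):
        validate_bd_timestep(mass=20.0, d_tr=1.2e-4, dt=1.0, kT=DEFAULT_KT)
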