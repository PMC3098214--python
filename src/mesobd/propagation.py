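"""Brownian and Langevin time stepping with per-gestalt scheme selection.

Massless gestalten follow the overdamped Brownian scheme

    dx = D/kT F dt + R,      <R^2> = 2 D dt per coordinate,

while gestalten with a defined mass are propagated with the finitely
damped Langevin scheme, which integrates the velocity analytically under
a force held constant over the step:

    v(dt) = v0 e^(-dt/tau) + (F/gamma)(1 - e^(-dt/tau))
    dx    = (F/gamma) dt + tau (v0 - F/gamma)(1 - e^(-dt/tau))

with gamma = kT/D and the velocity relaxation time tau = m/gamma.  The
random displacement is converted into an effective force f = gamma R / dt
so that for dt >> tau the Langevin scheme reduces exactly to the Brownian
one.  Both schemes can coexist in one simulation.

With hydrodynamics enabled, the deterministic forces of the hydrodynamic
subset are replaced by the TEA effective forces and the random
displacements are TEA-correlated before entering either scheme (for
Langevin particles the correlations are applied to the average forces
that would produce the same displacements in the Brownian picture).

Rotation is propagated by small Gaussian rotation vectors with per-axis
variance 2 D_rot dt plus the deterministic response D_rot/kT T dt,
composed onto the orientation quaternion, which is renormalised after
every update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import forces as _forces
from . import hydrodynamics as _hydro
from .boundaries import DensityInterface, minimum_image, reflect, wrap_positions
from .model import (System, SystemState, quat_from_rotvec, quat_multiply,
                    quat_normalize)

__all__ = [
    "PropagationDivergedError", "StepContext", "Trajectory", "bd_step",
    "displacement_to_force", "integrate", "ld_step", "random_displacement",
    "rotation_step", "validate_bd_timestep",
]


class PropagationDivergedError(RuntimeError):
    def __init__(self, step: int, gestalt: int):
        super().__init__(
            f"non-finite coordinate at step {step}, gestalt {gestalt}")
        self.step = step
        self.gestalt = gestalt


@dataclass
class StepContext:
    """Timestep, thermal energy, RNG stream and hydrodynamics switch.

    The same seed with the same configuration yields bit-identical
    trajectories: all random draws happen in a fixed order (translations,
    rotations, interface insertions) from one counter-based stream.
    ``tensor_stride`` > 1 recomputes the diffusion tensor only every so
    many steps (documented approximation; default recomputes every step).
    """

    dt: float
    kT: float = 2.4361e-3
    seed: int = 0
    hi: bool = False
    tensor_stride: int = 1
    rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)


def validate_bd_timestep(mass: float, d_tr: float, dt: float, kT: float) -> None:
    """Overdamped propagation is conceptually valid only for timesteps well
    above the velocity relaxation time; warn when dt < 10 m D / kT."""
    tau = mass * d_tr / kT
    if dt < 10.0 * tau:
        warnings.warn(
            f"timestep {dt} ps is below ten velocity relaxation times "
            f"(tau_rel = {tau:.3g} ps); the overdamped scheme is "
            "questionable here, consider the Langevin scheme",
            RuntimeWarning)


# ---------------------------------------------------------------------------
# single-gestalt operations (the vectorised integrate() inlines the same
# arithmetic; these are the reference forms)


def random_displacement(d_self: float, dt: float, rng, size=()) -> np.ndarray:
    """Gaussian displacement with zero mean and variance 2 D dt per
    coordinate (before any hydrodynamic correlation)."""
    if d_self == 0.0:
        return np.zeros(size + (3,))
    return rng.standard_normal(size + (3,)) * np.sqrt(2.0 * d_self * dt)


def displacement_to_force(R, d_self: float, dt: float, kT: float):
    """Effective force f = gamma R / dt (kDa nm ps^-2) producing the
    displacement R in one overdamped step; gamma = kT / D."""
    return (kT / d_self) * np.asarray(R) / dt


def bd_step(pos, f_kT_nm, d_self: float, dt: float, R=0.0):
    """One overdamped step; ``f_kT_nm`` in kT/nm, ``R`` already correlated
    when hydrodynamics is on."""
    return np.asarray(pos) + d_self * np.asarray(f_kT_nm) * dt + R


def ld_step(pos, vel, f_kT_nm, d_self: float, tau: float, dt: float, R=0.0):
    """One finitely damped step; returns (new_pos, new_vel).

    The random displacement R enters as the effective force R/(D dt) so
    that the scheme reduces to the Brownian step for dt >> tau.
    """
    f_tot = np.asarray(f_kT_nm) + np.asarray(R) / (d_self * dt)
    vdrift = d_self * f_tot                       # F/gamma, nm/ps
    e = np.exp(-dt / tau)
    new_pos = np.asarray(pos) + vdrift * dt + tau * (np.asarray(vel) - vdrift) * (1.0 - e)
    new_vel = np.asarray(vel) * e + vdrift * (1.0 - e)
    return new_pos, new_vel


def rotation_step(quat, torque_kT, d_rot: float, dt: float, rng):
    """Rotational analogue of the Brownian step: rotation vector
    ``D_rot T dt`` (torque in kT, i.e. already divided by the thermal
    energy) plus an isotropic Gaussian with variance 2 D_rot dt per axis,
    composed onto the quaternion."""
    phi = d_rot * np.asarray(torque_kT, dtype=float) * dt
    if d_rot > 0.0:
        phi = phi + rng.standard_normal(3) * np.sqrt(2.0 * d_rot * dt)
    q = quat_multiply(quat_from_rotvec(phi), np.asarray(quat, dtype=float))
    return quat_normalize(q)


# ---------------------------------------------------------------------------
# trajectory container


@dataclass
class Trajectory:
    """Frames recorded during :func:`integrate`.

    ``pos`` holds unwrapped coordinates (periodic crossings accumulated),
    shape (frames, replicas, gestalten, 3).  ``n_absorbed``/``n_inserted``
    are cumulative per-interface counters for transport fits.
    """

    times: np.ndarray
    pos: np.ndarray
    quat: np.ndarray | None = None
    active: np.ndarray | None = None
    n_absorbed: np.ndarray | None = None   # (frames, M, n_interfaces)
    n_inserted: np.ndarray | None = None
    energy: np.ndarray | None = None       # (frames, M)
    box: object = None
    system: object = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_mobile(self) -> np.ndarray:
        if self.active is None:
            return np.full(self.pos.shape[:2], self.pos.shape[2])
        return self.active.sum(axis=2)


# ---------------------------------------------------------------------------
# main loop


def integrate(system: System, state: SystemState, ctx: StepContext,
              n_steps: int, stride: int = 1,
              interfaces: tuple[DensityInterface, ...] = (),
              record_initial: bool = True,
              frame_callback=None) -> Trajectory:
    """Propagate ``state`` for ``n_steps`` timesteps, recording every
    ``stride`` steps.

    Per step: zero accumulators -> pair forces -> hydrodynamic effective
    forces -> (correlated) random displacements -> per-gestalt BD/LD and
    rotation -> boundary handling (wrap / reflect / interfaces) -> output.
    Raises :class:`PropagationDivergedError` on non-finite coordinates.
    """
    rng = ctx.rng
    dt = ctx.dt
    M, G = state.pos.shape[:2]
    D = system.g_dtr                                  # (G,)
    sqrt2Ddt = np.sqrt(2.0 * D * dt)[None, :, None]

    ld = system.ld_mask
    any_ld = bool(ld.any())
    if any_ld:
        tau = np.where(ld, system.g_mass * D / ctx.kT, np.inf)
        e_dt = np.exp(-dt / tau)[None, :, None]
        tau_b = tau[None, :, None]
    rot = system.rot_mask
    any_rot = bool(rot.any())
    if any_rot:
        sqrt2Drdt = np.sqrt(2.0 * system.g_drot * dt)[None, :, None]
        drot_dt = (system.g_drot * dt)[None, :, None]

    hi = ctx.hi and len(system.hydro_idx) > 0
    if hi:
        hidx = system.hydro_idx
        tea_op = None

    for itf in interfaces:
        if itf.n_absorbed is None or itf.n_absorbed.shape != (M,):
            itf.n_absorbed = np.zeros(M, dtype=np.int64)
            itf.n_inserted = np.zeros(M, dtype=np.int64)
        itf._slots = system.slots_by_template.get(itf.species)
        if itf._slots is None or len(itf._slots) == 0:
            raise ValueError(f"no slots reserved for species {itf.species!r}")
        g0 = itf._slots[0]
        itf._D = float(D[g0])
        itf._nu = itf.mean_insertions_per_step(system.box, itf._D, dt)
        s_idx = np.flatnonzero(system.sph_owner == g0)
        itf._radius = float(system.sph_radius[s_idx[0]]) if len(s_idx) else 0.0
        itf._colour = int(system.sph_colour[s_idx[0]]) if len(s_idx) else 0

    reflect_axes = tuple(ax for ax in range(3)
                         if system.box.modes[ax] == "reflecting")
    # faces of open axes that no interface absorbs act as reflecting walls
    # (species not exchanged with a reservoir stay confined)
    open_axes = tuple(ax for ax in range(3)
                      if system.box.modes[ax] == "interface")

    n_frames = (n_steps // stride) + (1 if record_initial else 0)
    t_times = np.empty(n_frames)
    t_pos = np.empty((n_frames, M, G, 3))
    t_quat = np.empty((n_frames, M, G, 4)) if any_rot else None
    t_active = np.empty((n_frames, M, G), dtype=bool) if interfaces else None
    t_abs = (np.empty((n_frames, M, len(interfaces)), dtype=np.int64)
             if interfaces else None)
    t_ins = (np.empty((n_frames, M, len(interfaces)), dtype=np.int64)
             if interfaces else None)
    t_energy = np.empty((n_frames, M))
    frame = 0

    def record(energy):
        nonlocal frame
        t_times[frame] = state.time
        t_pos[frame] = state.pos + state.images * system.box.lengths_array
        if t_quat is not None:
            t_quat[frame] = state.quat
        if interfaces:
            t_active[frame] = state.active
            for j, itf in enumerate(interfaces):
                t_abs[frame, :, j] = itf.n_absorbed
                t_ins[frame, :, j] = itf.n_inserted
        t_energy[frame] = energy
        if frame_callback is not None:
            frame_callback(system, state)
        frame += 1

    if record_initial and n_frames > 0:
        record(np.zeros(M))

    Lbox = system.box.lengths_array
    for step in range(n_steps):
        acc = _forces.accumulate(system, state)
        F = acc.force

        raw = rng.standard_normal((M, G, 3)) * sqrt2Ddt

        if hi:
            if tea_op is None or step % ctx.tensor_stride == 0:
                # only separations matter here, not absolute coordinates
                tea_op = _hydro.TEAOperator(_hydro.rpy_blocks(
                    state.pos[:, hidx, :], system.hydro_a, system.hydro_d,
                    box=system.box))
            F[:, hidx, :], raw[:, hidx, :] = tea_op.apply(
                F[:, hidx, :], raw[:, hidx, :])

        drift = (D[None, :, None] * dt) * F
        if any_ld:
            vdrift = (drift + raw) / (dt)                  # nm/ps over the step
            # overdamped part for BD gestalten
            dx_bd = drift + raw
            dx_ld = vdrift * dt + tau_b * (state.vel - vdrift) * (1.0 - e_dt)
            dx = np.where(ld[None, :, None], dx_ld, dx_bd)
            state.vel = np.where(ld[None, :, None],
                                 state.vel * e_dt + vdrift * (1.0 - e_dt),
                                 state.vel)
        else:
            dx = drift + raw
        dx *= state.active[..., None]
        state.pos += dx

        if any_rot:
            graw = rng.standard_normal((M, G, 3)) * sqrt2Drdt
            phi = drot_dt * acc.torque + graw
            phi *= (rot[None, :, None] & state.active[..., None])
            dq = quat_from_rotvec(phi)
            state.quat = quat_normalize(quat_multiply(dq, state.quat))

        if not np.all(np.isfinite(dx)):
            bad = np.argwhere(~np.isfinite(dx))
            raise PropagationDivergedError(step, int(bad[0][1]))

        wrap_positions(state.pos, state.images, system.box)
        if reflect_axes:
            reflect(state.pos, state.vel, system.box, reflect_axes)
        for itf in interfaces:
            _interface_step(system, state, itf, dt, rng)
        if open_axes:
            reflect(state.pos, state.vel, system.box, open_axes)

        state.time += dt
        if (step + 1) % stride == 0:
            record(acc.energy)

    return Trajectory(times=t_times[:frame], pos=t_pos[:frame],
                      quat=None if t_quat is None else t_quat[:frame],
                      active=None if t_active is None else t_active[:frame],
                      n_absorbed=None if t_abs is None else t_abs[:frame],
                      n_inserted=None if t_ins is None else t_ins[:frame],
                      energy=t_energy[:frame], box=system.box, system=system)


# ---------------------------------------------------------------------------
# constant-density interfaces


def _interface_step(system: System, state: SystemState, itf: DensityInterface,
                    dt: float, rng) -> None:
    slots = itf._slots
    ax = itf.axis
    L = system.box.lengths[ax]
    act = state.active[:, slots]

    # absorb: remove particles strictly on crossing the plane
    x = state.pos[:, slots, ax]
    crossed = act & (x < 0.0 if itf.side == "low" else x > L)
    if crossed.any():
        state.active[:, slots] = act & ~crossed
        itf.n_absorbed += crossed.sum(axis=1)

    # other species reflect at the face (and this species when rho == 0 it
    # still absorbs; reflection of non-listed species is handled by their
    # own interface or a reflecting plane)

    # inject: Poisson count with the reservoir crossing flux
    n_new = rng.poisson(itf._nu, size=state.replicas)
    for m in range(state.replicas):
        if n_new[m] == 0:
            continue
        free = np.flatnonzero(~state.active[m, slots])
        if len(free) < n_new[m]:
            warnings.warn("no free slots for interface insertion; deferred",
                          RuntimeWarning)
        for j in range(min(n_new[m], len(free))):
            g = slots[free[j]]
            placed = False
            for _ in range(itf.max_insert_retries):
                depth = itf.sample_depths(1, itf._D, dt, rng)[0]
                xax = depth if itf.side == "low" else L - depth
                p = np.empty(3)
                p[ax] = xax
                other = [a for a in range(3) if a != ax]
                for a in other:
                    p[a] = rng.uniform(0.0, system.box.lengths[a])
                if _insertion_clear(system, p, itf._radius, itf._colour):
                    placed = True
                    break
            if not placed:
                warnings.warn("insertion retry budget exhausted; deferred",
                              RuntimeWarning)
                continue
            state.pos[m, g] = p
            state.vel[m, g] = 0.0
            state.images[m, g] = 0
            state.quat[m, g] = (1.0, 0.0, 0.0, 0.0)
            state.active[m, g] = True
            itf.n_inserted[m] += 1


def _insertion_clear(system: System, p: np.ndarray, radius: float,
                     colour: int) -> bool:
    """Reject insertions overlapping a fixed structure beyond the
    linearization threshold."""
    if system.n_wall_sphere == 0:
        return True
    d = p[None, :] - system.wall_sph_pos
    minimum_image(d, system.box)
    r = np.linalg.norm(d, axis=1)
    r12 = r - radius - system.wall_sph_radius
    for w in range(system.n_wall_sphere):
        cp = system.colours.get(colour, int(system.wall_sph_colour[w]))
        if r12[w] < cp.r_lin_value(radius, float(system.wall_sph_radius[w])):
            return False
    return True
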