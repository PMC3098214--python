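"""Builders and drivers for the four canonical example studies.

The defaults reproduce the study conditions: bead-spring polymers in
reduced units (bead radius and D_bead = 1, dt = 5e-4), elastic
multi-bead particles with 2 nm beads on a 5 nm hexagonal lattice
(D_bead = 1.2e-4 nm^2/ps), diffusional transport through a
30 x 20 x 20 nm box bounded by constant-density reservoirs
(rho_0 = 4e-4 nm^-3, dt = 10 ps), and patchy-particle agglomeration
(27 particles in a 30 nm periodic box, Langevin propagation).

Run lengths default to desk-scale sizes (minutes, not the original days);
every driver accepts explicit ``steps``/``replicas`` arguments to scale
up.  Statistical errors are reported from the scatter of independent
replica groups.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .boundaries import DensityInterface, SimulationBox
from .model import (ColourPair, ColourTable, SystemBuilder, build_hcp_particle,
                    build_obstacle_wall, build_patchy_particle, build_polymer)
from .propagation import StepContext, integrate

__all__ = [
    "agglomeration_colours", "agglomeration_experiment", "hcp_dtr",
    "hcp_rescaled_dbead", "hcp_rotation_comparison", "hcp_scaling",
    "polymer_dcm", "polymer_rotation_times", "polymer_scaling",
    "polymer_timestep",
    "run_hcp", "run_polymer", "transport_experiment",
]

FREE_BOX = SimulationBox((1e6, 1e6, 1e6), ("none", "none", "none"))


def _repulsive_table(sigma: float) -> ColourTable:
    return ColourTable({(0, 0): ColourPair(epsilon=1.0, sigma=sigma,
                                           attractive=False)})


# ---------------------------------------------------------------------------
# Example 1: constrained bead-spring polymers


def polymer_timestep(k_n: float = 1000.0, k_2n: float = 0.1) -> float:
    """Largest stable explicit timestep for the bead-spring chain.

    The stiffest internal mode has a spring eigenvalue of up to about
    4(k_n + k_2n); the explicit overdamped update is stable only for
    D k dt < 2.  The standard reduced timestep 5e-4 sits just inside that
    margin for the soft chains (the top nearest-neighbour mode eigenvalue
    4 k_N sin^2 stays below 4 k_N) and is kept as the study condition
    there; chains with stiff next-neighbour springs push the top
    eigenvalue past the margin and get a conservative smaller step.
    """
    if k_2n <= 100.0:
        return 5e-4
    return 1.0 / (4.0 * (k_n + k_2n))


def run_polymer(n: int, k_2n: float = 0.1, with_hi: bool = False,
                seed: int = 0, replicas: int = 16, steps: int = 60_000,
                dt: float | None = None, stride: int = 100,
                k_n: float = 1000.0):
    """Propagate a bead-spring polymer ensemble; returns (trajectory, system).

    Beads repel each other through a short-ranged r^-12 potential
    (sigma = 0.25 bead radii surface range) which prevents overlap without
    perturbing the spring minima at separation 2.5.  ``dt=None`` picks the
    stability-limited timestep for the given stiffness.
    """
    if dt is None:
        dt = polymer_timestep(k_n, k_2n)
    template = build_polymer(n, k_n=k_n, k_2n=k_2n, with_hi=with_hi)
    builder = SystemBuilder(FREE_BOX, _repulsive_table(0.25))
    builder.instantiate(template, position=(5e5, 5e5, 5e5))
    system = builder.compile()
    state = system.initial_state(replicas)
    ctx = StepContext(dt=dt, seed=seed, hi=with_hi, tensor_stride=2)
    traj = integrate(system, state, ctx, steps, stride=stride)
    return traj, system


def polymer_dcm(n: int, k_2n: float = 0.1, with_hi: bool = False,
                seeds=(0, 1, 2), replicas: int = 16, steps: int = 60_000,
                dt: float | None = None, stride: int = 100,
                burn_frac: float = 0.1):
    """Long-time centre-of-mass diffusion coefficient, averaged over
    independent seeds; returns (D, stderr)."""
    est, fit_errs = [], []
    for s in seeds:
        traj, system = run_polymer(n, k_2n, with_hi, seed=s,
                                   replicas=replicas, steps=steps, dt=dt,
                                   stride=stride)
        f0 = int(burn_frac * traj.n_frames)
        com = analysis.com_positions(traj.pos[f0:], system.instances)
        T = traj.times[f0:] - traj.times[f0]
        series = analysis.msd_curve(com, T)
        t_max = series.lags.max()
        # without HI the centre of mass is exactly diffusive at every lag
        # (internal forces cancel, bead noises are independent), so short
        # lags give the tightest unbiased estimate; with HI stay at long
        # lags, above the conformational relaxation of the chain
        window = ((t_max / 8, t_max / 2) if with_hi
                  else (t_max / 30, t_max / 8))
        D, ferr = analysis.fit_long_time_D(series, window=window)
        est.append(D)
        fit_errs.append(ferr)
    est = np.asarray(est)
    err = (est.std(ddof=1) / np.sqrt(len(est)) if len(est) > 1
           else float(fit_errs[0]))
    return float(est.mean()), float(err)


def polymer_scaling(with_hi: bool = False, k_2n: float = 0.1,
                    ns=(3, 5, 10, 15), seeds=(0, 1, 2), replicas: int = 16,
                    steps: int = 60_000, **kw):
    """Scaling exponent of D_CM versus bead number; returns a dict with
    the exponent, its standard error and the per-size coefficients."""
    d_cm = {}
    for n in ns:
        d_cm[n] = polymer_dcm(n, k_2n, with_hi, seeds=seeds,
                              replicas=replicas, steps=steps, **kw)
    slope, fit_err = analysis.scaling_exponent(
        list(ns), [d_cm[n][0] for n in ns])
    stat = np.sqrt(fit_err ** 2 + np.mean(
        [(d_cm[n][1] / d_cm[n][0]) ** 2 for n in ns]) / len(ns))
    return {"exponent": float(slope), "stderr": float(stat), "D_cm": d_cm}


def polymer_rotation_times(n: int = 5, k_2n_values=(0.1, 1000.0),
                           with_hi: bool = False, seed: int = 0,
                           replicas: int = 8, steps: int = 300_000,
                           dt: float | None = None, stride: int = 100):
    """Orientation relaxation time of the end-to-end vector for a set of
    next-neighbour spring constants; returns {k_2n: (tau, err)}.

    ``steps`` refers to the soft-chain timestep; stiffer chains run at a
    smaller stability-limited dt with the step count scaled up so that
    every stiffness covers the same simulated time."""
    out = {}
    for i, k2 in enumerate(k_2n_values):
        dt_k = polymer_timestep(k_2n=k2) if dt is None else dt
        n_steps = int(round(steps * 5e-4 / dt_k))
        traj, system = run_polymer(n, k2, with_hi, seed=seed + 17 * i,
                                   replicas=replicas, steps=n_steps, dt=dt_k,
                                   stride=max(1, int(round(100 * 5e-4 / dt_k))))
        f0 = traj.n_frames // 10
        u = analysis.end_to_end(traj.pos[f0:])
        out[k2] = analysis.rotational_relaxation(u, traj.times[f0:])
    return out


# ---------------------------------------------------------------------------
# Example 2: elastic multi-bead particles


def run_hcp(n: int, with_hi: bool = True, d_bead: float = 1.2e-4,
            seed: int = 0, replicas: int = 16, steps: int = 40_000,
            dt: float = 20.0, stride: int = 50, k: float = 10.0):
    """Propagate a hexagonally packed elastic particle ensemble."""
    template = build_hcp_particle(n, d_bead=d_bead, with_hi=with_hi, k=k)
    builder = SystemBuilder(FREE_BOX, _repulsive_table(0.5))
    builder.instantiate(template, position=(5e5, 5e5, 5e5))
    system = builder.compile()
    state = system.initial_state(replicas)
    ctx = StepContext(dt=dt, seed=seed, hi=with_hi, tensor_stride=5)
    traj = integrate(system, state, ctx, steps, stride=stride)
    return traj, system


def hcp_dtr(n: int, with_hi: bool = True, d_bead: float = 1.2e-4,
            seed: int = 0, replicas: int | None = None,
            steps: int | None = None, dt: float = 20.0, stride: int = 50,
            burn_frac: float = 0.08):
    """Centre-of-mass diffusion coefficient of one particle size.

    Replica counts and run lengths default to a fixed compute budget:
    smaller particles get more replicas, so the statistical error is
    roughly size-independent.  Returns (D_tr, stderr) with the error from
    the scatter of four replica subgroups.
    """
    if replicas is None:
        budget = {4: 64, 13: 32, 39: 16, 57: 12} if with_hi else \
            {4: 32, 13: 16, 39: 10, 57: 8}
        replicas = budget.get(n, max(8, 256 // n))
    if steps is None:
        steps = 40_000
    traj, system = run_hcp(n, with_hi, d_bead, seed, replicas, steps, dt, stride)
    f0 = int(burn_frac * traj.n_frames)
    com = analysis.com_positions(traj.pos[f0:], system.instances)
    T = traj.times[f0:] - traj.times[f0]
    groups = np.array_split(np.arange(replicas), 4)
    est = []
    for grp in groups:
        series = analysis.msd_curve(com[:, grp], T)
        t_max = series.lags.max()
        D, _ = analysis.fit_long_time_D(series, window=(t_max / 30, t_max / 8))
        est.append(D)
    est = np.asarray(est)
    return float(est.mean()), float(est.std(ddof=1) / np.sqrt(len(est)))


def hcp_scaling(with_hi: bool = True, ns=(4, 13, 39, 57), seed: int = 0,
                steps: int | None = None, **kw):
    """Scaling exponent of D_tr versus bead number for the elastic
    particles; same return structure as :func:`polymer_scaling`."""
    d_tr = {}
    for n in ns:
        d_tr[n] = hcp_dtr(n, with_hi=with_hi, seed=seed + n, steps=steps, **kw)
    slope, fit_err = analysis.scaling_exponent(list(ns), [d_tr[n][0] for n in ns])
    stat = np.sqrt(fit_err ** 2 + np.mean(
        [(d_tr[n][1] / d_tr[n][0]) ** 2 for n in ns]) / len(ns))
    return {"exponent": float(slope), "stderr": float(stat), "D_tr": d_tr}


def hcp_rescaled_dbead(n: int = 4, d_bead: float = 1.2e-4, seed: int = 0,
                       confirm: bool = True, **kw):
    """Single-bead diffusion coefficient a no-HI simulation needs to
    reproduce the with-HI D_tr.

    Without hydrodynamic coupling the centre of mass of an N-bead particle
    diffuses with exactly D_bead / N (internal forces cancel pairwise and
    the bead noises are independent), so the rescaled coefficient is
    N * D_tr(HI).  ``confirm=True`` verifies with one no-HI run.
    """
    d_hi, err_hi = hcp_dtr(n, with_hi=True, d_bead=d_bead, seed=seed, **kw)
    rescaled = n * d_hi
    out = {"d_tr_hi": (d_hi, err_hi), "rescaled_d_bead": rescaled,
           "rescaled_err": n * err_hi}
    if confirm:
        d_chk, err_chk = hcp_dtr(n, with_hi=False, d_bead=rescaled,
                                 seed=seed + 1, **kw)
        out["d_tr_nohi_check"] = (d_chk, err_chk)
    return out


def _farthest_pair(system) -> tuple[int, int]:
    pos = system.g_init_pos
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    return tuple(int(i) for i in np.unravel_index(np.argmax(d), d.shape))


def hcp_rotation_time(n: int, with_hi: bool, d_bead: float = 1.2e-4,
                      seed: int = 0, replicas: int = 8, steps: int = 100_000,
                      dt: float = 20.0, stride: int = 200):
    """Orientation relaxation time of the axis between the two farthest
    beads; returns (tau, err)."""
    traj, system = run_hcp(n, with_hi, d_bead, seed, replicas, steps, dt, stride)
    i, j = _farthest_pair(system)
    f0 = traj.n_frames // 10
    u = traj.pos[f0:, :, j, :] - traj.pos[f0:, :, i, :]
    return analysis.rotational_relaxation(u, traj.times[f0:])


def hcp_rotation_comparison(ns=(4, 13), seed: int = 0, **kw):
    """tau_rot and D_tr with HI across sizes, plus the no-HI run at the
    rescaled (matched D_tr) bead coefficient for the smallest size."""
    out = {"hi": {}}
    for n in ns:
        steps = {4: 40_000, 13: 120_000}.get(n, 120_000)
        reps = {4: 16, 13: 8}.get(n, 8)
        tau = hcp_rotation_time(n, True, seed=seed + n, replicas=reps,
                                steps=steps, **kw)
        dtr = hcp_dtr(n, with_hi=True, seed=seed + 100 + n)
        out["hi"][n] = {"tau": tau, "d_tr": dtr}
    n0 = ns[0]
    rescaled = n0 * out["hi"][n0]["d_tr"][0]
    steps = {4: 40_000}.get(n0, 60_000)
    out["nohi_matched"] = {
        "d_bead": rescaled,
        "tau": hcp_rotation_time(n0, False, d_bead=rescaled, seed=seed + 7,
                                 replicas=16, steps=steps, **kw),
    }
    return out


# ---------------------------------------------------------------------------
# Example 3: diffusional transport through fixed obstacles


def _transport_builder(kind: str | None, n_layers: int, radius: float,
                       capacity: int, attract_eps: float = 2.0,
                       rows: int = 3, cols: int = 3):
    """Box with two constant-density interfaces and an optional obstacle
    array; mobile species: uncharged 2 nm spheres with D = 1e-4 nm^2/ps."""
    from .model import (GeomSpec, GestaltTemplate, ProteinTemplate, VdWSphere)
    box = SimulationBox((30.0, 20.0, 20.0),
                        ("interface", "periodic", "periodic"))
    colours = ColourTable({
        (0, 0): ColourPair(epsilon=1.0, sigma=0.5, attractive=False),
        (0, 1): ColourPair(epsilon=attract_eps if kind == "attractive" else 1.0,
                           sigma=0.5, attractive=(kind == "attractive")),
        (1, 1): ColourPair(epsilon=1.0, sigma=0.5, attractive=False),
    })
    builder = SystemBuilder(box, colours)
    if kind is not None:
        layers = (0.0,) if n_layers == 1 else (-10.0, 10.0)
        builder.add_wall(build_obstacle_wall(rows=rows, cols=cols,
                                             radius=radius, layer_x=layers,
                                             x_center=15.0))
    bead = ProteinTemplate("bead", (GestaltTemplate(
        geom=GeomSpec(d_tr=1e-4),
        vdw=(VdWSphere((0.0, 0.0, 0.0), 2.0, 0),)),))
    builder.reserve(bead, capacity)
    return builder.compile()


def transport_experiment(kind: str | None = None, n_layers: int = 1,
                         radius: float = 5.0, rho0: float = 4e-4,
                         steps: int = 1_200_000, dt: float = 10.0,
                         replicas: int = 3, seed: int = 0,
                         stride: int = 2000, capacity: int = 60,
                         rows: int = 3, cols: int = 3):
    """Stationary diffusion rate through the (optionally obstructed) box.

    Starts empty; one face at reservoir density ``rho0``, the opposite at
    zero.  The cumulative count of particles absorbed at the zero side,
    averaged over the replicas, is fitted with a straight line after the
    first-absorption burn-in.  Returns R_D (slope, ps^-1), T_D (x-axis
    intercept, ps), the combined error and the mean particle number.
    """
    system = _transport_builder(kind, n_layers, radius, capacity,
                                rows=rows, cols=cols)
    state = system.initial_state(replicas)
    state.active[:] = False
    interfaces = (
        DensityInterface(axis=0, side="high", species="bead", rho=rho0),
        DensityInterface(axis=0, side="low", species="bead", rho=0.0),
    )
    ctx = StepContext(dt=dt, seed=seed)
    traj = integrate(system, state, ctx, steps, stride=stride,
                     interfaces=interfaces)
    n_left = traj.n_absorbed[:, :, 1].astype(float)        # rho = 0 side
    r_mean, t_d, fit_err = analysis.transport_fit(traj.times,
                                                  n_left.mean(axis=1))
    per_rep = []
    for m in range(replicas):
        try:
            per_rep.append(analysis.transport_fit(traj.times, n_left[:, m])[0])
        except analysis.FitError:
            pass
    spread = (np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))
              if len(per_rep) > 1 else np.inf)
    return {
        "R_D": float(r_mean),
        "T_D": float(t_d),
        "err": float(np.sqrt(fit_err ** 2 + spread ** 2)),
        "n_p_mean": float(traj.n_mobile[traj.n_frames // 2:].mean()),
        "trajectory": traj,
    }


# ---------------------------------------------------------------------------
# Example 4: patchy-particle agglomeration


def agglomeration_colours(well_depth: float = 0.9) -> ColourTable:
    """Patch-patch attraction slightly below kT; everything else repulsive."""
    return ColourTable({
        (0, 0): ColourPair(epsilon=well_depth, sigma=0.3, attractive=True,
                           cutoff=1.5),
        (0, 1): ColourPair(epsilon=1.0, sigma=0.3, attractive=False),
        (1, 1): ColourPair(epsilon=1.0, sigma=0.3, attractive=False),
    })


def agglomeration_experiment(n_particles: int = 27, box_length: float = 30.0,
                             steps: int = 100_000, dt: float = 10.0,
                             seed: int = 0, stride: int = 1000,
                             network_cutoff: float = 4.0,
                             well_depth: float = 0.9):
    """Langevin simulation of patchy particles plus per-frame network
    measures of the patch-sphere interaction graph.

    Returns (trajectory, system, measures) where measures is a list of
    per-frame dicts from :func:`mesobd.analysis.network_measures`.
    """
    box = SimulationBox((box_length,) * 3)
    builder = SystemBuilder(box, agglomeration_colours(well_depth))
    template = build_patchy_particle()
    per_side = int(np.ceil(n_particles ** (1 / 3)))
    spacing = box_length / per_side
    rng = np.random.default_rng(seed)
    count = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if count >= n_particles:
                    break
                q = rng.normal(size=4)
                builder.instantiate(template,
                                    position=((i + 0.5) * spacing,
                                              (j + 0.5) * spacing,
                                              (k + 0.5) * spacing),
                                    orientation=q / np.linalg.norm(q))
                count += 1
    system = builder.compile()
    state = system.initial_state(1)
    ctx = StepContext(dt=dt, seed=seed)
    traj = integrate(system, state, ctx, steps, stride=stride)

    patch = np.flatnonzero(system.sph_colour == 0)
    measures = []
    from .model import quat_rotate
    for f in range(traj.n_frames):
        pos = traj.pos[f, 0][system.sph_owner[patch]]
        offs = quat_rotate(traj.quat[f, 0][system.sph_owner[patch]],
                           system.sph_offset[patch])
        net = analysis.build_network(pos + offs, network_cutoff, box)
        m = analysis.network_measures(net)
        m["time"] = float(traj.times[f])
        measures.append(m)
    return traj, system, measures
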