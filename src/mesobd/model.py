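"""Hierarchical particle model and deterministic builders for example systems.

A mobile particle ("protein") is a template of one or more independently
moving rigid units ("gestalten").  Each gestalt carries a geometry
specification (translational and rotational mobility, optional mass), a set
of van-der-Waals spheres with integer interaction colours, point charges
with burial depths, at most one hydrodynamic sphere, and external
restraints.  Bonds with harmonic plus quartic terms connect gestalten of
the same protein and may be hooked up eccentrically.  Templates are
immutable; instances placed into a :class:`System` never alias template
storage.

The builders at the bottom reproduce the four canonical example systems:
constrained bead-spring polymers, quasi-spherical elastic particles on a
hexagonal close packing, fixed obstacle arrays for transport studies, and
two-sphere patchy particles for agglomeration studies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .boundaries import ConfigurationError, SimulationBox, wrap_positions

__all__ = [
    "Bond", "ColourPair", "ColourTable", "ConstantForce", "GeomSpec",
    "GestaltTemplate", "HarmonicRestraint", "HydroSphere",
    "InvalidTemplateError", "PointCharge", "ProteinTemplate",
    "RejectedInsertionError", "System", "SystemBuilder", "SystemState",
    "VdWSphere", "WallTemplate", "build_hcp_particle", "build_obstacle_wall",
    "build_patchy_particle", "build_polymer",
]


class InvalidTemplateError(ValueError):
    """A particle template violates its structural invariants."""


class RejectedInsertionError(RuntimeError):
    """Insertion would overlap a fixed structure beyond the linearization
    threshold; the caller should retry at a different position."""


Vec3 = tuple[float, float, float]


def _vec3(v) -> Vec3:
    x, y, z = (float(c) for c in v)
    if not all(np.isfinite((x, y, z))):
        raise InvalidTemplateError("vector components must be finite")
    return (x, y, z)


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z); used for gestalt orientations


def quat_identity(shape=()) -> np.ndarray:
    q = np.zeros(shape + (4,))
    q[..., 0] = 1.0
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by unit quaternions ``q`` (broadcasting)."""
    w = q[..., :1]
    u = q[..., 1:]
    cross1 = np.cross(u, v)
    return v + 2.0 * (w * cross1 + np.cross(u, cross1))


def quat_from_rotvec(phi: np.ndarray) -> np.ndarray:
    """Unit quaternion for rotation vectors (axis * angle, radians)."""
    angle = np.linalg.norm(phi, axis=-1, keepdims=True)
    small = angle < 1e-12
    axis = np.where(small, 0.0, phi / np.where(small, 1.0, angle))
    half = 0.5 * angle
    q = np.concatenate([np.cos(half), axis * np.sin(half)], axis=-1)
    return q


# ---------------------------------------------------------------------------
# shape primitives


@dataclass(frozen=True)
class VdWSphere:
    """Short-range interaction sphere in the gestalt frame."""

    offset: Vec3
    radius: float
    colour: int

    def __post_init__(self):
        object.__setattr__(self, "offset", _vec3(self.offset))
        if self.radius <= 0:
            raise InvalidTemplateError("vdW sphere radius must be > 0")


@dataclass(frozen=True)
class PointCharge:
    """Screened point charge; ``burial`` is the depth (nm) by which the
    charge sits inside the low-dielectric particle, exempting that stretch
    of the separation from Debye screening."""

    offset: Vec3
    q: float
    burial: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "offset", _vec3(self.offset))
        if self.burial < 0:
            raise InvalidTemplateError("burial depth must be >= 0")


@dataclass(frozen=True)
class HydroSphere:
    """Hydrodynamic sphere centred on the gestalt origin."""

    radius: float
    d_self: float

    def __post_init__(self):
        if self.radius <= 0 or self.d_self <= 0:
            raise InvalidTemplateError("hydrodynamic radius and D_self must be > 0")


@dataclass(frozen=True)
class GeomSpec:
    """Mobility of a gestalt: translational diffusion coefficient ``d_tr``
    (nm^2/ps), rotational diffusion coefficient ``d_rot`` (ps^-1), and an
    optional mass (kDa).  A defined mass selects the finitely damped
    Langevin propagation; without it the overdamped Brownian scheme is
    used."""

    d_tr: float
    d_rot: float = 0.0
    mass: float | None = None

    def __post_init__(self):
        if self.d_tr <= 0:
            raise InvalidTemplateError("d_tr must be > 0")
        if self.d_rot < 0:
            raise InvalidTemplateError("d_rot must be >= 0")
        if self.mass is not None and self.mass <= 0:
            raise InvalidTemplateError("mass, when given, must be > 0")

    def tau_rel(self, kT: float) -> float:
        """Velocity relaxation time m/gamma = m * d_tr / kT (ps)."""
        if self.mass is None:
            return 0.0
        return self.mass * self.d_tr / kT


@dataclass(frozen=True)
class HarmonicRestraint:
    k: float              # kT / nm^2
    center: Vec3

    def __post_init__(self):
        object.__setattr__(self, "center", _vec3(self.center))
        if self.k < 0:
            raise InvalidTemplateError("restraint constant must be >= 0")


@dataclass(frozen=True)
class ConstantForce:
    f: Vec3               # kT / nm

    def __post_init__(self):
        object.__setattr__(self, "f", _vec3(self.f))


@dataclass(frozen=True)
class GestaltTemplate:
    geom: GeomSpec
    position: Vec3 = (0.0, 0.0, 0.0)   # placement in the protein frame
    vdw: tuple[VdWSphere, ...] = ()
    charges: tuple[PointCharge, ...] = ()
    hydro: HydroSphere | None = None
    restraints: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "position", _vec3(self.position))
        object.__setattr__(self, "vdw", tuple(self.vdw))
        object.__setattr__(self, "charges", tuple(self.charges))
        object.__setattr__(self, "restraints", tuple(self.restraints))


@dataclass(frozen=True)
class Bond:
    """Spring between two gestalten of the same protein.

    Hooks are attachment offsets in the respective gestalt frames; offsets
    away from the origin make the bond eccentric so that its force also
    exerts a torque.  The potential is ``U = k2/2 (d-L0)^2 + k4/4 (d-L0)^4``
    with ``d`` the hook-hook distance.
    """

    a: int
    b: int
    k2: float
    length: float
    k4: float = 0.0
    hook_a: Vec3 = (0.0, 0.0, 0.0)
    hook_b: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "hook_a", _vec3(self.hook_a))
        object.__setattr__(self, "hook_b", _vec3(self.hook_b))
        if self.a == self.b:
            raise InvalidTemplateError("bond must connect distinct gestalten")
        if self.k2 < 0 or self.k4 < 0 or (self.k2 == 0 and self.k4 == 0):
            raise InvalidTemplateError("bond needs k2 >= 0, k4 >= 0, not both zero")


@dataclass(frozen=True)
class ProteinTemplate:
    """An entity inserted into or removed from a simulation as a whole."""

    name: str
    gestalten: tuple[GestaltTemplate, ...]
    bonds: tuple[Bond, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "gestalten", tuple(self.gestalten))
        object.__setattr__(self, "bonds", tuple(self.bonds))
        if not self.gestalten:
            raise InvalidTemplateError("protein needs at least one gestalt")
        n = len(self.gestalten)
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise InvalidTemplateError("bond references gestalt out of range")


@dataclass(frozen=True)
class WallTemplate:
    """Fixed structure: van-der-Waals spheres and charges at absolute
    coordinates.  Fixed structures never move and no fixed-fixed pair
    interactions are ever evaluated."""

    name: str
    spheres: tuple[VdWSphere, ...] = ()
    charges: tuple[PointCharge, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "spheres", tuple(self.spheres))
        object.__setattr__(self, "charges", tuple(self.charges))


# ---------------------------------------------------------------------------
# colour-indexed short-range interaction parameters


@dataclass(frozen=True)
class ColourPair:
    """Parameters of the Lennard-Jones-type surface-distance potential for
    one unordered pair of colours.

    The potential is parameterised so that its minimum of depth ``epsilon``
    (kT) sits at surface-surface distance ``sigma`` (nm); repulsive-only
    pairs keep just the r^-12 branch.  ``cutoff`` defaults to 3 sigma.
    ``r_lin`` is the surface distance below which the force is held
    constant (energy continued linearly) for numerical stability; when
    None it defaults to 0.2 times the smaller sphere radius, capped at
    0.8 sigma.
    """

    epsilon: float
    sigma: float
    attractive: bool = False
    cutoff: float | None = None
    r_lin: float | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise InvalidTemplateError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise InvalidTemplateError("sigma must be > 0")

    @property
    def cutoff_value(self) -> float:
        return 3.0 * self.sigma if self.cutoff is None else self.cutoff

    def r_lin_value(self, a_i: float, a_k: float) -> float:
        if self.r_lin is not None:
            return self.r_lin
        return min(0.2 * min(a_i, a_k), 0.8 * self.sigma)


class ColourTable:
    """Symmetric lookup of :class:`ColourPair` parameters."""

    def __init__(self, pairs: dict | None = None):
        self._pairs: dict[tuple[int, int], ColourPair] = {}
        if pairs:
            for (a, b), p in pairs.items():
                self.set(a, b, p)

    def set(self, a: int, b: int, params: ColourPair) -> None:
        self._pairs[(min(a, b), max(a, b))] = params

    def get(self, a: int, b: int) -> ColourPair:
        try:
            return self._pairs[(min(a, b), max(a, b))]
        except KeyError:
            raise ConfigurationError(
                f"no interaction parameters for colour pair ({a}, {b})"
            ) from None

    def has(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self._pairs

    def items(self):
        return self._pairs.items()

    def max_cutoff(self, radii_by_colour: dict[int, float]) -> float:
        cut = 0.0
        for (a, b), p in self._pairs.items():
            ra = radii_by_colour.get(a, 0.0)
            rb = radii_by_colour.get(b, 0.0)
            cut = max(cut, p.cutoff_value + ra + rb)
        return cut


# ---------------------------------------------------------------------------
# compiled system


@dataclass
class SystemState:
    """Dynamic state of all mobile gestalten, replicated over independent
    simulation copies (leading axis M)."""

    pos: np.ndarray        # (M, G, 3) wrapped positions
    quat: np.ndarray       # (M, G, 4)
    vel: np.ndarray        # (M, G, 3) only meaningful for Langevin gestalten
    images: np.ndarray     # (M, G, 3) integer periodic image counts
    active: np.ndarray     # (M, G) bool
    time: float = 0.0

    @property
    def replicas(self) -> int:
        return self.pos.shape[0]

    def unwrapped(self, box: SimulationBox) -> np.ndarray:
        return self.pos + self.images * box.lengths_array

    def copy(self) -> "SystemState":
        return SystemState(self.pos.copy(), self.quat.copy(), self.vel.copy(),
                           self.images.copy(), self.active.copy(), self.time)


class System:
    """Flattened, array-based description of one simulation composition.

    Built by :class:`SystemBuilder`; immutable during propagation.  All
    per-gestalt, per-sphere and per-bond quantities live in contiguous
    arrays so that force evaluation and propagation vectorise over both
    gestalten and independent replicas.
    """

    def __init__(self, builder: "SystemBuilder"):
        self.box = builder.box
        self.colours = builder.colours
        self.kT = builder.kT
        self.kappa = builder.kappa
        self.eps_r = builder.eps_r

        g = builder._gestalts
        self.n_gestalt = len(g)
        self.g_dtr = np.array([x["geom"].d_tr for x in g])
        self.g_drot = np.array([x["geom"].d_rot for x in g])
        self.g_mass = np.array([np.nan if x["geom"].mass is None else x["geom"].mass
                                for x in g])
        self.ld_mask = ~np.isnan(self.g_mass)
        self.rot_mask = self.g_drot > 0
        self.g_template = [x["template"] for x in g]
        self.g_instance = np.array([x["instance"] for x in g])
        self.g_init_pos = np.array([x["pos"] for x in g]) if g else np.zeros((0, 3))
        self.g_init_quat = (np.array([x["quat"] for x in g]) if g
                            else np.zeros((0, 4)))
        self.g_init_active = np.array([x["active"] for x in g], dtype=bool)

        # hydrodynamic subset
        hydro = [(i, x["hydro"]) for i, x in enumerate(g) if x["hydro"] is not None]
        self.hydro_idx = np.array([i for i, _ in hydro], dtype=int)
        self.hydro_a = np.array([h.radius for _, h in hydro])
        self.hydro_d = np.array([h.d_self for _, h in hydro])

        # vdW spheres
        sph = builder._spheres
        self.n_sphere = len(sph)
        self.sph_owner = np.array([s[0] for s in sph], dtype=int)
        self.sph_offset = (np.array([s[1].offset for s in sph])
                           if sph else np.zeros((0, 3)))
        self.sph_radius = np.array([s[1].radius for s in sph])
        self.sph_colour = np.array([s[1].colour for s in sph], dtype=int)
        self.sph_has_offsets = bool(np.any(self.sph_offset))

        # point charges
        chg = builder._charges
        self.n_charge = len(chg)
        self.chg_owner = np.array([c[0] for c in chg], dtype=int)
        self.chg_offset = (np.array([c[1].offset for c in chg])
                           if chg else np.zeros((0, 3)))
        self.chg_q = np.array([c[1].q for c in chg])
        self.chg_b = np.array([c[1].burial for c in chg])
        self.chg_has_offsets = bool(np.any(self.chg_offset))

        # bonds
        bonds = builder._bonds
        self.n_bond = len(bonds)
        self.bond_a = np.array([b[0] for b in bonds], dtype=int)
        self.bond_b = np.array([b[1] for b in bonds], dtype=int)
        self.bond_hook_a = (np.array([b[2].hook_a for b in bonds])
                            if bonds else np.zeros((0, 3)))
        self.bond_hook_b = (np.array([b[2].hook_b for b in bonds])
                            if bonds else np.zeros((0, 3)))
        self.bond_k2 = np.array([b[2].k2 for b in bonds])
        self.bond_k4 = np.array([b[2].k4 for b in bonds])
        self.bond_l0 = np.array([b[2].length for b in bonds])
        self.bond_eccentric = bool(np.any(self.bond_hook_a) or np.any(self.bond_hook_b))

        # external restraints
        self.harm_k = np.zeros(self.n_gestalt)
        self.harm_c = np.zeros((self.n_gestalt, 3))
        self.const_f = np.zeros((self.n_gestalt, 3))
        for i, x in enumerate(g):
            for r in x["restraints"]:
                if isinstance(r, HarmonicRestraint):
                    self.harm_k[i] = r.k
                    self.harm_c[i] = r.center
                elif isinstance(r, ConstantForce):
                    self.const_f[i] += np.asarray(r.f)

        # fixed structures
        wall_sph = [(w.name, s) for w in builder._walls for s in w.spheres]
        self.n_wall_sphere = len(wall_sph)
        self.wall_sph_pos = (np.array([s.offset for _, s in wall_sph])
                             if wall_sph else np.zeros((0, 3)))
        self.wall_sph_radius = np.array([s.radius for _, s in wall_sph])
        self.wall_sph_colour = np.array([s.colour for _, s in wall_sph], dtype=int)
        wall_chg = [c for w in builder._walls for c in w.charges]
        self.wall_chg_pos = (np.array([c.offset for c in wall_chg])
                             if wall_chg else np.zeros((0, 3)))
        self.wall_chg_q = np.array([c.q for c in wall_chg])
        self.wall_chg_b = np.array([c.burial for c in wall_chg])

        # per-template slot bookkeeping for open interfaces
        self.slots_by_template: dict[str, np.ndarray] = {}
        for name in set(self.g_template):
            self.slots_by_template[name] = np.array(
                [i for i, t in enumerate(self.g_template) if t == name], dtype=int)

        # instance -> gestalt indices (for centre-of-mass analyses)
        self.instances: list[np.ndarray] = []
        for inst in range(int(self.g_instance.max()) + 1 if len(g) else 0):
            self.instances.append(np.flatnonzero(self.g_instance == inst))

        self._compile_pair_tables()

    # -- pair parameter matrices -------------------------------------------

    def _compile_pair_tables(self) -> None:
        S, W = self.n_sphere, self.n_wall_sphere
        colours_present = set(self.sph_colour.tolist()) | set(self.wall_sph_colour.tolist())
        for a, b in itertools.combinations_with_replacement(sorted(colours_present), 2):
            self.colours.get(a, b)  # raises ConfigurationError when missing

        def tables(col_i, rad_i, col_k, rad_k):
            n_i, n_k = len(col_i), len(col_k)
            eps = np.zeros((n_i, n_k))
            sig = np.ones((n_i, n_k))
            att = np.zeros((n_i, n_k), dtype=bool)
            cut = np.zeros((n_i, n_k))
            rlin = np.zeros((n_i, n_k))
            for ii in range(n_i):
                for kk in range(n_k):
                    p = self.colours.get(int(col_i[ii]), int(col_k[kk]))
                    eps[ii, kk] = p.epsilon
                    sig[ii, kk] = p.sigma
                    att[ii, kk] = p.attractive
                    cut[ii, kk] = p.cutoff_value
                    rlin[ii, kk] = p.r_lin_value(rad_i[ii], rad_k[kk])
            rsum = rad_i[:, None] + rad_k[None, :]
            return eps, sig, att, cut, rlin, rsum

        (self.pp_eps, self.pp_sig, self.pp_att, self.pp_cut, self.pp_rlin,
         self.pp_rsum) = tables(self.sph_colour, self.sph_radius,
                                self.sph_colour, self.sph_radius)
        # same-gestalt sphere pairs never interact
        same = self.sph_owner[:, None] == self.sph_owner[None, :]
        self.pp_valid = ~same
        self.pp_valid &= np.triu(np.ones((S, S), dtype=bool), k=1)

        if W:
            (self.pw_eps, self.pw_sig, self.pw_att, self.pw_cut, self.pw_rlin,
             self.pw_rsum) = tables(self.sph_colour, self.sph_radius,
                                    self.wall_sph_colour, self.wall_sph_radius)

        if W:
            self.pw_cut2 = (self.pw_cut + self.pw_rsum) ** 2
        self.pp_cut2 = (self.pp_cut + self.pp_rsum) ** 2

        # gestalt <- sphere / charge / bond incidence for force accumulation
        self.sph_incidence = np.zeros((self.n_gestalt, S))
        self.sph_incidence[self.sph_owner, np.arange(S)] = 1.0
        self.chg_incidence = np.zeros((self.n_gestalt, self.n_charge))
        if self.n_charge:
            self.chg_incidence[self.chg_owner, np.arange(self.n_charge)] = 1.0
        self.bond_inc_a = np.zeros((self.n_gestalt, self.n_bond))
        self.bond_inc_b = np.zeros((self.n_gestalt, self.n_bond))
        if self.n_bond:
            self.bond_inc_a[self.bond_a, np.arange(self.n_bond)] = 1.0
            self.bond_inc_b[self.bond_b, np.arange(self.n_bond)] = 1.0

        self.sph_identity = bool(
            S == self.n_gestalt and np.array_equal(self.sph_owner, np.arange(S)))
        self.has_restraints = bool(np.any(self.harm_k) or np.any(self.const_f))
        self.needs_torque = bool(self.rot_mask.any()) and bool(
            self.sph_has_offsets or self.chg_has_offsets or self.bond_eccentric)

        # largest centre-centre cutoff must respect the periodic minimum
        # image; only pairs with at least one mobile sphere are evaluated,
        # so fixed-fixed combinations do not constrain the box
        if self.n_sphere:
            mob: dict[int, float] = {}
            for c, r in zip(self.sph_colour.tolist(), self.sph_radius):
                mob[c] = max(mob.get(c, 0.0), float(r))
            alle = dict(mob)
            for c, r in zip(self.wall_sph_colour.tolist(), self.wall_sph_radius):
                alle[c] = max(alle.get(c, 0.0), float(r))
            cut = 0.0
            for (a, b), p in self.colours.items():
                for c1, c2 in ((a, b), (b, a)):
                    if c1 in mob and c2 in alle:
                        cut = max(cut, p.cutoff_value + mob[c1] + alle[c2])
            self.box.check_cutoff(cut)

        # same-gestalt charge pairs excluded
        if self.n_charge:
            self.cc_valid = np.triu(
                self.chg_owner[:, None] != self.chg_owner[None, :], k=1)

    # -- state construction -------------------------------------------------

    def initial_state(self, replicas: int = 1) -> SystemState:
        G = self.n_gestalt
        pos = np.broadcast_to(self.g_init_pos, (replicas, G, 3)).copy()
        quat = np.broadcast_to(self.g_init_quat, (replicas, G, 4)).copy()
        vel = np.zeros((replicas, G, 3))
        images = np.zeros((replicas, G, 3), dtype=np.int64)
        active = np.broadcast_to(self.g_init_active, (replicas, G)).copy()
        state = SystemState(pos, quat, vel, images, active)
        wrap_positions(state.pos, state.images, self.box)
        state.images[:] = 0
        return state

    def sphere_world_positions(self, state: SystemState) -> np.ndarray:
        """World coordinates of all mobile vdW spheres, (M, S, 3)."""
        base = state.pos[:, self.sph_owner, :]
        if not self.sph_has_offsets:
            return base
        q = state.quat[:, self.sph_owner, :]
        return base + quat_rotate(q, self.sph_offset)


class SystemBuilder:
    """Accumulates templates, walls and instances, then compiles a
    :class:`System`."""

    def __init__(self, box: SimulationBox, colours: ColourTable | None = None,
                 kT: float = 2.4361e-3, kappa: float = 0.0, eps_r: float = 80.0):
        self.box = box
        self.colours = colours if colours is not None else ColourTable()
        self.kT = kT
        self.kappa = kappa
        self.eps_r = eps_r
        self._gestalts: list[dict] = []
        self._spheres: list[tuple[int, VdWSphere]] = []
        self._charges: list[tuple[int, PointCharge]] = []
        self._bonds: list[tuple[int, int, Bond]] = []
        self._walls: list[WallTemplate] = []
        self._n_instances = 0

    def add_wall(self, wall: WallTemplate) -> None:
        self._walls.append(wall)

    def _check_fixed_overlap(self, sphere: VdWSphere, world_pos: np.ndarray) -> None:
        for w in self._walls:
            for fs in w.spheres:
                d = world_pos - np.asarray(fs.offset)
                from .boundaries import minimum_image
                minimum_image(d, self.box)
                r12 = float(np.linalg.norm(d)) - sphere.radius - fs.radius
                if self.colours.has(sphere.colour, fs.colour):
                    rlin = self.colours.get(sphere.colour, fs.colour).r_lin_value(
                        sphere.radius, fs.radius)
                    if r12 < rlin:
                        raise RejectedInsertionError(
                            f"sphere overlaps fixed structure {w.name!r}")

    def instantiate(self, template: ProteinTemplate,
                    position=(0.0, 0.0, 0.0), orientation=None,
                    active: bool = True, check_overlap: bool = True) -> int:
        """Place one copy of ``template``; returns the instance id.

        ``position`` shifts the protein frame; ``orientation`` (unit
        quaternion) rotates it.  With ``active=False`` the slots are
        reserved but dormant, for species whose population is controlled by
        a constant-density interface.
        """
        inst = self._n_instances
        self._n_instances += 1
        pos = np.asarray(position, dtype=float)
        q0 = quat_identity() if orientation is None else quat_normalize(
            np.asarray(orientation, dtype=float))
        base = len(self._gestalts)
        for gt in template.gestalten:
            gpos = pos + quat_rotate(q0, np.asarray(gt.position))
            gi = len(self._gestalts)
            self._gestalts.append(dict(
                geom=gt.geom, template=template.name, instance=inst,
                pos=gpos, quat=q0.copy(), active=active,
                hydro=gt.hydro, restraints=gt.restraints))
            for s in gt.vdw:
                if active and check_overlap:
                    world = gpos + quat_rotate(q0, np.asarray(s.offset))
                    self._check_fixed_overlap(s, world)
                self._spheres.append((gi, s))
            for c in gt.charges:
                self._charges.append((gi, c))
        for b in template.bonds:
            self._bonds.append((base + b.a, base + b.b, b))
        return inst

    def reserve(self, template: ProteinTemplate, count: int,
                d_probe: float | None = None) -> None:
        """Reserve ``count`` dormant slots for an interface-managed species.

        Only single-gestalt templates can be exchanged with a reservoir.
        """
        if len(template.gestalten) != 1:
            raise ConfigurationError(
                "constant-density interfaces support single-gestalt species only")
        for _ in range(count):
            self.instantiate(template, active=False, check_overlap=False)

    def compile(self) -> System:
        return System(self)


# ---------------------------------------------------------------------------
# example-system builders


def build_polymer(n: int, k_n: float = 1000.0, k_2n: float = 0.1,
                  l_n: float = 2.5, l_2n: float = 5.0, bead_radius: float = 1.0,
                  d_bead: float = 1.0, with_hi: bool = False,
                  colour: int = 0, name: str | None = None) -> ProteinTemplate:
    """Constrained bead-spring polymer.

    ``n`` beads on a line, nearest neighbours connected by springs
    (``k_n``, rest length ``l_n``) and next neighbours by the
    stiffness-controlling springs (``k_2n``, rest length ``l_2n``).  Each
    bead carries one vdW sphere of the given colour; with ``with_hi`` also
    a hydrodynamic sphere of the same radius.  Bead rotation is ignored
    (d_rot = 0).
    """
    if n < 2:
        raise InvalidTemplateError("polymer needs at least 2 beads")
    if min(k_n, l_n, l_2n, bead_radius, d_bead) <= 0 or k_2n < 0:
        raise InvalidTemplateError("polymer parameters must be positive")
    hydro = HydroSphere(bead_radius, d_bead) if with_hi else None
    gestalten = tuple(
        GestaltTemplate(
            geom=GeomSpec(d_tr=d_bead, d_rot=0.0),
            position=(i * l_n, 0.0, 0.0),
            vdw=(VdWSphere((0.0, 0.0, 0.0), bead_radius, colour),),
            hydro=hydro,
        )
        for i in range(n)
    )
    bonds = [Bond(i, i + 1, k2=k_n, length=l_n) for i in range(n - 1)]
    bonds += [Bond(i, i + 2, k2=k_2n, length=l_2n) for i in range(n - 2) if k_2n > 0]
    return ProteinTemplate(name or f"polymer{n}", gestalten, tuple(bonds))


def _hcp_sites(spacing: float, extent: int = 3) -> np.ndarray:
    """Ideal hexagonal-close-packing sites on a finite block around 0."""
    s = spacing
    c = s * np.sqrt(2.0 / 3.0)       # inter-layer distance
    sites = []
    for l in range(-extent, extent + 1):
        off = np.array([s / 2.0, s / (2.0 * np.sqrt(3.0)), 0.0]) if l % 2 else 0.0
        for i in range(-extent, extent + 1):
            for j in range(-extent, extent + 1):
                p = (np.array([i * s + (j % 2) * s / 2.0,
                               j * s * np.sqrt(3.0) / 2.0,
                               l * c]) + off)
                sites.append(p)
    return np.asarray(sites)


def _compact_selection(sites: np.ndarray, n: int, spacing: float) -> np.ndarray:
    """Pick the most compact ``n``-site cluster.

    Candidate centres are every site and the centroid of every mutually
    adjacent site triple (which covers the tetrahedral voids); for each
    candidate the ``n`` nearest sites are taken (ties broken by site
    index) and the candidate minimising the largest distance wins.
    """
    # limit the candidate scan to the neighbourhood of the block centre
    d0 = np.linalg.norm(sites, axis=1)
    near = np.flatnonzero(d0 < 2.5 * spacing)
    adj = {}
    tol = 1.001 * spacing
    for i in near:
        d = np.linalg.norm(sites - sites[i], axis=1)
        adj[i] = set(np.flatnonzero((d > 0) & (d < tol)).tolist())
    centres = [sites[i] for i in sorted(near)]
    for i in sorted(near):
        for j in sorted(adj[i]):
            if j <= i:
                continue
            for k in sorted(adj[i] & adj.get(j, set())):
                if k > j:
                    centres.append((sites[i] + sites[j] + sites[k]) / 3.0)
    best = None
    for ci, c in enumerate(centres):
        d = np.linalg.norm(sites - c, axis=1)
        order = np.lexsort((np.arange(len(sites)), np.round(d, 9)))
        chosen = order[:n]
        score = float(np.round(d[chosen].max(), 9))
        key = (score, ci)
        if best is None or key < best[0]:
            best = (key, chosen)
    return sites[np.sort(best[1])]


def build_hcp_particle(n: int, bead_radius: float = 2.0, spacing: float = 5.0,
                       k: float = 10.0, d_bead: float = 1.2e-4,
                       with_hi: bool = False, colour: int = 0,
                       name: str | None = None) -> ProteinTemplate:
    """Quasi-spherical elastic particle of beads on a hexagonal close
    packing, each bead connected to its up-to-twelve direct neighbours by
    springs of rest length ``spacing``."""
    if spacing <= 0:
        raise InvalidTemplateError("lattice spacing must be positive")
    if n < 1:
        raise InvalidTemplateError("need at least one bead")
    sites = _compact_selection(_hcp_sites(spacing), n, spacing)
    sites = sites - sites.mean(axis=0)
    hydro = HydroSphere(bead_radius, d_bead) if with_hi else None
    gestalten = tuple(
        GestaltTemplate(
            geom=GeomSpec(d_tr=d_bead, d_rot=0.0),
            position=tuple(p),
            vdw=(VdWSphere((0.0, 0.0, 0.0), bead_radius, colour),),
            hydro=hydro,
        )
        for p in sites
    )
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(sites[j] - sites[i]) < 1.001 * spacing:
                bonds.append(Bond(i, j, k2=k, length=spacing))
    return ProteinTemplate(name or f"hcp{n}", gestalten, tuple(bonds))


def build_patchy_particle(sphere_radius: float = 1.7, displacement: float = 0.5,
                          d_tr: float = 1.2e-4, d_rot: float = 2.26e-5,
                          mass: float | None = 18.0, patch_colour: int = 0,
                          body_colour: int = 1,
                          name: str = "patchy") -> ProteinTemplate:
    """Rigid two-sphere particle with an attractive patch.

    Two vdW spheres displaced by +-``displacement`` along the gestalt
    z-axis; the patch sphere (at +z) carries ``patch_colour``, the body
    sphere ``body_colour``.  A defined mass selects Langevin propagation.
    """
    if displacement >= sphere_radius:
        raise InvalidTemplateError("displacement must be smaller than the radius")
    g = GestaltTemplate(
        geom=GeomSpec(d_tr=d_tr, d_rot=d_rot, mass=mass),
        vdw=(VdWSphere((0.0, 0.0, displacement), sphere_radius, patch_colour),
             VdWSphere((0.0, 0.0, -displacement), sphere_radius, body_colour)),
    )
    return ProteinTemplate(name, (g,))


def build_obstacle_wall(rows: int = 3, cols: int = 3,
                        cross_section: tuple[float, float] = (20.0, 20.0),
                        radius: float = 5.0, layer_x=(0.0,), colour: int = 1,
                        x_center: float = 15.0,
                        name: str = "obstacles") -> WallTemplate:
    """Array of fixed spherical obstacles on a rows x cols rectangular grid
    spanning the (periodic) y-z cross-section, one grid per entry of
    ``layer_x`` (x offsets relative to ``x_center``)."""
    if radius <= 0:
        raise InvalidTemplateError("obstacle radius must be positive")
    layer_x = tuple(layer_x)
    if not layer_x:
        raise InvalidTemplateError("need at least one obstacle layer")
    Ly, Lz = cross_section
    spheres = []
    for lx in layer_x:
        for i in range(rows):
            for j in range(cols):
                y = (i + 0.5) * Ly / rows
                z = (j + 0.5) * Lz / cols
                spheres.append(VdWSphere((x_center + lx, y, z), radius, colour))
    return WallTemplate(name, tuple(spheres))
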