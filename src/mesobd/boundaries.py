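"""Simulation box geometry, periodic wrapping, reflection and open interfaces.

Supported per-axis boundary modes:

``periodic``
    minimum-image convention for pair separations; coordinates are kept in
    the half-open interval ``[0, L)`` and image counts are tracked so that
    trajectories can be unwrapped for diffusion analysis.
``reflecting``
    specular reflection of the overshoot at both faces; the velocity
    component of inertial (Langevin) particles is flipped.
``interface``
    open axis bounded by constant-density reservoir interfaces; particles
    crossing a face are absorbed and new ones are injected at a rate that
    corresponds to the reservoir density.  Species not handled by an
    interface reflect at the face.
``none``
    unbounded axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_NAMES = {"x": 0, "y": 1, "z": 2}
MODES = ("periodic", "reflecting", "interface", "none")


class ConfigurationError(ValueError):
    """Inconsistent simulation setup (box, cutoffs, species, colours)."""


@dataclass(frozen=True)
class SimulationBox:
    """Rectangular simulation cell with per-axis boundary modes."""

    lengths: tuple[float, float, float]
    modes: tuple[str, str, str] = ("periodic", "periodic", "periodic")

    def __post_init__(self):
        if any(L <= 0 for L in self.lengths):
            raise ConfigurationError("box edge lengths must be positive")
        for m in self.modes:
            if m not in MODES:
                raise ConfigurationError(f"unknown boundary mode {m!r}")

    @property
    def periodic(self) -> np.ndarray:
        return np.array([m == "periodic" for m in self.modes])

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    def check_cutoff(self, cutoff: float) -> None:
        """Largest interaction cutoff must fit in half the periodic cell."""
        for L, m in zip(self.lengths, self.modes):
            if m == "periodic" and cutoff >= L / 2:
                raise ConfigurationError(
                    f"cutoff {cutoff} nm exceeds half the periodic edge {L} nm"
                )


def minimum_image(dvec: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Apply the minimum-image convention to separation vectors in place."""
    L = box.lengths_array
    for ax in range(3):
        if box.modes[ax] == "periodic":
            dvec[..., ax] -= L[ax] * np.round(dvec[..., ax] / L[ax])
    return dvec


def wrap_positions(pos: np.ndarray, images: np.ndarray, box: SimulationBox) -> None:
    """Wrap coordinates into the primary cell, accumulating image counts.

    ``images`` (same shape as ``pos``, integer) records how many cell
    lengths each coordinate has been shifted; ``pos + images * L`` is the
    unwrapped trajectory.
    """
    L = box.lengths_array
    for ax in range(3):
        if box.modes[ax] == "periodic":
            shift = np.floor(pos[..., ax] / L[ax])
            if np.any(shift):
                pos[..., ax] -= shift * L[ax]
                images[..., ax] += shift.astype(images.dtype)


def reflect(pos: np.ndarray, vel: np.ndarray, box: SimulationBox,
            axes: tuple[int, ...] | None = None) -> None:
    """Specular reflection of overshoots at reflecting faces (in place).

    A particle that ends a step at ``-d`` is placed at ``+d``; the velocity
    component along the axis is flipped so Langevin particles bounce.
    Repeated folding handles overshoots beyond a full box length.
    """
    L = box.lengths_array
    if axes is None:
        axes = tuple(ax for ax in range(3) if box.modes[ax] == "reflecting")
    for ax in axes:
        # fold onto the triangle wave [0, L]; the fold is mirroring exactly
        # when the coordinate lands in the upper half of the 2L period, and
        # each mirroring corresponds to an odd number of wall hits
        m = np.mod(pos[..., ax], 2 * L[ax])
        mirrored = m > L[ax]
        pos[..., ax] = np.where(mirrored, 2 * L[ax] - m, m)
        vel[..., ax] = np.where(mirrored, -vel[..., ax], vel[..., ax])


@dataclass
class DensityInterface:
    """Constant-density reservoir bounding one face of the box.

    Particles of ``species`` that cross the plane are removed and counted;
    new particles are injected with the one-step crossing statistics of an
    equilibrated reservoir at number density ``rho`` (nm^-3).  The mean
    number of insertions per step is ``rho * A * sqrt(D * dt / pi)``, the
    one-sided diffusive crossing count of a homogeneous half-space during
    one timestep.
    """

    axis: int
    side: str  # "low" (plane at 0, inflow +) or "high" (plane at L, inflow -)
    species: str
    rho: float
    max_insert_retries: int = 20
    n_absorbed: np.ndarray | None = None   # (M,) cumulative, set by the engine
    n_inserted: np.ndarray | None = None
    events: list = field(default_factory=list)  # (time, replica, +1/-1) audit log

    def __post_init__(self):
        if isinstance(self.axis, str):
            self.axis = AXIS_NAMES[self.axis]
        if self.side not in ("low", "high"):
            raise ConfigurationError("interface side must be 'low' or 'high'")
        if self.rho < 0:
            raise ConfigurationError("reservoir density must be >= 0")

    def area(self, box: SimulationBox) -> float:
        L = box.lengths_array
        return float(np.prod(np.delete(L, self.axis)))

    def mean_insertions_per_step(self, box: SimulationBox, D: float, dt: float) -> float:
        """nu = rho * A * sqrt(D dt / pi), the reservoir crossing flux."""
        return self.rho * self.area(box) * np.sqrt(D * dt / np.pi)

    def crossed(self, pos_axis: np.ndarray, box: SimulationBox) -> np.ndarray:
        if self.side == "low":
            return pos_axis < 0.0
        return pos_axis > box.lengths[self.axis]

    def sample_depths(self, n: int, D: float, dt: float, rng) -> np.ndarray:
        """Penetration depths of reservoir particles that crossed this step.

        For a uniform half-space taking one Gaussian step of standard
        deviation ``sigma = sqrt(2 D dt)``, the step length of crossing
        particles is Rayleigh(sigma) distributed and the crossing point is
        uniform along the step, so the depth is ``s * u`` with
        ``s ~ Rayleigh(sigma)`` and ``u ~ U(0, 1)``.
        """
        sigma = np.sqrt(2.0 * D * dt)
        s = rng.rayleigh(sigma, size=n)
        return s * rng.uniform(0.0, 1.0, size=n)
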