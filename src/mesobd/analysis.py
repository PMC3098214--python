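"""Trajectory post-processing.

Diffusion coefficients from time- and ensemble-averaged mean-squared
displacements, rotational relaxation times from orientation
autocorrelations, scaling exponents from log-log fits, transport rates
from cumulative absorption counts, and dynamic interaction networks from
a distance criterion.

All routines accept plain arrays so they work on freshly generated
in-memory trajectories and on trajectories read back from disk alike.
Coordinates must be unwrapped (periodic crossings accumulated), which is
what :func:`mesobd.propagation.integrate` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .boundaries import SimulationBox, minimum_image

__all__ = [
    "FitError", "MSDSeries", "apparent_diffusion", "build_network",
    "com_positions", "end_to_end", "fit_long_time_D", "msd_curve",
    "network_measures", "rotational_relaxation", "scaling_exponent",
    "transport_fit",
]


class FitError(ValueError):
    """Not enough valid data for the requested fit."""


@dataclass
class MSDSeries:
    """Mean-squared displacement versus lag time.

    ``counts`` is the number of (window x particle x replica) samples
    entering each lag.  ``msd / (6 lag)`` is the apparent diffusion
    coefficient at that observation interval.
    """

    lags: np.ndarray     # ps, strictly increasing
    msd: np.ndarray      # nm^2
    counts: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag grid must be strictly increasing")


def com_positions(pos: np.ndarray, groups) -> np.ndarray:
    """Centre-of-mass trajectory per instance group (equal-weight beads).

    ``pos``: (frames, M, G, 3); ``groups``: sequence of index arrays.
    Returns (frames, M, n_groups, 3).
    """
    return np.stack([pos[:, :, g, :].mean(axis=2) for g in groups], axis=2)


def end_to_end(pos: np.ndarray, first: int = 0, last: int = -1) -> np.ndarray:
    """Vector from the first to the last bead, (frames, M, 3)."""
    return pos[:, :, last, :] - pos[:, :, first, :]


def msd_curve(pos: np.ndarray, times: np.ndarray, lags=None) -> MSDSeries:
    """Time- and ensemble-averaged MSD on an (frames, ..., 3) trajectory.

    All axes between the frame axis and the coordinate axis are treated as
    independent ensemble members (replicas, equivalent particles).  Lags
    are frame offsets; by default up to half the trajectory on a grid of
    at most ~60 points.  Overlapping windows are used, so neighbouring
    lag estimates are correlated; ``counts`` reports raw sample numbers.
    """
    pos = np.asarray(pos)
    F = pos.shape[0]
    if lags is None:
        lags = np.unique(np.linspace(1, F // 2, 60).astype(int))
    lags = np.asarray([l for l in np.atleast_1d(lags) if 0 < l < F], dtype=int)
    if len(lags) == 0:
        raise FitError("no usable lags for this trajectory length")
    msd = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    flat = pos.reshape(F, -1, 3)
    for i, l in enumerate(lags):
        d = flat[l:] - flat[:-l]
        msd[i] = np.mean(np.sum(d * d, axis=-1))
        counts[i] = d.shape[0] * d.shape[1]
    dt_frame = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return MSDSeries(lags * dt_frame, msd, counts)


def apparent_diffusion(series: MSDSeries) -> np.ndarray:
    """Apparent D(lag) = MSD / (6 lag) per lag."""
    return series.msd / (6.0 * series.lags)


def fit_long_time_D(series: MSDSeries, window=None):
    """Long-time diffusion coefficient from a straight-line fit.

    ``window = (t_min, t_max)`` restricts the lags; the default takes the
    last decade (lags above one tenth of the largest lag), where internal
    relaxation is assumed to have decayed.  Returns ``(D, stderr)`` in
    nm^2/ps.
    """
    if window is None:
        window = (series.lags.max() / 10.0, np.inf)
    m = (series.lags >= window[0]) & (series.lags <= window[1])
    if m.sum() < 3:
        raise FitError("fewer than 3 lag points in the fit window")
    res = stats.linregress(series.lags[m], series.msd[m])
    return res.slope / 6.0, res.stderr / 6.0


def rotational_relaxation(u: np.ndarray, times: np.ndarray,
                          fit_floor: float = np.exp(-2.0)):
    """Orientation relaxation time from a single-exponential fit.

    ``u``: (frames, ..., 3) vectors (normalised internally).  The
    autocorrelation C(lag) = <u_hat(0) . u_hat(lag)> is fitted by
    exp(-t/tau) on the lags from zero to its first crossing of
    ``fit_floor`` (default e^-2).  Returns ``(tau, stderr)``; if C never
    decays below e^-1 the fit is flagged unreliable with a warning and
    tau = inf is returned.
    """
    u = np.asarray(u, dtype=float)
    F = u.shape[0]
    uhat = u / np.linalg.norm(u, axis=-1, keepdims=True)
    flat = uhat.reshape(F, -1, 3)
    max_lag = F - 1
    corr = np.empty(max_lag + 1)
    corr[0] = 1.0
    for l in range(1, max_lag + 1):
        corr[l] = np.mean(np.sum(flat[l:] * flat[:-l], axis=-1))
    dt_frame = float(times[1] - times[0]) if len(times) > 1 else 1.0

    below = np.flatnonzero(corr < fit_floor)
    below_e1 = np.flatnonzero(corr < np.exp(-1.0))
    if len(below_e1) == 0:
        warnings.warn("orientation correlation never decays below e^-1; "
                      "relaxation time unreliable", RuntimeWarning)
        return np.inf, np.inf
    # never fit into the noise plateau beyond the resolved decay: stop at
    # the first crossing of the floor, or of e^-1 when the trajectory is
    # too short to resolve the floor
    end = below[0] if len(below) else below_e1[0]
    end = int(min(end, 3 * below_e1[0]))
    lags = np.arange(1, max(end, 3) + 1)
    c = corr[lags]
    good = c > 0
    if good.sum() < 2:
        raise FitError("correlation drops below zero immediately")
    res = stats.linregress(lags[good] * dt_frame, np.log(c[good]))
    tau = -1.0 / res.slope
    err = tau * abs(res.stderr / res.slope) if res.slope != 0 else np.inf
    return tau, err


def scaling_exponent(sizes, values):
    """Least-squares slope of log(values) against log(sizes).

    Returns ``(exponent, stderr)``.  Needs at least 3 strictly positive
    points."""
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(sizes) < 3:
        raise FitError("need at least 3 points for a scaling fit")
    if np.any(sizes <= 0) or np.any(values <= 0):
        raise FitError("scaling fit requires positive sizes and values")
    res = stats.linregress(np.log(sizes), np.log(values))
    return res.slope, res.stderr


def transport_fit(times: np.ndarray, n_left: np.ndarray):
    """Straight-line fit of the cumulative absorbed-particle count.

    Returns ``(R_D, T_D, stderr)``: the slope (exit rate, inverse time
    units of ``times``) and the x-axis intercept (transit time).  Frames
    before the first absorption event are discarded as burn-in.  A series
    without any absorption has no defined fit.
    """
    times = np.asarray(times, dtype=float)
    n_left = np.asarray(n_left, dtype=float)
    nz = np.flatnonzero(n_left > 0)
    if len(nz) == 0:
        raise FitError("no particles absorbed; transport rate undefined")
    i0 = nz[0]
    if len(times) - i0 < 3:
        raise FitError("too few frames after the first absorption")
    res = stats.linregress(times[i0:], n_left[i0:])
    if res.slope <= 0:
        raise FitError("non-positive transport slope")
    return res.slope, -res.intercept / res.slope, res.stderr


# ---------------------------------------------------------------------------
# dynamic interaction networks


def build_network(points: np.ndarray, cutoff: float,
                  box: SimulationBox | None = None) -> nx.Graph:
    """Graph with one node per point and links between all pairs with
    centre-to-centre distance strictly below ``cutoff`` (minimum-image
    distances under periodic boundaries)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n > 1:
        d = points[:, None, :] - points[None, :, :]
        if box is not None:
            minimum_image(d, box)
        r = np.sqrt(np.sum(d * d, axis=-1))
        ii, kk = np.nonzero(np.triu(r < cutoff, k=1))
        g.add_edges_from(zip(ii.tolist(), kk.tolist()))
    return g


def network_measures(g: nx.Graph) -> dict:
    """Cluster and degree measures of one interaction-network frame.

    Returns mean degree <k>, max(k), the number of connected components
    with more than one node #CC(N>1), their average size <N>(N>1), the
    size of the largest cluster and the full cluster-size multiset.
    """
    n = g.number_of_nodes()
    degrees = [d for _, d in g.degree()]
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    big = [s for s in sizes if s > 1]
    return {
        "n_nodes": n,
        "mean_degree": float(np.mean(degrees)) if n else 0.0,
        "max_degree": int(max(degrees)) if n else 0,
        "n_clusters_gt1": len(big),
        "mean_size_gt1": float(np.mean(big)) if big else 0.0,
        "largest_cluster": sizes[0] if sizes else 0,
        "cluster_sizes": sizes,
    }
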