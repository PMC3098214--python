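"""Rotne-Prager-Yamakawa diffusion tensors and the truncated expansion
approximation (TEA) for hydrodynamically correlated forces.

The configuration-dependent mobility of ``N`` hydrodynamic spheres is the
3N x 3N tensor ``D`` with diagonal blocks ``D_ii = D_self I`` and pairwise
far-field blocks on the Rotne-Prager-Yamakawa level; for overlapping
spheres the regularised form is used (for unequal radii the closed form of
the generalised RPY regularisation, which reduces to the classical
overlap expression for equal spheres).

Correlating the random displacements with the square root of ``D``
(Ermak-McCammon) costs O(N^3) per factorisation.  The TEA replaces the
square root by normalised pairwise couplings:

    R_i = C_i sum_k beta_ik (D_ik / D_ii) r_k

with ``beta_ii = 1``, a single uniform off-diagonal weight ``beta`` fixed
by a mean-field quadratic in the average normalised coupling
``eps = <tr(D_ik) / (3 D_ii)>``, and per-coordinate normalisation factors
``C_i`` that preserve the self covariance 2 D_ii dt exactly ("temperature
conservation").  The expansion is always truncated after the first
correction, so the cost per step is O(N^2) like the force loop itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boundaries import minimum_image

__all__ = [
    "FactorizationError", "TEACoefficients", "build_rpy_tensor",
    "rpy_blocks", "tea_apply", "TEAOperator",
    "cholesky_oracle", "correlation_recovery", "dimer_max_error",
    "rpy_pair_block", "tea_coefficients", "tea_correlate",
    "tea_covariance", "tea_effective_forces",
]


class FactorizationError(np.linalg.LinAlgError):
    """The diffusion tensor is not positive definite (overlapping or
    otherwise invalid geometry)."""


def rpy_pair_block(rvec, a_i: float, a_k: float,
                   d_i: float = 1.0, d_k: float = 1.0) -> np.ndarray:
    """Single 3x3 mobility block for a pair of hydrodynamic spheres.

    ``rvec`` points from sphere k to sphere i.  The self-mobility scale is
    taken from the spheres' own diffusion coefficients via
    ``kT / 6 pi eta = sqrt(d_i a_i d_k a_k)``.
    """
    rvec = np.asarray(rvec, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r < 1e-12:
        raise FactorizationError("coincident hydrodynamic spheres")
    rhat = rvec / r
    P = np.outer(rhat, rhat)
    mu = np.sqrt(d_i * a_i * d_k * a_k)
    if r >= a_i + a_k:
        pref = 0.75 * mu / r
        asum2 = a_i * a_i + a_k * a_k
        c_iso = pref * (1.0 + asum2 / (3.0 * r * r))
        c_par = pref * (1.0 - asum2 / (r * r))
    else:
        r_eff = max(r, abs(a_i - a_k))
        dd = (a_i - a_k) ** 2
        c_iso = mu / (a_i * a_k) * (
            (16.0 * r_eff ** 3 * (a_i + a_k) - (dd + 3.0 * r_eff ** 2) ** 2)
            / (32.0 * r_eff ** 3))
        c_par = mu / (a_i * a_k) * 3.0 * (dd - r_eff ** 2) ** 2 / (32.0 * r_eff ** 3)
    return c_iso * np.eye(3) + c_par * P


def rpy_blocks(pos: np.ndarray, radii: np.ndarray, d_self: np.ndarray,
               box=None) -> np.ndarray:
    """Pairwise mobility blocks, shape (M, N, N, 3, 3).

    Block form of the tensor used by the per-step TEA path (no 3N x 3N
    reshuffle); :func:`build_rpy_tensor` flattens it for factorisation
    and tests.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    M, N = pos.shape[:2]
    radii = np.asarray(radii, dtype=float)
    d_self = np.asarray(d_self, dtype=float)

    rvec = pos[:, :, None, :] - pos[:, None, :, :]
    if box is not None:
        minimum_image(rvec, box)
    r2 = np.einsum("mikd,mikd->mik", rvec, rvec)
    off = ~np.eye(N, dtype=bool)
    if np.any(r2[:, off] < 1e-24):
        raise FactorizationError("coincident hydrodynamic spheres")
    r = np.sqrt(np.where(r2 < 1e-24, 1.0, r2))

    a_i = radii[:, None]
    a_k = radii[None, :]
    mu = np.sqrt(d_self[:, None] * a_i * d_self[None, :] * a_k)
    asum = a_i + a_k
    asum2 = a_i ** 2 + a_k ** 2
    adiff = np.abs(a_i - a_k)

    far = r >= asum[None]
    pref = 0.75 * mu[None] / r
    inv_r2 = 1.0 / (r * r)
    c_iso_far = pref * (1.0 + asum2[None] * inv_r2 / 3.0)
    c_par_far = pref * (1.0 - asum2[None] * inv_r2)

    # overlap regularisation (generalised RPY; classical form for a_i = a_k)
    r_eff = np.maximum(r, adiff[None] + 1e-30)
    dd = (adiff ** 2)[None]
    scale = (mu / (a_i * a_k))[None] / (32.0 * r_eff ** 3)
    c_iso_ovl = scale * (16.0 * r_eff ** 3 * asum[None]
                         - (dd + 3.0 * r_eff ** 2) ** 2)
    c_par_ovl = scale * 3.0 * (dd - r_eff ** 2) ** 2

    c_iso = np.where(far, c_iso_far, c_iso_ovl)
    c_par = np.where(far, c_par_far, c_par_ovl)
    c_par = c_par * inv_r2     # fold the 1/r^2 of the projector in

    blocks = (c_par[..., None, None] * rvec[..., :, None]) * rvec[..., None, :]
    for d in range(3):
        blocks[..., d, d] += c_iso
    diag = np.arange(N)
    blocks[:, diag, diag] = 0.0
    for d in range(3):
        blocks[:, diag, diag, d, d] = d_self
    return blocks


def build_rpy_tensor(pos: np.ndarray, radii: np.ndarray, d_self: np.ndarray,
                     box=None) -> np.ndarray:
    """Assemble the 3N x 3N RPY tensor, batched over leading replicas.

    ``pos`` has shape (M, N, 3) (or (N, 3), promoted).  Under periodic
    boundary modes the minimum-image pair separation is used; there is no
    Ewald summation, so periodic hydrodynamics is an O(1/L) approximation.
    """
    squeeze = np.asarray(pos).ndim == 2
    blocks = rpy_blocks(pos, radii, d_self, box)
    M, N = blocks.shape[:2]
    D = blocks.transpose(0, 1, 3, 2, 4).reshape(M, 3 * N, 3 * N)
    return D[0] if squeeze else D


class TEAOperator:
    """Precomputed TEA coupling matrices for one tensor snapshot.

    Splitting the (relatively expensive) coefficient determination from
    the cheap per-step matrix-vector products lets the caller reuse one
    snapshot over a few steps when the configuration changes slowly.
    """

    def __init__(self, blocks: np.ndarray):
        M, N = blocks.shape[:2]
        self.M, self.N = M, N
        n3 = 3 * N
        diag_idx = np.arange(N)
        d_part = blocks[:, diag_idx, diag_idx, 0, 0]          # (M, N)

        if N > 1:
            tr = (blocks[..., 0, 0] + blocks[..., 1, 1]
                  + blocks[..., 2, 2]) / 3.0
            tr = tr / d_part[:, :, None]
            off = ~np.eye(N, dtype=bool)
            eps = np.clip(tr[:, off].reshape(M, -1).mean(axis=1), 0.0, 0.9999)
        else:
            eps = np.zeros(M)
        A = eps * ((N - 2) - (N - 1) * eps)
        disc = 1.0 + A
        if np.any(disc < 0.0):
            warnings.warn("TEA beta quadratic has no real root; falling back "
                          "to beta = 1", RuntimeWarning)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(np.abs(A) > 1e-12,
                            (np.sqrt(np.maximum(disc, 0.0)) - 1.0) / A, 0.5)
        self.beta = np.where(disc < 0.0, 1.0, beta)
        self.eps = eps

        # flatten to 3N x 3N and use BLAS products from here on
        Dm = np.ascontiguousarray(
            blocks.transpose(0, 1, 3, 2, 4)).reshape(M, n3, n3)
        diag = np.repeat(d_part, 3, axis=1)                   # (M, 3N)
        dnorm = Dm * (1.0 / diag)[:, :, None]
        bd = self.beta[:, None, None] * dnorm
        sb = _self_block_mask(N)
        bd[:, sb] = dnorm[:, sb]
        var = np.matmul(bd * bd, diag[:, :, None])[..., 0]
        self.C = np.sqrt(diag / var)
        self.dnorm = dnorm
        self.bd = bd

    def apply(self, forces: np.ndarray, raw: np.ndarray):
        """Effective forces and correlated randoms, both (M, N, 3)."""
        M, N = self.M, self.N
        n3 = 3 * N
        f_eff = np.matmul(self.dnorm, forces.reshape(M, n3, 1))[..., 0]
        r_corr = self.C * np.matmul(self.bd, raw.reshape(M, n3, 1))[..., 0]
        return f_eff.reshape(M, N, 3), r_corr.reshape(M, N, 3)


def tea_apply(blocks: np.ndarray, forces: np.ndarray, raw: np.ndarray):
    """One-shot TEA evaluation on the block tensor.

    ``forces`` and ``raw`` have shape (M, N, 3); returns the effective
    forces and the correlated random displacements.  Equivalent to
    ``tea_effective_forces`` + ``tea_correlate`` on the flattened tensor.
    """
    return TEAOperator(blocks).apply(forces, raw)


@dataclass
class TEACoefficients:
    """Coupling coefficients of the truncated expansion, recomputed
    whenever the tensor changes.

    ``eps``: mean normalised off-diagonal coupling; ``beta``: uniform
    off-diagonal weight (beta_ii = 1); ``C``: per-coordinate normalisation
    preserving the self covariance.  ``dnorm`` is the row-normalised
    tensor D_ik / D_ii and ``bd`` the beta-weighted version used for the
    correlated randoms.
    """

    eps: np.ndarray       # (M,)
    beta: np.ndarray      # (M,)
    C: np.ndarray         # (M, 3N)
    dnorm: np.ndarray     # (M, 3N, 3N)
    bd: np.ndarray        # (M, 3N, 3N)


_SELF_BLOCK_CACHE: dict[int, np.ndarray] = {}


def _self_block_mask(n_particles: int) -> np.ndarray:
    m = _SELF_BLOCK_CACHE.get(n_particles)
    if m is None:
        m = np.kron(np.eye(n_particles, dtype=bool), np.ones((3, 3), dtype=bool))
        _SELF_BLOCK_CACHE[n_particles] = m
    return m


def _promote(D):
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        return D[None], True
    return D, False


def tea_coefficients(D: np.ndarray) -> TEACoefficients:
    """Determine (eps, beta, C_i) for a (batch of) diffusion tensor(s).

    beta solves the mean-field covariance condition
    ``beta^2 eps [(N-2) - (N-1) eps] + 2 beta - 1 = 0`` and the root
    continuous with beta -> 1/2 in the uncoupled limit is taken.  If the
    quadratic has no real root, beta falls back to 1 with a warning.
    """
    D, squeeze = _promote(D)
    M, n3 = D.shape[:2]
    N = n3 // 3
    diag = np.einsum("mii->mi", D)
    dnorm = D / diag[:, :, None]

    if N > 1:
        blocks = D.reshape(M, N, 3, N, 3)
        tr = np.einsum("mhaka->mhk", blocks)          # (M, N, N) block traces
        d_part = diag[:, ::3]
        norm_tr = tr / (3.0 * d_part[:, :, None])
        off = ~np.eye(N, dtype=bool)
        eps = norm_tr[:, off].reshape(M, -1).mean(axis=1)
    else:
        eps = np.zeros(M)
    eps = np.clip(eps, 0.0, 0.9999)

    A = eps * ((N - 2) - (N - 1) * eps)
    beta = np.full(M, 0.5)
    ok = np.abs(A) > 1e-12
    disc = 1.0 + A
    bad = disc < 0.0
    if np.any(bad):
        warnings.warn("TEA beta quadratic has no real root; falling back to "
                      "beta = 1", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(ok, (np.sqrt(np.maximum(disc, 0.0)) - 1.0) / A, beta)
    beta = np.where(bad, 1.0, beta)

    # beta matrix: 1 on the 3x3 self blocks, beta elsewhere
    self_block = _self_block_mask(N)
    bd = beta[:, None, None] * dnorm
    bd[:, self_block] = dnorm[:, self_block]
    # per-coordinate normalisation: sum_k (B d)_ik^2 D_kk / D_ii = 1 / C_i^2
    C = 1.0 / np.sqrt(np.einsum("mik,mik,mk->mi", bd, bd, diag) / diag)
    coeffs = TEACoefficients(eps=eps, beta=beta, C=C, dnorm=dnorm, bd=bd)
    if squeeze:
        coeffs = TEACoefficients(eps[0], beta[0], C[0], dnorm[0], bd[0])
    return coeffs


def tea_effective_forces(D: np.ndarray, F: np.ndarray,
                         coeffs: TEACoefficients | None = None) -> np.ndarray:
    """Hydrodynamically corrected deterministic forces
    ``F_i^eff = sum_k (D_ik / D_ii) F_k`` (flattened 3N vectors)."""
    D, squeeze = _promote(D)
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[None]
    dnorm = coeffs.dnorm if coeffs is not None else D / np.einsum("mii->mi", D)[:, :, None]
    if dnorm.ndim == 2:
        dnorm = dnorm[None]
    out = np.einsum("mik,mk->mi", dnorm, F)
    return out[0] if squeeze else out


def tea_correlate(coeffs: TEACoefficients, raw: np.ndarray) -> np.ndarray:
    """Correlate raw Gaussian displacements (variance 2 D_ii dt per
    coordinate) into TEA-HI displacements ``C_i sum_k beta_ik d_ik r_k``."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        return coeffs.C * (coeffs.bd @ raw)
    return coeffs.C * np.einsum("mik,mk->mi", coeffs.bd, raw)


def tea_covariance(D: np.ndarray) -> np.ndarray:
    """Analytic covariance of the TEA displacements, in the units of the
    tensor (i.e. per 2 dt).  Equals ``C M diag(D_kk) M^T C`` with
    ``M = beta_ik D_ik / D_ii``; the diagonal reproduces D_ii exactly."""
    D, squeeze = _promote(D)
    coeffs = tea_coefficients(D)
    diag = np.einsum("mii->mi", D)
    CM = coeffs.C[:, :, None] * coeffs.bd
    cov = np.einsum("mik,mk,mjk->mij", CM, diag, CM)
    return cov[0] if squeeze else cov


def cholesky_oracle(D: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Exactly correlated displacements via Cholesky factorisation
    (Ermak-McCammon).  ``raw`` is standard normal per coordinate; the
    output covariance equals the tensor exactly.  Reference implementation
    for accuracy tests; O(N^3)."""
    D = np.asarray(D, dtype=float)
    try:
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError as exc:
        raise FactorizationError(str(exc)) from exc
    return L @ np.asarray(raw, dtype=float)


# ---------------------------------------------------------------------------
# accuracy diagnostics


def dimer_max_error(radius: float = 1.0, d_self: float = 1.0,
                    separation: float | None = None) -> float:
    """Maximum elementwise deviation (normalised by the self term) of the
    TEA covariance from the exact tensor for a dimer of equal spheres;
    default separation is contact (2a), the worst case."""
    r = 2.0 * radius if separation is None else separation
    pos = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    D = build_rpy_tensor(pos, np.full(2, radius), np.full(2, d_self))
    cov = tea_covariance(D)
    return float(np.abs(cov - D).max() / d_self)


def random_sphere_configuration(n: int, radius: float, volume_fraction: float,
                                rng) -> np.ndarray:
    """Random non-overlapping spheres in a cube at the given volume
    fraction (rejection sampling)."""
    L = (4.0 / 3.0 * np.pi * radius ** 3 * n / volume_fraction) ** (1.0 / 3.0)
    pos: list[np.ndarray] = []
    while len(pos) < n:
        p = rng.uniform(0.0, L, 3)
        if all(np.linalg.norm(p - q) >= 2.0 * radius for q in pos):
            pos.append(p)
    return np.asarray(pos)


def correlation_recovery(n: int, volume_fraction: float, rng,
                         radius: float = 1.0) -> float:
    """Fraction of the exact pairwise displacement correlations recovered
    by the TEA on one random configuration.

    For every pair the displacement cross-covariance is projected on the
    line of centres (where the hydrodynamic correlation is strongest) and
    the TEA/exact ratio is averaged over pairs.
    """
    pos = random_sphere_configuration(n, radius, volume_fraction, rng)
    D = build_rpy_tensor(pos, np.full(n, radius), np.ones(n))
    cov = tea_covariance(D)
    Tc = cov.reshape(n, 3, n, 3)
    Td = D.reshape(n, 3, n, 3)
    ratios = []
    for i in range(n):
        for k in range(i + 1, n):
            rhat = pos[k] - pos[i]
            rhat = rhat / np.linalg.norm(rhat)
            exact = rhat @ Td[i, :, k, :] @ rhat
            ratios.append((rhat @ Tc[i, :, k, :] @ rhat) / exact)
    return float(np.mean(ratios))
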