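# Methods

## Model

`mesobd` propagates coarse-grained particles in an implicit solvent.
A *protein* is a template of one or more rigid units (*gestalten*) that
move independently; each gestalt carries

- a geometry record: translational diffusion coefficient `D_tr`
  (nm²/ps), rotational diffusion coefficient `D_rot` (ps⁻¹), and an
  optional mass (kDa).  A defined mass selects the finitely damped
  Langevin scheme, otherwise the overdamped Brownian scheme is used;
  both can coexist in one simulation;
- van-der-Waals spheres with an integer *colour*.  Each unordered colour
  pair maps to a Lennard-Jones-type potential in the surface-surface
  distance `r12 = |r| − a_i − a_k`:
  `U = ε[(σ/r12)¹² − 2(σ/r12)⁶]` for attractive pairs (minimum −ε at
  `r12 = σ`), the `(σ/r12)¹²` branch alone for repulsive-only pairs.
  The cutoff defaults to `3σ` (unshifted; the residual step is ≤
  3·10⁻³ ε).  Below a linearization threshold
  `r_lin = min(0.2·min(a_i,a_k), 0.8σ)` the force is held constant and
  the energy continued linearly, so transient overlaps (insertions,
  hard collisions) stay finite;
- point charges with a burial depth `b` interacting through a screened
  Coulomb potential `U = C_e q_i q_k exp(−κ(r − B))/(ε_r r)` with
  `B = b_i + b_k`: the stretch of the separation buried inside the
  low-dielectric particles sees no counter ions.  The interaction is cut
  off at `r = B + 5/κ` (< 1% of its contact value);
- at most one hydrodynamic sphere at the gestalt origin;
- harmonic position restraints and constant external forces.

Bonds connect gestalten of one protein with
`U = k₂/2 (d−L₀)² + k₄/4 (d−L₀)⁴` in the hook-hook distance; hooks may
be eccentric, in which case the bond force also exerts the torque
`offset × force` about the gestalt origin.  A bond compressed to exactly
zero extension has an undefined direction; the force is applied along +x
by convention.

Fixed structures (walls, obstacle arrays) are gestalten that never move;
fixed-fixed pair interactions are never evaluated, so the pair count per
step is `N_p(N_p−1)/2 + N_p·N_o`.

### Units and thermal energy

Lengths in nm, times in ps, masses in kDa, charges in e.  Energies are
kept in units of kT and forces in kT/nm, so the overdamped displacement
is simply `Δx = D F Δt`.  The thermal energy enters only where absolute
energies matter (Coulomb prefactor, friction `γ = kT/D`, velocity
relaxation `τ_rel = m D/kT`); its default is
`kT = 2.4361·10⁻³ kDa nm²/ps²` (k_B·293 K in this unit system), chosen
because it reproduces the reference velocity-relaxation times
(20 kDa, D = 1.2·10⁻⁴ nm²/ps → τ_rel = 0.985 ≈ 0.99 ps).

## Propagation

Brownian step: `Δx = D F Δt + R` with independent Gaussian `R`,
`⟨R²⟩ = 2DΔt` per coordinate.  Langevin step (constant force over the
step, velocity integrated analytically):

    v(Δt) = v₀ e^(−Δt/τ) + (F/γ)(1 − e^(−Δt/τ))
    Δx    = (F/γ)Δt + τ(v₀ − F/γ)(1 − e^(−Δt/τ))

The random displacement is converted to an effective force
`f = γR/Δt`, which makes the Langevin scheme reduce exactly to the
Brownian one for `Δt ≫ τ`.  At `Δt ≲ τ` the scheme reproduces the
inertial free-particle MSD `6D[t − τ(1−e^(−t/τ))]` to a few percent
(its per-step velocity kick variance carries the factor
`(2τ/Δt)tanh(Δt/2τ) → 1`).  No divergence-term corrections for
position-dependent mobility are applied.

Rotation uses small Gaussian rotation vectors (variance `2 D_rot Δt`
per axis) plus the deterministic response `D_rot T Δt`, composed onto a
unit quaternion that is renormalised after every update; validity
requires `D_rot·Δt ≪ 1`, which all shipped setups satisfy by 3+ orders
of magnitude.  There is no rotational hydrodynamic coupling; rotational
response exists only through `D_rot`.

One counter-based RNG stream per simulation, drawn in a fixed order
(translations, rotations, interface events), makes trajectories
bit-reproducible under a fixed seed on one platform.

## Hydrodynamics

Translational Rotne-Prager-Yamakawa pair mobilities, with the classical
regularised form for overlapping equal spheres and the generalised
closed form for overlapping unequal spheres (reducing to the classical
one for `a_i = a_k`).  The self-mobility scale of a mixed pair is
`kT/6πη := sqrt(D_i a_i D_k a_k)`.  Under periodic boundaries the
minimum-image separation is used (no Ewald summation — an O(1/L)
approximation).  Particles without a hydrodynamic sphere, including all
fixed structures, are hydrodynamically invisible.

The exact Ermak-McCammon correlation of the random displacements with
the tensor square root (O(N³) Cholesky) is kept as a reference oracle.
Production steps use the truncated expansion approximation (TEA):

    R_i = C_i Σ_k β_ik (D_ik/D_ii) r_k,   β_ii = 1, β_ik = β (i≠k)

- `ε` = average of the normalised pair-block traces
  `tr(D_ik)/(3 D_ii)` over ordered particle pairs, clipped to [0, 1);
- `β` solves the mean-field covariance condition
  `β²ε[(N−2) − (N−1)ε] + 2β − 1 = 0`; the root continuous with the
  uncoupled limit `β → 1/2` is taken (for N = 2 this reduces to
  `β = (1−√(1−ε²))/ε²`); if the discriminant is negative, `β = 1` with
  a warning;
- `C_i` normalise each coordinate exactly so that the self covariance
  `2 D_ii Δt` is preserved ("temperature conservation").

Deterministic forces are corrected as `F_i^eff = Σ_k (D_ik/D_ii) F_k`.
With the Langevin scheme the correlations are applied to the average
forces that would produce the same displacements in the Brownian
picture, i.e. to `F + γR/Δt`.

Measured accuracy of this formulation (reproduced by the test suite and
the `hi-report` command): maximum elementwise covariance error 2.27% of
the self term for a touching equal dimer, and 94–95% mean recovery of
the exact pairwise displacement correlation projected on the line of
centres for random configurations of 10–50 spheres at volume fraction
0.1.

The engine materialises the pairwise block tensor per snapshot (O(N²)
memory, a few MB at the shipped sizes) and turns the TEA sums into BLAS
matrix products; `tensor_stride` optionally reuses one snapshot over a
few steps, a documented approximation that is safe when per-step
displacements are small against the pair separations (the elastic
multi-bead runs use stride 5: beads move ~0.07 nm per step against 5 nm
separations).

## Boundaries and open systems

Per-axis modes: periodic (minimum image plus image-count tracking for
unwrapped analysis), reflecting (specular, with velocity flip for
Langevin particles), open (`interface`), or none.  A constant-density
interface bounds one face of an open axis for one single-gestalt
species: crossers are removed and counted; insertions are drawn
Poisson with the one-sided reservoir crossing flux
`ν = ρ A sqrt(DΔt/π)` per step.  The penetration depth of an inserted
particle is sampled exactly from the one-step crossing statistics of a
uniform half-space: the step length of a crossing particle is
Rayleigh(`sqrt(2DΔt)`) distributed and the crossing point uniform along
the step, so depth = Rayleigh × Uniform(0,1) (validated against a
brute-force half-space simulation).  Insertions overlapping a fixed
structure beyond the linearization threshold are redrawn (bounded
retries).  Faces of open axes not covered by an interface reflect all
species.  With these rules a box fed by one interface equilibrates to
the reservoir density within sampling error, which is the scheme's
defining contract.

## Analysis

- MSD: time average over overlapping windows plus ensemble average over
  replicas and equivalent particles; apparent `D(Δt) = MSD/6Δt`.
  Long-time D from a straight-line fit over a lag window (default: the
  last decade of lags).  Without hydrodynamics the centre of mass of a
  bonded cluster is exactly diffusive at every lag (internal forces
  cancel pairwise, bead noises are independent), so the polymer
  experiments fit short lags there, where the estimator is tightest.
- Rotational relaxation: single-exponential fit of the orientation
  autocorrelation from lag 0 to its first crossing of e⁻² (or of e⁻¹
  when the trajectory is too short to resolve e⁻², never more than 3×
  the e⁻¹ crossing) — long-lag autocorrelation estimates plateau at a
  noise floor that must not enter the fit.  A correlation that never
  reaches e⁻¹ is flagged unreliable.
- Scaling exponents: least-squares slope in log-log.
- Transport: straight-line fit of the cumulative absorbed-particle
  count, burn-in = frames before the first absorption; the slope is the
  exit rate `R_D`, the x-intercept the transit time `T_D`.
- Interaction networks: one node per patch sphere, link iff the
  centre-to-centre distance is strictly below the cutoff (minimum image
  under periodic boundaries); cluster measures (`⟨k⟩`, `max k`,
  `#CC(N>1)`, `⟨N⟩(N>1)`, size multiset) via standard graph components.

## Example-study conditions (and what the desk-scale runs show)

The drivers in `mesobd.examples` pin the reference study conditions:

1. **Polymers**: beads with radius and `D_bead` = 1 (reduced units),
   nearest-neighbour springs `k_N = 1000`, length 2.5; next-neighbour
   springs length 5 with `k_2N ∈ [0.1, 1000]`; `Δt = 5·10⁻⁴`; bead
   repulsion `ε = 1 kT`, `σ = 0.25` (short enough not to perturb the
   spring minima).  N ∈ {3, 5, 10, 15}.
2. **Elastic multi-bead particles**: 2 nm beads, `D_bead =
   1.2·10⁻⁴ nm²/ps`, hexagonal lattice spacing 5 nm, springs to all
   nearest neighbours.  The spring constant is a free choice here; 10 kT/nm²
   is used (bond-length fluctuations ~0.3 nm, a stiff but clearly
   sub-rigid particle; the long-time transport coefficients are
   insensitive to this choice well above ~1 kT/nm²).  `Δt = 20 ps`
   (spring relaxation ≈ 400 ps).  N ∈ {4, 13, 39, 57}; the lattice
   cluster is the most compact N-site selection (candidate centres:
   every site and every mutually-adjacent triple centroid, which covers
   the tetrahedral voids; ties broken by site index) — this yields the
   tetrahedron at N = 4 and the centred 12-neighbour shell at N = 13.
3. **Transport**: box 30×20×20 nm, x open with reservoirs at
   `ρ₀ = 4·10⁻⁴ nm⁻³` and 0, y/z periodic; mobile spheres a = 2 nm,
   `D = 10⁻⁴ nm²/ps`, repulsive `ε = 1 kT`, `σ = 0.5`; `Δt = 10 ps`;
   started empty.  Obstacles: 3×3 grid per layer over the cross
   section.  Note the reference geometry is internally
   inconsistent: with a 20×20 nm cross section the deepest pore point of
   the grid lies 4.71 nm from the nearest obstacle centre, so 5 nm
   obstacles already seal the plane, while the reference impermeability
   threshold (7.4 nm) and analytic rate (1.1·10⁻⁶ ps⁻¹) both match a
   40×40 nm cross section exactly.  This package keeps the 20×20
   geometry for the control rate and runs the attractive-vs-repulsive
   comparison on a permeable scaled-down array (2×2 grid of 3 nm
   obstacles; attraction `ε = 2 kT`, `σ = 0.5`) — with the 20×20 cross
   section even point obstacles on a 3×3 grid exclude most of the plane
   for 2 nm particles.  The steady-state control rate of the 20×20
   geometry is `D ρ₀ A/L_x = 5.3·10⁻⁷ ps⁻¹`; the measured value agrees
   with that, not with the reference 1.2·10⁻⁶ ps⁻¹, and is reported
   as computed.
4. **Agglomeration**: 27 patchy particles (two 1.7 nm spheres displaced
   ±0.5 nm; patch-patch attraction 0.9 kT — "slightly below thermal" so
   complexes form transiently — `σ = 0.3`, cutoff 1.5 nm; all other
   colour combinations repulsive) in a 30 nm periodic cube; Langevin
   propagation with m = 18 kDa, `D_tr = 1.2·10⁻⁴`,
   `D_rot = 2.26·10⁻⁵ ps⁻¹`, `Δt = 10 ps`; network criterion 4 nm.

Default run lengths are desk scale: tens of thousands to ~10⁶ steps
and 8–64 replicas per condition instead of the original 10⁷-step
single-trajectory runs.  Statistical errors are taken from the scatter
of independent seeds or replica subgroups.  At these lengths the
scaling exponents carry standard errors of ~0.03, transport rates
~15–20%, and relaxation times ~5%; the tests assert bands sized for
those errors.  What desk-scale passing shows: the propagators,
hydrodynamic coupling, boundary bookkeeping and estimators are correct
and reproduce the qualitative and most quantitative anchors.  What it
does not show: long-time tails, rare-event statistics, or behaviour of
systems far larger than ~60 coupled spheres.

The synthetic systems are idealised: perfectly spherical interaction
sites, no electrostatics in the shipped examples, no solvent structure,
far-field hydrodynamics without lubrication, and obstacle walls
invisible to the hydrodynamic coupling.  Conclusions about real protein
solutions require mapping these idealisations onto the system at hand.

## Numerical choices and degenerate inputs

- Linearized vdW core (force constant, energy linear) instead of the
  diverging branch below `r_lin`; insertion overlap uses the same
  threshold.
- Bond at exactly zero extension: force along +x (documented
  tie-break).
- TEA quadratic without a real root: `β = 1` plus a warning.
- Non-finite coordinate: the step aborts with the step index and
  gestalt id.
- Timestep guards: `validate_bd_timestep` warns when an overdamped
  species is stepped below ten velocity-relaxation times of its
  physical mass.
- Overlapping hydrodynamic spheres are regularised; exactly coincident
  centres raise.

## Known limitations

- No rotational or rotation-translation hydrodynamic blocks, no
  lubrication corrections, no Ewald hydrodynamics.
- Constant-density interfaces support single-gestalt species only.
- The engine targets ≲10² coupled spheres per replica; it vectorises
  over replicas rather than scaling to large N.
- Electrostatics is plain screened Coulomb (no reaction field/Ewald);
  energies under periodicity use minimum image only.
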