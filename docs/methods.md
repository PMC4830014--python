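# Methods

This note documents the models, numerical choices and known limitations of
`tiltsplay`.  Everything quantitative here is computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The estimator chain

The tilt modulus κ_t and bending rigidity K_c of a lipid assembly are read
off the equilibrium distributions of two microscopic observables:

* **Tilt** θ of a lipid: the angle between its director (unit vector from
  the center of mass of the tail selection to that of the headgroup
  selection) and the unit normal of the time-averaged water–lipid interface
  at the point nearest the headgroup.  Under a harmonic tilt energy the
  density is P(θ) ∝ sin θ · exp(−κ_t θ²/2k_BT); the sin θ factor is the
  solid-angle Jacobian, removed when forming the PMF
  −k_BT ln(P/sin θ) = a + b θ², κ_t = 2b.

* **Splay** S of a pair of nearby lipids: the finite-difference directional
  derivative S = [(n₂−n₁)·e + (N₂−N₁)·e]/h, where e is the unit step from
  lipid 1 to lipid 2 orthogonalized against N₁ and h the tangential step
  length.  Weakly correlated splays are Gaussian,
  P(S) ∝ exp(−K_c A_L S²/2k_BT), so −k_BT ln P = a + b S² with
  A_L K_c = 2b.

Fitting protocol (identical for both observables): histogram the samples
(defaults: 90 one-degree bins on [0°, 90°] for tilts; 100 bins spanning the
sample range for splays); least-squares fit a Gaussian to the distribution
to locate its mean μ and width σ (fallback to sample moments on
non-convergence); form the PMF on non-empty bins, shifted so its minimum is
zero; fit a + b·x² by unweighted least squares over the five windows
[μ−cσ, μ+cσ], c ∈ {1, 1.25, 1.5, 1.75, 2}.  The reported modulus uses
c = 1; the uncertainty is the population standard deviation of the ≤ 5
moduli.  Windows with fewer than 3 PMF points are skipped with a warning.
A centered variant a + b(x−μ)² is available (`centered=True`) for systems
with nonzero spontaneous splay; the default fits the uncentered form, which
is the form the harmonic model implies at the neutral plane.

Temperature enters only through the k_BT energy unit.  Since tilt angles
and splays are dimensionless/inverse-length samples, the moduli in k_BT are
temperature-independent; the `temperature` arguments exist for unit
conversion in summaries.

Mixtures: per-species tilt moduli and per-pair splay moduli are combined by
count-weighted harmonic means (weights: number of lipids per species for
tilts, number of sampled splays per species pair for splays).  A single
shared A_L (in-plane cell area / lipids per leaflet) is used for all
species; per-species areas would require reweighting the pair contributions
and are out of scope.  Asymmetric membranes are handled by partitioning the
system (per-leaflet residue masks or selections) and running the analysis
once per part.

The splay combines the director and normal differences with a **plus**
sign, matching the finite-difference definition used throughout; for flat
interfaces the normal term vanishes and the sign is immaterial.  A
`normal_term_sign` switch exposes the minus variant (the derivative of
n − N) for curved systems; we deliberately do not guess which convention a
given downstream comparison expects.

### Choices the data do not fix

* **h is the tangential distance**, not the full 3-D separation: the
  finite-difference step e is perpendicular to N₁, so the step length must
  be measured in the tangent plane.  The *pair cutoff* (default 10 Å, about
  one lipid diameter, beyond which splay correlations have decayed) is
  applied to the 3-D distance between the per-species "distance" sites —
  which conveniently keeps the two leaflets of a bilayer from pairing.
* **Tilt folding**: θ = arccos(|n·N|) ∈ [0, π/2].  With solvent-oriented
  normals, lower-leaflet directors anti-align with the normal field;
  folding makes the estimator leaflet-agnostic without flags.
* **Pair flag rule**: a pair contributes when *at least one* member carries
  `do_splay`.  Requiring both would silently drop the pairs between
  central-cell lipids and their periodic replicas, defeating the purpose of
  the cell extension.
* **PMF fits are unweighted** over bins; count-weighting changes the c = 1
  modulus by less than its quoted uncertainty in all synthetic checks and
  is not offered.
* The Gaussian for (μ, σ) is fitted to the raw tilt histogram including the
  sin θ region near zero, not to the Jacobian-corrected density.

## Alignment and interface

For assemblies without a flat reference plane, frames are aligned
rigid-body onto the solvent density of frame 0.  The density of a point set
is a sum of mass-weighted isotropic Gaussians, σ = resolution/2 (default
resolution 4 Å), amplitude (2πσ²)^{−3/2}·m so each atom integrates to its
mass, truncated at 3σ per axis, accumulated on a regular grid (1 Å voxels
by default).  The reference map is low-pass filtered with a Gaussian blur
(default width 4 Å) and each frame maximizes

    Σ_waters ρ(T x) − Σ_lipids ρ(T x)

over rigid transforms T, parameterized by intrinsic z-y-x Euler angles plus
a translation.  The optimizer is Nelder-Mead, warm-started from the
previous frame's transform (MD frames are temporally correlated), with an
initial simplex of 0.02 rad / 0.5 Å steps and a two-stage polish; it is
deterministic, and non-convergence returns the best-found transform with a
warning flag.  Map values at atom positions are trilinear interpolations
(zero outside the grid).  On a 1 Å mesh the trilinear facets limit
self-alignment accuracy to roughly 0.1°; a 0.5 Å mesh reduces this
fourfold where it matters.

The interface is the surface where the time-averaged solvent and lipid
densities are equal: vertices are placed by linear interpolation of
(ρ_W − ρ_L) along the edges of the density mesh (a marching-cubes vertex
set; the triangulation is discarded — downstream stages need only points
and normals).  Grid cells where both densities stay below 1 % of the global
density maximum are masked out, so no spurious surface appears in vacuum.
Per-point normals are the smallest-eigenvalue eigenvectors of the
covariance of all surface points within 10 Å (points with < 3 neighbors are
dropped with a warning), oriented toward increasing ρ_W − ρ_L, i.e. toward
the solvent.  Nearest-surface-point queries are exact (a k-d tree
accelerates them; exact ties resolve to the lowest index).

Periodic boundaries: rather than littering the analysis with minimum-image
logic (awkward for triclinic cells, and impossible to store in DCD after a
rotation), the trajectory is extended to the neighboring unit cells of
interest first — replicas get suffixed chain names (M → M1, M2, …) and
cleared flags — and the central-cell lipids are flagged.  The interface and
normal field are then artifact-free over the central cell, which is also
how the planar geometry check below is evaluated.

## The synthetic generators

The generators produce self-contained systems with *known* ground truth;
they define the conditions under which the estimators are validated.

**Direct samplers.**  `sample_tilt_angles` rejection-samples the tilt
density exactly (proposal sin θ by inverse CDF, acceptance
exp(−κθ²/2)); `sample_splays` draws Gaussians with variance 1/(K_c·A_L).
Both are pure functions of (parameters, seed), PRNG: numpy PCG64.

**Planar pseudo-bilayer.**  Two leaflets of three-site lipids
(HD/MD/TL, 72 amu beads; species "LIP") on jittered rectangular lattices at
exactly the requested A_L (defaults: 200 lipids/leaflet, A_L = 60 Å², the
textbook DPPC area), plus jittered water slabs (OW, 18 amu, "SOL") starting
2 Å above the head plane.  The MD anchor of each lipid is frozen, so the
pair geometry (and hence h) is constant; HD/TL sit ±6 Å along the director.
The nominal interface plane — midway between the head plane and the water
face — is recorded as ground truth.

Directors: per frame and leaflet, a tangential Gaussian random field
t(x) with per-component variance v = 1/κ_t and spatial covariance
C(r) = v·exp(−r²/2ℓ²) is sampled (Cholesky of the frozen lattice
covariance); the magnitude |t| is pushed through a quantile map so the
polar angle has **exactly** the target tilt distribution at κ_t, and the
azimuth is the field direction.  A smooth field is essential: independent
per-lipid angles would add 2·Var(t)/h² to every pair's splay variance and
destroy the splay statistics entirely.  The correlation length is set to
ℓ = √(v·K_c·A_L) (7.1 Å at the defaults — below the 10 Å pair cutoff), the
value for which the small-h limit of the field's variogram reproduces the
nominal K_c.  At finite neighbor distances and through the mildly nonlinear
quantile map the *effective* splay stiffness differs from nominal (the
defaults give ≈ 15.5 k_BT for nominal 10), so the generator computes the
exact pooled splay variance of its own construction — a Monte Carlo over
the frozen pair list using the known bivariate field law, independent of
the analysis code — and records K_c_calibrated = 1/(A_L·Var S).  The tilt
truth is the nominal κ_t (exact by construction).

**Cylindrical (inverted-hexagonal-like) system.**  A water channel along z
(jittered lattice inside r < R−1) surrounded by rings of radially oriented
lipids (heads at R+3.5, tails at R+10.5, directors pointing inward, toward
the solvent).  Frames 1… are exact rigid copies of frame 0 under known
random rotations (±8° per Euler angle) and translations (±3 Å), recorded in
the ground truth.  Two construction details exist purely to make the
recovery problem well-posed: frozen positional jitter (a perfect lattice
has lattice-translation ambiguities), and a dense off-axis water column
spanning three quarters of the tube length, deep inside the channel
(r ≈ R/2), which breaks the tube's continuous azimuthal and axial symmetry
without touching the water/lipid interface at the wall.  The recorded
interface radius is the stated water-cylinder radius R.

What the generators do *not* emulate: temporal correlations (frames are
i.i.d.), realistic force-field energetics, protrusion/undulation modes,
area fluctuations, or solvent penetration.  Passing tests therefore
demonstrate the correctness of the *estimator chain* — alignment, interface
and normal construction, tilt/splay accounting, PMF fitting, mixture
combination — under the stated statistical models, not the convergence
behavior of any particular force field's trajectories.

## Validation conditions and observed behavior

Problem sizes are the package's own validation conditions:

* Sampler recovery: 2×10⁵ samples; κ_t ∈ {5, 10, 20} k_BT recovered within
  ~1 %, K_c = 10 k_BT (A_L = 60 Å²) within ~3 %.
* End-to-end planar pipeline: 200 lipids/leaflet × 500 frames
  (2×10⁵ tilt, ≈4×10⁵ splay samples); density averaging over every 25th
  frame (the interface is static by construction, so a stride is
  statistically sufficient); κ_t within a few percent of truth, K_c within
  a few percent of the calibrated truth.
* Geometry: a 64-lipid patch extended to its 8 in-plane neighbor cells,
  densities averaged over 30 frames; central-cell interface within 1.5 Å of
  the constructed plane.  Cylinder: interface radius within 1.5 Å of R over
  the axial interior (the open tube ends of the finite construction are
  excluded), normals within ~2° of radial on average.
* Alignment: 6-frame cylindrical trajectory; transforms recovered within
  ~0.2° / 0.05 Å (tolerances 0.5° / 0.2 Å).

The estimator's dominant error at large n is the fit-window statistics of
the c = 1 quadratic fit (a ~2 % floor at 2×10⁵ samples), not histogram
binning; the median recovery error still decreases from 10⁴ to 2×10⁵
samples (checked over fixed seed families).

## Degenerate inputs and numerical tie-breaks

* Coincident head/tail sites, empty selections for COM, zero-variance splay
  sets, non-invertible cells, all-empty histograms, and non-positive moduli
  or counts in the mixture formulas raise `ValueError`s.
* Pairs whose separation is parallel to the local normal (no tangential
  component) are skipped, as are fit windows with < 3 points and surface
  points with < 3 neighbors (each with a warning).
* Wrapping uses round-half-to-even on fractional offsets, making it exactly
  idempotent including points on the cell boundary.
* Empty selections in `select_atoms` return empty index lists (not errors);
  downstream stages that cannot proceed with empty input raise.

## Known limitations

* Alignment is a local search: frames must be within the basin of the
  reference orientation (true for temporally correlated MD; the synthetic
  transforms stay within ±8°).  No multi-start global alignment.
* The interface mesh resolution is the density grid (1 Å); sub-voxel
  features are smoothed away by the 4 Å Gaussian kernel.
* No curvature tensors, surface areas, pivotal-plane determination,
  spontaneous-curvature estimation, or splay spatial-correlation analysis.
* The selection dialect is deliberately minimal (chain/residue/atom name
  conjunctions); geometric predicates are served by mask helpers instead.
* Masses come from a small element table keyed by atom-name heuristics;
  coarse-grained beads need a user-supplied mass table.
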