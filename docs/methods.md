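# Methods

## Model

`fourierforce` implements a linear-in-features machine-learned interatomic
potential (MLIP) with a random Fourier feature (RFF) regression head.  The
energy of a configuration **R** with atoms n = 1..N is a sum of atomic
contributions,

    E(R; w) = sum_s mu_s N_s  +  sum_n w . phi(z_n(R)),

where `mu_s` are per-species baseline offsets, `z_n` is the standardized
invariant descriptor of atom n's environment, and `phi` is a frozen random
feature map.  Forces are the exact analytic negative gradient of E — the
model is a conservative force field by construction, which the test suite
verifies both by finite differences and by microcanonical (NVE) energy
conservation.

### Descriptors

The built-in descriptor is a two-body radial design in the Behler G2 family:
channel (s, q) of atom n sums `exp(-(r - mu_q)^2 / (2 eta^2)) * f_cut(r)`
over species-s neighbors within the cutoff, with a smooth cosine cutoff
`f_cut(r) = (cos(pi r / r_c) + 1) / 2`.  It is rigid-motion and permutation
invariant by construction and analytically differentiable.  Defaults:
`r_c = 5 A`, `Q = 8` centers uniform on `[0, r_c]`, `eta = r_c / Q`.  The
descriptor (and its Jacobian) is a pluggable boundary: any provider
returning per-atom features and position Jacobians — e.g. invariant node
features extracted from a frozen pre-trained graph network — can be
registered, and the invariant test battery applies to it unchanged.  The
backbone is frozen by contract; the only trained parameters are `w` and the
affine standardization statistics.

Descriptors are standardized per species (mean and population standard
deviation over training atoms of that species; near-constant channels get
unit scale to keep the affine map invertible).  Statistics come from the
training split only.

### Random features

`phi(z) = sqrt(2/D) * cos(W z + b)` with offsets `b ~ U[0, 2pi)` and
frequency rows `W` drawn orthogonally: stacked Haar-orthogonal blocks whose
rows are rescaled by chi-distributed norms, so each row is marginally
standard Gaussian while intra-block orthogonality lowers the kernel
estimator variance.  The dot product `phi(z)^T phi(z')` is an unbiased
estimator of the Gaussian kernel `exp(-||z - z'||^2 / (2 sigma^2))`; the
scale is absorbed into `W` (block rows divided by sigma).  Multiscale maps
concatenate equal-size blocks at scales `sigma_1..sigma_S` and estimate the
uniform kernel mixture.  Default scales: `{8, 16, 24, 32}`.

The `1/sqrt(D)` normalization is carried explicitly inside the map rather
than absorbed into `w`.  This makes kernel estimates directly testable and
leaves the model class unchanged; it does rescale what a given ridge
strength `lambda` means (see Numerical choices).

### Training

The weights minimize the convex combined loss

    l_alpha(w) = (1 - alpha) * sum_t (phibar_t . w - E_t)^2
               + alpha * sum_t || G_t w + vec(F_t) ||^2  + lambda ||w||^2,

with pooled features `phibar = sum_n phi(z_n)`, force design
`G[(m,k), r] = d phibar_r / d R_mk`, and baseline-subtracted energies.  The
unique global minimizer solves D x D normal equations assembled in one
streaming pass; the sufficient statistics (C_E, b_E, C_F, b_F) are additive
over dataset partitions, so hyperparameter search reuses a single
accumulation.  Defaults: `alpha` grid {0.01, 0.5, 0.99}, `lambda` grid
{1e-6 .. 1e-11}; selection minimizes validation force RMSE, ties toward
larger `lambda`.  Force residuals enter per Cartesian component — the only
reading under which the force loss is quadratic with the stated gradient —
and energy residuals are per configuration (a per-atom weighting variant is
out of scope by default).

## Synthetic data and the benchmark

The generator produces clusters (or small periodic boxes) labeled with
exact analytic Lennard-Jones or Morse energies and forces, shifted to zero
at the cutoff.  Atoms sit on a cubic lattice perturbed by isotropic
Gaussian jitter, with rejection sampling against a minimum pair distance;
everything is reproducible from a single seed.

The standard benchmark is argon: LJ epsilon = 10.4 meV, sigma = 3.4 A,
cutoff 5 A (matching the descriptor cutoff so the two-body model class can
represent the target nearly exactly), 8-atom clusters, jitter 0.4 A and
minimum distance 3.0 A.  The jitter is a Lindemann-scale fraction of the
3.82 A lattice spacing — melt-adjacent thermal disorder, emulating ab
initio MD sampling between the cold-crystal and melt regimes — and the
minimum distance approximates the thermally accessible closest approach;
harder walls would inject force outliers that no thermal ensemble samples
and that dominate small validation sets.  The benchmark's radial centers
span [2.5, 5] A, the sampled distance range: centers deep inside the
repulsive wall would be dead channels (constant columns) that only degrade
conditioning.

What the generator does *not* emulate: many-body interactions (the labels
are strictly pairwise), chemical diversity, label noise, and the
high-dimensional learned descriptors of a pre-trained backbone.  Passing
tests therefore demonstrate the correctness of the regression machinery and
its symmetry/conservativeness properties, not transferability to ab initio
data.

A consequence of the desk scale deserves note: with 64 training frames of 8
atoms there are ~1600 labeled scalars, and validation force error saturates
at its data-limited floor already around D = 128 features (the D = 2048
model crosses the interpolation threshold).  The capacity-limited regime in
which error decreases monotonically with D — as it does for data-rich
training sets — is not reachable at this problem size; the kernel
approximation itself is instead validated directly by the D^(-1/2)
convergence of `phi(z)^T phi(z')` to the closed-form kernel.

## MD-level validation

A minimal velocity-Verlet NVE integrator (Maxwell-Boltzmann initial
velocities at a given temperature, net momentum removed) probes
conservativeness at the integration level: total-energy drift of a trained
potential stays bounded and shrinks ~4x when the timestep halves
(second-order integrator).  Thermostatted dynamics are out of scope.
Radial distribution functions use minimum-image histograms normalized by
exact ideal-gas shell counts at the system's number density; the RDF error
metric is `sqrt(integral (g - g_ref)^2 dr)` by trapezoidal quadrature (the
L2 reading — a signed integral could cancel structure).

## Numerical choices

- Normal equations are solved by Cholesky factorization with one step of
  iterative refinement (recovers the last ~2 digits when `lambda` is many
  orders below the top eigenvalue) and a single 10x-`lambda` jittered retry
  before failing with advice to increase `lambda`.
- The `lambda` grid values apply literally to the normalized-feature normal
  equations.  Under an unnormalized `sqrt(2) cos` map the same printed
  values would be a factor D weaker; the two conventions differ only by a
  rescaling of `w` and `lambda`.
- The energy baseline is a least-squares fit of total energies on species
  counts, minimum-norm when compositions are collinear (e.g. a single
  species at fixed N).
- Periodic neighbor search enumerates explicit image shells covering the
  cutoff (correct for triclinic cells and cutoffs beyond half the box);
  neighbor pairs are directed/double-counted, which simplifies Jacobian
  assembly, and list symmetry is asserted in tests rather than assumed.
- Standardizer scale floor: population standard deviations below 1e-8 are
  replaced by 1, so degenerate channels pass through unscaled.
- Extended-XYZ floats are written in shortest round-trip representation, so
  read(write(x)) is bitwise exact.
- Model archives are versioned single `.npz` files; loading refuses unknown
  versions and predictions round-trip bitwise.

## Problem sizes

Tests and the acceptance script run entirely on generated data: benchmark
splits of 64/32 frames (8 atoms), feature counts up to 2048 for training
studies and up to 32768 for direct kernel-quality measurements, NVE runs of
2000-4000 steps at 0.25-0.5 fs, and a 27-atom periodic box for RDF
comparisons.  These sizes were chosen so the full pipeline — including the
5-seed median curves — completes in minutes on one CPU.

## Known limitations

- The built-in descriptor is two-body; angular structure is invisible to it
  and three-body reference potentials would not be recoverable.
- No stress/virial, no uncertainty quantification, no thermostats, no
  sparse solvers; D is limited by the dense D x D solve.
- The multiscale default `{8, 16, 24, 32}` is calibrated to the distance
  scale of high-dimensional backbone features; on the 8-channel built-in
  descriptor (standardized distances ~3) these scales all sit in the smooth
  regime, and the benchmark's best single scale is accordingly the largest.
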