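# Methods

`orientem` recovers the unknown orientations of single-particle diffraction
snapshots and assembles the three-dimensional diffraction volume. It
implements two Bayesian expectation–maximization algorithms on one shared
core — EMC, with a Poisson photon-count likelihood and a
compression–expansion contiguity constraint, and GTM, with a Gaussian
intensity likelihood and a regularized smooth basis-function map — together
with the Shannon-criterion sampling of the rotation group, a synthetic
snapshot simulator, and gauge-aware evaluation. This note records the model,
the numerical choices, and what the synthetic studies do and do not show.

## Model

A snapshot is a vector of p photon counts; the detector maps pixel (i, j)
to the scattering vector q = (ŝ − ẑ)/λ on the Ewald sphere. An object in
orientation x (a unit quaternion; q and −q are the same rotation) produces
the model snapshot y(x), the Ewald-sphere slice of the 3D intensity I(q)
rotated by x. The rotation group is discretized into K nodes x_k; each node
carries a model snapshot ("tomogram") Y_k, and a snapshot T_n with hidden
orientation is explained by the mixture

    p(T_n) = Σ_k p(x_k) p(T_n | Y_k),   p(x_k) = 1/K by default.

Both algorithms alternate a responsibility (E) step — the posterior
R_kn = p(x_k | T_n) via a per-snapshot softmax in the log domain — and a
model (M) step, and differ only in the noise model and in how the
*contiguity constraint* is imposed. The raw likelihood is exactly invariant
under permuting the K tomograms, so likelihood maximization alone cannot
order the nodes; each algorithm adds a mechanism that forces nearby
orientations to carry nearby tomograms:

* **EMC** (Poisson): log p(T|Y_k) = Σ_i (T_i ln Y_ki − Y_ki), M-step
  Y_k = Σ_n R_kn T_n / Σ_n R_kn. After each EM step the tomograms are
  *compressed* — scattered with trilinear weights into the L³ reciprocal
  lattice and locally averaged — and *expanded* — re-sliced from that
  volume. Slices through one common volume must agree along their
  intersection lines, which both smooths the map and globally orders it.
* **GTM** (Gaussian, precision β): tomograms are constrained to
  Y = Φ W, with Φ_km = exp(−angle(x_k, c_m)²/2σ_φ²) a Gaussian basis on M
  centers c_m on the grid, and a zero-centered Gaussian prior of strength α
  on the weights W. The M-step solves the penalized normal equations
  (ΦᵀGΦ + (α/β) I) W = Φᵀ R T, G = diag(Σ_n R_kn); β is re-estimated from
  the mean weighted residual (optionally held fixed). Smooth basis plus
  small weights is the contiguity constraint.

In the limit of a delta basis (M = K, Φ = I), α = 0, no
compression–expansion, a shared noise model and a shared start, the two
M-steps are algebraically the same responsibility-weighted average, so the
two algorithms coincide iteration by iteration; `orientem.equivalence`
demonstrates this numerically through the two separate code paths and also
shows the trajectories separate as soon as either constraint is switched on.

## Sampling the rotation group

Recovering structure at resolution r for an object of diameter D requires
orientational sampling at the Shannon angle Δθ = r/D: rotating by Δθ moves
a feature at radius D/2 by half a resolution element. Measured in
quaternion arc (half the rotation angle), the rotation group has volume π²
after the double-cover reduction and one Shannon element occupies (Δθ/2)³,
giving K = 8π²/(S·Δθ³) nodes for point symmetry order S (ceil-rounded:
the criterion is a minimum density). Grids are built by seeded random
initialization followed by pairwise repulsion relaxation on the
three-sphere (forces act between double-cover equivalence classes; 500
iterations; step ∝ K^(−1/3)), then folded to the w ≥ 0 hemisphere.
Relaxed grids have minimum spacing ≈ 0.85–0.95 of the ideal uniform value
and covering radius below Δθ. When a grid of prescribed size K is wanted,
its nominal Shannon angle is the inversion Δθ(K) = (8π²/K)^(1/3) — the
natural unit for that grid's orientation errors.

## Synthetic data

Phantoms are sums of Gaussian density blobs (default 8) with centers
uniform in a sphere of 0.8 × the nominal diameter, widths ≈ D/30 and
random weights; their diffraction intensity has the closed form of a
coherent Gaussian sum, evaluated directly on the lattice (no FFT), which
supplies analytic oracles for every interpolation step. Intensities are
Friedel-symmetric by construction. Snapshots are slices at uniform-random
hidden orientations, rescaled by one global factor so the *expected* total
count per snapshot equals `mean_photons` (per-snapshot totals then
fluctuate Poissonically), Poisson-sampled per pixel, with an optional
clipped zero-mean Gaussian background standing in for non-Poisson
background scattering. The regime of interest is ~100 photons per snapshot
(~10⁻² per pixel on a 10⁴-pixel detector).

What the phantom does not emulate: atomic form factors (its spectral
envelope decays like a Gaussian, attenuating detector-edge speckle much
faster than a molecule made of point-like atoms would), incoherent
scattering, detector gain structure, and structured background. Passing
tests therefore demonstrate the estimators' statistical machinery under
controlled conditions, not instrument-level performance.

## Numerical choices

* **Log-domain E-steps** with per-snapshot max subtraction; at 10⁻²
  photons/pixel raw likelihoods underflow. The constant ln T! is dropped
  from the Poisson log-likelihood (model-independent), so traces are
  comparable across runs but offset from the true log-probability.
* **Tomogram floor** ε = 10⁻¹⁰ × mean data intensity keeps ln Y finite.
  Because the floored M-step is the exact maximizer over {Y ≥ ε}, plain-EM
  monotonicity is preserved exactly.
* **One gridding kernel.** Trilinear gather (slicing) and scatter
  (inserting) share the corner-weight computation, so scatter is the exact
  adjoint of gather; compression, expansion, and volume merging are the
  same code. Voxels receiving no weight are nearest-neighbor filled and the
  volume is re-symmetrized so Friedel symmetry is exact. The lattice is odd
  with q = 0 at the central voxel; default spacing is the oversampled
  Shannon spacing 1/(2D) (merging studies use 1/(4D) to keep interpolation
  loss below the quantities being measured).
* **Initialization.** Default is distance-weighted (k-means++-style)
  seeding from the data: K snapshots chosen with probability proportional
  to squared distance from the nearest chosen seed. A spherically averaged
  radial-profile volume with multiplicative seeded noise is available as
  `init="radial"`, but at high photon counts the sharp Poisson E-step
  hard-assigns against its nearly identical tomograms on the first
  iteration and freezes in a permutation-scrambled local optimum; data
  seeding anchors the mixture to real, distinct patterns in both the high-
  and low-signal regimes. EM carries no global-optimum guarantee, so
  `n_restarts` runs independent seeded starts and keeps the best final
  log-likelihood; the sweep studies use 3 restarts.
* **GTM scale conventions.** α is quoted for unit-RMS data and internally
  divided by the data mean square — the weight prior must scale as
  intensity⁻² for the fit to be invariant under rescaling counts.
  β is a single scalar precision. Defaults: basis centers at every 8th
  node (M ≈ K/8), σ_φ = 2 × the mean nearest-center spacing. This stiff
  basis enforces contiguity strongly (it is the configuration used for the
  permutation-degeneracy study) at the cost of map resolution; node-exact
  discrimination needs a finer basis (centers at every node or every other
  node, σ_φ ≈ 0.5–0.75 × the node spacing), where contiguity is carried by
  the weight penalty instead. Basis-width *annealing*, which full
  self-organization from an uninformative start would require, is out of
  scope; GTM is used to refine an informative start (e.g. an EMC solution)
  or with data seeding.
* **Convergence**: |ΔlogL| < tol·|logL| with tol = 10⁻⁴, max 100
  iterations, both configurable. A final E-step synchronizes the stored
  responsibilities with the final tomograms.
* **Gauge and flip.** The likelihood is invariant under one global
  rotation of all orientations, so accuracy is measured after fitting that
  gauge (scan over grid nodes, then Nelder–Mead refinement of the median
  geodesic error). Because the intensity is Friedel-symmetric, a slice and
  the slice at the orientation composed with a half-turn about the beam
  axis deposit identical information (exactly so for a flat detector,
  nearly so at the mild default curvature); data cannot distinguish the
  two branches snapshot by snapshot, and the error metric folds this flip
  per snapshot. Flip-branch "errors" are harmless for the merged volume:
  both placements coincide under Friedel symmetrization.
* **Operation accounting.** The per-iteration multiply–add count is a
  closed-form function of (K, N, p, L) dominated by the two K·N·p matrix
  products; running estimators accumulate exactly this count (verified
  against the formula in tests). The scaling study evaluates the verified
  counter at Shannon-consistent sizes (K ∝ (D/r)³, N = 10K, p ∝ (D/r)²),
  where the leading term gives the characteristic (D/r)⁸ growth, inside
  the expected 6th-to-9th-power band.

## Study sizes and what they show

All studies are desk-scale; sizes were chosen so each runs in minutes on
one CPU core while exercising the claimed property.

* **Low-signal sweep**: D/r = 8 phantom, K = 200 grid, 32×32
  Shannon-sampled detector, N = 2000 snapshots per level over
  {1600, 800, 400, 200, 100, 50} mean photons, errors in the grid's
  Shannon-angle unit Δθ(200) ≈ 0.73 rad. Median errors are ≈ 0.5 Δθ
  (quantization-dominated) down to 200 photons and degrade below. At 100
  photons the outcome is realization-dependent and sits at the information
  limit of these scaled-down conditions: an E-step against the *exact true
  model* already yields median errors of ≈ 1.0–1.7 Δθ across phantom
  realizations, i.e. the single-snapshot posterior at 100 photons is about
  one Shannon angle wide. At production scale (10⁴-pixel detectors, far
  larger N) the ~100-photon operating point is the published regime; the
  desk-scale sweep reproduces the approach to it and the breakdown below
  it.
* **Volume recovery**: Shannon-consistent setting (D/r = 4, 16×16
  detector, K = 3000 ≈ half-Shannon spacing, N = 4000 at 400 photons,
  1/(4D) lattice). The merged generative volume reaches Pearson ≥ 0.96
  with the phantom on covered voxels after gauge alignment; the
  measured hard-assignment ceiling of the same configuration is 0.976.
  At exactly-Shannon node spacing the ceiling is ≈ 0.92 for *any* D/r,
  because nearest-node quantization smears the resolution shell by a fixed
  fraction of a speckle — volume-fidelity studies therefore oversample the
  grid.
* **Equivalence, monotonicity, degeneracy**: small instances (K = 12–632)
  verify the limit-mode identity to 10⁻¹⁴, EM monotonicity across 20
  seeds to 10⁻⁹, exact permutation invariance of the unconstrained
  likelihood, and strict penalized-likelihood decrease under 100/100
  random permutations once the contiguity constraint is active.

## Known limitations

* From-scratch GTM does not globally self-organize on SO(3) with a fixed
  basis width; it needs either an informative start or the out-of-scope
  annealing schedules. EMC's volume-consistency constraint is the stronger
  ordering mechanism and is the from-scratch path.
* At high signal the Poisson E-step is effectively hard assignment and EM
  is a greedy partition refinement; isolated swapped node pairs can
  survive restarts (there is no global-optimum guarantee).
* The per-snapshot flip ambiguity is intrinsic to Friedel-symmetric
  intensities on (near-)flat Ewald slices; orientations are meaningful
  modulo that two-fold branch, and chirality of the merged volume is set
  only by the Ewald curvature.
* Multi-panel detectors, per-pixel gain/masks beyond a single boolean
  mask, polarization and solid-angle corrections, and phasing of the
  merged volume are out of scope.
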