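# Methods

## Measurement model

All pipelines share one forward model.  A reference structure `V` (a 2D
image or a 3D density) is acted on by an unknown rotation `g`,
`(g ∘ V)(x) = V(g⁻¹x)`, passed through a known linear operator `Π`
(tomographic projection plus discretization, or discretization alone), and
corrupted by isotropic Gaussian noise:

    y = Π(g ∘ V) + ε,    ε ~ N(0, σ²I).

Three measurement domains are implemented: `projection-2d` (N×N line
integral along z of the rotated volume — single-particle geometry),
`subtomogram-3d` (N³ rotated volume, no projection — cryo-ET subtomogram
alignment), and `polar-2d` (d_r×L_θ polar-grid image where in-plane
rotation is an exact cyclic shift of the angular axis).  CTF, translations
and colored noise are deliberately out of scope.

## Estimators

The posterior over rotations is discretized on a grid `{g_ℓ, λ_ℓ}` with
templates `x_ℓ = Π(g_ℓ ∘ V)`:

    w_ℓ ∝ λ_ℓ · Λ(g_ℓ) · exp(−‖y − x_ℓ‖² / 2σ²).

* **MLE** — grid node minimizing `‖y − x_ℓ‖²`; prior-free; ties break to
  the lowest index (relevant only in the σ→∞ limit).
* **MAP** — node maximizing `λ_ℓ Λ(g_ℓ) · likelihood`.  The quadrature
  weight is kept inside the argmax, so with equal weights this is the
  exact discrete MAP; under a uniform prior it coincides with the MLE.
* **MMSE** — Bayes estimator of the squared chordal loss: the
  posterior-mean matrix `E = Σ_ℓ w_ℓ g_ℓ` (not a rotation) projected back
  onto SO(3) by the orthogonal Procrustes solution (SVD with determinant
  sign fix).  If the projection is degenerate (two vanishing singular
  values of `E`, a measure-zero event) the MAP node is substituted and the
  result flagged rather than silently picking an arbitrary minimizer.

All weights are computed in the log domain with max-subtraction, so the
largest term is always exp(0) = 1 and the computation is finite for σ down
to at least 1e-6.  Templates are rendered once per (reference, grid) pair
and cached as an (L, d) matrix; batch estimation is then a single
matrix-matrix product, which is what keeps the Monte-Carlo harnesses and
the EM loops tractable on one CPU.

## Metrics

Chordal distance `d_F = ‖g₁ − g₂‖_F` and geodesic distance
`d_G = arccos((tr(g₁ᵀg₂) − 1)/2)`, related exactly by
`d_F = 2√2·sin(d_G/2)`; for small angles `d_F ≈ √2·d_G`.  All accuracy
numbers in the harnesses are geodesic (radians).

## SO(3) grids and priors

* **Product quadrature** — ⌈L^{2/3}⌉ Fibonacci-sphere viewing directions ×
  ⌈L^{1/3}⌉ equispaced in-plane angles, equal product weights.  The
  in-plane factor is an exact circular rule; the spherical factor is
  near-uniform.  The realized node count is the product of the rounded
  factors and may differ slightly from the request.  An external
  quadrature table (9 matrix entries + weight per line) can be supplied
  instead.
* **Monte-Carlo grids** — i.i.d. samples from Haar or from a non-uniform
  prior, equal weights.  When nodes are drawn from the prior itself the
  prior density must *not* be applied again in the posterior weights (it
  is encoded in the node density); the harnesses handle this
  automatically.
* **IGSO(3) prior** — isotropic Gaussian on SO(3) with scalar variance η²:
  axes uniform, rotation angle ω with density proportional to the
  truncated heat-kernel character series
  `(1−cos ω)/π · Σ_{l≤l_max} (2l+1) e^{−l(l+1)η²/2} sin((l+½)ω)/sin(ω/2)`,
  truncated at `l_max = max(10, ⌈5/η⌉)` and renormalized on a
  4096-point angle grid.  Sampling is inverse-transform from the tabulated
  CDF.  Limits: Haar-uniform as η→∞ (verified pointwise to 1e-3 at η=10),
  concentration at the identity as η→0.
* **Covering radius** of a grid is estimated by Monte Carlo (max over
  probe rotations of the nearest-node geodesic distance); it bounds the
  discretization error of grid search and is itself an estimate, so tests
  using it allow a few percent slack.

## SNR convention

`snr = ‖x‖² / (d·σ²)` — signal energy per measurement element over noise
variance, with `d` the number of elements.  Harnesses set σ from the
*unrotated* reference (rotation preserves energy up to interpolation
error) and record σ alongside every result row.  Any comparison across
measurement domains must account for `d`: the same nominal SNR carries
`d`-fold different total information.

## Iterative reconstruction

For the no-projection model with M observations, the EM M-step is the
average of posterior-weighted back-rotations:

    V^{t+1} = (1/M) Σ_i Σ_ℓ w_iℓ · (g_ℓ⁻¹ ∘ y_i),

implemented by reordering the double sum so only L back-rotations are
applied per iteration regardless of M.  Hard assignment replaces the inner
sum by the single MLE node.  Iteration stops when the relative change
drops below 1e-3 or after 100 iterations.  The discretized marginal
log-likelihood is recorded every iteration; in the 2D polar pipeline the
group action is exact and the trace is non-decreasing (EM monotonicity),
in 3D cubic interpolation perturbs it at the interpolation-error level.
Reconstruction is identifiable only up to a global rotation, so all scores
are computed after searching the estimation grid for the best-aligning
rotation.

## Heterogeneity benchmark

The conformational trajectory is a rigid asymmetric blob body plus one
sub-blob translating along a curved path (three-quarter ellipse arc plus a
z-drift), discretized into K equally spaced states.  The path is long
relative to the blob width so that several principal components of the
conformational covariance carry appreciable variance — the spectrum decays
gently rather than collapsing after one mode, which is what makes
mid-spectrum comparisons (k ≈ 5) statistically meaningful.

Subspace recovery is direct align-average-debias covariance estimation:
back-rotate every observation by its pose (trilinear), block-mean
downsample to 16³ voxels, form the sample covariance (via thin SVD of the
centered data matrix), subtract the noise variance from the spectrum and
clip at zero.  Back-rotation interpolates and block-averaging pools b³
voxels, so the per-voxel noise variance after alignment is `c·σ²` with an
operator-dependent factor `c` (≈ interpolation correction / b³); `c` is
estimated by pushing a small batch of unit-variance noise volumes through
the identical operator, with a fixed internal stream and a canonical
(sorted) pose subset so the debias is deterministic and invariant to
observation order.

The pose-source comparison estimates per-observation poses against a
consensus reference (the observation mean refined by 3 EM rounds, then
registered to a common global frame over the estimation grid — the model
is identifiable only up to a global rotation, and a common frame is needed
for subspaces under different pose sources to be comparable to the same
ground-truth factor).  Subspace quality is the percentage of total
variance captured, `100·‖U_kᵀ Σ^{1/2}‖_{S1} / ‖Σ^{1/2}‖_{S1}` (Schatten
1-norms), evaluated through the covariance factor so the full covariance
matrix is never formed.  Eigenvalue recovery is reported as the ratio of
the estimated to the true eigenvalue at each order.

## Synthetic data: what it does and does not emulate

Phantoms are sums of anisotropic Gaussians inside a tapered support
sphere (radius 0.45·N) so rotations never clip signal.  The `blob-asym`
kind mixes two feature scales, mimicking the spectral content of real
macromolecular density: a few elongated broad lobes give template
matching a wide angular correlation basin — without them, templates
decorrelate within ~0.1 rad and coarse rotation grids (L ≈ 200) produce
gross mismatches that corrupt the error-vs-L scaling — while compact
blobs at spread-out radii provide fine angular precision and break
symmetry.  The build-time asymmetry check requires the rotational
self-correlation to stay below 0.8 over a 500-rotation scan *outside a
30° exclusion ball*: the ball must exceed the density's intrinsic angular
correlation length (every smooth structure correlates >0.9 with a
6°-rotated copy of itself), and 30° still catches any nontrivial
point-group symmetry, whose rotations lie at 60° or more.  `blob-bar` is
deliberately near-symmetric and unsuitable for pose benchmarks.

Polar phantoms use many compact signed-contrast features so that two
independently drawn phantoms are nearly uncorrelated (aligned correlation
≈ 0.2) — necessary for template-bias experiments, where a template that
accidentally resembles the truth would mask the effect, and for the
soft-versus-hard comparison, where a truth-correlated template hands both
methods the same head start.

None of the generators model CTF, shifts, solvent background, radiation
damage or non-Gaussian detector noise, so passing tests demonstrate the
estimator-level claims (Bayes-risk ordering, scaling laws, template bias,
pose-to-heterogeneity coupling) under the stated model — not end-to-end
performance on experimental micrographs.

## Numerical choices

* Rotation of volumes: `scipy.ndimage.affine_transform` about the voxel
  (N/2, N/2, N/2), cubic spline by default (trilinear available), zero
  outside the grid.  Rotation by the identity returns the input exactly.
* Projection: real-space sum along z times the voxel size — exactly
  linear, adequate at desk scale; no Fourier central slice.
* Quaternions are stored canonically (w ≥ 0, unit norm); STAR/CSV pose
  tables carry quaternions plus intrinsic ZYZ Euler angles in degrees.
* Per-trial randomness uses counter-based streams derived from the master
  seed (`SeedSequence(entropy=(seed, trial))`), so results are independent
  of batching and execution order, and trials are paired across
  estimators and noise levels.

## Problem sizes

The default experiment sizes are chosen for a single-CPU desk run: N = 24
volumes with grids up to L = 6000 and a few thousand Monte-Carlo trials
for the estimator studies; d_r = 64 × L_θ = 30 polar images with M = 2000
observations for the reconstruction studies; N = 32, K = 10, M in the
hundreds for the heterogeneity benchmark.  All claims tested are
orderings, convergence properties and scaling exponents, which are
scale-stable; absolute error values shift with N, d and M.

## Known limitations

* The product quadrature has no polynomial exactness guarantee; it is a
  practical near-uniform rule, and all quadrature-dependent claims are
  verified against its realized covering radius.
* The 3D in-plane FFT factorization (an L^{1/3} speedup of template
  matching) is not implemented; the cached-template GEMM path is fast
  enough at these scales.  The 2D polar pipeline does provide the FFT
  path (`fast_polar_correlations`).
* The heterogeneity benchmark replaces projection-based covariance
  estimation with the no-projection subtomogram model, where every step
  is fully specified; conclusions about the *pose-source ordering* carry
  over, absolute variance-captured percentages do not.
* `mmse_back_rotate` is exact for the cyclic polar action; in 3D it
  inherits cubic-interpolation error, and weights below 1e-14 are skipped.
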