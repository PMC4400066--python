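# Methods

This note documents the models, estimators, numerical choices and known
limitations of `dwieval`, in the spirit of a model-documentation page.

## Signal model and conventions

The relative diffusion-weighted signal is S(θ, b) = S_b(θ)/S₀ with
S₀ the **mean** of all b = 0 volumes (the median is the obvious
alternative; the mean is standard and is the aggregation used
throughout). The decay model is S = exp(−b·A(θ)) with the apparent
diffusion coefficient A(θ) in mm²/s and b in s/mm².

Diffusion measurements cannot distinguish θ from −θ, so directions are
axial everywhere: angular comparisons fold into [0°, 90°], and
eigenvectors / peak directions are canonicalized to the hemisphere with
z ≥ 0 (ties broken toward y ≥ 0, then x ≥ 0) so that principal
directions are reproducible across runs.

Gradient tables are stored as FSL-dialect bvals/bvecs (3 rows × T
columns). A `coordinate_frame` tag (`image`/`world`) documents the
frame; no reorientation is performed — motion correction and gradient
rotation are assumed done upstream.

## Diffusion tensor model

A(θ) = θᵀQθ, Q symmetric positive-definite, 6 free parameters.

* **OLS/WLS** minimize squared error of log S against the linear model
  −b·θᵀQθ. WLS weights are the squared predicted signals from a
  first-pass OLS fit; one reweighting pass by default (configurable).
* **NLLS** minimizes squared error of S itself, using a trust-region
  Levenberg–Marquardt on the Cholesky factorization Q = LLᵀ (which
  keeps Q positive semi-definite by construction), initialized from the
  WLS solution; up to 6000 function evaluations, gradient tolerance
  1e-10.
* Non-positive samples (possible after noise rectification) are dropped
  from the log-domain fits with a warning; a configurable floor
  (`log_floor`) is available instead. Fewer than 6 usable samples or a
  rank-deficient design marks the voxel `fit_failed`.
* A noisy log-linear fit can produce a non-positive-definite tensor.
  Such fits are **flagged, not clamped**: FA/MD/linearity are NaN for
  those voxels (the PDD is still reported, since the leading
  eigenvector is usually meaningful). Eigenvalue clipping is available
  explicitly (`_clip_spd`) but is never applied silently.
* Scalars: FA = √(3/2)·‖λ − mean λ‖/‖λ‖; MD = mean λ; linearity
  defaults to the Westin index c_l = (λ1 − λ2)/(λ1 + λ2 + λ3)
  (a normalized variant (λ1 − λ2)/λ1 is selectable). The Westin form is
  used for the "most linear" ranking in the corpus-callosum ROI.

## Sparse fascicle model

Each voxel is an isotropic compartment plus F candidate fascicle
compartments, every fascicle responding as the canonical axially
symmetric kernel (axial/radial diffusivity, default 1.5e-3 / 0.5e-3
mm²/s; estimable from data, see ROI below) rotated to a candidate
direction. Removing each response's spherical mean μᵢ makes the
fascicle regressors zero-mean, which folds the isotropic term, the
isotropic diffusivity D, and the weighted μ's into a single constant
W₀ equal to the directional mean signal S̄. **D and β₀ are therefore
never estimated separately**; the fit records S̄ and the fascicle
weights only. On a uniform 150-point direction set the μᵢ vary by
≲0.05% across orientations (the acceptance script recomputes this), so
treating μ as fascicle-independent is safe.

* **Candidate directions**: a deterministic 362-point electrostatic set
  by default (seeded, reproducible); the acquisition's own directions
  can be used instead. The basis deduplicates antipodal candidates.
* **Solver**: the Elastic Net objective
  ‖s − Xβ‖² + λΣ(αβᵢ² + (1−α)|βᵢ|) is solved by cyclic coordinate
  descent with soft thresholding, optional non-negativity (default ON —
  weights are volume fractions, and peaks/dispersion semantics assume
  β ≥ 0). Convergence: max coordinate update < 1e-8, or a cap of 10⁴
  sweeps (the cap is a legitimate stop: on this strongly correlated
  design the iterates wander in a near-null space that barely moves the
  objective; a warning fires only if the last update is large relative
  to the solution scale).
* **Pathwise warm starts**: cold-started descent at a tiny λ provably
  mis-converges on the fascicle design (nearly collinear columns), so
  the solver follows a 30-step geometric λ path from λ_max (where β = 0
  is optimal) down to the target, warm-starting each step, with
  active-set sweeps between full KKT sweeps. This is the standard
  pathwise coordinate-descent strategy.
* **Mixing convention**: α = 1 is ridge and α = 0 is lasso — the
  *reverse* of the common `l1_ratio` convention. The mapping to the
  scikit-learn objective (a·l1_ratio = λ(1−α)/(2T),
  a·(1−l1_ratio) = λα/T) is covered by a dedicated test.
* **Penalty scale**: `fit_sfm` treats λ as a per-measurement weight —
  the solver receives λ·T on the sum-of-squares scale. This makes λ
  independent of the number of directions and is the scale on which the
  default λ = 0.0005, α = 0.2 produces sparse, stable fits; against the
  raw sum of squares that λ would be ~150× too weak and the model
  overfits badly (checked empirically: fascicle weights an order of
  magnitude too large, peak validity destroyed).
* **Peaks**: weights above 0.1× the maximum weight are greedily
  accepted in descending order subject to a 15° minimum separation
  (both configurable; unstated in the source methodology and needed for
  the dispersion index and validity metrics). The largest peak is the
  SFM analog of the PDD.
* **Summaries**: fascicle anisotropy FA = Σβ/W₀ and dispersion index
  DI = Σ_{i≥2} βᵢ²·sin αᵢ / Σᵢ βᵢ² over extracted peaks, αᵢ the axial
  angle to the dominant peak.
* **Hyperparameters**: `grid_search_hyperparameters` picks (λ, α)
  minimizing the median cross-validated rRMSE across voxels from
  two-repeat data; λ = 0.0005, α = 0.2 are the defaults when no search
  is run.

## Model accuracy

RMSE(x, y) = √(Σ(xᵢ−yᵢ)²/T);
rRMSE = (RMSE(M1, D2) + RMSE(M2, D1)) / (2·RMSE(D1, D2)), with M1 fit
on D1 and scored against D2 and vice versa. Each repeat is fit and
predicted with its own (motion-corrected) gradient table; the
test–retest denominator pairs the two repeats index-wise. rRMSE is
scale-invariant, so raw scanner units and S₀-normalized signals give
identical values; the implementation accepts either. The null
repeat-the-data model scores exactly 1; a perfect model under IID
Gaussian noise has expectation 1/√2 (one noise sample in the numerator
comparisons, two in the denominator).

SNR = μ/σ with μ the mean diffusion-weighted signal and σ the sample
standard deviation of the b0 measurements divided by the Gaussian
small-sample factor c₄(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2), which makes
the estimator unbiased (c₄(10) ≈ 0.9727).

Median confidence intervals use a seeded percentile bootstrap over
voxels (1000 resamples by default).

### Number-of-directions experiment

To fit on n ≤ T directions, the ideal n-point electrostatic set is
rotated so its first point coincides with a chosen origin direction,
and each ideal point is greedily matched to the nearest unused measured
direction. The spin about the origin axis is not fixed by the origin
alignment, so 36 evenly spaced spins are tried and the subset with the
largest minimum pairwise angle kept (deterministic). Models are refit
on the subsample of each repeat and still predict (and are scored on)
the full other repeat. Note that subset separation quality is bounded
by the angular resolution of the measured set: on a 150-point table the
selected subsets reach ≈97%/85%/63% of the ideal minimum pairwise angle
at n = 10/20/40.

## Simulations

Crossing voxels contain two fascicles at a configurable angle (truth
directions placed at ±angle/2 about z in the x–z plane — any placement
is equivalent by rotation invariance, which is itself tested) and
weight ratio w1:w2, w1 + w2 = 1. Noise options:

* `gaussian(σ)` / `rician(σ)` — additive per-direction; Rician takes
  the magnitude of a complex Gaussian perturbation;
* `empirical(pool)` — a half-difference vector (D1 − D2)/2 drawn at
  random from a pool built from paired measurements. When no measured
  repeats exist, `synthetic_noise_pool` emulates the pool from two
  σ-calibrated renderings of tensor signals; pool entries then have
  standard deviation σ/√2.

When σ is not given it is calibrated so mean-signal/σ matches realistic
white-matter SNR: 7 at b = 1000 and 2 at b = 4000 s/mm², log-log
interpolated in between (≈3.7 at b = 2000). Signals are rectified at
zero after noise addition. Every realization is bit-reproducible from
(seed, repetition index).

The reliability/validity experiment fits both models to paired noisy
realizations: DTM validity is the minimal axial angle between the PDD
and either truth direction; SFM validity is the median over extracted
peaks of each peak's minimal angle to either truth ("non-zero weight"
uses the peak-extraction threshold, since coordinate-descent zeros are
tolerance-dependent); reliability is the angle between the PDDs of the
two realizations. Default 500 repetitions per cell; the test suite runs
50 with correspondingly widened tolerances, and the documented problem
sizes throughout the tests (40-voxel two-repeat sets, 100-point test
bases) are chosen to keep Monte-Carlo error well inside the asserted
tolerances.

## White-matter masks, CC ROI, kernel estimation

* `refine_wm_mask` drops voxels whose MD exceeds the in-mask median by
  more than 2 IQR (one-sided: the target is CSF/GM partial volume).
* `select_cc_roi` filters voxels by left-right PDD
  (|PDD_x| > max(|PDD_y|, |PDD_z|); no numeric cone threshold is
  specified by the source methodology, so component dominance is used),
  FA > 0.4 and MD strictly inside 0.7–1.1 × 10⁻³ mm²/s (the printed
  bounds are interpreted at the standard white-matter diffusivity
  scale), then returns the 250 most linear survivors. An optional
  b0-uniformity filter (±2 IQR around the ROI median b0, OFF by
  default) is provided since its exact published form is unspecified.
* `estimate_kernel` takes the ROI median of per-voxel axial (λ1) and
  radial ((λ2+λ3)/2) diffusivities.

## What the synthetic data do and do not show

The generator produces single- and two-fascicle voxels with IID (or
pooled half-difference) noise. It does not emulate spatially correlated
physiological noise, motion-induced gradient deviations beyond
treating repeat tables as interchangeable, Rician floor effects at very
low SNR, three-way crossings, or orientation dispersion within a
fascicle. Passing tests therefore demonstrate correctness of the
estimators and the evaluation machinery under the stated noise models,
not performance claims about any particular scanner or protocol.

## Known limitations

* Single-shell SFM only: the design matrix rejects mixed b-values.
* No robust (outlier-rejecting) tensor variants, no kurtosis, no
  spherical-harmonic deconvolution.
* The elastic-net solution at very small λ is not unique (F > T);
  reported weights are the pathwise coordinate-descent solution, which
  is reproducible but not the only minimizer.
* Whether fascicle weights should be constrained non-negative is a
  modeling choice; both modes are available, and the summary statistics
  assume the default non-negative mode.
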