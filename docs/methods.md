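# Methods

## Connectivity estimators

Three per-pair measures are implemented, plus an unsigned Pearson variant:

* **Pcor** — Pearson correlation of the two ROIs' voxel-mean time series.
  `unsigned_pcor` flips the sign of negative values, giving the same [0, 1]
  range as distance correlation (distance correlation cannot distinguish
  positive from negative coupling: the distance matrices of perfectly
  anticorrelated signals are identical to those of perfectly correlated
  ones).
* **uvDcor** — distance correlation of the voxel-mean series, using
  *double centering* of the Euclidean distance matrices (subtract row,
  column and grand means; normalisation K = n²).
* **mvDcor** — multivariate distance correlation of the full voxel
  patterns, using *U-centering* (row and column sums zero, zero diagonal,
  K = n(n−3), n ≥ 4), which yields an unbiased distance-covariance
  estimator and removes the dependence of the estimate on the number of
  voxels in an ROI. Each voxel is z-scored first.

The reported value is the ratio dCov/√(dVar·dVar), truncated to 0 when
dCov ≤ 0. On the double-centred path this ratio equals the **square** of
the classic distance correlation of Székely, Rizzo & Bakirov (2007); on the
U-centred path it is the bias-corrected R\* of Székely & Rizzo (2014). The
single-formula convention keeps the two variants directly comparable and is
the scale on which all package statistics operate. The U-centred dCov can
be legitimately negative under independence (its null distribution is
shifted left); truncated entries are counted and the count is carried in
the connectivity matrix (`n_truncated`) and its JSON sidecar, enabling
control analyses that zero the same number of weakest Pearson connections
(`evaluation.zero_weakest`).

Numerical conventions: the diagonal of a connectivity matrix is stored as
NaN (self-connections are undefined) and excluded from all vectorised
analyses, which use the lower triangle in fixed ROI order. A zero distance
variance (constant distance matrix) returns dCor = 0 with a warning rather
than an error, so degenerate simulated ROIs do not abort batch runs.
Z-scoring uses the population SD (ddof 0) per session; voxels with
SD < 1e−12 are dropped with a warning.

## Pre-processing pipeline

Confound regression and filtering happen in one GLM per ROI:

* **Confounds** — the 6 rigid-body motion parameters plus mean WM and CSF
  signals, each expanded into {base, backward-difference derivative (first
  sample 0), base², derivative²}: 32 regressors. Pipeline options N / C /
  CW / CWG use motion only, +CSF, +CSF+WM, +CSF+WM+global. The global
  signal is the mean over the whole analysis mask (a grey-matter-only mean
  is a defensible alternative; the whole-mask choice is exposed, not
  buried).
* **Filtering** — a discrete-cosine basis inside the GLM. Component k has
  frequency k/(2·n·TR); high-pass keeps the ⌊2·n·TR·f_hp⌋
  lowest-frequency components as regressors, band-pass regresses out the
  components below f_lo *plus* those above f_hi. At n = 261, TR = 1.97 s,
  f_hp = 0.008 Hz this gives 8 regressors.
* **Autocorrelation model** — per ROI, the residual temporal covariance is
  modelled as white noise plus 8 exponentials exp(−|Δt|·ln2/h) with
  half-lives h ∈ {0.5, 1, 2, 4, 8, 16, 32, 64} TR (an AR(1)+white model is
  too rigid for resting-state data). Hyperparameters are fitted to the
  voxel-pooled sample covariance, additionally averaged along diagonals:
  the family is stationary, so only the Toeplitz part of the sample
  covariance is informative, and lag-pooling tames the variance of the
  rank-v voxel covariance. Because the regressors have already been
  removed, maximising this pooled likelihood is the restricted likelihood
  of the original model. The optimiser is box-constrained L-BFGS-B with
  analytic gradients (weights ≥ 0, white-noise weight bounded away from 0).
  A projected Fisher-scoring iteration was tried first and abandoned: the
  exponential components are nearly collinear, so the projected Newton step
  is frequently not a descent direction and the iteration stalls far from
  the optimum. On AR(1) synthetic data the fitted model reproduces the
  pooled lag-1 autocorrelation to within ±0.01.
* **Prewhitening** — residuals are multiplied by the inverse symmetric
  square root of the fitted covariance. On high-passed AR(1) data this
  drives |lag-1| below 0.05. After *band-pass* filtering (0.008–0.1 Hz) the
  residuals live in a low-frequency subspace whose autocovariance no
  monotone exponential family can represent, and whitening cannot restore
  exchangeability: lag-1 stays above 0.5. Correlational connectivity on
  band-passed data is therefore unreliable by construction, and the test
  suite asserts this directionally.
* **Motion summary** — Jenkinson-style RMS volume-to-volume displacement
  over an 80 mm sphere with the small-angle approximation:
  d_t = √(‖Δtranslation‖² + (2/5)·R²·‖Δrotation‖²); the scalar total is the
  mean over the n−1 volume-to-volume values.
* **Structural data** — voxelwise grey-matter volumes are residualized
  per voxel (with intercept) against total grey matter across participants,
  isolating regional variability before covariance estimation.

## Atlas handling

The analysis mask keeps voxels at ≥ 70% of mean signal intensity, where the
reference mean is over **nonzero** voxels (the all-voxel mean is exposed as
an option; with large empty backgrounds the nonzero mean is the only
sensible reference). ROI coverage: an ROI is kept iff ≥ 25% of its voxels
fall inside the mask (boundary inclusive), and kept ROIs retain only
in-mask voxels. WM/CSF nuisance masks use the strict rule GM < 1% and
tissue > 80%. Voxel order within extracted blocks is the sorted C-order
linear index — deterministic, so extraction round-trips and all estimators
are invariant to storage order. ROI summaries are the voxel mean or the
first singular vector of the column-demeaned block (scaled by its singular
value, sign aligned to the voxel mean for reproducibility). Atlas
resampling to the functional grid is assumed done upstream
(nearest-neighbour); labels are never interpolated implicitly.

## Simulation engine

Two ROIs of `n_voxels` (default 20) voxels over `n_time` (default 200) time
points. Latent signals are unit-variance Gaussians; every voxel adds
independent N(0, 0.2²) noise. Scenarios: one signal per ROI with inter-ROI
correlation r ∈ {0, 0.5} (baseline); two anticorrelated sub-populations per
ROI, implemented as sign-flipped copies, each correlating 0.5 with its
counterpart (the ROI average carries no signal); and a half-shared design
where only half of each ROI's voxels carry the shared signal. Bias studies
vary ROI size (20 vs 40), noise type (voxel-specific SD 2; ROI-shared
SD 0.55/0.55 or 0.2/0.8 added on top of the voxel noise), and AR(1)
autocorrelation x_t = αx_{t−1} + w_t applied to the generating signals
(x₁ = w₁; the series are not re-standardised, so variance grows with α as
in the underlying construction). `n_time = 200` sits between the two
emulated session lengths; replicate counts default to 1,000 for bias
curves and 200 for case comparisons (Monte-Carlo SE of a mean U-centred
dCov at n = 200, v = 20 is ≈ 0.0015 over 1,000 replicates). One root seed
spawns independent child streams per replicate.

## Cohort generator

The synthetic cohort emulates the features that matter for comparing
measures, not realistic haemodynamics: R ROIs (default 8) in `n_modules`
modules with within/between-module signal correlation 0.5/0.1; two sessions
of 261 and 152 volumes at TR = 1.97 s; 20 participants. A fraction of ROIs
(default 0.5) is inhomogeneous: two anticorrelated sub-populations whose
mixing fraction is participant-specific (U(0.35, 0.65)) *plus a per-session
jitter* (SD 0.1). The jitter models between-session differences in head
position and coregistration — the mechanism by which different voxels
dominate an ROI average in different sessions — and is what makes
ROI-average Pearson estimates unreliable while leaving the multivariate
estimator untouched. The default AR(1) coefficient is 0 (the block-level
cohort emulates already-prewhitened residuals); the on-disk path can
generate autocorrelated data for end-to-end pipeline tests. Optional
motion-coupled artefacts enter as a low-rank time series with spatially
smooth ROI gains, scaled by each participant's motion level.

What passing cohort tests does **not** show about real data: no
haemodynamic response or physiological noise model, no spatial smoothness
within ROIs, no registration errors beyond the mixing-fraction proxy, and
ground-truth connectivity that is exactly modular. The generator's manifest
records the full ground truth so every evaluation metric can be scored
without re-reading generator code.

## Evaluation battery

* **ICC** — own ANOVA implementation; default form is one-way random,
  single measures, ICC(1,1) (the two-way forms ICC(2,1)/ICC(3,1) are
  available and every output records the form used). Verified against an
  independent ANOVA oracle.
* Within-participant reliability (matrix-level and per-ROI), per-connection
  ICC across participants, and between-participant similarity (Pearson with
  the group-average matrix, participant included by default; leave-one-out
  available).
* **ROI homogeneity** — percent of variance of voxelwise connectivity
  patterns explained by their first principal component, after removing
  each voxel's mean pattern level (so overall connectivity strength cannot
  masquerade as homogeneity).
* **Cross-parcellation robustness** — ROI matrices are projected to voxel
  pairs; pairs inside a single ROI in either parcellation are excluded
  (self-connections are undefined); Pearson correlation over shared pairs.
* **Swap permutation test** — |ρ_S(d₁,d₂)| − |ρ_S(p₁,p₂)| with
  measure-labels swapped per connection consistently across sessions
  (default 5,000 permutations, seed-deterministic); Spearman is used
  because connection-strength distributions are positively skewed. The
  p-value is the fraction of permuted |differences| ≥ the observed
  |difference|; calibration under an exchangeable null is tested.
* **Motion association** — per-connection Pearson correlation of
  connectivity with total motion across participants; summaries are the
  mean correlation and its dependence on inter-ROI centroid distance.
* **Structural covariance** — the same estimator code path with
  participants as the exchangeable axis; structure–function correspondence
  uses Spearman over the lower triangle, optionally restricted to
  connections positive in both matrices.

## Known limitations

* dCor values are on a squared scale relative to Pearson and compressed
  near zero; on *homogeneous* data this costs a small but systematic amount
  of reliability relative to signed Pearson (the package's cohort tests
  measure ≈ 0.005–0.01 mean ICC/similarity deficit), consistent with the
  general range-restriction effect. The multivariate advantage appears
  when, and only when, ROIs are inhomogeneous.
* U-centred estimates below zero are truncated; for data with many truly
  null connections (e.g. structural covariance) a substantial fraction of
  entries can be exact zeros, which changes value distributions — the
  matched-zeroing control exists for exactly this comparison.
* The whitening operator assumes the exponential covariance family is
  adequate; it is not for band-limited data (see above).
* The cohort generator's session jitter is a proxy for all session-level
  voxel-composition changes; its SD (0.1) is a design constant, not a
  fitted quantity.
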