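# dcorconn

ROI-based functional connectivity and structural covariance estimated with
**multivariate distance correlation**, as a drop-in alternative to the
Pearson correlation of ROI-average signals.

## The problem

Brain-wide connectivity analyses reduce each region of interest (ROI) to a
single time series — usually the mean over its voxels — and correlate those
series between regions. When an ROI is *inhomogeneous* (it contains voxel
sub-populations with different, even anticorrelated, signals), averaging
destroys or distorts the dependence between regions: two strongly coupled
regions can appear disconnected simply because their average signals cancel.

Distance correlation (dCor) measures statistical dependence between two
*sets* of signals — the full n×v time-by-voxel pattern of each ROI — without
averaging, and detects both linear and non-linear coupling. This package
implements it for network estimation from fMRI time series (dependence
across time points) and from grey-matter volumes (structural covariance,
dependence across participants).

## The statistic

For ROI blocks X (n×v₁) and Y (n×v₂), with every voxel z-scored:

1. pairwise Euclidean distances between time points,
   a_ij = ‖X_i − X_j‖, b_ij = ‖Y_i − Y_j‖;
2. centering of each distance matrix — *double centering* (rows, columns and
   grand mean; K = n²) for the univariate estimator, or *U-centering*
   (row/column sums zero, zero diagonal; K = n(n−3)) which makes the
   estimator **unbiased with respect to the number of voxels**, so ROIs of
   different sizes are comparable;
3. dCov(X,Y) = Σ A_ij B_ij / K, dVar(X) = Σ A_ij² / K;
4. dCor = dCov / √(dVar(X)·dVar(Y)) if dCov > 0, else 0
   (a negative U-centred dCov indicates non-significant dependence; such
   connections are truncated to zero and their count reported).

The package also provides the surrounding pipeline: 32-regressor motion/WM/
CSF confound expansion, DCT high-/band-pass filtering in the GLM,
per-ROI temporal autocorrelation modelling (white noise + 8 exponentials,
half-lives 0.5–64 TR, fitted by restricted maximum likelihood) with
prewhitening, atlas coverage filtering, a two-ROI simulation engine for bias
studies, a synthetic multi-session cohort generator, and an evaluation
battery (ICC reliability, between-participant similarity, ROI homogeneity,
cross-parcellation robustness, permutation tests, motion association,
structure–function correspondence).

## Worked example

Two ROIs of 20 voxels share a latent signal pair correlated at r = 0.5
(n = 200 time points, voxel noise SD 0.2). In the *baseline* case every
voxel carries its ROI's signal; in the *anticorrelated-halves* case each ROI
splits into two sub-populations carrying sign-flipped copies, so the ROI
averages cancel:

```python
from dcorconn import SimSpec, gen_case, connectivity_matrix

for case in ("baseline", "anticorrelated_halves"):
    spec = SimSpec(case=case, inter_roi_r=0.5, seed=0)
    X, Y = gen_case(spec)
    vals = {m: connectivity_matrix([X, Y], m).values[0, 1]
            for m in ("pcor", "mvdcor")}
    print(f"{case:24s} Pcor = {vals['pcor']:+.3f}   mvDcor = {vals['mvdcor']:.3f}")
```

```
baseline                 Pcor = +0.520   mvDcor = 0.227
anticorrelated_halves    Pcor = +0.095   mvDcor = 0.231
```

Pearson correlation collapses from 0.52 to 0.10 when the ROI averages
cancel, while the multivariate distance correlation is unchanged (0.23 in
both cases — note dCor values are not on the Pearson scale; at a generating
r = 0.5 the truncated U-centred estimate sits near 0.23).

A command-line interface wraps the main workflows:

```sh
dcorconn simulate --case anticorrelated_halves --reps 200 --seed 1 --out table.tsv
dcorconn fixtures-generate --out cohort/ --participants 5 --seed 1
dcorconn fc-matrix --config pipeline.yaml --out matrices/
dcorconn evaluate --dataset cohort/ --metric icc --out icc.tsv
```

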