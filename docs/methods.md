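# Methods

## Generative model

The simulator writes subject k's masked voxels-by-time matrix as a linear
superposition of three component groups plus a constant signal level:

```
Y_k = baseline + c_k · a s' + B T_k + N_k
```

* **Task component.** `a` is a sum of isotropic Gaussian foci (one per
  region of interest) over masked voxels; `s` is the active-block boxcar
  convolved with a canonical double-gamma HRF (response gamma with shape
  6 s / dispersion 1 s, undershoot 16 s / 1 s, undershoot ratio 6, 32 s
  support, unit peak). Both are identical across subjects; only the positive
  intensity `c_k` varies (drawn Uniform(0.7, 1.3)).
* **Background networks.** `B` holds m spatial maps common to all subjects;
  each subject gets its own timecourses `T_k`, drawn as Gaussian processes
  smoothed with an 8 s kernel and standardized to zero mean, unit variance —
  slow, subject-specific dynamics of spatially fixed networks.
* **Noise.** `N_k` is Gaussian with marginal standard deviation
  `noise_sigma` and AR(1) temporal autocorrelation (default ρ = 0.3),
  independent across subjects and voxels.
* **Baseline.** A constant intensity (default 100 a.u. in the standard
  conditions, 0 in the bare container) added to every voxel. It exists so
  the temporal-SNR statistic — ROI mean *signal* over noise-region
  variability — is meaningful: high-pass filtering removes the mean, so the
  pipeline records the pre-filter temporal mean per voxel and restores it
  when computing SNR in either arm.

The block paradigm defaults to 4 active + 4 static 35 s blocks at
TR 3.5 s (80 volumes, the first 5 discarded, 75 analyzed), static block
first.

### Standard study conditions

All validation experiments run one fixed cohort layout: a 24 × 24 × 12 grid
of 3 mm voxels with an ellipsoidal mask (2640 voxels), 25 subjects, four
task foci (FWHM 9 mm) with peak amplitudes 0.5 (EBA/SI/PMd analogues) and
0.25 (the deliberately weak PMv analogue) against unit noise — peak
contrast-to-noise 0.5 — three two-focus background maps of unit amplitude, a
27-voxel signal-free noise-reference region, and a 144-voxel ventricle-like
CSF region. These sizes keep a full two-arm experiment near five seconds on
one CPU so that 25-replicate validation runs finish in minutes; they are the
package's chosen desk scale, with the subject count matching a realistic
cohort.

What the simulator does *not* model: head motion, scanner drift fields,
spatial normalization error (data are born aligned on a common grid),
physiological time-locked confounds outside the optional CSF artifact, and
k-space artifacts. Passing tests therefore demonstrate the estimator's
behaviour under the stated superposition model, not robustness to
registration or motion failure modes.

## Conventional preprocessing

Both arms receive identical treatment: isotropic Gaussian smoothing
(default FWHM 8 mm, `σ = FWHM / (2√(2 ln 2))` per axis, zero-padded outside
the mask and re-masked) followed by high-pass filtering, realized as
per-voxel regression on a discrete-cosine drift basis with periods ≥ the
cutoff (default 128 s), constant included — so filtered voxel means are
exactly zero and the filter is an idempotent linear projection. Smoothing
precedes filtering by default; the order is configurable. The GLM design
therefore omits an intercept when data are pre-filtered (with both condition
regressors present an added constant is collinear).

## Common-subspace estimation (gCCA, MAXVAR)

1. **Per-subject reduction.** Each preprocessed `Y_k` is reduced to the left
   singular vectors whose squared singular values cumulate to ≥ 95% of
   energy (`energy_keep`, configurable). Signs are fixed (largest-magnitude
   entry positive) for reproducibility.
2. **MAXVAR.** The bases are stacked column-wise and decomposed,
   `[U_1 … U_K] = W Σ V'`. The leading columns of `W` maximize the summed
   squared projections onto all subjects' spans — equivalently they are the
   top eigenvectors of `Σ_k U_k U_k'`. Scores `σ_i²/K` lie in (0, 1] and
   equal the mean squared projection of direction i onto the subject spans.
   A Gram-matrix route (eigendecomposition of the (Σr_k)² matrix `S'S`) is
   available for very wide problems and agrees with the direct SVD to 1e-8.
3. **Dimension.** `threshold` method (default): keep scores ≥ 0.75. Under
   the standard conditions the four planted components score 0.84–0.95
   while the continuum of smoothing-induced shared-noise directions sits
   near 0.65–0.70, so the threshold separates them cleanly. A `gap` method
   (largest consecutive score drop) is provided. Selection never returns 0;
   an empty selection falls back to 1 with a warning.
4. **CSF filter (optional).** Components whose squared mass inside a CSF
   mask exceeds 50% (strict inequality, configurable) are dropped before
   reconstruction; removing every component is an error.
5. **Projection.** `Ŷ_k = W_d W_d' Y_k`, the orthogonal projection applied
   identically to every subject.

The 0.75 threshold, 0.95 energy and the MAXVAR construction were fixed at
design time; the dimension criterion is a reasoned stand-in for a
data-driven rule, and its calibration against the smooth-noise continuum is
documented above rather than tuned per dataset.

## Statistics

* **First level.** Per-voxel OLS on HRF-convolved active and static
  regressors; `t = c'β / √(σ̂² c'(X'X)⁻¹c)` with `df = T − rank(X)`. No
  autocorrelation prewhitening (a deliberate simplification; the residual
  df after high-pass filtering is likewise not reduced by the DCT rank —
  both are documented fixed choices). Voxels with exactly zero residual
  variance yield t = 0 when the effect is zero and signed infinity (logged)
  otherwise.
* **Second level.** One-sample t over subjects' contrast values (df n−1)
  and paired t between arms (gCCA minus original, so positive favours the
  processed arm).
* **Thresholding.** One-tailed Student p-values; activation maps use the
  positive tail.
* **ROI report.** Extent = suprathreshold voxel count in the ROI at
  p < 0.01 (first level); peak t reported even below threshold; temporal
  SNR = grand mean of the ROI timeseries (mean restored) divided by the
  standard deviation over time of the noise-region-averaged timeseries.
  The grand mean over voxels and time equals the temporal mean of the
  voxel-averaged series, so the two readings of the numerator coincide.
  Percent change = 100(gCCA − original)/original, missing where the
  denominator is zero. Paired t per ROI and a two-way fully-within
  (ROI × dataset) repeated-measures ANOVA — each effect tested against its
  own effect-by-subject interaction, sums of squares computed directly —
  summarize the comparison.
* **Cluster-extent threshold.** Monte-Carlo: white Gaussian volumes,
  smoothed to the stated FWHM, standardized within the mask, thresholded at
  the one-tailed normal quantile; the returned extent is the smallest k
  with empirical P(max cluster ≥ k) ≤ α. Connectivity defaults to 18
  neighbours. Noise is standardized after smoothing so the voxel threshold
  maps to a z-quantile. A voxelwise p near 1 triggers an "alpha
  unreachable" warning and returns mask size + 1.

## Numerical and design choices

* All linear algebra inside `run_experiment` and the validation experiments
  runs single-threaded, making reports bit-reproducible across hosts for a
  fixed seed; every random draw descends from the experiment's single seed.
* Subspace recovery is measured against the planted maps *after smoothing
  with the data's kernel*: the common subspace of the preprocessed cohort is
  the span of the smoothed maps, so comparing against unsmoothed maps would
  measure the smoothing kernel (≈ 20° for 9 mm foci under an 8 mm kernel)
  rather than the estimator. The recovery angle reported is the largest
  canonical angle (the strictest single-number subspace distance); under the
  standard conditions it concentrates near 9–10° with each individual
  planted direction captured at 0.97–0.99 squared projection.
* The CSF artifact used by the specificity experiments is a single 9 mm
  focus of amplitude 2.0 inside the CSF region whose per-subject timecourse
  mixes the task response (weight 0.4) with a subject-specific smoothed
  process orthogonalized against it. A fully task-locked artifact is
  temporally indistinguishable from the task component within each subject
  and merges with it into one blended component that no spatial-overlap rule
  can isolate; the mixed design separates the artifact into its own common
  component (CSF overlap 0.6–0.8) while retaining enough task correlation to
  produce spurious first-level CSF activation when not filtered.
* Dimension ties, degenerate thresholds and zero-variance voxels all take
  documented branches (see docstrings); subject bases reject all-zero data;
  the CSF filter refuses to empty the subspace.

## Known limitations

* **t statistics on low-rank projections are anti-conservative off
  support.** Projection onto a d-dimensional basis leaves tiny but nonzero
  values at voxels where the components carry estimation leak; t statistics
  are scale-invariant, so such voxels inherit the components' task
  correlation and can pass voxelwise thresholds even though the underlying
  data are numerically negligible. At this desk scale (d = 4, 2640 voxels)
  the effect is visible as suprathreshold voxels outside the planted
  support in the processed arm — including inside the CSF region even after
  the overlap filter has removed the artifact component (the filter removes
  the artifact-attributable activation; it cannot remove leak inflation).
  At realistic scale (d in the tens, hundreds of thousands of voxels) the
  leak is diluted by orders of magnitude. Consumers of processed-arm maps
  should interpret suprathreshold extent jointly with effect size, or apply
  cluster-extent criteria.
* The group-level one-sample t over projected data is similarly inflated:
  all subjects share one basis, so leak has a consistent sign across
  subjects.
* No autocorrelation correction at the first level; df are nominal.
* The dimension criterion assumes the commonness-score continuum of shared
  smooth noise stays below the threshold; very small cohorts (K ≲ 5) push
  noise scores upward and can inflate the selected dimension.
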