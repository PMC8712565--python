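# gccafmri

Common-subspace sensitivity enhancement for multi-subject block-design task
fMRI, built around generalized canonical correlation analysis (gCCA).

## The problem

Group task-fMRI studies fight a low signal-to-noise ratio: the BOLD response
to a blocked stimulus is small against scanner and physiological noise, and
conventional preprocessing (spatial smoothing, high-pass filtering) only goes
so far. But much of the *structure* in every subject's recording is shared
across the cohort. Writing subject k's masked voxels-by-time matrix as

```
Y_k = c_k · a s'  +  B T_k  +  N_k
```

— a task component with spatial map `a` and HRF-convolved temporal response
`s`, common to all subjects up to an intensity `c_k`; background
("resting-state") networks with common spatial maps `B` but subject-specific
timecourses `T_k`; and strong noise `N_k` independent across subjects — the
spatial span of the first two groups is *common* to everyone. Estimating that
common spatial subspace and projecting each subject's data onto it suppresses
whatever is not shared, raising SNR and GLM sensitivity in weakly activated
regions while leaving the shared signal intact.

`gccafmri` implements this pipeline end to end for simulated cohorts with
known ground truth: a generative simulator matching the model above, the
conventional preprocessing stage, the MAXVAR gCCA estimator with a
data-driven dimension criterion and a CSF-overlap component filter, first and
second level GLM contrast t-maps, ROI extent/peak/SNR statistics with
Monte-Carlo cluster-extent thresholds, and a two-arm comparison harness
(conventional vs gCCA-processed).

## The estimator

Each preprocessed `Y_k` is reduced to an orthonormal spatial basis `U_k`
(left singular vectors keeping 95% of squared-singular-value energy). With
`S = [U_1 … U_K]` and SVD `S = W Σ V'`, the MAXVAR common directions are the
leading columns of `W`; the *commonness score* of direction i is
`σ_i² / K ∈ (0, 1]`, equal to the mean squared projection onto the subjects'
spans (1 ⇔ the direction lies in every subject's span). The subspace
dimension is the number of scores above a threshold (default 0.75).
Components with more than 50% of their squared mass inside a CSF mask can be
excluded before reconstruction. Denoising is the orthogonal projection
`Ŷ_k = W_d W_d' Y_k`.

## Worked example

`examples/03_two_arm_experiment.py` runs the standard study conditions
(25 subjects, 24×24×12 grid of 3 mm voxels, four planted activation foci of
which the "PMv" analogue is deliberately weak, three background networks,
unit noise, peak contrast-to-noise 0.5) through both arms:

```
common subspace dimension: 4
recovery angle vs planted span: 8.93 deg

roi  mean_extent_original  mean_extent_gcca  mean_peak_t_original  mean_peak_t_gcca  mean_snr_original  mean_snr_gcca  pct_change_snr_mean
EBA                 76.28             78.00                 14.08             21.57             958.96        2827.69               199.74
PMd                 76.44             79.36                 13.39             20.95            1019.46        3006.09               199.74
PMv                 58.72             75.08                  7.64             21.42             981.35        2893.71               199.74
 SI                 74.80             76.00                 13.90             21.10             981.90        2895.36               199.74
```

Reading the numbers: the data-driven criterion picks exactly the four planted
common components, and their span sits 8.9° from the ground truth. In the
gCCA-processed arm every region's first-level suprathreshold extent
(p < 0.01) and peak t rise — most dramatically in the weak PMv-like focus
(peak t 7.6 → 21.4), and temporal SNR (ROI mean signal over the temporal
standard deviation of a noise-region-averaged timeseries) triples. The
accompanying ROI × dataset repeated-measures ANOVA shows the main effect of
dataset and the interaction driven by the weak region. Other examples cover
the simulator, the subspace estimator, Monte-Carlo cluster thresholds and the
CSF specificity guard.

A thin CLI mirrors the library (`gccafmri simulate | preprocess | gcca |
glm | cluster-thresh | run`).

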