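"""Run the full two-arm experiment: conventional vs gCCA-processed.

Simulates the standard cohort, preprocesses it once, runs the GLM on the
conventionally preprocessed data and on the same data projected onto the
common spatial subspace, and prints the ROI comparison the package is
built to produce: suprathreshold extent, peak t and temporal SNR per ROI,
with percent changes across subjects.
"""

from gccafmri import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=1))

print(f"common subspace dimension: {result.selected_d}")
print(f"recovery angle vs planted span: {result.recovery_angle_deg:.2f} deg\n")

cols = ["roi", "mean_extent_original", "mean_extent_gcca",
        "mean_peak_t_original", "mean_peak_t_gcca",
        "mean_snr_original", "mean_snr_gcca", "pct_change_snr_mean"]
print(result.report.per_roi[cols].round(2).to_string(index=False))

print("\nROI x dataset repeated-measures ANOVA on peak t:")
print(result.report.anova["peak_t"].round(4).to_string(index=False))

# Positive percent changes mean the gCCA-processed arm is more sensitive:
# larger activation extent, higher peak t (especially in the weak PMv-like
# focus) and higher temporal SNR, at identical planted ground truth.
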