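"""Estimate the common spatial subspace of a simulated cohort with gCCA.

Preprocesses every subject (8 mm smoothing, 128 s high-pass), reduces each
to an orthonormal spatial basis, stacks the bases and reads off the MAXVAR
common directions with their commonness scores; then measures how well the
estimate recovers the planted span.
"""

import numpy as np

from gccafmri import (
    PreprocessConfig,
    estimate_common_subspace,
    preprocess_subject,
    principal_angle_deg,
    simulate_standard_cohort,
    subject_basis,
    truth_span,
)

cohort = simulate_standard_cohort(seed=0)
cfg = PreprocessConfig()
filtered = [preprocess_subject(ts, cfg)[0] for ts in cohort.subjects]

bases = [subject_basis(ts, energy_keep=0.95) for ts in filtered]
print(f"per-subject spatial ranks r_k (95% energy): "
      f"{[b.rank for b in bases[:6]]} ...")

subspace = estimate_common_subspace(bases, grid=cohort.grid)
print(f"selected dimension d = {subspace.dim} "
      f"(scores >= 0.75 are kept)")
print(f"commonness scores: {np.round(subspace.scores, 3)}")

span = truth_span(cohort, cfg.smooth_fwhm_mm)
angle = principal_angle_deg(subspace.basis[:, : span.shape[1]], span)
print(f"largest principal angle to the planted task+background span: "
      f"{angle:.2f} degrees")
# Scores near 1 mark directions present in every subject's data span; the
# cohort's four planted components (task + 3 background networks) stand far
# above the smooth-noise continuum (~0.65-0.70).
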