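"""Decode left vs right motor imagery with the full chain:
band-pass -> CSP spatial filtering -> normalized-variance features ->
Fisher LDA, evaluated with leakage-free repeated stratified
cross-validation.
"""

import numpy as np

from midecode import (
    PipelineConfig,
    SynthConfig,
    bandpass_filter,
    csp_fit,
    generate_mi_dataset,
    run_pipeline,
)

data, forward = generate_mi_dataset(
    SynthConfig(n_trials_per_class=100, erd_depth=0.8, noise_sd=0.1, seed=3)
)

# inspect the fitted spatial filters on the mu band
model = csp_fit(bandpass_filter(data, 8, 13))
print("CSP class-1 whitened eigenvalues:", np.round(model.eigvals, 3))
patterns = model.patterns
cos = abs(patterns[:, -1] @ forward.mixing[:, 0]) / (
    np.linalg.norm(patterns[:, -1]) * np.linalg.norm(forward.mixing[:, 0])
)
print(f"bottom CSP pattern vs true class-1 mixing column: |cos| = {cos:.3f}")

# cross-validated accuracy with per-fold automatic band selection
result = run_pipeline(data, PipelineConfig(band="auto", cv_folds=5, cv_repeats=5, seed=3))
print(f"mean held-out accuracy: {result.accuracy_mean:.2f}%")
print(f"band used (mean over folds): {result.band_used[0]:.1f}-{result.band_used[1]:.1f} Hz")
print("confusion matrix (rows true class 1/2):")
print(result.confusion)
# Eigenvalues far from 0.5 mean strongly class-specific variance; the
# extreme CSP patterns recover the planted sources, and accuracy near 100%
# reflects the large planted ERD (depth 0.8) at low noise.
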