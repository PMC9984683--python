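# SYNTHETIC IMPACT logistic-model coefficients.
#
# The published IMPACT model's coefficients are not redistributed here; this
# file carries a synthetic, order-of-magnitude-plausible set matching the
# synthetic cohort generator's covariates, for examples and tests only.
# Replace with the published coefficient set for any real analysis.
intercept: -3.0
age: 0.04            # per year
motor_score: -0.25   # per admission motor-score level (higher = better)
pupils: 0.7          # per non-reactive pupil
hypoxia: 0.4
hypotension: 0.5
ct_class: 0.25       # per Marshall class
tsah: 0.5
epidural_hematoma: -0.3
glucose: 0.1         # per mmol/L
hemoglobin: -0.2     # per mmol/L
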