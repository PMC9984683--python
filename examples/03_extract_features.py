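"""Extract the sixteen quantitative EEG feature families from one segment.

The feature vector summarizes a 10-min multichannel segment: classical
spectral measures (band powers, alpha/delta ratio, spectral edge frequency,
band-power variability), interhemispheric symmetry (BSI), synchronization
(mean magnitude-squared coherence), signal statistics (spectral Shannon
entropy, amplitude regularity), the aperiodic 1/f fit (offset, exponent),
long-range temporal correlations (amplitude- and phase-DFA Hurst exponents
per band) and broken detailed balance (entropy production, flux curl per
band).  Seven families are band-resolved, giving 9 + 7 x 4 = 37 values.
"""

import numpy as np

import icueeg as q
from icueeg.features import extract_segment_features

profile = q.EEGProfile(duration=600.0, seed=3, asymmetry=0.2,
                       envelope_hurst=0.75, aperiodic_exponent=1.8)
rec = q.generate_recording(profile, t_after_trauma=71.75)
seg = q.Segment(samples=rec.samples, labels=list(rec.labels), fs=rec.fs,
                clean_windows=np.ones((rec.n_channels, 60), bool))

feats = extract_segment_features(seg)
print(f"{len(feats)} feature values from one 10-min segment\n")
notable = {
    "rel_power.alpha": "fraction of power in 8-13 Hz",
    "adr": "(alpha-delta)/(alpha+delta) slowing contrast",
    "sef90": "Hz below which 90% of power lies",
    "bsi": "left-right asymmetry, 0 symmetric .. 1 one-sided",
    "coherence": "mean pairwise synchronization",
    "aperiodic_exponent": "1/f^a slope (generator used 1.8)",
    "dfa_amp.alpha": "alpha-envelope Hurst exponent (generator used 0.75)",
    "variability.alpha": "MAD/median of 10-s alpha power",
    "entropy_production.alpha": "detailed-balance violation, nats/step",
}
for name, meaning in notable.items():
    print(f"  {name:26s} {feats[name]:8.3f}   {meaning}")
print("\nThe BSI reflects the planted asymmetry of 0.2; the aperiodic "
      "exponent and envelope Hurst estimates track their generative knobs.")
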