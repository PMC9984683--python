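# Methods

This note documents the models, estimators and design choices behind
`icueeg`, and what the synthetic validation does and does not establish.

## Preprocessing

The analysis band-pass is a Butterworth of design order 6 (as passed to
`scipy.signal.butter`, i.e. 6 pole pairs for the band-pass realization)
applied forward–backward with `sosfiltfilt`, which cancels the group delay
and squares the magnitude response.  Recordings shorter than three times
the filter's settling span are rejected rather than padded.

Flat channels (amplitude variance ≤ 0.1 µV² after filtering) are identified
*before* common-average referencing and excluded from the average —
referencing first would inject the negated scalp average into an otherwise
silent electrode and hide it from the flatness rule.  Artifact detection
then runs on the re-referenced signal in non-overlapping 10-s windows; a
(channel, window) is flagged when **any** of the three rules fires:
|x| ≥ 200 µV, variance ≥ 1400 µV², or variance ≤ 1 µV².  Rejection is
per-channel rather than whole-window: a window remains usable for channels
on which it is clean, which retains more data at identical thresholds.
Only the printed amplitude/variance rules are implemented; no additional
muscle-band heuristics are assumed.

The "30 min around the timepoint of interest" is the centred window
[t − 15 min, t + 15 min], split into three 10-min segments.  If no non-flat
channel remains the timepoint's feature vector is missing (all-NaN row).

## Feature estimators

* **Welch PSD** — 10-s windows, no overlap, periodic Hamming taper, one-sided
  density in µV²/Hz (0.1-Hz resolution); per channel, only its clean
  windows are averaged.  Band edges are inclusive; the alpha (8–13 Hz) and
  beta (10–20 Hz) bands deliberately overlap, so band powers need not tile
  total power.
* **Variability** — MAD/median over the per-window band-power series;
  requires ≥ 5 clean windows, NaN otherwise.  MAD is the raw median
  absolute deviation (no normal-consistency factor).
* **BSI** — homologous-pair version: mean of |(R−L)/(R+L)| over the eight
  10–20 left/right pairs and 0.5–20-Hz bins.  Midline electrodes never
  enter; a montage without any homologous pair yields NaN.
* **Coherence** — magnitude-squared coherence from 4-s Hann windows with
  2-s overlap, averaged over 0.5–40 Hz (the filtered band) and all
  unordered pairs.  Frames are used only when clean on *every* retained
  channel; the estimator floor for independent signals is ≈ 1/#frames.
* **Shannon entropy** — spectral entropy (bits) of the PSD normalized to a
  probability distribution.  The amplitude-histogram alternative was
  rejected because every other feature in this family is
  spectrum-derived and the spectral version has clean endpoint anchors
  (0 for a line spectrum, log₂N for a flat one).
* **Regularity** — squared signal, 0.5-s moving average, descending sort
  q(1..N), then sqrt(3·Σi²q_i/(N²Σq)), clipped to [0, 1].  Equals 1 in the
  constant-amplitude limit by Σi² = N(N+1)(2N+1)/6.
* **Aperiodic fit** — ordinary least squares of log₁₀PSD on log₁₀f over
  1–40 Hz with ≤ 3 re-fits after masking bins > 2.5 residual SD *above*
  the line (peaks only bias upward; the high-pass rolloff below 1 Hz is
  excluded by the range).  No knee parameter.  Exact on noiseless power
  laws; cross-checked in tests against a Theil–Sen robust slope.
* **DFA** — cumulative sum of the demeaned series, ~15 log-spaced
  non-overlapping window sizes, linear detrending per window, Hurst
  exponent = least-squares slope of log F(n) vs log n.  Windows run from
  one oscillation period of the band's geometric-mean frequency up to a
  quarter of the segment.  The lower bound is additionally floored at
  2·fs/bandwidth: a band of width B cannot transmit envelope fluctuations
  faster than ~1/B, and windows below that scale measure only the
  filter's smoothness — numerically this inflates H by ≈ +0.15–0.2 even
  for memoryless envelopes, whereas with the floor the generator's
  envelope Hurst knob is recovered within ±0.1.  Degenerate
  (near-constant) inputs return NaN with a low fit-r² flag.
* **Band decomposition** — the zero-phase band filter (design order 4) and
  Hilbert transform are applied jointly in the frequency domain (positive
  spectrum × |H|²), which is the exact response of a forward–backward
  filter followed by the analytic-signal construction, at a third of the
  cost.
* **Broken detailed balance** — the band-filtered channels are projected on
  their first two principal components (sign fixed by positive loading
  sum, projections z-scored), each axis is split into 3 equal-occupancy
  bins (9 states), and lag-1 transition frequencies F are accumulated.
  Entropy production is the pair-regularized ½Σ(F_ij−F_ji)ln(F_ij/F_ji)
  over pairs observed in both directions — one-sided pairs are skipped, so
  a deterministic cycle has finite (zero) EP rather than a divergent one.
  The flux curl sums net circulation over the four elementary plaquettes,
  counterclockwise-positive in the (PC1, PC2) plane.  Time reversal
  negates the curl and preserves EP; both vanish for symmetric F.

Per-channel features are averaged over clean channels so the classifier
receives fixed-length vectors; 16 families, 7 band-resolved → 37 columns.

## Classification

Random forest, 200 trees (the OOB-error curve utility shows the plateau),
impurity importances.  Cross-validation is 5-fold, stratified by outcome
and *grouped by patient*: the 3-segment augmentation multiplies training
rows but all segments of a patient share a fold, and metrics are computed
on patient-level scores (mean of segment probabilities).  The operating
point for sensitivity/specificity is the Youden-optimal threshold of the
training patients' out-of-bag scores — never fitted on the test fold.
Missing values are imputed with training-fold medians.  Backward
elimination retrains after dropping the least-important feature
(lexicographically last name on ties) and the chosen subset is the smallest
within `drop_tol = 0.02` AUC of the path maximum — a fixed, configurable
stand-in for a by-eye "substantial drop".  McNemar's test switches from the
exact binomial to the continuity-corrected χ² form at 25 discordant pairs.
IMPACT coefficients are consumed from YAML config; the bundled file is
synthetic (the published coefficients are not redistributed).

## Synthetic cohort generator

Each channel is an aperiodic 1/f^α background (spectral synthesis with
random phases, flat below 0.5 Hz, offset = log₁₀ density at 1 Hz) plus one
oscillation per band: a constant-modulus carrier whose instantaneous
frequency wanders inside the band (Gaussian-lowpassed frequency noise, SD =
bandwidth/4, rate ≈ bandwidth/10), amplitude-modulated by a positive
envelope 1 + m·z built from exact-covariance fractional Gaussian noise z
(circulant embedding) shared across channels.  Constant modulus makes the
realized band envelope equal the prescribed one, so the envelope Hurst knob
propagates to the measured amplitude-DFA; sharing the envelope emulates
global arousal modulation (and is why inter-channel *envelope* correlation
is 1 even though phase coherence stays at the estimator floor).  The
modulation depth m is the variability knob; asymmetry multiplies
right-hemisphere amplitudes by (1+a)/(1−a).

Because the band scheme overlaps and carriers have spectral tails, the four
band-power targets are realized jointly: the generator measures each
carrier's per-band power fractions and solves a non-negative least-squares
system for the carrier weights.  Default targets (δ 120, θ 40, α 80,
β 60 µV²) are chosen feasible — a beta target below the alpha spill into
10–13 Hz (e.g. 25 µV² with α = 80) is unrealizable for *any* generator
under this band scheme and will be met only in the least-squares sense.
Realized in-band powers sit within ~8 % of feasible targets averaged over
10 seeds.  Defaults give ≈ 17 µV total RMS — comfortably inside the
clean-artifact corridor (window variance ≈ 300 µV², peaks ≈ 100 µV).

Cohorts: IMPACT covariates are drawn from plausible ICU distributions, the
poor-outcome label from a logistic model over their standardized values
(intercept calibrated so the expected poor fraction equals `p_poor`), and
the EEG profile of poor-outcome patients is then shifted by the requested
effect sizes in units of the between-patient SD of each knob — lower alpha
power, higher delta, more asymmetry, less variability, higher age via its
positive log-odds.  Everything derives from one seed; cohort feature tables
are byte-identical across runs.

What the generator does **not** emulate: realistic head-model topographies
(all channels are statistically exchangeable up to the hemispheric gain),
epileptiform or sedation-related patterns, partial inter-channel envelope
correlation, non-stationary artifact mixtures.  Passing cohort-level tests
therefore demonstrates the *pipeline's* statistical integrity (no leakage,
monotone knob→feature response, recoverable planted effects), not clinical
performance on real ICU recordings.

## Validation sizes and numerical choices

The test suite uses: 50 seeds × 2¹⁶ samples for DFA consistency (white
noise and fGn at H ∈ {0.3, 0.7, 0.9}); a 60-patient single-timepoint cohort
with 2-SD effects and full 3 × 10-min segments for the prediction,
label-shuffle (20 shuffles) and combination checks; and a 50-patient
two-timepoint cohort (effects only at 72 h, 3 × 5-min segments) for the
timepoint-comparison analysis.  These sizes are the package's choice of a
desk-scale working point with comfortable statistical margins.  A single
finite cohort always exhibits some spurious feature–label association
(≈ 0.65 cross-validated AUC for 37 features on 50 no-effect labels), so
chance-level claims are asserted against patient-level label-shuffle
nulls, which are centred on 0.5 regardless of that association.

EDF export writes 16-bit records with per-channel symmetric physical
ranges (≤ 0.02 µV quantization at typical amplitudes) and a 1-s record
duration; reading goes through MNE.  Single precision is used inside the
synthesis (the generator is statistical); all analysis paths are double
precision.

## Known limitations

* Independent-component-based ECG removal is out of scope (it requires
  visual component review); the amplitude/variance mask is the full
  artifact rule set.
* The amplitude-DFA Hurst estimate remains upward-biased by ~+0.1 for
  weakly persistent envelopes (H ≤ 0.6) — the band-limited observation
  ceiling; the knob→estimate response stays monotone.
* Sensitivity/specificity at the Youden point on small folds are noisy;
  AUC is the primary metric.
* `flux_curl` depends on the plaquette orientation convention
  (counterclockwise-positive); only its sign convention, not its
  magnitude, is arbitrary.
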