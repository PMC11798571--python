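# Methods

## Signal model

The analyses target steady-state evoked responses to rhythmic audiovisual
biological motion. A walking stimulus presents a gait cycle at frequency
`f_g` (1 Hz in the fast designs, 10/12 Hz in the slow design) and a step
cycle at `2 f_g`; six gait cycles form one trial (6 s or 7.2 s), preceded
by a 1 s pre-stimulus baseline. Because the evoked response is phase-locked
to stimulus onset, averaging the epoched EEG across trials before the FFT
preserves the response while shrinking non-phase-locked background activity
by `1/√n_trials`.

The synthetic generator mirrors exactly this structure. Each trial is

```
x_c(t) = Σ_f  g_s · g_sc · A_f · τ_f(c) · sin(2π f t + φ_sf)  +  pink + white noise
```

with channel `c`, component frequency `f`, amplitude `A_f` (µV), per-channel
topographic gain `τ_f ∈ [0, 1]`, a per-subject lognormal gain `g_s`
(σ = 0.2), a per-subject-per-condition lognormal jitter `g_sc` (σ = 0.15,
emulating block-to-block SNR drift), and a phase `φ_sf` drawn once per
subject and frequency so the component survives trial averaging. Noise is
1/f^α ("pink", α = 1, SD 2.5 µV) plus white noise (SD 1 µV), generated by
frequency-domain shaping of Gaussian noise and rescaled to an exact sample
SD. Component frequencies are snapped to the 1/12 Hz analysis grid, so
"1 Hz", "2 Hz", "0.83 Hz" and "1.67 Hz" sit exactly on FFT bins and no
scalloping correction is needed.

Default amplitudes encode the effect structure the analysis is meant to
detect: at the step frequency the audiovisual amplitude equals the sum of
the unisensory amplitudes (additive, A = V = 1 µV each), while at the gait
frequency it equals `γ (A + V)` with γ = 1.5 (super-additive, A = V =
0.3 µV each). The step-cycle response is deliberately the stronger one,
matching the recorded pattern where step-frequency peaks carry much larger
t-values than gait-frequency peaks. In the congruency design, a
subject-varying boost (mean 0.4 µV, SD 0.15 µV) is added at the gait
frequency only in the congruent–upright condition with a topography centered
on right centro-parietal channels (around CP2), a smaller boost (0.3 µV,
broad topography) is added at the step frequency in both orientations, and
AQ scores are generated to correlate ρ = −0.5 with the ground-truth boost.

What the generator does *not* emulate: eye/cardiac artifacts (an external
trial-rejection mask hook stands in for artifact removal), non-stationary
or spatially correlated background noise, volume-conduction structure, and
any behavioral response process beyond schedule bookkeeping. Passing tests
therefore demonstrate correctness and calibration of the analysis chain
under its own assumptions, not fidelity of the generator to recorded EEG.

## Preprocessing

Fixed order: band-pass filter → resample → epoch → (artifact hook) →
mastoid re-reference → crop analysis window → trial average; the order is
recorded in every report's provenance block. All stages are linear, so
averaging and re-referencing commute (asserted to 1e-9).

- **Filter.** Zero-phase Butterworth cascade: 2nd-order high-pass at
  0.1 Hz and 4th-order low-pass at 30 Hz, each applied forward-backward
  (`sosfiltfilt`), doubling the effective order. A single 4th-order
  *band-pass* was rejected because its shared poles give only ~15 dB at
  45 Hz; a 4th-order *high-pass* was rejected because a 0.1 Hz cutoff lies
  so far below Nyquist at 1000 Hz that the sections become numerically
  ill-conditioned (passband gain errors up to 17% were measured). The
  implemented cascade attenuates 45 Hz by >96% and passes 1 Hz within 1%.
- **Resampling.** Polyphase with an exact rational factor (e.g. 10:1 for
  1000 → 100 Hz); upsampling is rejected as out of scope.
- **Crop.** The retained analysis window runs from the end of the first
  gait cycle (1 s, or 1.2 s in the slow design) to the stimulus offset,
  excluding onset-evoked transients: 500 samples (5 s) or 600 samples (6 s)
  at 100 Hz.
- **Re-reference.** Every channel minus the mean of M1/M2; the mastoids are
  dropped from the analysis set afterwards.

## Spectral conventions

Single-sided amplitude spectrum of the Hann-windowed, zero-padded
(n_fft = 1200) average; with fs = 100 Hz the bin spacing is 1/12 Hz.
Scaling is chosen so an on-bin unit sinusoid analyzed without a window
reads 1.0; the Hann coherent gain (exactly 1/2 for the periodic window) is
*not* compensated, because every reported quantity is a difference or ratio
of identically processed amplitudes. Note that with a 500-sample window the
Hann main lobe spans several bins of the zero-padded grid, so neighbor-bin
normalization removes part of the peak as well — again a fixed linear
factor common to all conditions.

Normalization subtracts the mean of the k = 2 bins on each side
("neighboring" is read as the immediately adjacent bins, with no guard
bin); the first/last k bins are flagged invalid and excluded from testing.
The transform is linear in amplitudes, cancels any locally linear trend
exactly at interior bins, and leaves zero-mean noise at zero mean.

## Statistics

- **Peak tests.** Right-tailed one-sample t against zero per bin on the
  channel-averaged normalized amplitude, Benjamini–Hochberg FDR at 0.05
  over all valid bins below 5.33 Hz. BH was chosen over BY; the FDR family
  starts at the first valid (normalizable) bin.
- **Contrasts.** Two-tailed paired t with `d_z = mean(diff)/sd(diff) =
  t/√n`; the published (t, d) pairs of this design satisfy the identity to
  the printed precision (e.g. 4.664/√24 = 0.952).
- **Additive model.** AV vs A+V paired contrast; super-additive/sub-additive
  require p < α with the corresponding sign, additive otherwise. Because
  spectral amplitudes are magnitudes, very low per-bin SNR induces a small
  nonlinear bias in this comparison; at the default noise levels and 40
  trials the bias is negligible (empirical additive-label rate ≈ 95% under
  a true additive structure).
- **Congruency effect.** Congruent minus the unweighted mean of the two
  incongruent runs (0.6 and 1.4 Hz sounds), per subject and electrode.
- **Cluster permutation test.** Per-electrode paired t on
  upright − inverted congruency effects; two-sided threshold at the
  α = 0.05 critical value; an electrode is retained only if at least two
  adjacent electrodes are supra-threshold with the same sign; connected
  components (chord-distance adjacency on an idealized 10-20 montage, 0.5
  radius ≈ 7 neighbors/electrode) are scored by summed t. The null is the
  maximum absolute cluster statistic over per-subject sign flips (1000 by
  default; exhaustive enumeration available for n ≤ 16), and
  `p = (1 + #{null ≥ observed}) / (1 + m)` avoids zero p-values.
  The retention rule can only remove clusters, so it makes the test
  conservative; on sparse montages (e.g. a 16-electrode grid) it suppresses
  null cluster formation almost entirely. Calibration is therefore checked
  in two parts: the sign-flip max-statistic machinery without retention has
  a null any-cluster false-positive rate at the nominal 5% level, and the
  operational test with retention stays below it.
- **Trait correlation.** Pearson r between AQ and the cluster-mean
  upright-minus-inverted effect after removing, in a single pass, subjects
  whose neural response deviates more than 3 sample SDs from the group mean
  (the threshold uses the SD including the candidate outlier, so a lone
  extreme point in a small sample may survive — documented single-pass
  behavior). Median split: AQ ≤ median forms the low group (ties low),
  Welch t on the effect.

## Problem sizes used in validation

Simulation studies run at reduced scale chosen to keep the full suite
comfortably reproducible on a single CPU: additive-model recovery uses 200
cohorts of 24 subjects × 40 trials × 4 central channels; cluster recovery
uses 100 cohorts of subject-by-electrode effect maps on the full
60-channel montage (boost 0.2 µV on the 9 seeded centro-parietal
electrodes, between-subject SD 0.25 µV, i.e. a per-electrode effect size
d ≈ 0.8, comparable to the within-cluster effects reported for this
paradigm); null calibration uses 500 cohorts of 12 subjects × 16
electrodes; FDR calibration uses 1000 simulations of 24 subjects × 64 bins
with 8 signal bins. Monte-Carlo permutation p-values are validated against
exhaustive 2^8 sign-flip enumeration at n = 8 subjects.

## Known limitations

- The montage is an idealized geometric 10-20/10-10 construction on a unit
  sphere, adequate for adjacency-based statistics but not for source-level
  interpretation.
- Unisensory topographies are broad central gradients by default; no claim
  of fidelity to recorded unisensory maps is made.
- The additive-model comparison inherits the small-sample magnitude bias of
  amplitude spectra at very low SNR (see above); users lowering trial
  counts or amplitudes far below the defaults should expect the additive
  null to drift.
- Behavioral accuracy analyses and ICA-based artifact removal are out of
  scope; the artifact hook only applies an externally supplied trial mask.
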