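# freqtag

Frequency-tagging EEG analysis of hierarchical audiovisual rhythms, with a
synthetic cohort generator so every stage of the pipeline is testable
without any recorded data.

## The scientific problem

When we watch a person walk while hearing their footsteps, the brain
integrates visual and auditory rhythms that are organized hierarchically: a
*step cycle* (each footfall, e.g. 2 Hz) nested inside a *gait cycle* (the
full antiphase oscillation of both legs, e.g. 1 Hz). Rhythmic cortical
activity "tags" these frequencies: the trial-averaged EEG spectrum shows
amplitude peaks exactly at the stimulation rates, so the strength of
cortical tracking can be read off spectral bins.

This package implements the complete analysis chain for that paradigm:

1. **Preprocessing** — zero-phase band-pass (0.1–30 Hz), polyphase
   down-sampling to 100 Hz, epoching, mastoid re-referencing, exclusion of
   the pre-stimulus second and the first stimulus cycle, and trial
   averaging (which preserves phase-locked components while averaging out
   non-phase-locked noise).
2. **Spectral analysis** — Hann-windowed, zero-padded (1200-point) FFT of
   the averaged waveform giving a 1/12 Hz grid, followed by *neighbor-bin
   normalization*: each bin minus the mean of the two bins on each side,
   which removes the smooth 1/f background so that genuine peaks can be
   tested against zero,

   `normamp(f) = amp(f) − mean(amp(f±1), amp(f±2))`.
3. **Inference** — right-tailed one-sample t-tests per bin with
   Benjamini–Hochberg FDR below 5.33 Hz; paired contrasts with the paired
   effect size `d_z = t/√n`; the additive-model classification of
   multisensory integration (super-additive if AV > A+V, sub-additive if
   AV < A+V, additive otherwise); per-electrode audiovisual congruency
   effects; a sign-flip cluster-based permutation test over electrodes
   (two-sided t at p < 0.05, ≥ 2 significant neighbors, max-statistic null)
   for the congruency × orientation interaction; and Pearson correlation of
   the biological-motion-specific effect with Autism-Spectrum Quotient (AQ)
   scores after single-pass 3-SD outlier removal, plus a median-split
   comparison.
4. **Synthetic cohorts** — phase-locked sinusoids at the gait/step/harmonic
   frequencies with configurable topographies, embedded in 1/f plus white
   noise, with per-subject and per-condition gain variability, randomized
   trial schedules with catch trials, and AQ scores generated with a target
   correlation to the ground-truth effect.

The key scientific contrast the pipeline reproduces on synthetic data:
audiovisual integration is *super-additive* at the gait frequency
(AV > A+V) but *additive* at the step frequency (AV = A+V), and the
congruency effect at the gait frequency is specific to upright biological
motion over right centro-parietal electrodes.

## Worked example

```python
from freqtag.pipeline import ExperimentConfig, run_experiment1

cfg = ExperimentConfig.exp1a(
    n_subjects=24, n_trials_per_condition=40,
    channel_subset=["C1", "CZ", "C2", "CP1", "CPZ", "CP2", "CP4", "P1", "PZ", "P2"],
    seed=1)
report = run_experiment1(cfg)
print(report["bins"])                    # {'gait': 12, 'step': 24, 'harmonic': 48}
print(report["integration"]["gait"]["label"])   # super-additive
print(report["integration"]["step"]["label"])   # additive
print(report["contrasts"]["gait"]["AV_vs_V"])
```

Output of the last line for this seed:

```
{'t': 12.009, 'p': 2.18e-11, 'd': 2.451, 'df': 23, 'mean_diff': 0.0463}
```

meaning: across the 24 simulated subjects the normalized amplitude at the
gait bin (bin 12 = 1 Hz on the 1/12 Hz grid) is on average 0.046 µV higher
in the audiovisual than in the visual condition (paired t(23) = 12.0,
d_z = t/√24 = 2.45). The AV-vs-(A+V) contrast at the same bin is labeled
super-additive (t(23) = 9.30, p < 0.001), while at the step bin AV is
statistically indistinguishable from A+V (t(23) = 0.78, p = 0.45 →
additive), reproducing the two distinct integration modes the design is
built to detect.

A command-line entry point wraps the same machinery:

```bash
freqtag run --config experiment.yaml --seed 1 --out report_dir/
freqtag simulate --config experiment.yaml --seed 1 --out cohort_dir/
```

where `experiment.yaml` holds `experiment: exp1a|exp1b|exp2` plus any
`ExperimentConfig` field.

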