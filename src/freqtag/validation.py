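"""Simulation studies that calibrate and validate the inferential machinery.

These routines run many small synthetic cohorts through the analysis chain
and measure operating characteristics: the rate at which the additive-model
test recovers a super-additive gait-frequency gain and stays additive at the
step frequency, the spatial cluster test's recovery of a seeded
centro-parietal interaction and its false-positive rate under the null, and
the empirical false-discovery proportion of the FDR-corrected peak test.
They are used both by the test suite and by the acceptance script; problem
sizes are arguments so callers choose their own scale.
"""

from __future__ import annotations

import numpy as np

from .montage import Montage
from .preprocess import average_trials, crop_analysis_window
from .spectral import amplitude_spectrum, freq_to_bin, normalize_spectrum
from .stats import (additive_classification, cluster_permutation_interaction,
                    peak_ttest_fdr)
from .synth import ConditionSpec, SimConfig, simulate_cohort, simulate_effect_matrices

#: Reduced montage for scaled-down cluster simulations: a connected 4 x 4
#: grid of fronto-central to parietal electrodes.
SMALL_GRID_16 = ("FC3", "FC1", "FCZ", "FC2",
                 "C3", "C1", "CZ", "C2",
                 "CP3", "CP1", "CPZ", "CP2",
                 "P3", "P1", "PZ", "P2")


def _cohort_bin_values(config: SimConfig, specs, montage, gait: float, step: float):
    """Per-subject channel-averaged normalized amplitude at the gait/step bins."""
    cohort = simulate_cohort(config, specs, montage)
    out: dict[str, dict[str, np.ndarray]] = {}
    b_gait = b_step = None
    for subject, conditions in cohort.items():
        for cond, rec in conditions.items():
            rec = crop_analysis_window(rec, cycle_duration=1.0 / gait)
            evoked = average_trials(rec)
            norm = normalize_spectrum(amplitude_spectrum(evoked, n_fft=1200), k=2)
            if b_gait is None:
                b_gait = freq_to_bin(norm, gait)
                b_step = freq_to_bin(norm, step)
            vals = norm.channel_mean()
            out.setdefault(cond, {})[subject] = (vals[b_gait], vals[b_step])
    arrays = {}
    for cond, d in out.items():
        pairs = np.array([d[s] for s in sorted(d)])
        arrays[cond] = {"gait": pairs[:, 0], "step": pairs[:, 1]}
    return arrays


def superadditive_label_rates(
    n_cohorts: int,
    montage: Montage,
    seed: int,
    n_subjects: int = 24,
    n_trials: int = 40,
    gait_amp: float = 0.3,
    step_amp: float = 1.0,
    gamma: float = 1.5,
    gait: float = 1.0,
    step: float = 2.0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Label rates for the additive-model test across simulated cohorts.

    Each cohort carries the generative structure AV_gait = gamma * (A + V)
    and AV_step = A + V, with A = V = ``gait_amp`` at the gait frequency and
    ``step_amp`` at the step frequency (the step-cycle response is the
    stronger one, as in the recorded data); returns the fraction of cohorts
    labeled super-additive at the gait bin and additive at the step bin.
    Noise and subject-variability parameters are the SimConfig defaults.
    """
    topo = np.ones(montage.n_channels)
    ss = np.random.SeedSequence(seed)
    n_super = n_additive = 0
    for cohort_seed in ss.generate_state(n_cohorts):
        cfg = SimConfig(n_subjects=n_subjects, fs=100.0, trial_duration=6.0 / gait,
                        pre_duration=0.0, n_trials_per_condition=n_trials,
                        superadditive_gamma=gamma, seed=int(cohort_seed % (2**31)))
        freqs = [gait, step]
        specs = [
            ConditionSpec("V", freqs, [gait_amp, step_amp], topo),
            ConditionSpec("A", freqs, [gait_amp, step_amp], topo),
            ConditionSpec("AV", freqs, [gamma * 2 * gait_amp, 2 * step_amp], topo),
        ]
        vals = _cohort_bin_values(cfg, specs, montage, gait, step)
        mode_gait = additive_classification(vals["AV"]["gait"], vals["A"]["gait"],
                                            vals["V"]["gait"], alpha=alpha)
        mode_step = additive_classification(vals["AV"]["step"], vals["A"]["step"],
                                            vals["V"]["step"], alpha=alpha)
        n_super += mode_gait.label == "super-additive"
        n_additive += mode_step.label == "additive"
    return {"superadditive_rate_gait": n_super / n_cohorts,
            "additive_rate_step": n_additive / n_cohorts}


def cluster_recovery_rate(
    n_cohorts: int,
    montage: Montage,
    target_labels,
    seed: int,
    n_subjects: int = 24,
    boost: float = 0.2,
    noise_sd: float = 0.25,
    n_perm: int = 500,
    min_overlap: int = 5,
    alpha: float = 0.05,
) -> float:
    """Fraction of cohorts in which the cluster test recovers the seeded effect.

    Success requires a significant positive cluster overlapping at least
    ``min_overlap`` of the seeded electrodes.
    """
    ss = np.random.SeedSequence(seed)
    targets = set(target_labels)
    hits = 0
    for s in ss.generate_state(n_cohorts * 2).reshape(n_cohorts, 2):
        up, inv = simulate_effect_matrices(n_subjects, montage, list(targets),
                                           boost, noise_sd, seed=int(s[0] % (2**31)))
        res = cluster_permutation_interaction(up, inv, montage, n_perm=n_perm,
                                              seed=int(s[1] % (2**31)))
        for c in res.clusters:
            if c.p < alpha and c.polarity == "positive" \
                    and len(targets & set(c.electrodes)) >= min_overlap:
                hits += 1
                break
    return hits / n_cohorts


def null_cluster_false_positive_rate(
    n_cohorts: int,
    montage: Montage,
    seed: int,
    n_subjects: int = 12,
    n_perm: int = 250,
    alpha: float = 0.05,
    min_neighbors: int = 0,
) -> float:
    """Fraction of pure-noise cohorts yielding any cluster with p < alpha.

    With ``min_neighbors=0`` (default here) this measures the exactness of
    the max-statistic sign-flip machinery, whose false-positive rate should
    sit at the nominal level.  The operational retention rule
    (``min_neighbors=2``) suppresses cluster formation on sparse montages and
    is deliberately conservative, so its rate falls well below the level.
    """
    ss = np.random.SeedSequence(seed)
    false_pos = 0
    n_e = montage.n_channels
    for s in ss.generate_state(n_cohorts * 2).reshape(n_cohorts, 2):
        rng = np.random.default_rng(int(s[0] % (2**31)))
        up = rng.standard_normal((n_subjects, n_e))
        inv = rng.standard_normal((n_subjects, n_e))
        res = cluster_permutation_interaction(up, inv, montage, n_perm=n_perm,
                                              min_neighbors=min_neighbors,
                                              seed=int(s[1] % (2**31)))
        false_pos += any(c.p < alpha for c in res.clusters)
    return false_pos / n_cohorts


def fdr_false_discovery_proportion(
    n_sims: int,
    seed: int,
    n_subjects: int = 24,
    n_bins: int = 64,
    n_signal_bins: int = 8,
    effect: float = 1.5,
    alpha: float = 0.05,
) -> float:
    """Mean empirical false-discovery proportion of the peak test (partial null).

    Each simulation draws subjects x bins standard-normal values, adds
    ``effect`` to the first ``n_signal_bins`` bins, applies the right-tailed
    FDR-corrected peak test, and computes the fraction of discoveries that
    fall on null bins; Benjamini-Hochberg bounds its mean by
    alpha * (n_null / n_bins).
    """
    rng = np.random.default_rng(seed)
    freqs = np.arange(n_bins) / 12.0
    signal = np.zeros(n_bins)
    signal[:n_signal_bins] = effect
    fdps = np.empty(n_sims)
    for i in range(n_sims):
        values = rng.standard_normal((n_subjects, n_bins)) + signal
        res = peak_ttest_fdr(values, freqs, f_max=np.inf, alpha=alpha)
        n_disc = res.q_significant.sum()
        n_false = res.q_significant[n_signal_bins:].sum()
        fdps[i] = n_false / n_disc if n_disc else 0.0
    return float(fdps.mean())
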