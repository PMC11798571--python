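"""End-to-end experiment reproductions: config -> synthetic cohort -> report.

Three designs are modeled.  Experiments 1a/1b present visual (V), auditory
(A), and audiovisual (AV) rhythmic walking stimuli (gait cycle at 1 Hz or
0.83 Hz, step cycle at twice that) and ask whether the cortical tracking
response in AV exceeds each unisensory response and the additive sum A+V.
Experiment 2 crosses audiovisual congruency (congruent vs incongruent
footstep sounds) with stimulus orientation (upright vs inverted walker); the
congruency effect's upright-minus-inverted difference is tested over
electrodes with a cluster-based permutation test and correlated with AQ.

Synthetic amplitudes implement the generative structure the analysis is
meant to detect: AV gait-frequency amplitude = gamma * (A + V) with
gamma > 1 (super-additive), AV step-frequency amplitude = A + V (additive),
and in Experiment 2 a congruency boost at the gait frequency confined to
upright stimuli over right centro-parietal channels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .montage import Montage, make_montage
from .preprocess import (PIPELINE_ORDER, average_trials, bandpass_filter,
                         crop_analysis_window, rereference_mastoids, resample)
from .spectral import amplitude_spectrum, freq_to_bin, normalize_spectrum
from .stats import (additive_classification, cluster_permutation_interaction,
                    congruency_effect, median_split_compare, paired_contrast,
                    peak_ttest_fdr, pearson_outlier_removed)
from .synth import (ConditionSpec, SimConfig, gaussian_topography,
                    simulate_aq_scores, simulate_cohort)

#: Centro-parietal electrodes carrying the simulated BM-specific boost,
#: mirroring the reported right-hemisphere cluster.
BM_CLUSTER_LABELS = ("C2", "CPZ", "CP2", "CP4", "CP6", "PZ", "P2", "P4", "P6")


@dataclass
class ExperimentConfig:
    """Parameters of one experiment reproduction.

    Physical invariants are enforced on construction: the step frequency is
    twice the gait frequency and the stimulus lasts six gait cycles.
    Amplitudes are in microvolt (sinusoid peak amplitude before windowing).
    """

    experiment: str = "exp1a"            # exp1a | exp1b | exp2
    gait_freq: float = 1.0
    step_freq: float = 2.0
    stimulus_duration: float = 6.0
    n_subjects: int = 24
    n_trials_per_condition: int = 40
    catch_min: int = 10
    catch_max: int = 15
    fs: float = 100.0
    # unisensory amplitudes feeding the additive structure
    v_gait_amp: float = 0.3
    a_gait_amp: float = 0.3
    v_step_amp: float = 1.0
    a_step_amp: float = 1.0
    harmonic_amp: float = 0.5            # at 2 x step frequency, per modality
    superadditive_gamma: float = 1.5
    # experiment 2 effect structure
    congruency_boost_gait: float = 0.4   # upright-only, BM cluster topography
    congruency_boost_step: float = 0.3   # both orientations, broad topography
    boost_sd: float = 0.15               # between-subject SD of the gait boost
    incongruent_amp: float = 0.3
    aq_rho: float = -0.5
    # noise / subject variability
    noise_alpha: float = 1.0
    noise_sd: float = 2.5
    white_sd: float = 1.0
    subject_gain_sd: float = 0.2
    condition_gain_sd: float = 0.15
    # preprocessing
    band_low: float = 0.1
    band_high: float = 30.0
    fs_analysis: float = 100.0
    # spectral / stats
    n_fft: int = 1200
    window: str = "hann"
    k_neighbors: int = 2
    f_max: float = 5.33
    alpha: float = 0.05
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    min_neighbors: int = 2
    neighbor_radius: float = 0.5
    channel_subset: list[str] | None = None   # scalp subset for scaled-down runs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1a", "exp1b", "exp2"):
            raise ConfigurationError(f"unknown experiment {self.experiment!r}")
        if not np.isclose(self.step_freq, 2.0 * self.gait_freq):
            raise ConfigurationError("step_freq must equal 2 x gait_freq")
        if not np.isclose(self.stimulus_duration, 6.0 / self.gait_freq):
            raise ConfigurationError("stimulus_duration must equal six gait cycles")

    @classmethod
    def exp1a(cls, **overrides) -> "ExperimentConfig":
        return cls(experiment="exp1a", gait_freq=1.0, step_freq=2.0,
                   stimulus_duration=6.0, **overrides)

    @classmethod
    def exp1b(cls, **overrides) -> "ExperimentConfig":
        # 0.83 Hz gait = 10/12 Hz, exactly on the 1/12 Hz analysis grid
        return cls(experiment="exp1b", gait_freq=10.0 / 12.0, step_freq=20.0 / 12.0,
                   stimulus_duration=7.2, **overrides)

    @classmethod
    def exp2(cls, **overrides) -> "ExperimentConfig":
        return cls(experiment="exp2", gait_freq=1.0, step_freq=2.0,
                   stimulus_duration=6.0, **overrides)

    @property
    def cycle_duration(self) -> float:
        return 1.0 / self.gait_freq

    @property
    def harmonic_freq(self) -> float:
        return 2.0 * self.step_freq

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects=self.n_subjects, fs=self.fs,
            trial_duration=self.stimulus_duration, pre_duration=1.0,
            n_trials_per_condition=self.n_trials_per_condition,
            noise_alpha=self.noise_alpha, noise_sd=self.noise_sd,
            white_sd=self.white_sd, subject_gain_sd=self.subject_gain_sd,
            condition_gain_sd=self.condition_gain_sd,
            superadditive_gamma=self.superadditive_gamma,
            aq_rho=self.aq_rho, seed=self.seed)


def _snap(freq: float, resolution: float = 1.0 / 12.0) -> float:
    """Snap a nominal frequency to the nearest analysis-grid bin center."""
    return round(freq / resolution) * resolution


def analysis_montages(config: ExperimentConfig) -> tuple[Montage, Montage]:
    """(simulation montage incl. mastoids, analysis montage of scalp channels)."""
    full = make_montage(64, neighbor_radius=config.neighbor_radius)
    scalp = [l for l in full.labels if l not in ("M1", "M2", "CB1", "CB2")]
    if config.channel_subset is not None:
        scalp = list(config.channel_subset)
    sim = full.subset(scalp + ["M1", "M2"])
    return sim, full.subset(scalp)


def exp1_condition_specs(config: ExperimentConfig, sim_montage: Montage) -> list[ConditionSpec]:
    """V / A / AV specs with the additive structure at step and 2 x step and the
    super-additive gamma applied to the AV gait amplitude."""
    gait = _snap(config.gait_freq)
    step = _snap(config.step_freq)
    harm = _snap(config.harmonic_freq)
    freqs = [gait, step, harm]
    broad = gaussian_topography(sim_montage, "CZ", width=1.2)
    g = config.superadditive_gamma
    amps = {
        "V": [config.v_gait_amp, config.v_step_amp, config.harmonic_amp],
        "A": [config.a_gait_amp, config.a_step_amp, config.harmonic_amp],
        "AV": [g * (config.v_gait_amp + config.a_gait_amp),
               config.v_step_amp + config.a_step_amp,
               2 * config.harmonic_amp],
    }
    return [ConditionSpec(name=name, component_freqs=freqs, component_amps=a,
                          topography=broad) for name, a in amps.items()]


def exp2_condition_specs(
    config: ExperimentConfig, sim_montage: Montage, rng: np.random.Generator
) -> tuple[list[ConditionSpec], np.ndarray]:
    """Six condition specs (congruency x orientation) and the per-subject
    ground-truth BM-specific gait boost (microvolt, pre-windowing scale)."""
    gait = _snap(config.gait_freq)
    step = _snap(config.step_freq)
    slow = _snap(0.6)    # incongruent sound rates snapped to the grid
    fast = _snap(1.4)
    broad = gaussian_topography(sim_montage, "CZ", width=1.2)
    bm_topo = gaussian_topography(sim_montage, "CP2", width=0.45)
    n = config.n_subjects
    boost = np.clip(rng.normal(config.congruency_boost_gait, config.boost_sd, n), 0.0, None)

    base_gait = config.v_gait_amp + config.a_gait_amp
    base_step = config.v_step_amp + config.a_step_amp
    step_boost = config.congruency_boost_step

    def spec(name, freqs, amps, topos):
        return ConditionSpec(name=name, component_freqs=freqs, component_amps=amps,
                             topography=topos)

    specs = []
    # congruent-upright: gait boost (subject-varying, BM topography) + step boost
    amps_cu = np.column_stack([
        np.full(n, base_gait), boost,
        np.full(n, base_step + step_boost),
    ])
    specs.append(spec("AV-congruent-upright", [gait, gait, step],
                      amps_cu, np.vstack([broad, bm_topo, broad])))
    specs.append(spec("AV-congruent-inverted", [gait, step],
                      [base_gait, base_step + step_boost], np.vstack([broad, broad])))
    for orient in ("upright", "inverted"):
        specs.append(spec(f"AV-incongruent-fast-{orient}", [gait, step, fast],
                          [base_gait, base_step, config.incongruent_amp],
                          np.vstack([broad, broad, broad])))
        specs.append(spec(f"AV-incongruent-slow-{orient}", [gait, step, slow],
                          [base_gait, base_step, config.incongruent_amp],
                          np.vstack([broad, broad, broad])))
    return specs, boost


# --------------------------------------------------------------------------
# per-subject processing chain
# --------------------------------------------------------------------------

def _process_subject(rec, config: ExperimentConfig, schedule):
    """filter -> resample -> re-reference -> crop -> average -> spectra."""
    rec = bandpass_filter(rec, config.band_low, config.band_high)
    rec = resample(rec, config.fs_analysis)
    rec = rereference_mastoids(rec)
    rec = crop_analysis_window(rec, config.cycle_duration)
    evoked = average_trials(rec, exclude_catch=schedule is not None, schedule=schedule)
    spec = amplitude_spectrum(evoked, n_fft=config.n_fft, window=config.window)
    return spec, normalize_spectrum(spec, k=config.k_neighbors)


def _norm_amplitudes(cohort, config, schedules):
    """Normalized spectra for every subject x condition.

    Returns (freqs, valid, {condition: subjects x channels x bins}, labels).
    """
    per_cond: dict[str, list[np.ndarray]] = {}
    freqs = valid = labels = None
    for subject, conditions in cohort.items():
        for cond, rec in conditions.items():
            sched = schedules.get(cond) if schedules else None
            _, norm = _process_subject(rec, config, sched)
            per_cond.setdefault(cond, []).append(norm.amps)
            freqs, valid, labels = norm.freqs, norm.valid, norm.labels
    stacked = {c: np.stack(v) for c, v in per_cond.items()}
    return freqs, valid, stacked, labels


def _contrast_dict(c) -> dict:
    return {"t": c.t, "p": c.p, "d": c.d, "df": c.df, "mean_diff": c.mean_diff}


# --------------------------------------------------------------------------
# experiment runners
# --------------------------------------------------------------------------

def run_experiment1(config: ExperimentConfig) -> dict:
    """Simulate and analyze Experiment 1a/1b: peaks, contrasts, integration modes."""
    if config.experiment not in ("exp1a", "exp1b"):
        raise ConfigurationError("run_experiment1 requires exp1a or exp1b")
    sim_montage, _ = analysis_montages(config)
    specs = exp1_condition_specs(config, sim_montage)
    cohort = simulate_cohort(config.sim_config(), specs, sim_montage)
    # simulated trials are all experimental: catch trials carry no EEG
    # difference and would be excluded before averaging anyway
    freqs, valid, amps, _ = _norm_amplitudes(cohort, config, None)

    bins = {
        "gait": freq_to_bin_like(freqs, _snap(config.gait_freq)),
        "step": freq_to_bin_like(freqs, _snap(config.step_freq)),
        "harmonic": freq_to_bin_like(freqs, _snap(config.harmonic_freq)),
    }
    grand = {c: a.mean(axis=1) for c, a in amps.items()}  # subjects x bins

    peaks = {}
    for cond in ("V", "A", "AV"):
        res = peak_ttest_fdr(grand[cond], freqs, valid, f_max=config.f_max,
                             alpha=config.alpha)
        peaks[cond] = {
            "significant_freqs": [float(f) for f in res.significant_freqs],
            "t_at": {k: float(res.t[b]) for k, b in bins.items()},
            "p_at": {k: float(res.p[b]) for k, b in bins.items()},
            "significant_at": {k: bool(res.q_significant[b]) for k, b in bins.items()},
        }

    contrasts, integration = {}, {}
    for scale, b in bins.items():
        av, a, v = grand["AV"][:, b], grand["A"][:, b], grand["V"][:, b]
        mode = additive_classification(av, a, v, alpha=config.alpha)
        integration[scale] = {"label": mode.label, "contrast": _contrast_dict(mode.contrast)}
        contrasts[scale] = {
            "AV_vs_V": _contrast_dict(paired_contrast(av, v)),
            "AV_vs_A": _contrast_dict(paired_contrast(av, a)),
            "AV_vs_A_plus_V": _contrast_dict(mode.contrast),
        }

    return {
        "experiment": config.experiment,
        "provenance": _provenance(config),
        "bins": {k: int(v) for k, v in bins.items()},
        "frequencies": {"gait": _snap(config.gait_freq), "step": _snap(config.step_freq),
                        "harmonic": _snap(config.harmonic_freq)},
        "peaks": peaks,
        "contrasts": contrasts,
        "integration": integration,
    }


def freq_to_bin_like(freqs: np.ndarray, f: float) -> int:
    """freq_to_bin for a bare frequency grid (uniform spacing assumed)."""
    class _G:
        pass
    g = _G()
    g.freqs = freqs
    g.resolution = float(freqs[1] - freqs[0])
    return freq_to_bin(g, f)


def run_experiment2(config: ExperimentConfig) -> dict:
    """Simulate and analyze Experiment 2: congruency x orientation and AQ link."""
    if config.experiment != "exp2":
        raise ConfigurationError("run_experiment2 requires exp2")
    sim_montage, analysis_montage = analysis_montages(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    specs, boost = exp2_condition_specs(config, sim_montage, rng)
    cohort = simulate_cohort(config.sim_config(), specs, sim_montage)
    freqs, valid, amps, labels = _norm_amplitudes(cohort, config, None)
    assert labels == analysis_montage.labels

    bins = {"gait": freq_to_bin_like(freqs, _snap(config.gait_freq)),
            "step": freq_to_bin_like(freqs, _snap(config.step_freq))}

    # ground-truth per-subject effect drives AQ (generator side)
    aq_table = simulate_aq_scores(boost, rho=config.aq_rho,
                                  seed=int(rng.integers(2**31)))

    report: dict = {
        "experiment": "exp2",
        "provenance": _provenance(config),
        "bins": {k: int(v) for k, v in bins.items()},
        "subjects": aq_table.to_dict(orient="list"),
        "cluster_tests": {}, "congruency": {}, "aq": {},
    }

    effects = {}
    for scale, b in bins.items():
        eff = {}
        for orient in ("upright", "inverted"):
            eff[orient] = congruency_effect(
                amps[f"AV-congruent-{orient}"][:, :, b],
                [amps[f"AV-incongruent-fast-{orient}"][:, :, b],
                 amps[f"AV-incongruent-slow-{orient}"][:, :, b]])
        effects[scale] = eff
        res = cluster_permutation_interaction(
            eff["upright"], eff["inverted"], analysis_montage,
            n_perm=config.n_perm, cluster_alpha=config.cluster_alpha,
            min_neighbors=config.min_neighbors,
            seed=int(rng.integers(2**31)))
        report["cluster_tests"][scale] = {
            "clusters": [{"electrodes": list(c.electrodes), "stat": c.stat,
                          "p": c.p, "polarity": c.polarity} for c in res.clusters],
            "n_permutations": res.n_permutations,
        }

    sig = [c for c in report["cluster_tests"]["gait"]["clusters"]
           if c["p"] < config.alpha and c["polarity"] == "positive"]
    if sig:
        members = [analysis_montage.index(l) for l in sig[0]["electrodes"]]
        report["cluster_tests"]["gait"]["selected_electrodes"] = sig[0]["electrodes"]
        for scale in ("gait", "step"):
            block = {}
            for orient in ("upright", "inverted"):
                within = effects[scale][orient][:, members].mean(axis=1)
                block[orient] = _contrast_dict(paired_contrast(within, np.zeros_like(within)))
            report["congruency"][scale] = block
        bm_effect = (effects["gait"]["upright"][:, members].mean(axis=1)
                     - effects["gait"]["inverted"][:, members].mean(axis=1))
        bm_effect_2hz = (effects["step"]["upright"][:, members].mean(axis=1)
                         - effects["step"]["inverted"][:, members].mean(axis=1))
        aq = aq_table["aq_score"].to_numpy(float)
        for scale, eff in (("gait", bm_effect), ("step", bm_effect_2hz)):
            corr = pearson_outlier_removed(aq, eff)
            split = median_split_compare(aq, eff)
            report["aq"][scale] = {
                "pearson": {"r": corr.r, "p": corr.p, "n_used": corr.n_used,
                            "n_removed_outliers": corr.n_removed_outliers},
                "median_split": {"t": split.t, "p": split.p,
                                 "mean_low_aq": split.mean_low,
                                 "mean_high_aq": split.mean_high},
            }
    else:
        report["cluster_tests"]["gait"]["selected_electrodes"] = []
    return report


def _provenance(config: ExperimentConfig) -> dict:
    cfg = asdict(config)
    return {"config": cfg, "seed": config.seed, "version": __version__,
            "pipeline_order": list(PIPELINE_ORDER)}


def save_report(report: dict, out_dir) -> Path:
    """Write report.json (sorted keys, reproducible bytes) plus CSV companions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    if "contrasts" in report:
        rows = [{"scale": s, "contrast": name, **vals}
                for s, block in report["contrasts"].items()
                for name, vals in block.items()]
        pd.DataFrame(rows).to_csv(out / "contrasts.csv", index=False)
    if "subjects" in report:
        pd.DataFrame(report["subjects"]).to_csv(out / "subjects.csv", index=False)
    return path
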