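"""Synthetic EEG cohort generation for frequency-tagging analyses.

This module produces multi-subject, multi-condition epoched EEG with the
statistical structure the downstream analysis assumes: phase-locked sinusoidal
components at the gait-cycle and step-cycle frequencies (and harmonics)
embedded in 1/f ("pink") plus white background noise, with per-channel
topographic gains, per-subject multiplicative gain variability, randomized
trial schedules with catch trials, and Autism-Spectrum Quotient (AQ) scores
correlated with a ground-truth per-subject effect.

Everything is reproducible from explicit integer seeds: the same
``SimConfig`` yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .montage import Montage
from .preprocess import EpochedRecording


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class ConditionSpec:
    """Deterministic signal content of one stimulation condition.

    ``component_amps`` may be a vector (one amplitude in microvolt per
    component frequency, shared by all subjects) or an (n_subjects, n_freqs)
    array when an effect must vary across subjects (e.g. an individual
    congruency boost tied to AQ).  ``topography`` may be a single per-channel
    gain vector in [0, 1] or one such vector per component frequency.
    """

    name: str
    component_freqs: np.ndarray
    component_amps: np.ndarray
    topography: np.ndarray
    phase_locked: bool = True

    def __post_init__(self) -> None:
        self.component_freqs = np.atleast_1d(np.asarray(self.component_freqs, float))
        self.component_amps = np.asarray(self.component_amps, float)
        self.topography = np.atleast_1d(np.asarray(self.topography, float))
        if (self.component_freqs <= 0).any():
            raise ConfigurationError(f"{self.name}: component frequencies must be > 0")
        if (self.component_amps < 0).any():
            raise ConfigurationError(f"{self.name}: amplitudes must be >= 0")
        if (self.topography < 0).any() or (self.topography > 1).any():
            raise ConfigurationError(f"{self.name}: topography gains must lie in [0, 1]")

    def validate_against(self, n_channels: int, n_subjects: int) -> None:
        nf = self.component_freqs.size
        if self.component_amps.ndim == 1:
            if self.component_amps.size != nf:
                raise ConfigurationError(f"{self.name}: one amplitude per frequency required")
        elif self.component_amps.shape != (n_subjects, nf):
            raise ConfigurationError(
                f"{self.name}: per-subject amplitudes must be (n_subjects, n_freqs)")
        topo = np.atleast_2d(self.topography)
        if topo.shape not in ((1, n_channels), (nf, n_channels)):
            raise ConfigurationError(
                f"{self.name}: topography must have {n_channels} channels "
                "(one vector, or one per component)")

    def topography_matrix(self, n_channels: int) -> np.ndarray:
        """Per-component topography as an (n_freqs, n_channels) matrix."""
        topo = np.atleast_2d(self.topography)
        if topo.shape[0] == 1:
            topo = np.repeat(topo, self.component_freqs.size, axis=0)
        return topo

    def amps_for_subject(self, subject_index: int) -> np.ndarray:
        if self.component_amps.ndim == 1:
            return self.component_amps
        return self.component_amps[subject_index]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions of the experiments modeled here:
    24 subjects, 6 s stimulation preceded by 1 s pre-stimulus baseline,
    100 Hz sampling, 40 experimental trials per condition, pink (1/f) noise
    of 2.5 microvolt SD plus 1 microvolt white noise, lognormal per-subject
    gain with sigma 0.2 (plus an independent per-condition gain jitter of
    sigma 0.15 emulating block-to-block SNR drift), a super-additive gain of
    1.5 at the gait frequency, and an AQ correlation of -0.5 with the
    ground-truth effect.
    """

    n_subjects: int = 24
    fs: float = 100.0
    trial_duration: float = 6.0
    pre_duration: float = 1.0
    n_trials_per_condition: int = 40
    noise_alpha: float = 1.0
    noise_sd: float = 2.5
    white_sd: float = 1.0
    subject_gain_sd: float = 0.2
    condition_gain_sd: float = 0.15
    superadditive_gamma: float = 1.5
    aq_rho: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.fs <= 0 or self.trial_duration <= 0:
            raise ConfigurationError("fs and trial_duration must be > 0")
        if self.superadditive_gamma <= 0:
            raise ConfigurationError("superadditive_gamma must be > 0")
        if abs(self.aq_rho) > 1:
            raise ConfigurationError("|aq_rho| must be <= 1")
        if self.noise_alpha < 0:
            raise ConfigurationError("noise_alpha must be >= 0")


@dataclass
class TrialInfo:
    condition: str
    is_catch: bool
    n_color_changes: int


@dataclass
class Schedule:
    """Ordered trial list with catch-trial bookkeeping."""

    trials: list[TrialInfo] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_catch(self) -> int:
        return sum(t.is_catch for t in self.trials)

    @property
    def catch_fraction(self) -> float:
        return self.n_catch / len(self.trials) if self.trials else 0.0

    @property
    def is_catch(self) -> np.ndarray:
        return np.array([t.is_catch for t in self.trials], dtype=bool)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def pink_noise(
    n_samples: int,
    alpha: float = 1.0,
    sd: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Zero-mean 1/f^alpha noise with exact sample SD ``sd``.

    Generated by spectral shaping: white Gaussian noise is filtered in the
    frequency domain with gain f^(-alpha/2) (DC removed), inverse
    transformed, then rescaled trace-by-trace to the requested SD.  With
    ``alpha=0`` this reduces to white noise.  ``size`` prepends batch axes,
    e.g. ``size=(trials, channels)``.
    """
    if n_samples <= 1:
        raise ConfigurationError("n_samples must be > 1")
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    shape = tuple(size) + (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x * (sd / s)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig,
    specs: Sequence[ConditionSpec],
    montage: Montage,
) -> dict[str, dict[str, EpochedRecording]]:
    """Simulate an epoched EEG cohort: subject -> condition -> recording.

    Each trial is ``sum_f amp * topo * sin(2 pi f t + phi_f)`` during the
    stimulation window plus pink and white noise over the whole epoch
    (including the pre-stimulus second).  The signal phase ``phi_f`` is drawn
    once per subject and frequency and reused across trials and conditions,
    so trial averaging preserves the phase-locked component.  A per-subject
    multiplicative gain ``lognormal(0, subject_gain_sd)`` scales all signal
    components, and an independent per-condition jitter
    ``lognormal(0, condition_gain_sd)`` emulates block-to-block SNR drift.
    """
    n_ch = montage.n_channels
    for spec in specs:
        spec.validate_against(n_ch, config.n_subjects)
        if spec.component_freqs.max() >= config.fs / 2:
            raise ConfigurationError(
                f"{spec.name}: component frequency at or above Nyquist ({config.fs / 2} Hz)")

    fs = config.fs
    n_pre = int(round(config.pre_duration * fs))
    n_stim = int(round(config.trial_duration * fs))
    n_total = n_pre + n_stim
    t = np.arange(n_stim) / fs
    all_freqs = np.unique(np.concatenate([s.component_freqs for s in specs]))

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    cohort: dict[str, dict[str, EpochedRecording]] = {}
    for si in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[si])
        gain = float(rng.lognormal(mean=0.0, sigma=config.subject_gain_sd))
        phases = dict(zip(all_freqs, rng.uniform(0.0, 2 * np.pi, size=all_freqs.size)))
        conditions: dict[str, EpochedRecording] = {}
        for spec in specs:
            amps = spec.amps_for_subject(si)
            topo = spec.topography_matrix(n_ch)
            cond_gain = float(rng.lognormal(mean=0.0, sigma=config.condition_gain_sd)) \
                if config.condition_gain_sd > 0 else 1.0
            # (channels, samples) phase-locked signal for the stimulus window
            sig = np.zeros((n_ch, n_stim))
            for f_hz, amp, tp in zip(spec.component_freqs, amps, topo):
                if amp == 0.0:
                    continue
                sig += (gain * cond_gain * amp) * np.outer(
                    tp, np.sin(2 * np.pi * f_hz * t + phases[f_hz]))
            n_trials = config.n_trials_per_condition
            data = np.zeros((n_trials, n_ch, n_total))
            data[:, :, n_pre:] = sig
            if config.noise_sd > 0:
                data += pink_noise(n_total, config.noise_alpha, config.noise_sd,
                                   rng=rng, size=(n_trials, n_ch))
            if config.white_sd > 0:
                data += config.white_sd * rng.standard_normal((n_trials, n_ch, n_total))
            conditions[spec.name] = EpochedRecording(
                data=data, fs=fs, labels=list(montage.labels),
                t0=-config.pre_duration)
        cohort[f"sub-{si + 1:02d}"] = conditions
    return cohort


# --------------------------------------------------------------------------
# trial schedules
# --------------------------------------------------------------------------

def generate_trial_schedule(
    n_experimental: int | Mapping[str, int],
    catch_min: int,
    catch_max: int,
    seed: int | None = None,
) -> Schedule:
    """Randomized trial order with a uniform catch-trial count.

    ``n_experimental`` is either a single count (all trials share the label
    ``"experimental"``) or a mapping of condition label to count, as in the
    congruent / incongruent-fast / incongruent-slow blocks.  The number of
    catch trials is drawn uniformly from [catch_min, catch_max]; each catch
    trial carries one or two color changes, experimental trials carry none.
    """
    if isinstance(n_experimental, Mapping):
        counts = dict(n_experimental)
    else:
        counts = {"experimental": int(n_experimental)}
    if any(c < 0 for c in counts.values()):
        raise ConfigurationError("experimental trial counts must be >= 0")
    if not (0 <= catch_min <= catch_max):
        raise ConfigurationError("need 0 <= catch_min <= catch_max")
    rng = np.random.default_rng(seed)
    n_catch = int(rng.integers(catch_min, catch_max + 1))
    labels = [lbl for lbl, c in counts.items() for _ in range(c)]
    trials = [TrialInfo(lbl, False, 0) for lbl in labels]
    catch_labels = rng.choice(list(counts), size=n_catch) if counts else []
    trials += [TrialInfo(str(lbl), True, int(rng.integers(1, 3))) for lbl in catch_labels]
    order = rng.permutation(len(trials))
    return Schedule(trials=[trials[i] for i in order])


# --------------------------------------------------------------------------
# covariates and effect-level simulation
# --------------------------------------------------------------------------

def simulate_aq_scores(
    effects: Sequence[float],
    rho: float,
    seed: int | None = None,
    mean: float = 20.0,
    sd: float = 7.0,
) -> pd.DataFrame:
    """AQ scores with target correlation ``rho`` to a per-subject effect.

    The latent score is ``rho * z(effect) + sqrt(1 - rho^2) * noise``; an
    affine map to the instrument scale (default mean 20, SD 7) is rounded to
    integers and clipped to the AQ range [0, 50].  Returns a table with
    columns ``subject_id``, ``aq_score``, ``simulated_effect``.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size < 3:
        raise ConfigurationError("need at least 3 subjects")
    if abs(rho) > 1:
        raise ConfigurationError("|rho| must be <= 1")
    e_sd = effects.std(ddof=0)
    if e_sd == 0 and rho != 0:
        raise DataError("effects have zero variance; correlation undefined")
    z = (effects - effects.mean()) / (e_sd if e_sd > 0 else 1.0)
    rng = np.random.default_rng(seed)
    latent = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(effects.size)
    aq = np.clip(np.rint(mean + sd * latent), 0, 50).astype(int)
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:02d}" for i in range(effects.size)],
        "aq_score": aq,
        "simulated_effect": effects,
    })


def simulate_effect_matrices(
    n_subjects: int,
    montage: Montage,
    target_labels: Sequence[str],
    boost: float,
    noise_sd: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-by-electrode effect maps for cluster-test validation.

    Returns ``(effect_upright, effect_inverted)`` where the upright map
    carries ``boost`` (microvolt) on the target electrodes plus Gaussian
    between-subject noise of SD ``noise_sd`` on every electrode, and the
    inverted map is pure noise -- i.e. a spatially localized
    congruency-by-orientation interaction.
    """
    rng = np.random.default_rng(seed)
    n_e = montage.n_channels
    idx = [montage.index(l) for l in target_labels]
    upright = noise_sd * rng.standard_normal((n_subjects, n_e))
    upright[:, idx] += boost
    inverted = noise_sd * rng.standard_normal((n_subjects, n_e))
    return upright, inverted


def gaussian_topography(montage: Montage, center_label: str, width: float = 0.8) -> np.ndarray:
    """Per-channel gain in [0, 1]: Gaussian in arc distance from a center electrode."""
    center = montage.positions[montage.index(center_label)]
    cosang = np.clip(montage.positions @ center, -1.0, 1.0)
    arc = np.arccos(cosang)
    return np.exp(-0.5 * (arc / width) ** 2)
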