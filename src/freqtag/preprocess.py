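"""Deterministic preprocessing from epoched EEG to per-condition averages.

The fixed pipeline order is: band-pass filter -> resample -> epoch ->
(artifact hook) -> mastoid re-reference -> crop to the analysis window ->
trial average.  All steps are linear, so phase-locked signal components
survive averaging unchanged.

Filtering uses a zero-phase forward-backward 4th-order Butterworth (the band
edges are the scientific parameters; zero phase preserves the phase-locked
components that trial averaging relies on).  Resampling is polyphase with an
exact rational factor, so a 1000 -> 100 Hz conversion introduces no drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataError

#: Canonical stage order; echoed into pipeline reports.
PIPELINE_ORDER = (
    "bandpass_filter", "resample", "segment_epochs", "artifact_hook",
    "rereference_mastoids", "crop_analysis_window", "average_trials",
)


@dataclass
class EpochedRecording:
    """Trials x channels x samples (microvolt) with sampling metadata."""

    data: np.ndarray
    fs: float
    labels: list[str]
    t0: float = 0.0  # seconds of first sample relative to stimulus onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        if self.data.ndim != 3:
            raise DataError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.labels):
            raise DataError("labels must match the channel dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(self.data.copy(), self.fs, list(self.labels), self.t0)


@dataclass
class Evoked:
    """Trial-averaged channels x samples waveform."""

    data: np.ndarray
    fs: float
    labels: list[str]
    t0: float
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.n_trials_averaged < 1:
            raise DataError("n_trials_averaged must be >= 1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise DataError("data must be channels x samples matching labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass_filter(rec: EpochedRecording, low: float, high: float) -> EpochedRecording:
    """Zero-phase Butterworth band-pass between ``low`` and ``high`` Hz.

    Realized as a cascade of high-pass (2nd-order) and low-pass (4th-order)
    sections, each applied forward-backward, so the passband phase is exactly
    zero and each edge rolls off at twice its section order.  The high-pass
    order is kept low because a 0.1 Hz cutoff sits so far below Nyquist that
    higher-order IIR sections become numerically ill-conditioned.
    """
    if not (0 <= low < high < rec.fs / 2):
        raise ConfigurationError(f"invalid band [{low}, {high}] for fs={rec.fs}")
    out = rec.data
    if low > 0:
        sos_hp = signal.butter(2, low, btype="highpass", fs=rec.fs, output="sos")
        out = signal.sosfiltfilt(sos_hp, out, axis=-1)
    sos_lp = signal.butter(4, high, btype="lowpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos_lp, out, axis=-1)
    return EpochedRecording(out, rec.fs, rec.labels, rec.t0)


def resample(rec: EpochedRecording, fs_target: float) -> EpochedRecording:
    """Polyphase down-sampling to ``fs_target`` (upsampling is rejected)."""
    if fs_target > rec.fs:
        raise ConfigurationError("upsampling not supported")
    if fs_target == rec.fs:
        return rec.copy()
    frac = Fraction(int(round(fs_target * 1_000_000)), int(round(rec.fs * 1_000_000)))
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return EpochedRecording(out, fs_target, rec.labels, rec.t0)


def segment_epochs(
    continuous: np.ndarray,
    onsets: Sequence[int],
    pre: float,
    post: float,
    fs: float,
    labels: Sequence[str],
) -> EpochedRecording:
    """Cut a channels x samples recording into onset-locked epochs.

    Each epoch spans ``[-pre, +post]`` seconds around its onset sample and is
    an independent copy (overlapping epochs do not alias each other).
    """
    continuous = np.asarray(continuous, dtype=float)
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_win = n_pre + n_post
    trials = []
    for onset in onsets:
        start, stop = int(onset) - n_pre, int(onset) + n_post
        if start < 0 or stop > continuous.shape[1]:
            raise DataError(f"epoch window for onset {onset} exceeds recording bounds")
        trials.append(continuous[:, start:stop].copy())
    data = (np.stack(trials) if trials
            else np.empty((0, continuous.shape[0], n_win)))
    return EpochedRecording(data, fs, list(labels), t0=-pre)


def crop_analysis_window(rec: EpochedRecording, cycle_duration: float) -> EpochedRecording:
    """Drop the pre-stimulus segment and the first stimulus cycle.

    The retained window runs from ``+cycle_duration`` (relative to stimulus
    onset) to the end of the epoch (the stimulus offset), excluding
    onset-evoked transients from the spectral decomposition.
    """
    if cycle_duration < 0:
        raise ConfigurationError("cycle_duration must be >= 0")
    start = int(round((cycle_duration - rec.t0) * rec.fs))
    if start >= rec.n_samples:
        raise DataError("cycle_duration longer than the epoch")
    return EpochedRecording(rec.data[:, :, start:].copy(), rec.fs, rec.labels,
                            t0=cycle_duration)


def rereference_mastoids(
    rec: EpochedRecording, refs: tuple[str, str] = ("M1", "M2")
) -> EpochedRecording:
    """Subtract the average of the two mastoid channels; drop them from the output."""
    try:
        idx = [rec.labels.index(r) for r in refs]
    except ValueError as exc:
        raise DataError(f"reference channel missing: {exc}") from None
    ref = rec.data[:, idx, :].mean(axis=1, keepdims=True)
    keep = [i for i in range(len(rec.labels)) if i not in idx]
    out = rec.data[:, keep, :] - ref
    return EpochedRecording(out, rec.fs, [rec.labels[i] for i in keep], rec.t0)


def reject_trials(rec: EpochedRecording, keep_mask: Sequence[bool]) -> EpochedRecording:
    """Artifact hook: retain trials flagged True in an external rejection mask."""
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.shape != (rec.n_trials,):
        raise DataError("keep_mask must have one entry per trial")
    return EpochedRecording(rec.data[keep_mask].copy(), rec.fs, rec.labels, rec.t0)


def average_trials(
    rec: EpochedRecording,
    exclude_catch: bool = False,
    schedule=None,
    keep_mask: Sequence[bool] | None = None,
) -> Evoked:
    """Pointwise mean over retained trials.

    Catch trials (per the schedule) and externally rejected trials are
    excluded before averaging; averaging at least one trial is required.
    """
    keep = np.ones(rec.n_trials, dtype=bool)
    if exclude_catch:
        if schedule is None:
            raise ConfigurationError("exclude_catch requires a schedule")
        is_catch = schedule.is_catch
        if is_catch.shape != (rec.n_trials,):
            raise DataError("schedule length must match trial count")
        keep &= ~is_catch
    if keep_mask is not None:
        keep &= np.asarray(keep_mask, dtype=bool)
    if not keep.any():
        raise DataError("all trials excluded; nothing to average")
    return Evoked(rec.data[keep].mean(axis=0), rec.fs, rec.labels, rec.t0,
                  n_trials_averaged=int(keep.sum()))
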