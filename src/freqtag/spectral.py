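"""Amplitude spectra and neighbor-bin normalization.

The core cortical-tracking statistic: the trial-averaged waveform is Hann
windowed, zero padded, Fourier transformed, and the single-sided amplitude at
each bin is baseline-corrected by subtracting the mean amplitude of the k
neighboring bins on each side (k=2 by default).  The subtraction removes the
locally smooth 1/f background exactly (any linear trend cancels at interior
bins), so genuine response peaks can be tested against zero.

Amplitude convention: an on-bin unit sinusoid analyzed without a window reads
1.0.  The Hann window's coherent gain (0.5) is deliberately not compensated:
all reported quantities are differences or ratios of identically processed
amplitudes, for which a common scale factor is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import windows

from .errors import ConfigurationError, DataError
from .preprocess import Evoked


@dataclass
class AmplitudeSpectrum:
    """Single-sided channels x bins amplitude spectrum (microvolt)."""

    amps: np.ndarray
    freqs: np.ndarray
    resolution: float
    window: str
    n_fft: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amps = np.asarray(self.amps, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.amps.ndim != 2 or self.amps.shape[1] != self.freqs.size:
            raise DataError("amps must be channels x bins aligned with freqs")


@dataclass
class NormalizedSpectrum:
    """Neighbor-bin-corrected spectrum; edge bins lack neighbors and are invalid."""

    amps: np.ndarray
    freqs: np.ndarray
    resolution: float
    k_neighbors: int
    valid: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amps = np.asarray(self.amps, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def channel_mean(self) -> np.ndarray:
        """Grand average over channels (one value per bin)."""
        return self.amps.mean(axis=0)


def amplitude_spectrum(evoked: Evoked, n_fft: int = 1200, window: str = "hann") -> AmplitudeSpectrum:
    """Windowed, zero-padded FFT amplitude spectrum of an averaged waveform.

    ``n_fft`` must be at least the sample count; with fs = 100 Hz and
    n_fft = 1200 the bin spacing is 1/12 Hz, placing the gait (1 Hz, bin 12)
    and step (2 Hz, bin 24) frequencies exactly on bins.
    """
    n = evoked.n_samples
    if n_fft < n:
        raise ConfigurationError(f"n_fft ({n_fft}) must be >= sample count ({n})")
    if window == "hann":
        w = windows.hann(n, sym=False)
    elif window in ("none", "boxcar", None):
        window = "none"
        w = np.ones(n)
    else:
        raise ConfigurationError(f"unknown window {window!r}")
    spec = np.fft.rfft(evoked.data * w, n=n_fft, axis=-1)
    amps = np.abs(spec) * (2.0 / n)
    amps[:, 0] /= 2.0
    if n_fft % 2 == 0:
        amps[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / evoked.fs)
    return AmplitudeSpectrum(amps=amps, freqs=freqs, resolution=evoked.fs / n_fft,
                             window=window, n_fft=n_fft, labels=list(evoked.labels))


def normalize_spectrum(spec: AmplitudeSpectrum, k: int = 2) -> NormalizedSpectrum:
    """Subtract the mean amplitude of the k bins on each side of every bin.

    ``out[i] = amps[i] - mean(amps[i-k..i-1], amps[i+1..i+k])``; the first and
    last k bins have too few neighbors and are flagged invalid.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    n_bins = spec.freqs.size
    if n_bins < 2 * k + 1:
        raise ConfigurationError("spectrum too short for the requested neighborhood")
    kernel = np.full(2 * k + 1, 1.0 / (2 * k))
    kernel[k] = 0.0
    baseline = ndimage.convolve1d(spec.amps, kernel, axis=1, mode="constant")
    out = spec.amps - baseline
    valid = np.ones(n_bins, dtype=bool)
    valid[:k] = False
    valid[-k:] = False
    return NormalizedSpectrum(amps=out, freqs=spec.freqs, resolution=spec.resolution,
                              k_neighbors=k, valid=valid, labels=list(spec.labels))


def freq_to_bin(spec, f: float) -> int:
    """Nearest bin index for frequency ``f``; off-grid requests are rejected.

    The guard fires when ``f`` is farther than resolution/4 from the nearest
    bin center, preventing silent scalloping losses at off-bin frequencies.
    """
    freqs = np.asarray(spec.freqs)
    if not (freqs[0] <= f <= freqs[-1]):
        raise ConfigurationError(f"{f} Hz outside the spectrum range")
    idx = int(round((f - freqs[0]) / spec.resolution))
    idx = min(max(idx, 0), freqs.size - 1)
    if abs(f - freqs[idx]) > spec.resolution / 4:
        lo, hi = freqs[max(idx - 1, 0)], freqs[min(idx + 1, freqs.size - 1)]
        raise ConfigurationError(
            f"{f} Hz is off the spectral grid (nearest bins {lo:.4f}, "
            f"{freqs[idx]:.4f}, {hi:.4f} Hz)")
    return idx


def spectrum_to_frame(
    spec: AmplitudeSpectrum,
    norm: NormalizedSpectrum,
    subject: str,
    condition: str,
    f_max: float | None = None,
) -> pd.DataFrame:
    """Long-format export: subject, condition, channel, freq_hz, amp, normalized_amp."""
    sel = np.ones(spec.freqs.size, dtype=bool) if f_max is None else spec.freqs <= f_max
    rows = []
    for ci, ch in enumerate(spec.labels):
        rows.append(pd.DataFrame({
            "subject": subject, "condition": condition, "channel": ch,
            "freq_hz": spec.freqs[sel], "amp": spec.amps[ci, sel],
            "normalized_amp": norm.amps[ci, sel],
        }))
    return pd.concat(rows, ignore_index=True)
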