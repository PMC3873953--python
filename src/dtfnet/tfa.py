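"""Time-frequency analysis: STFT spectrograms and band peak features.

Spectrograms use a 500 ms Hamming window by default, one-sided density
(PSD) scaling, and 75% overlap.  Peak features are read off the
time-averaged spectrum inside a band; the dominance rule declares one
band's rhythm dominant when its peak power is more than twice the other's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Spectrogram",
    "stft_spectrogram",
    "average_spectrogram_over_channels",
    "peak_features",
    "dominance",
]


@dataclass
class Spectrogram:
    """One-sided PSD over time bins; power has shape (n_times, n_freqs)."""

    power: np.ndarray
    time_axis_s: np.ndarray
    freq_axis_hz: np.ndarray
    window_s: float
    n_channels_averaged: int = 1

    def time_averaged(self) -> np.ndarray:
        return self.power.mean(axis=0)


def stft_spectrogram(
    epoch: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    overlap_fraction: float = 0.75,
    time_offset_s: float = 0.0,
) -> Spectrogram:
    """Hamming-windowed one-sided PSD spectrogram of a single-channel epoch.

    ``time_offset_s`` shifts the time axis (e.g. minus the pre-event
    duration, so bins are relative to the behavioural event).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("stft_spectrogram expects a single channel (1-D)")
    nperseg = round(window_s * fs)
    if nperseg < 16:
        raise ValueError(f"window of {nperseg} samples is too short (need >= 16)")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if x.size < nperseg:
        raise ValueError(
            f"epoch of {x.size} samples is shorter than one {nperseg}-sample window"
        )
    noverlap = int(np.floor(overlap_fraction * nperseg))
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=fs,
        window=signal.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=noverlap,
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return Spectrogram(
        power=sxx.T,
        time_axis_s=times + time_offset_s,
        freq_axis_hz=freqs,
        window_s=window_s,
    )


def average_spectrogram_over_channels(spectrograms: Sequence[Spectrogram]) -> Spectrogram:
    """Element-wise mean over channels' spectrograms (axes must match)."""
    if not spectrograms:
        raise ValueError("need at least one spectrogram")
    ref = spectrograms[0]
    for s in spectrograms[1:]:
        if not (
            np.array_equal(s.freq_axis_hz, ref.freq_axis_hz)
            and np.array_equal(s.time_axis_s, ref.time_axis_s)
        ):
            raise ValueError("spectrogram axes differ; cannot average")
    mean_power = np.mean([s.power for s in spectrograms], axis=0)
    return Spectrogram(
        power=mean_power,
        time_axis_s=ref.time_axis_s.copy(),
        freq_axis_hz=ref.freq_axis_hz.copy(),
        window_s=ref.window_s,
        n_channels_averaged=len(spectrograms),
    )


def peak_features(spec: Spectrogram, band: tuple) -> tuple[float, float]:
    """(peak frequency Hz, peak power) of the time-averaged PSD in a band.

    Ties break toward the lower frequency (argmax returns the first hit on
    an ascending frequency axis).
    """
    low, high = band
    mask = (spec.freq_axis_hz >= low) & (spec.freq_axis_hz <= high)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency axis")
    avg = spec.time_averaged()[mask]
    freqs = spec.freq_axis_hz[mask]
    idx = int(np.argmax(avg))
    return float(freqs[idx]), float(avg[idx])


def dominance(peak_power_region_a: float, peak_power_region_b: float) -> bool:
    """True iff region a's peak power is strictly more than twice region b's."""
    if peak_power_region_a < 0 or peak_power_region_b < 0:
        raise ValueError("peak powers must be non-negative")
    return peak_power_region_a > 2.0 * peak_power_region_b
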