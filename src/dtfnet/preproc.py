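"""LFP signal conditioning: zero-phase FIR filtering and epoching.

All filters are symmetric least-squares FIR designs applied forward and
backward (``filtfilt``), so the net phase shift is zero and the effective
stop-band attenuation is twice the single-pass figure.  Line noise (50 Hz
and its 100 Hz harmonic) is removed with narrow notches; theta (3-10 Hz)
and gamma (55-75 Hz) components are extracted with band-pass filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import EpochSet, MultiChannelRecording

__all__ = [
    "FilterSpec",
    "BANDS",
    "notch_line_noise",
    "bandpass",
    "epoch_around_events",
]

BANDS = {"theta": (3.0, 10.0), "gamma": (55.0, 75.0)}


@dataclass
class FilterSpec:
    """A designed zero-phase FIR filter (least-squares, forward-backward)."""

    kind: str  # notch | bandpass | lowpass
    band_hz: tuple
    order_taps: int
    taps: np.ndarray

    def __post_init__(self) -> None:
        if self.order_taps % 2 == 0:
            raise ValueError("order_taps must be odd (symmetric linear-phase FIR)")

    def apply(self, rec: MultiChannelRecording) -> MultiChannelRecording:
        n = rec.n_samples
        padlen = min(3 * (self.order_taps - 1), n - 1)
        out = signal.filtfilt(self.taps, [1.0], rec.data, axis=0, padlen=padlen)
        return rec.copy_with(out)


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def design_notch(
    sampling_rate_hz: float,
    stop_bands: tuple = ((49.0, 51.0), (99.0, 101.0)),
    transition_hz: float = 2.0,
    n_taps: int = 801,
) -> FilterSpec:
    """Least-squares FIR with unit response everywhere except the stop bands."""
    nyq = sampling_rate_hz / 2.0
    edges = [0.0]
    desired = [1.0, 1.0]
    for low, high in stop_bands:
        if high + transition_hz >= nyq:
            raise ValueError(
                f"sampling rate {sampling_rate_hz} Hz too low to place a "
                f"stop band at {low}-{high} Hz"
            )
        edges += [low - transition_hz, low, high, high + transition_hz]
        desired += [0.0, 0.0, 1.0, 1.0]
    edges.append(nyq)
    taps = signal.firls(_odd(n_taps), edges, desired, fs=sampling_rate_hz)
    return FilterSpec("notch", stop_bands[0], _odd(n_taps), taps)


def design_bandpass(
    sampling_rate_hz: float,
    band: tuple,
    n_taps: int | None = None,
) -> FilterSpec:
    """Band-pass FIR with transitions spanning the octave outside the band.

    The lower transition runs from low/2 to low, the upper from high to
    2*high (clipped below Nyquist), so one octave outside the band is fully
    in the stop band.  Tap count defaults to ~6.6 cycles of the narrowest
    transition, which comfortably reaches 40 dB after two-way application.
    """
    low, high = band
    nyq = sampling_rate_hz / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) or inverted")
    stop_lo = low / 2.0
    stop_hi = min(2.0 * high, 0.98 * nyq)
    if stop_hi <= high:
        raise ValueError(f"band {band} too close to Nyquist for a transition band")
    if n_taps is None:
        min_trans = min(low - stop_lo, stop_hi - high)
        n_taps = _odd(int(np.ceil(6.6 * sampling_rate_hz / min_trans)))
        n_taps = min(n_taps, 9601)
    bands = [0.0, stop_lo, low, high, stop_hi, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    # weight stop bands harder than the pass band: attenuation matters more
    # than ripple for band isolation
    taps = signal.firls(_odd(n_taps), bands, desired, weight=[10.0, 1.0, 10.0], fs=sampling_rate_hz)
    return FilterSpec("bandpass", (low, high), _odd(n_taps), taps)


def notch_line_noise(
    rec: MultiChannelRecording,
    stop_bands: tuple = ((49.0, 51.0), (99.0, 101.0)),
    transition_hz: float = 2.0,
    n_taps: int = 801,
) -> MultiChannelRecording:
    """Remove mains line noise and its first harmonic with zero-phase notches."""
    if rec.sampling_rate_hz < 400.0:
        raise ValueError(
            f"sampling rate {rec.sampling_rate_hz} Hz < 400 Hz: cannot place "
            "notch stop bands"
        )
    spec = design_notch(rec.sampling_rate_hz, stop_bands, transition_hz, n_taps)
    return spec.apply(rec)


def bandpass(
    rec: MultiChannelRecording,
    band,
    n_taps: int | None = None,
) -> MultiChannelRecording:
    """Zero-phase band-pass; *band* is ``"theta"``, ``"gamma"`` or an
    explicit (low, high) Hz pair."""
    if isinstance(band, str):
        try:
            band = BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    spec = design_bandpass(rec.sampling_rate_hz, tuple(band), n_taps)
    return spec.apply(rec)


def epoch_around_events(
    rec: MultiChannelRecording,
    events: np.ndarray | None = None,
    pre_s: float = 2.0,
    post_s: float = 1.0,
) -> tuple[EpochSet, int]:
    """Cut [event - pre_s, event + post_s) epochs out of a recording.

    Pure slicing: sample values are never altered.  Events without a full
    margin inside the recording are dropped; the second return value is the
    number dropped.  The event lands at sample index ``round(pre_s * fs)``
    of each epoch.
    """
    fs = rec.sampling_rate_hz
    if events is None:
        events = rec.events
    events = np.asarray(events, dtype=np.intp)
    n_pre = round(pre_s * fs)
    n_post = round(post_s * fs)
    n_len = n_pre + n_post
    kept, dropped = [], 0
    for ev in events:
        start = ev - n_pre
        if start < 0 or start + n_len > rec.n_samples:
            dropped += 1
            continue
        kept.append(rec.data[start : start + n_len])
    if not kept:
        warnings.warn("no events with a full epoch margin; returning empty EpochSet")
        data = np.empty((0, n_len, rec.n_channels))
    else:
        data = np.stack(kept)
    labels = pd.DataFrame({"section": np.arange(len(kept))})
    return EpochSet(data, fs, labels, event_index=n_pre), dropped
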