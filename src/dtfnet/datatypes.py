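"""Core in-memory containers shared across the pipeline.

A recording is a plain ``samples x channels`` float array plus its sampling
rate and (optionally) event markers; an epoch set is a stack of equal-length
event-aligned segments with a tidy label table.  Everything downstream
(filters, spectrograms, MVAR fits) operates on these two containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_COLUMNS = ["group", "day", "subject", "section"]


@dataclass
class MultiChannelRecording:
    """A continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal samples, one column per channel.
    sampling_rate_hz : float
        Sampling rate in Hz.
    events : ndarray of int, optional
        Sample indices of behavioural event markers ("tripping points").
    """

    data: np.ndarray
    sampling_rate_hz: float
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (samples x channels), got ndim={self.data.ndim}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.events = np.asarray(self.events, dtype=np.intp)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, data: np.ndarray) -> "MultiChannelRecording":
        """Same metadata, new samples (used by filters)."""
        return MultiChannelRecording(data, self.sampling_rate_hz, self.events.copy())


@dataclass
class EpochSet:
    """A stack of fixed-length event-aligned epochs ("sections").

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_samples, n_channels)
    sampling_rate_hz : float
    labels : DataFrame
        One row per epoch; canonical columns are ``group, day, subject,
        section`` but any subset is allowed (e.g. epochs cut from a single
        recording only carry ``section``).
    event_index : int
        Sample index of the aligning event within each epoch.
    """

    data: np.ndarray
    sampling_rate_hz: float
    labels: pd.DataFrame
    event_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x samples x channels)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"labels has {len(self.labels)} rows for {self.data.shape[0]} epochs"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n_epochs

    def __getitem__(self, idx) -> np.ndarray:
        return self.data[idx]

    def select(self, **criteria) -> "EpochSet":
        """Subset epochs by label equality, e.g. ``select(group="PRO", day=1)``."""
        mask = np.ones(self.n_epochs, dtype=bool)
        for key, value in criteria.items():
            mask &= (self.labels[key] == value).to_numpy()
        return EpochSet(
            self.data[mask],
            self.sampling_rate_hz,
            self.labels.loc[mask].reset_index(drop=True),
            self.event_index,
        )
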