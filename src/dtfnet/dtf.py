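"""Normalized directed transfer function (DTF) and band averaging.

gamma2[f, i, j] = |H_ij(f)|^2 / sum_m |H_im(f)|^2  is the fraction of the
total inflow to sink *i* at frequency *f* that originates from source *j*
(the normalizing sum runs over all sources including *i* itself, so each row
of gamma2 sums to one exactly).  Band matrices are entry-wise means of
gamma2 over the grid frequencies inside a band, with the diagonal zeroed
before any network analysis — self-inflow is not functional connectivity
between electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import TransferMatrix

__all__ = ["DTFResult", "compute_dtf", "band_average", "mean_dtf_value"]


@dataclass
class DTFResult:
    """Per-frequency normalized DTF plus named band-averaged matrices."""

    freqs_hz: np.ndarray
    gamma2: np.ndarray  # (n_freqs, M, M), rows sum to 1
    band_matrices: dict = field(default_factory=dict)
    mean_dtf: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.gamma2.shape[-1]


def compute_dtf(h: TransferMatrix) -> DTFResult:
    """Row-normalized squared transfer magnitudes; exact by construction."""
    if not np.isfinite(h.H).all():
        raise ValueError("transfer matrix contains non-finite entries")
    power = np.abs(h.H) ** 2
    denom = power.sum(axis=-1, keepdims=True)
    if np.any(denom == 0.0):
        f_bad = h.freqs_hz[np.nonzero((denom == 0).any(axis=(1, 2)))[0][0]]
        raise ValueError(f"all-zero transfer row at f = {f_bad} Hz")
    return DTFResult(freqs_hz=np.asarray(h.freqs_hz, float), gamma2=power / denom)


def band_average(dtf: DTFResult, band: tuple, label: str) -> DTFResult:
    """Average gamma2 over grid frequencies in [low, high] (closed interval),
    zero the diagonal, and store the matrix and its off-diagonal mean under
    *label*.  Returns the same DTFResult for chaining."""
    low, high = band
    mask = (dtf.freqs_hz >= low) & (dtf.freqs_hz <= high)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band} covers {int(mask.sum())} grid frequencies; need >= 2"
        )
    mat = dtf.gamma2[mask].mean(axis=0)
    np.fill_diagonal(mat, 0.0)
    dtf.band_matrices[label] = mat
    dtf.mean_dtf[label] = mean_dtf_value(mat)
    return dtf


def mean_dtf_value(band_matrix: np.ndarray) -> float:
    """Mean of the M(M-1) off-diagonal entries — the paper-style scalar
    summary of overall coupling strength."""
    mat = np.asarray(band_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"band matrix must be square, got shape {mat.shape}")
    m = mat.shape[0]
    off = ~np.eye(m, dtype=bool)
    return float(mat[off].mean())
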