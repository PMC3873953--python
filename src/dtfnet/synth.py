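"""Synthetic multichannel LFP generation with known directed coupling.

The generator realises ground truth *inside* the model class that the
estimator assumes: every channel is a stable autoregressive resonator (poles
placed at the theta and gamma band centres) and directed coupling between
channels enters as off-diagonal MVAR coefficients.  Because the ground truth
is exactly an MVAR process, the true transfer matrix, spectrum and directed
transfer function are all analytically computable, and attenuating the
off-diagonal coefficients is a faithful stand-in for a pharmacological
weakening of functional connectivity.

The experiment generator reproduces the study design: three dose groups
(control / pro / PRO), several recording days, several subjects per group and
many event-aligned epochs ("sections") per subject per day, with a
group-by-day attenuation schedule applied to the coupling coefficients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import EpochSet, MultiChannelRecording

__all__ = [
    "StationarityError",
    "NotPositiveDefiniteError",
    "CouplingSpec",
    "ExperimentDesign",
    "default_attenuation",
    "simulate_mvar",
    "make_band_resonant_spec",
    "default_coupling_edges",
    "default_base_spec",
    "simulate_experiment",
]

THETA_BAND = (3.0, 10.0)
GAMMA_BAND = (55.0, 75.0)

#: Pole radii of the per-band AR(2) resonators.  The radius controls the
#: resonance bandwidth (roughly fs·(1-r)/pi Hz); a slow theta pole needs to
#: sit much closer to the unit circle than a gamma pole for the spectral
#: peak to remain inside the band at a 2 kHz sampling rate (an AR(2) pole
#: at angle 2*pi*6.5/2000 has no interior spectral peak at all below
#: r ~ 0.984).
DEFAULT_POLE_RADII = {"theta": 0.992, "gamma": 0.96}

_STABILITY_MARGIN = 0.999
_DEFAULT_BURN_IN = 2000


class StationarityError(ValueError):
    """The MVAR coefficient tensor defines a non-stationary process."""


class NotPositiveDefiniteError(ValueError):
    """The innovation covariance is not symmetric positive definite."""


# ---------------------------------------------------------------------------
# Coupling specification
# ---------------------------------------------------------------------------


@dataclass
class CouplingSpec:
    """Ground-truth MVAR generator: coefficients, noise covariance, bands.

    ``coeff_tensor[n, i, j]`` is the influence of channel *j* at lag *n+1*
    on channel *i* — the same convention the estimator uses.
    """

    n_channels: int
    order: int
    coeff_tensor: np.ndarray
    noise_cov: np.ndarray
    oscillator_bands: tuple = ()
    sampling_rate_hz: float = 2000.0

    def __post_init__(self) -> None:
        self.coeff_tensor = np.asarray(self.coeff_tensor, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        expected = (self.order, self.n_channels, self.n_channels)
        if self.coeff_tensor.shape != expected:
            raise ValueError(
                f"coeff_tensor shape {self.coeff_tensor.shape} != {expected}"
            )
        if self.noise_cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov must be n_channels x n_channels")

    # -- invariants ---------------------------------------------------------

    def companion_matrix(self) -> np.ndarray:
        """Stacked first-order form of the lag polynomial, shape (pM, pM)."""
        p, m = self.order, self.n_channels
        comp = np.zeros((p * m, p * m))
        comp[:m, :] = np.concatenate(self.coeff_tensor, axis=1)
        if p > 1:
            comp[m:, : (p - 1) * m] = np.eye((p - 1) * m)
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def validate(self) -> None:
        """Raise unless the process is stationary and noise_cov is SPD."""
        if not np.isfinite(self.coeff_tensor).all():
            raise ValueError("coeff_tensor contains non-finite entries")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StationarityError(
                f"companion spectral radius {rho:.6f} >= 1: process is non-stationary"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-12):
            raise NotPositiveDefiniteError("noise_cov is not symmetric")
        eigvals = np.linalg.eigvalsh(self.noise_cov)
        if eigvals.min() <= 0:
            raise NotPositiveDefiniteError(
                f"noise_cov has non-positive eigenvalue {eigvals.min():.3e}"
            )

    def with_scaled_coupling(self, factor: float) -> "CouplingSpec":
        """Copy with every off-diagonal (cross-channel) coefficient scaled."""
        coeffs = self.coeff_tensor.copy()
        mask = ~np.eye(self.n_channels, dtype=bool)
        coeffs[:, mask] *= factor
        return dataclasses.replace(self, coeff_tensor=coeffs)

    def analytic_spectrum(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Exact power spectral density matrix S(f) = H Σ H*, shape (F, M, M).

        Per-channel power spectra are the (real) diagonal entries.
        """
        from .mvar import spectral_transfer  # deferred: mvar does not import synth

        h = spectral_transfer(self.coeff_tensor, self.sampling_rate_hz, freqs_hz)
        return h @ self.noise_cov @ np.conjugate(np.swapaxes(h, -1, -2))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _simulate_batch(
    coeff_batch: np.ndarray,
    chol: np.ndarray,
    n_samples: int,
    burn_in: int,
    rngs: Sequence[np.random.Generator],
) -> np.ndarray:
    """Simulate B independent MVAR chains (each with its own coefficients).

    coeff_batch: (B, p, M, M); returns (B, n_samples, M).  One time loop is
    shared across the batch so the Python overhead is paid once per step.
    """
    n_batch, p, m, _ = coeff_batch.shape
    n_tot = n_samples + burn_in
    innov = np.empty((n_batch, n_tot, m))
    for b, rng in enumerate(rngs):
        innov[b] = rng.standard_normal((n_tot, m)) @ chol.T
    # (B, M, p*M): lag-1 block first, matching the rolling state layout below
    a_flat = np.ascontiguousarray(coeff_batch.transpose(0, 2, 1, 3).reshape(n_batch, m, p * m))
    x = np.empty((n_batch, n_tot, m))
    state = np.zeros((n_batch, p * m))  # [x(t-1), x(t-2), ..., x(t-p)] flattened
    out = np.empty((n_batch, m))
    for t in range(n_tot):
        np.einsum("bij,bj->bi", a_flat, state, out=out)
        out += innov[:, t]
        x[:, t] = out
        state[:, m:] = state[:, :-m]
        state[:, :m] = out
    return x[:, burn_in:]


def simulate_mvar(
    spec: CouplingSpec,
    n_samples: int,
    seed: int,
    burn_in: int = _DEFAULT_BURN_IN,
) -> MultiChannelRecording:
    """Draw one realisation of the MVAR process defined by *spec*.

    An initial ``burn_in`` stretch (default 1000 samples, well past the
    mixing time of poles at radius <= 0.995) is simulated and discarded so
    the returned samples are draws from the stationary distribution.
    Identical ``(spec, n_samples, seed)`` gives identical output.
    """
    spec.validate()
    if n_samples <= 10 * spec.order:
        raise ValueError(
            f"n_samples={n_samples} too short for order {spec.order} "
            f"(need > {10 * spec.order})"
        )
    chol = np.linalg.cholesky(spec.noise_cov)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    x = _simulate_batch(spec.coeff_tensor[None], chol, n_samples, burn_in, [rng])[0]
    return MultiChannelRecording(x, spec.sampling_rate_hz)


# ---------------------------------------------------------------------------
# Band-resonant spec construction
# ---------------------------------------------------------------------------


def _resonator_poly(center_hz: float, radius: float, fs: float) -> np.ndarray:
    """AR(2) characteristic polynomial [1, a1, a2] for a complex pole pair."""
    theta = 2.0 * np.pi * center_hz / fs
    return np.array([1.0, -2.0 * radius * np.cos(theta), radius**2])


def _poly_gain(poly: np.ndarray, freq_hz: float, fs: float) -> float:
    """|poly(e^{-i 2 pi f / fs})| — magnitude of a lag polynomial at f."""
    z = np.exp(-2j * np.pi * freq_hz / fs * np.arange(len(poly)))
    return float(np.abs(poly @ z))


def make_band_resonant_spec(
    n_channels: int,
    theta_band: tuple | None = THETA_BAND,
    gamma_band: tuple | None = GAMMA_BAND,
    coupling_edges: Sequence[tuple] = (),
    sampling_rate_hz: float = 2000.0,
    pole_radii: Mapping[str, float] | None = None,
    noise_cov: np.ndarray | None = None,
    center_spread: float = 0.4,
    coupling_mode: str = "band-matched",
) -> CouplingSpec:
    """Build a stationary MVAR spec whose channels resonate in the LFP bands.

    Each channel's own dynamics are the product of damped AR(2) resonators,
    one per requested band.  Resonator centre frequencies are staggered
    across channels over the middle ``center_spread`` fraction of each band
    (``center_spread=0`` puts every pole at the band centre): real
    electrodes do not oscillate at one identical frequency, and coincident
    poles on all channels make the joint system's stationarity
    pathologically sensitive to coupling (a repeated eigenvalue of
    multiplicity M moves like the M-th root of the perturbation).

    ``coupling_edges`` entries are ``(source, target, strength)``; strengths
    may be signed (DTF depends on |H|^2, so signs only shape the dynamics
    and keep coupling row sums small).  Two coupling kernels are available:

    * ``"band-matched"`` (default): each edge couples through a short lag
      polynomial built from the source's own resonators, scaled so that the
      cross-to-self transfer ratio at *each* band's resonance equals
      |strength|.  The two bands' resonance gains differ by nearly two
      orders of magnitude (the low-frequency pole pair nearly coincides
      with its conjugate), so a plain lag-1 coupling either saturates the
      slow band or is invisible in the fast one; the matched kernel makes
      coupling, and hence attenuation, detectable in both bands at once.
    * ``"lag1"``: the raw strength at lag 1, ``coeff_tensor[0, target,
      source] += strength`` — the textbook construction, useful for small
      didactic systems.

    If the requested strengths make the process non-stationary they are
    uniformly scaled down until the companion spectral radius is below 1
    (an error is raised if even a vanishing coupling cannot stabilise the
    system).
    """
    radii = dict(DEFAULT_POLE_RADII)
    if pole_radii:
        radii.update(pole_radii)
    if not 0.0 <= center_spread < 1.0:
        raise ValueError("center_spread must lie in [0, 1)")
    nyq = sampling_rate_hz / 2.0
    bands = []
    for name, band in (("theta", theta_band), ("gamma", gamma_band)):
        if band is None:
            continue
        low, high = band
        if not (0.0 < low < high < nyq):
            raise ValueError(f"{name} band {band} outside (0, Nyquist={nyq})")
        bands.append((name, band))
    if not bands:
        raise ValueError("at least one oscillator band is required")

    def channel_center(band: tuple, i: int) -> float:
        low, high = band
        mid, width = (low + high) / 2.0, high - low
        if n_channels == 1 or center_spread == 0.0:
            return mid
        frac = i / (n_channels - 1) - 0.5  # in [-1/2, 1/2]
        return mid + frac * center_spread * width

    order = 2 * len(bands)
    band_polys = [
        [
            _resonator_poly(channel_center(band, i), radii[name], sampling_rate_hz)
            for name, band in bands
        ]
        for i in range(n_channels)
    ]
    centers = [
        [channel_center(band, i) for _, band in bands] for i in range(n_channels)
    ]
    coeffs = np.zeros((order, n_channels, n_channels))
    for i in range(n_channels):
        poly = np.array([1.0])
        for bp in band_polys[i]:
            poly = np.polymul(poly, bp)
        coeffs[:, i, i] = -poly[1:]  # x_t = sum_n c_n x_{t-n} + e_t

    def coupling_kernel(source: int) -> np.ndarray:
        """Lag polynomial (lags 1..len) with unit cross/self transfer ratio
        at each of the source's band resonances."""
        kernel = np.zeros(order - 1)
        for b, bp in enumerate(band_polys[source]):
            gain = _poly_gain(bp, centers[source][b], sampling_rate_hz)
            others = np.array([1.0])
            for b2, bp2 in enumerate(band_polys[source]):
                if b2 != b:
                    others = np.polymul(others, bp2)
            term = gain * others
            kernel[: len(term)] += term
        return kernel

    for source, target, strength in coupling_edges:
        if source == target:
            raise ValueError("coupling_edges must connect distinct channels")
        if coupling_mode == "band-matched":
            kernel = strength * coupling_kernel(source)
            coeffs[: len(kernel), target, source] += kernel
        elif coupling_mode == "lag1":
            coeffs[0, target, source] += strength
        else:
            raise ValueError(f"unknown coupling_mode {coupling_mode!r}")

    cov = np.eye(n_channels) if noise_cov is None else np.asarray(noise_cov, float)
    spec = CouplingSpec(
        n_channels=n_channels,
        order=order,
        coeff_tensor=coeffs,
        noise_cov=cov,
        oscillator_bands=tuple(band for _, band in bands),
        sampling_rate_hz=sampling_rate_hz,
    )

    # rescale cross-coupling until stationary (diagonal alone is stable by
    # construction, so this terminates unless strengths are pathological)
    scale = 1.0
    while spec.spectral_radius() >= _STABILITY_MARGIN:
        scale *= 0.8
        if scale < 1e-6:
            raise StationarityError(
                "coupling strengths cannot be rescaled to a stationary system"
            )
        rescaled = coeffs.copy()
        mask = ~np.eye(n_channels, dtype=bool)
        rescaled[:, mask] *= scale
        spec = dataclasses.replace(spec, coeff_tensor=rescaled)
    spec.validate()
    return spec


def default_coupling_edges(
    n_channels: int,
    out_degree: int = 5,
    strength: float = 0.35,
    graph_seed: int = 20140106,
) -> list[tuple[int, int, float]]:
    """The study generator's directed coupling graph.

    Every channel drives ``out_degree`` pseudo-randomly chosen targets with
    fixed-magnitude, randomly signed strengths (under the band-matched
    kernel, |strength| is the cross-to-self transfer ratio at each band's
    resonance).  Signed couplings keep the row sums near zero, so the graph
    perturbs the channels' oscillatory poles only weakly; the
    ~out_degree/(M-1) true-edge density (~1/3 at M=16) leaves plenty of
    transitive triangles for the clustering coefficient to pick up.  The
    graph is a deterministic function of ``graph_seed`` — it is part of the
    study definition, not of the noise.
    """
    out_degree = min(out_degree, n_channels - 1)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(graph_seed)))
    edges = []
    for i in range(n_channels):
        others = np.array([j for j in range(n_channels) if j != i])
        targets = rng.choice(others, size=out_degree, replace=False)
        signs = rng.choice([-1.0, 1.0], size=out_degree)
        edges.extend((i, int(t), float(s * strength)) for t, s in zip(targets, signs))
    return edges


def default_base_spec(n_channels: int = 16, sampling_rate_hz: float = 2000.0) -> CouplingSpec:
    """Canonical ground truth used by the analysis scripts: theta- and
    gamma-resonant channels coupled by :func:`default_coupling_edges`."""
    return make_band_resonant_spec(
        n_channels,
        coupling_edges=default_coupling_edges(n_channels),
        sampling_rate_hz=sampling_rate_hz,
    )


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------


def default_attenuation(group: str, day: int) -> float:
    """Coupling attenuation schedule: the high-dose (PRO) group starts at a
    strong suppression and recovers by day 3; low dose (pro) and control are
    never attenuated."""
    if group == "PRO":
        return {1: 0.3, 2: 0.6}.get(day, 1.0)
    return 1.0


@dataclass
class ExperimentDesign:
    """The group x day x subject x section layout of the synthetic study."""

    groups: tuple = ("control", "pro", "PRO")
    days: tuple = (1, 2, 3, 4, 5)
    subjects_per_group: int = 6
    sections_per_day: int = 60
    attenuation: Callable[[str, int], float] = default_attenuation
    epoch_length_s: float = 3.0
    pre_event_s: float = 2.0
    sampling_rate_hz: float = 2000.0
    seed: int = 0
    subject_jitter: float = 0.1

    def __post_init__(self) -> None:
        n = self.epoch_length_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length_s x sampling_rate_hz must be an integer")
        for day in self.days:
            if "control" in self.groups and self.attenuation("control", day) != 1.0:
                raise ValueError("control group must have attenuation 1.0 on every day")

    @property
    def n_epoch_samples(self) -> int:
        return round(self.epoch_length_s * self.sampling_rate_hz)

    @property
    def event_index(self) -> int:
        return round(self.pre_event_s * self.sampling_rate_hz)

    @property
    def n_epochs(self) -> int:
        return (
            len(self.groups)
            * len(self.days)
            * self.subjects_per_group
            * self.sections_per_day
        )


def _epoch_rng(design: ExperimentDesign, group_idx: int, day: int, subject: int, section: int):
    """Per-epoch generator: PCG64 keyed by SeedSequence(seed; spawn_key=ids).

    The spawn-key construction is numpy's documented, platform-independent
    way of deriving independent streams, so regeneration of any single cell
    of the design reproduces the full run bit for bit.
    """
    ss = np.random.SeedSequence(design.seed, spawn_key=(1, group_idx, day, subject, section))
    return np.random.Generator(np.random.PCG64(ss))


def _subject_coupling_factor(design: ExperimentDesign, group_idx: int, subject: int) -> float:
    """Multiplicative between-subject coupling variability (day-independent)."""
    if design.subject_jitter == 0.0:
        return 1.0
    ss = np.random.SeedSequence(design.seed, spawn_key=(2, group_idx, subject))
    rng = np.random.Generator(np.random.PCG64(ss))
    return float(max(0.1, 1.0 + design.subject_jitter * rng.standard_normal()))


def simulate_experiment(design: ExperimentDesign, base_spec: CouplingSpec) -> EpochSet:
    """Generate the full synthetic study as one labelled :class:`EpochSet`.

    For group *g* on day *d*, subject *s*, every off-diagonal coefficient of
    ``base_spec`` is multiplied by ``attenuation(g, d)`` times the subject's
    persistent jitter factor; the diagonal (each channel's own oscillatory
    dynamics) is untouched.  The result is a pure function of
    ``(design, base_spec)``.
    """
    base_spec.validate()
    if abs(base_spec.sampling_rate_hz - design.sampling_rate_hz) > 1e-9:
        raise ValueError("design and base_spec sampling rates disagree")
    n_samples = design.n_epoch_samples
    chol = np.linalg.cholesky(base_spec.noise_cov)
    m = base_spec.n_channels

    coeff_batch = np.empty((design.n_epochs, base_spec.order, m, m))
    rngs = []
    rows = []
    idx = 0
    for g_idx, group in enumerate(design.groups):
        for day in design.days:
            att = design.attenuation(group, day)
            if not 0.0 <= att <= 1.0:
                raise ValueError(f"attenuation({group}, {day}) = {att} outside [0, 1]")
            for subject in range(design.subjects_per_group):
                factor = att * _subject_coupling_factor(design, g_idx, subject)
                sub_spec = base_spec.with_scaled_coupling(factor)
                while sub_spec.spectral_radius() >= _STABILITY_MARGIN:
                    factor *= 0.9  # jitter pushed the system to the margin
                    sub_spec = base_spec.with_scaled_coupling(factor)
                for section in range(design.sections_per_day):
                    coeff_batch[idx] = sub_spec.coeff_tensor
                    rngs.append(_epoch_rng(design, g_idx, day, subject, section))
                    rows.append((group, day, subject, section))
                    idx += 1

    # one shared time loop over every epoch of the study
    data = _simulate_batch(coeff_batch, chol, n_samples, _DEFAULT_BURN_IN, rngs)
    labels = pd.DataFrame(rows, columns=["group", "day", "subject", "section"])
    return EpochSet(data, design.sampling_rate_hz, labels, event_index=design.event_index)
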