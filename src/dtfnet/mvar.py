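"""Multivariate autoregressive (MVAR) estimation and the transfer matrix.

The model is  X(t) = sum_{n=1..p} A_n X(t-n) + E(t)  with white innovations
E(t); in the frequency domain  A(f) = I - sum_n A_n exp(-i 2 pi f n / fs)
and the transfer matrix is H(f) = A(f)^{-1}.  Coefficients are estimated by
ordinary least squares on the lagged design matrix (with an intercept), and
the model order is chosen by minimising the Bayesian information criterion
over a candidate range on a fixed effective sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "SingularDesignError",
    "MVARModel",
    "TransferMatrix",
    "fit_mvar",
    "select_order_bic",
    "transfer_matrix",
    "spectral_transfer",
]

_COND_LIMIT = 1e10


class SingularDesignError(np.linalg.LinAlgError):
    """Lagged regression design is rank deficient (e.g. duplicated channels)."""


@dataclass
class MVARModel:
    """Fitted MVAR model.

    ``coeffs[n, i, j]`` is the estimated influence of channel *j* at lag
    *n+1* on channel *i*; ``resid_cov`` is the innovation covariance
    estimated from the fit residuals.
    """

    order_p: int
    coeffs: np.ndarray
    resid_cov: np.ndarray
    sampling_rate_hz: float
    n_samples_fit: int
    intercept: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def transfer(self, freqs_hz: np.ndarray) -> "TransferMatrix":
        return transfer_matrix(self, freqs_hz)

    def simulate(self, n_samples: int, seed: int):
        """Draw from the fitted model (used for consistency checks)."""
        from .synth import CouplingSpec, simulate_mvar

        spec = CouplingSpec(
            n_channels=self.n_channels,
            order=self.order_p,
            coeff_tensor=self.coeffs,
            noise_cov=self.resid_cov,
            sampling_rate_hz=self.sampling_rate_hz,
        )
        return simulate_mvar(spec, n_samples, seed)


@dataclass
class TransferMatrix:
    """H(f) evaluated on a frequency grid; shape (n_freqs, M, M)."""

    freqs_hz: np.ndarray
    H: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.H.shape[-1]


def _lagged_design(x: np.ndarray, p: int, n_eff: int | None = None):
    """Response X[t] and predictors [X[t-1] ... X[t-p], 1] as flat matrices.

    If ``n_eff`` is given, only the last ``n_eff`` rows are used so that
    models of different order can be compared on the same sample.
    """
    n, m = x.shape
    y = x[p:]
    z = np.empty((n - p, p * m + 1))
    for lag in range(1, p + 1):
        z[:, (lag - 1) * m : lag * m] = x[p - lag : n - lag]
    z[:, -1] = 1.0
    if n_eff is not None:
        y, z = y[-n_eff:], z[-n_eff:]
    return y, z


def _ols(z: np.ndarray, y: np.ndarray, x_for_error: np.ndarray | None = None) -> np.ndarray:
    """Solve the multichannel least-squares problem via normal equations.

    The Gram matrix is tiny (p*M+1 square) so a Cholesky solve is an order
    of magnitude faster than an SVD-based lstsq on tall designs; singularity
    is detected from the Gram eigenvalue range.
    """
    gram = z.T @ z
    w = np.linalg.eigvalsh(gram)
    if w[0] > w[-1] * 1e-10:
        c, low = sla.cho_factor(gram)
        return sla.cho_solve((c, low), z.T @ y)
    # near-unit-root oscillatory regressors square the design's condition
    # number in the Gram matrix; fall back to an SVD solve and only call
    # the design singular when it is genuinely rank deficient
    beta, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
    if rank < z.shape[1]:
        pairs = _collinear_channels(x_for_error) if x_for_error is not None else []
        detail = f"; collinear channel pairs: {pairs}" if pairs else ""
        raise SingularDesignError(
            f"lagged design is rank deficient (rank {rank} < {z.shape[1]}){detail}"
        )
    return beta


def _collinear_channels(x: np.ndarray) -> list[tuple[int, int]]:
    """Pairs of (near-)perfectly correlated channels, for error messages."""
    c = np.corrcoef(x, rowvar=False)
    m = c.shape[0]
    return [
        (i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if abs(c[i, j]) > 1.0 - 1e-10
    ]


def fit_mvar(epoch: np.ndarray, p: int, sampling_rate_hz: float = 2000.0) -> MVARModel:
    """Least-squares MVAR fit of order *p* to one epoch (samples x channels).

    The residual covariance uses the unbiased denominator
    ``n_eff - (p*M + 1)`` (lagged predictors plus intercept).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 2:
        raise ValueError("epoch must be 2-D (samples x channels)")
    n, m = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if n <= 10 * p * m:
        raise ValueError(
            f"epoch of {n} samples is below the identifiability floor "
            f"10*p*M = {10 * p * m}"
        )
    y, z = _lagged_design(x, p)
    n_eff = y.shape[0]
    beta = _ols(z, y, x_for_error=x)
    resid = y - z @ beta
    dof = n_eff - (p * m + 1)
    resid_cov = resid.T @ resid / dof
    coeffs = np.empty((p, m, m))
    for lag in range(p):
        coeffs[lag] = beta[lag * m : (lag + 1) * m].T
    return MVARModel(
        order_p=p,
        coeffs=coeffs,
        resid_cov=resid_cov,
        sampling_rate_hz=sampling_rate_hz,
        n_samples_fit=n,
        intercept=beta[-1].copy(),
    )


def select_order_bic(
    epoch: np.ndarray,
    p_max: int,
    sampling_rate_hz: float = 2000.0,
) -> tuple[int, np.ndarray]:
    """Pick the MVAR order minimising BIC over 1..p_max; ties go to smaller p.

    BIC(p) = n_eff * log det(Sigma_p) + p * M^2 * log(n_eff), where Sigma_p
    is the maximum-likelihood residual covariance and n_eff = n - p_max is
    held fixed across candidate orders so the criteria are comparable.
    """
    x = np.asarray(epoch, dtype=float)
    n, m = x.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if n <= 10 * p_max * m:
        raise ValueError(
            f"epoch of {n} samples is below the identifiability floor for p_max={p_max}"
        )
    n_eff = n - p_max
    bic = np.empty(p_max)
    for p in range(1, p_max + 1):
        y, z = _lagged_design(x, p, n_eff=n_eff)
        beta = _ols(z, y, x_for_error=x)
        resid = y - z @ beta
        sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise SingularDesignError(f"singular residual covariance at order {p}")
        bic[p - 1] = n_eff * logdet + p * m * m * np.log(n_eff)
    p_best = int(np.argmin(bic)) + 1  # argmin returns the first (smallest p) tie
    return p_best, bic


def spectral_transfer(
    coeffs: np.ndarray, sampling_rate_hz: float, freqs_hz: np.ndarray
) -> np.ndarray:
    """H(f) = (I - sum_n A_n e^{-i 2 pi f n / fs})^{-1} for a coefficient
    tensor of shape (p, M, M); returns complex (n_freqs, M, M)."""
    coeffs = np.asarray(coeffs, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    p, m, _ = coeffs.shape
    lags = np.arange(1, p + 1)
    # phase[f, n] = exp(-i 2 pi f n / fs)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] / sampling_rate_hz)
    a_f = np.eye(m)[None] - np.einsum("fn,nij->fij", phase, coeffs)
    try:
        h = np.linalg.inv(a_f)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"A(f) exactly singular on the grid: {exc}") from exc
    # 1-norm condition estimate per frequency: cheap and an upper bound on
    # the forward-error amplification, unlike a full SVD
    cond = np.abs(a_f).sum(axis=1).max(axis=1) * np.abs(h).sum(axis=1).max(axis=1)
    bad = np.nonzero(~np.isfinite(h).all(axis=(1, 2)) | (cond > _COND_LIMIT))[0]
    if bad.size:
        raise np.linalg.LinAlgError(
            f"A(f) numerically singular at f = {freqs[bad[0]]:.3f} Hz "
            f"(1-norm condition estimate {cond[bad[0]]:.2e})"
        )
    return h


def transfer_matrix(model: MVARModel, freqs_hz: np.ndarray) -> TransferMatrix:
    """Evaluate the model's transfer matrix on a frequency grid in [0, Nyquist]."""
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    nyq = model.sampling_rate_hz / 2.0
    if freqs.min() < 0 or freqs.max() > nyq:
        raise ValueError(f"frequencies must lie in [0, {nyq}] Hz")
    h = spectral_transfer(model.coeffs, model.sampling_rate_hz, freqs)
    return TransferMatrix(freqs_hz=freqs, H=h)
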