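"""Fractional Gaussian noise / fractional Brownian motion synthesis.

Fractional Brownian motion (fBm) with Hurst exponent ``H`` is the standard
stationary-increment Gaussian process whose mean-squared displacement follows
a power law, ``Var[B_H(t)] = t^{2H}``.  Subdiffusive tracer motion with
``MSD ∝ τ^α`` corresponds to ``H = α/2``.

Paths are generated by circulant embedding (Davies–Harte), which reproduces
the fGn covariance exactly in O(n log n); short paths, or the rare embedding
with a negative eigenvalue, fall back to a dense Cholesky factorization of
the exact covariance matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = ["fgn_autocovariance", "sample_fgn", "sample_fbm"]

# below this length the dense Cholesky route is cheaper than setting up FFTs
_CHOLESKY_MAX_N = 16


def fgn_autocovariance(n_lags: int, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}), k = 0..n_lags-1.
    """
    k = np.arange(n_lags, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def _sample_fgn_cholesky(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    gamma = fgn_autocovariance(n, hurst)
    lower = cholesky(toeplitz(gamma), lower=True)
    return lower @ rng.standard_normal(n)


def _sample_fgn_davies_harte(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Exact fGn sample via circulant embedding; None if the embedding fails."""
    m = 2 * n
    gamma = fgn_autocovariance(n + 1, hurst)
    # first row of the circulant matrix: gamma(0..n), then gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)

    # Hermitian-symmetric spectral coefficients; fixed draw order for determinism
    edge = rng.standard_normal(2)
    v1 = rng.standard_normal(n - 1)
    v2 = rng.standard_normal(n - 1)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * edge[0]
    w[n] = np.sqrt(lam[n] / m) * edge[1]
    w[1:n] = np.sqrt(lam[1:n] / (2.0 * m)) * (v1 + 1j * v2)
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    return np.fft.fft(w)[:n].real


def sample_fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` samples of unit-variance fGn with Hurst exponent ``hurst``.

    Parameters
    ----------
    n
        Number of increments.
    hurst
        Hurst exponent in (0, 1); 0.5 gives white noise (Brownian increments).
    rng
        NumPy generator; the only source of randomness.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("need at least one increment")
    if hurst == 0.5:
        return rng.standard_normal(n)
    if n <= _CHOLESKY_MAX_N:
        return _sample_fgn_cholesky(n, hurst, rng)
    out = _sample_fgn_davies_harte(n, hurst, rng)
    if out is None:
        out = _sample_fgn_cholesky(n, hurst, rng)
    return out


def sample_fbm(
    n_steps: int,
    hurst: float,
    dt: float,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> np.ndarray:
    """One fBm path observed at times 0, dt, ..., n_steps*dt.

    Returns ``n_steps + 1`` positions starting at 0 with
    ``Var[x(k dt)] = scale**2 * (k dt)^{2H}``.  For tracer motion with
    generalized diffusion coefficient D (per coordinate MSD = 2 D t^alpha)
    use ``scale = sqrt(2 D)`` and ``hurst = alpha / 2``.
    """
    increments = sample_fgn(n_steps, hurst, rng) * (scale * dt**hurst)
    path = np.empty(n_steps + 1)
    path[0] = 0.0
    np.cumsum(increments, out=path[1:])
    return path
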