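"""MCMC convergence diagnostics: split-chain Rhat and effective sample size."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["gelman_rubin", "effective_n"]


def _split(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half (dropping one draw if the length is odd)."""
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, n - half:]])


def gelman_rubin(chains) -> float:
    """Split-chain potential scale reduction factor (Rhat).

    ``chains`` is (m, n): m >= 2 chains of equal length n. Each chain is
    split in half; Rhat = sqrt(((n−1)/n · W + B/n) / W) over the split
    halves, where W is the mean within-chain variance and B the
    between-chain variance of the means. Values near 1 indicate the
    chains have mixed; > 1.1 is taken as non-convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    s = _split(chains)
    m, n = s.shape
    if n < 2:
        raise ValueError("chains too short to split")
    means = s.mean(axis=1)
    W = s.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0  # all halves constant and equal
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance function via FFT (normalized by n)."""
    n = x.size
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    return acov


def effective_n(chains) -> float:
    """Autocorrelation-based effective sample size across chains.

    Combines within- and between-chain variance as in the split-Rhat
    computation, sums paired autocorrelations with Geyer's initial
    positive sequence truncation, and returns m·n / (1 + 2·sum(rho)).
    A constant chain has no information about autocorrelation; the total
    draw count is returned with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    total = m * n
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        warnings.warn("constant chains: n_eff undefined, reporting total")
        return float(total)
    B = n * chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n

    acov = np.mean([_autocov(c) for c in chains], axis=0)
    rho = 1.0 - (W - acov) / var_plus
    rho[0] = 1.0
    # Geyer initial positive sequence on paired sums
    tmax = (n - 1) // 2
    rho_sum = 0.0
    for t in range(1, tmax + 1):
        pair = rho[2 * t - 1] + rho[2 * t]
        if pair < 0:
            break
        rho_sum += pair
    ess = total / (1.0 + 2.0 * rho_sum)
    return float(min(ess, total))
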