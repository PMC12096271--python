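"""Convergence diagnostics for multi-chain MCMC output."""

from __future__ import annotations

import numpy as np

__all__ = ["psr"]


def psr(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction for one parameter.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws) of retained draws; requires
        at least two chains of equal length.

    Returns
    -------
    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B the between-chain variance of chain means times n.
    Degenerate chains (W = 0) return 1.0 when all chains agree exactly
    and inf otherwise.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("psr requires >= 2 chains of equal retained length")
    m, n = x.shape
    if n < 2:
        raise ValueError("psr requires >= 2 draws per chain")
    chain_means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B = float(n * chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))
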