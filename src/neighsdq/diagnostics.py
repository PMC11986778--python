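"""Convergence diagnostics and posterior summarisation.

Gelman-Rubin potential scale reduction factor (classic two-chain, non-split
formulation; a split-chain variant behind a flag) and equal-tailed credible
intervals with the interval-excludes-zero significance rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .sampler import PosteriorDraws

__all__ = ["gelman_rubin", "summarize_posterior"]


def _rhat(chains: np.ndarray) -> float:
    """Classic PSRF from an (m, n) array of chains.

    V_hat = (n-1)/n * W + B/n with W the mean within-chain variance and B/n
    the variance of chain means; R_hat = sqrt(V_hat / W).  Zero within-chain
    variance is reported as NaN (undefined).
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        raise DataError("Gelman-Rubin needs >= 2 chains with >= 2 draws each")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W <= 0.0:
        return float("nan")
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def gelman_rubin(draws, split: bool = False):
    """Potential scale reduction factor per parameter.

    Accepts a :class:`PosteriorDraws` (returns a Series over its labels) or a
    2-D (chains x iterations) array for a single parameter (returns a float).
    ``split=True`` halves each chain first (the split-R-hat variant).
    """
    def prep(arr):
        if not split:
            return arr
        n2 = arr.shape[1] // 2
        return np.concatenate([arr[:, :n2], arr[:, n2: 2 * n2]], axis=0)

    if isinstance(draws, PosteriorDraws):
        vals = {lab: _rhat(prep(draws.param(lab))) for lab in draws.labels}
        return pd.Series(vals, name="rhat")
    return _rhat(prep(np.asarray(draws, dtype=float)))


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Pooled posterior means, equal-tailed credible intervals, significance.

    Draws are pooled across chains; ``significant`` is True when the
    credible interval excludes zero.  R-hat is attached per parameter when
    at least two chains are available.
    """
    if draws.n_saved == 0:
        raise DataError("no draws to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    pooled = draws.stacked()
    mean = pooled.mean(axis=0)
    lo = np.quantile(pooled, lo_q, axis=0)
    hi = np.quantile(pooled, hi_q, axis=0)
    if draws.n_chains >= 2 and draws.n_saved >= 2:
        rhat = np.array([_rhat(draws.param(lab)) for lab in draws.labels])
    else:
        rhat = np.full(len(draws.labels), np.nan)
    out = pd.DataFrame(
        {
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "significant": (lo > 0) | (hi < 0),
            "rhat": rhat,
        },
        index=pd.Index(draws.labels, name="parameter"),
    )
    return out
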