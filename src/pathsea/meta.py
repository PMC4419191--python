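"""Meta-analysis of per-data-set pathway p-values and FDR estimation.

Per-pathway p-values computed separately per data set (to respect data
set-specific feature counts and platforms) are combined with Fisher's
chi-square method or Stouffer's z method, then converted to false
discovery rates either by Benjamini-Hochberg or — when a permutation test
produced null meta-p-values for every pathway and permutation round — by a
plug-in permutation FDR: the average number of null meta-p-values at or
below a threshold divided by the observed count at that threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["meta_fisher", "meta_stouffer", "bh_fdr", "perm_meta_fdr"]

_TINY = np.finfo(float).tiny


def meta_fisher(pvals) -> float:
    """Fisher's method: chi-square upper tail of -2*sum(log p) with 2D dof."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def meta_stouffer(pvals) -> float:
    """Stouffer's method with equal weights: 1 - Phi(sum(z_d)/sqrt(D)).

    Boundary p-values of exactly 0 or 1 have infinite z-scores; they are
    clamped to the nearest machine-representable open-interval value with a
    warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0) or np.any(p == 1):
        warnings.warn(
            "p-values of exactly 0 or 1 clamped for Stouffer combination",
            UserWarning,
            stacklevel=2,
        )
        eps = np.finfo(float).epsneg
        p = np.clip(p, _TINY, 1 - eps)
    z = stats.norm.isf(p).sum() / np.sqrt(p.size)
    return float(stats.norm.sf(z))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def perm_meta_fdr(
    observed, permuted, monotonize: bool = True
) -> np.ndarray:
    """Permutation FDR per pathway from observed and null meta-p-values.

    ``permuted`` is a P×Npath matrix of meta-p-values recomputed under P
    random permutation rounds for the same pathway set.  For each observed
    meta-p threshold p0, FDR(p0) is the mean permutation count of null
    meta-p-values <= p0 divided by the observed count <= p0, capped at 1
    and (optionally) monotonized to be non-decreasing in p0.
    """
    obs = np.asarray(observed, dtype=float)
    perm = np.atleast_2d(np.asarray(permuted, dtype=float))
    P = perm.shape[0]
    if perm.shape[1] != obs.size:
        raise ValueError("permuted matrix width must equal the pathway count")
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]
    pooled = np.sort(perm.ravel())
    n_le_perm = np.searchsorted(pooled, sorted_obs, side="right")
    obs_sorted = np.sort(obs)
    n_le_obs = np.searchsorted(obs_sorted, sorted_obs, side="right")
    fdr = np.minimum(1.0, (n_le_perm / P) / n_le_obs)
    if monotonize:
        # non-decreasing in p0: relax each FDR to the minimum at any larger p0
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty(obs.size)
    out[order] = fdr
    return out
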