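"""Shared statistical primitives: BH adjustment and the empirical-Bayes
variance squeeze behind the moderated t-statistic.

The variance squeeze fits a scaled inverse-chi-square prior to the observed
per-feature sample variances by moment matching on log variances, then
shrinks each variance toward the fitted prior:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

where d is the residual degrees of freedom of the two-group design and
(d0, s0^2) are the fitted prior degrees of freedom and scale.  The moderated
t uses s_tilde and is referred to a t distribution with d + d0 degrees of
freedom.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "fit_variance_prior", "squeeze_variances"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of a scaled inverse-chi-square prior to sample variances.

    Moment matching on z = log(s2): under the model, z - digamma(df/2) +
    log(df/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2).  Returns ``(0.0, nan)`` when fewer than two
    finite variances are available (no shrinkage possible), and
    ``(inf, s0^2)`` when the observed spread is at or below the sampling
    noise (variances treated as identical).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return 0.0, float("nan")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(emean))
    return float(d0), s20


def squeeze_variances(s2, df: float, prior_df: float | None = None) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward the fitted (or supplied) prior.

    Returns ``(s2_post, d0, s20)``.  ``prior_df`` overrides the fitted d0
    (0 disables shrinkage entirely; inf collapses onto the prior scale).
    """
    s2 = np.asarray(s2, dtype=float)
    d0, s20 = fit_variance_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
        pos = s2[np.isfinite(s2) & (s2 > 0)]
        if d0 > 0 and pos.size:
            # re-derive the prior scale consistently for the imposed d0
            emean = float(np.mean(np.log(pos))) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
            if np.isinf(d0):
                s20 = float(np.exp(emean))
            else:
                s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if d0 == 0 or not np.isfinite(s20):
        return s2.copy(), 0.0, s20
    if np.isinf(d0):
        return np.full_like(s2, s20), d0, s20
    s2_post = (d0 * s20 + df * s2) / (d0 + df)
    return s2_post, d0, s20
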