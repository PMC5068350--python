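"""Empirical-Bayes shrinkage of per-gene residual variances.

Moment-matching on log variances: if s_g^2 ~ s0^2 * F(df_g, d0) under the
hierarchical model, then log s_g^2 has excess variance trigamma(d0/2)
beyond trigamma(df_g/2).  Inverting the trigamma gives the prior df d0;
the prior variance s0^2 comes from the mean of the corrected logs.  When
the observed variances carry no excess spread the prior df is infinite
and every gene shares the common variance.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def _trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ~ 1/y (trigamma(x) ~ 1/x + 1/(2x^2)) and
    the monotone decreasing shape of trigamma for a safeguarded update.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-gene variances with common residual df.

    Returns d0 = inf when the variances show no excess dispersion (then the
    moderated variance is the common geometric-mean-based variance for all
    genes).
    """
    s2 = np.asarray(s2, float)
    if np.any(s2 <= 0):
        s2 = np.maximum(s2, np.finfo(float).tiny)
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if len(s2) < 2:
        return np.inf, float(np.exp(emean))
    evar = float(e.var(ddof=1)) - float(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderate_variances(s2: np.ndarray, df: float, d0: float, s02: float
                       ) -> np.ndarray:
    """Posterior variances: weighted average of gene and prior variances."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s02)
    return (d0 * s02 + df * np.asarray(s2, float)) / (d0 + df)
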