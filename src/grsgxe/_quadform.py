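"""Tail probabilities of positive weighted sums of chi-square(1) variables.

``P(sum_k w_k X_k > q)`` with X_k iid chi-square(1) arises as the null
distribution of variance-component score statistics.  The primary route is
Imhof's exact inversion integral evaluated by adaptive quadrature; if the
integral misbehaves numerically the Liu et al. moment-matching approximation
(non-central chi-square matched on the first three cumulants plus kurtosis)
is used instead.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import ncx2


def imhof_pvalue(q: float, weights: np.ndarray) -> float:
    """Imhof (1961) inversion:  P(Q > q) = 1/2 + (1/pi) int_0^inf sin(theta)/(u rho) du."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("at least one positive weight is required")
    if w.size == 1:
        # exact: the integrand decays too slowly for quadrature here
        from scipy.stats import chi2
        return float(chi2.sf(q / w[0], 1))

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    return 0.5 + val / np.pi


def liu_pvalue(q: float, weights: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to the same tail."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    c1, c2, c3, c4 = (np.sum(w), np.sum(w**2), np.sum(w**3), np.sum(w**4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2 if s2 > 0 else 1.0
        a = np.sqrt(dof)
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x = dof + delta
    sigma_x = np.sqrt(2.0 * (dof + 2.0 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(ncx2.sf(t, dof, delta))


def quadform_pvalue(q: float, weights: np.ndarray) -> float:
    """Exact-tail p-value with a moment-matching fallback, clipped to [0, 1]."""
    try:
        p = imhof_pvalue(q, weights)
    except Exception:
        p = np.nan
    if not np.isfinite(p) or not (-1e-6 <= p <= 1.0 + 1e-6) or p <= 1e-10:
        p = liu_pvalue(q, weights)
    return float(min(1.0, max(p, 1e-300)))
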