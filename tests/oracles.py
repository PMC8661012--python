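"""Independent oracles used by the test-suite.

Each function re-derives a quantity by a route different from the package
implementation (direct log-factorial enumeration instead of the ratio
recurrence, explicit normal equations instead of the estimator code, a
scalar cumulative-weight walk instead of the vectorized interpolation), so
agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

#: shared tie convention for the two-sided exact test: a configuration
#: counts as "no more probable" when its probability exceeds the observed
#: one by less than this relative margin (guards exact mathematical ties
#: against floating-point noise; both routes apply the same rule).
TIE_RTOL = 1e-9


def hwe_exact_bruteforce(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided HWE exact p-value by direct enumeration.

    Enumerates every admissible heterozygote count given the allele counts,
    computes each conditional probability from first principles via
    log-factorials — P(h) = [n! / (hr! h! hc!)] 2^h / [(2n)! / (rare! common!)]
    — and sums those no more probable than the observed configuration.
    """
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + hets * math.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(probs[probs <= p_obs * (1.0 + TIE_RTOL)].sum(), 1.0))


def wls_through_origin(bx, by, weights) -> tuple[float, float]:
    """Weighted least squares of by on bx through the origin.

    Returns (slope, fixed-effect SE) from the explicit normal equation
    slope = sum(w bx by) / sum(w bx^2), SE = sum(w bx^2)^(-1/2).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    w = np.asarray(weights, float)
    sxx = float(np.sum(w * bx * bx))
    return float(np.sum(w * bx * by)) / sxx, sxx**-0.5


def wls_with_intercept(bx, by, weights) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted regression of by on [1, bx] by explicit 2x2 normal equations.

    Returns (coef [intercept, slope], SEs with the residual variance factor
    floored at 1, raw residual mean square).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    w = np.asarray(weights, float)
    s0 = w.sum()
    s1 = float(np.sum(w * bx))
    s2 = float(np.sum(w * bx * bx))
    t0 = float(np.sum(w * by))
    t1 = float(np.sum(w * bx * by))
    det = s0 * s2 - s1 * s1
    intercept = (s2 * t0 - s1 * t1) / det
    slope = (s0 * t1 - s1 * t0) / det
    resid = by - intercept - slope * bx
    phi_raw = float(np.sum(w * resid**2)) / (bx.size - 2)
    phi = max(1.0, phi_raw)
    se_int = math.sqrt(phi * s2 / det)
    se_slope = math.sqrt(phi * s0 / det)
    return np.array([intercept, slope]), np.array([se_int, se_slope]), phi_raw


def weighted_median_walk(ratios, weights) -> float:
    """Scalar cumulative-weight walk for the interpolated weighted median."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    cum = 0.0
    prev_p = None
    prev_r = None
    for j in range(r.size):
        p_j = cum + w[j] / 2.0
        if p_j >= 0.5:
            if prev_p is None:
                return float(r[0])
            return float(prev_r + (0.5 - prev_p) * (r[j] - prev_r) / (p_j - prev_p))
        cum += w[j]
        prev_p, prev_r = p_j, r[j]
    return float(r[-1])


def ols_normal_equations(y, design_no_intercept) -> np.ndarray:
    """OLS coefficients by the explicit (X'X)^-1 X'y arithmetic."""
    X = np.column_stack(
        [np.ones(len(y)), np.asarray(design_no_intercept, float)]
    )
    return np.linalg.inv(X.T @ X) @ (X.T @ np.asarray(y, float))
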