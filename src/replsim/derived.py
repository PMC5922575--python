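"""Post-estimation arithmetic: percent effects, quadratic turning points,
heterogeneity variance shares, correlations, and replacement-per-death
ratios.

These are the small closed-form quantities a reader derives from the fitted
coefficients: a log-interval coefficient d translates into a
100*(exp(d)-1) percent change in the expected interval; a quadratic
log-interval profile in the mortality equation has its minimum at
exp(-linear/(2*quadratic)) months; the share of unsystematic variance
explained by mother-level heterogeneity is var(alpha)/(var(alpha)+var(u));
and a simulated x% rise in births at a mortality rate of m per 1000 live
births means 10x/m extra births per infant death.  Raw unrounded values are
always returned; rounding to printed precision is the caller's business.
"""
from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np


@dataclass(frozen=True)
class QuadraticProfile:
    """Linear + quadratic coefficients of a log-regressor, with an optional
    interaction added to the linear term when a condition holds."""

    linear: float
    quadratic: float
    interaction: float = 0.0


def percent_effect(delta_index: float) -> float:
    """Percent change implied by a shift of a log-scale linear index:
    100 * (exp(delta) - 1)."""
    return 100.0 * (math.exp(delta_index) - 1.0)


def interval_turning_point(profile: QuadraticProfile,
                           prev_died: int = 0) -> float:
    """Birth-interval length (months) at which a U-shaped quadratic profile
    in the log interval attains its minimum:
    exp(-(linear + died * interaction) / (2 * quadratic))."""
    if profile.quadratic <= 0:
        raise ValueError("turning point requires positive (U-shaped) curvature")
    lin = profile.linear + (profile.interaction if prev_died else 0.0)
    return math.exp(-lin / (2.0 * profile.quadratic))


def age_minimum(linear: float, quadratic: float) -> float:
    """Age (years) minimizing a quadratic age profile: -linear/(2*quadratic)."""
    if quadratic <= 0:
        raise ValueError("age minimum requires positive curvature")
    return -linear / (2.0 * quadratic)


def variance_share(var_alpha: float, var_u: float) -> float:
    """Share of unsystematic variance explained by mother-level
    heterogeneity: var(alpha) / (var(alpha) + var(u))."""
    if var_alpha < 0 or var_u < 0:
        raise ValueError("variances must be non-negative")
    denom = var_alpha + var_u
    if denom == 0:
        raise ValueError("zero total variance")
    return var_alpha / denom


def corr_from_cov(cov_matrix) -> np.ndarray:
    """Correlation matrix r_ij = c_ij / sqrt(c_ii c_jj)."""
    c = np.asarray(cov_matrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(c, c.T):
        raise ValueError("covariance matrix must be symmetric")
    d = np.diag(c)
    if np.any(d <= 0):
        raise ValueError("diagonal entries must be positive")
    s = np.sqrt(d)
    r = c / np.outer(s, s)
    np.fill_diagonal(r, 1.0)
    return r


def replacement_per_death(pct_change_births: float,
                          mortality_per_1000: float) -> float:
    """Births per infant death implied by a percent change in total births at
    a given mortality rate: (10 * pct) / (mortality per 1000)."""
    if mortality_per_1000 <= 0:
        raise ValueError("mortality rate must be positive")
    return 10.0 * pct_change_births / mortality_per_1000
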