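"""Preset parameter values: the published benchmark estimates for the Matlab
comparison area (standard government health services), used as the default
data-generating process for simulation experiments and counterfactuals.

Coefficient order follows the layouts in :mod:`replsim.model`.  The loading
``theta`` of the mother-level mortality effect in the first-born equation is
not reported in the published table; it is set to 1, matching the (fixed)
unit loading of the later-born equation.
"""
from __future__ import annotations

import numpy as np

from .model import ParameterSet

# Estimated covariance of (alpha_m, alpha_b, alpha_f), comparison area.
COV_ALPHA_COMPARISON = np.array([
    [0.0625, -0.0002, -0.188],
    [-0.0002, 0.007, -0.088],
    [-0.188, -0.088, 2.306],
])


def comparison_area_params() -> ParameterSet:
    """Benchmark estimates, comparison area (n = 32,366 children)."""
    beta_mort = np.array([
        -1.7239,   # log preceding interval
        0.2094,    # log preceding interval squared
        0.0648,    # log interval x previous sibling died
        -0.2703,   # previous sibling died
        0.0111,    # male child
        -0.0503,   # muslim
        -0.1512,   # birth order
        0.0199,    # birth order squared
        -0.1516, -0.3055, -0.5461,   # mother's cohort 1966-70 / 71-75 / post-75
        -0.0321, 0.0004,             # mother's age at birth, squared
        0.0096, -0.0896,             # mother's education primary / secondary+
        -0.0286, -0.1312,            # father's education primary / secondary+
        0.1239,    # father day labourer
        -0.0194,   # hygienic drinking water
        0.0064,    # distance to health facility (km)
        2.8594,    # constant
    ])
    beta_first = np.array([
        0.0648,    # male child
        0.0082,    # muslim
        0.0030, -0.0085, -0.1789,    # cohort dummies
        -0.1507, 0.0028,             # age at first birth, squared
        -0.1373, -0.2984,            # mother's education
        -0.0569, -0.0529,            # father's education
        0.0659,    # day labourer
        -0.0731,   # hygienic water
        0.0158,    # distance
        -0.6178,   # constant
    ])
    beta_interval = np.array([
        -0.6107,   # previous sibling died
        -0.0306,   # male child (child beginning the interval)
        0.0090,    # muslim
        0.0746, -0.0136,             # birth order, squared
        0.0461, 0.1072, 0.1554,      # cohort dummies
        0.0207, -0.0002,             # mother's age at birth, squared
        0.0565, 0.1247,              # mother's education
        -0.0171, 0.0066,             # father's education
        -0.0440,   # day labourer
        0.0243,    # hygienic water
        -0.0009,   # distance
        0.1226, 0.0723,              # at least one boy / girl surviving
        0.0764, 0.0197,              # boys / girls surviving in excess of 1
        3.0370,    # constant
    ])
    beta_fert = np.array([
        -0.2092,   # previous sibling died
        -0.0197,   # male child
        0.3869,    # muslim
        0.3148, -0.0173,             # birth order, squared
        -0.1730, -0.5095, -0.9052,   # cohort dummies
        -0.0613, -0.0028,            # mother's age at birth, squared
        -0.1940, -0.5045,            # mother's education
        0.1156, -0.0957,             # father's education
        -0.4155,   # day labourer
        -0.1453,   # hygienic water
        0.0245,    # distance
        -1.2778, -1.2930,            # at least one boy / girl surviving
        -1.1801, -0.6347,            # boys / girls in excess of 1
        6.9565,    # constant
    ])
    return ParameterSet(
        beta_first=beta_first,
        theta=1.0,
        beta_mort=beta_mort,
        beta_interval=beta_interval,
        sigma_b=0.4356,
        beta_fert=beta_fert,
        cov_alpha=COV_ALPHA_COMPARISON.copy(),
    )


#: Published first-born infant mortality rates (share of first-borns dying in
#: infancy) by area, used to calibrate the first-born constant below.
FIRST_BORN_MORTALITY = {"comparison": 0.0890, "icddrb": 0.0670}


def calibrated_dgp(mothers, area: str = "comparison",
                   params: ParameterSet | None = None) -> ParameterSet:
    """Data-generating parameter set for simulation experiments.

    The published first-born equation is internally inconsistent: with ages in
    years (the scale implied by the age-27 mortality minimum) its printed
    constant yields an average first-born mortality of ~0.4%, against the
    published sample rate of 8.90% (comparison area).  This helper re-solves
    *only* the constant so that the population-average first-born mortality,
    integrating the mother-level heterogeneity, matches the published rate for
    the given area; all other coefficients stay at their printed values.
    """
    import scipy.optimize
    from scipy.special import ndtr

    from .model import mortality_first_row

    if params is None:
        params = comparison_area_params()
    target = FIRST_BORN_MORTALITY[area]
    rows = np.array([
        mortality_first_row(m.covariates, m.age_at_first_birth, male)
        for m in mothers for male in (0, 1)
    ])
    idx = rows @ params.beta_first
    # integrate theta * a_m over its normal law by Gauss-Hermite quadrature
    nodes, weights = np.polynomial.hermite.hermgauss(31)
    sd = params.theta * np.sqrt(params.cov_alpha[0, 0])
    shocks = np.sqrt(2.0) * sd * nodes
    w = weights / np.sqrt(np.pi)

    def mean_rate(delta: float) -> float:
        return float(np.mean(ndtr(idx[:, None] + delta + shocks) @ w))

    delta = scipy.optimize.brentq(lambda d: mean_rate(d) - target, -6.0, 6.0)
    beta_first = params.beta_first.copy()
    beta_first[-1] += delta
    out = ParameterSet(
        beta_first=beta_first, theta=params.theta, beta_mort=params.beta_mort,
        beta_interval=params.beta_interval, sigma_b=params.sigma_b,
        beta_fert=params.beta_fert, cov_alpha=params.cov_alpha.copy(),
    )
    return out
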