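"""Markdown report of the derived quantities implied by a parameter set and,
optionally, a counterfactual simulation table."""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import derived
from .model import (
    MORTALITY_FIRST_TERMS,
    MORTALITY_LATER_TERMS,
    SPACING_FERTILITY_TERMS,
    ParameterSet,
)


def derived_report(params: ParameterSet, table: pd.DataFrame | None = None
                   ) -> str:
    """Human-readable summary of every closed-form derived quantity, each
    line stating which coefficients it came from."""
    cm = dict(zip(MORTALITY_LATER_TERMS, params.beta_mort))
    c1 = dict(zip(MORTALITY_FIRST_TERMS, params.beta_first))
    cb = dict(zip(SPACING_FERTILITY_TERMS, params.beta_interval))
    profile = derived.QuadraticProfile(
        linear=cm["log_prev_interval"], quadratic=cm["log_prev_interval_sq"],
        interaction=cm["logb_x_prev_died"])
    corr = derived.corr_from_cov(params.cov_alpha) \
        if np.all(np.diag(params.cov_alpha) > 0) else None
    lines = ["# Derived quantities", ""]
    lines.append(
        f"- Interval change after an infant death: "
        f"{derived.percent_effect(cb['prev_sibling_died']):+.1f}% "
        f"(from interval-equation coefficient {cb['prev_sibling_died']:.4f})")
    lines.append(
        f"- One surviving boy vs one surviving girl, next interval: "
        f"{derived.percent_effect(cb['at_least_one_boy'] - cb['at_least_one_girl']):+.1f}%")
    lines.append(
        f"- Third surviving boy vs girl (one of each already): "
        f"{derived.percent_effect(cb['boys_excess_1'] - cb['girls_excess_1']):+.1f}%")
    if profile.quadratic > 0:
        lines.append(
            f"- Mortality-minimizing interval, previous sibling survived: "
            f"{derived.interval_turning_point(profile, 0):.1f} months")
        lines.append(
            f"- Mortality-minimizing interval, previous sibling died: "
            f"{derived.interval_turning_point(profile, 1):.1f} months")
    if c1["age_first_birth_sq"] > 0:
        lines.append(
            f"- First-born mortality minimized at maternal age "
            f"{derived.age_minimum(c1['age_first_birth'], c1['age_first_birth_sq']):.1f} years")
    v = np.diag(params.cov_alpha)
    if v[0] > 0:
        lines.append(
            f"- Heterogeneity share, mortality: "
            f"{derived.variance_share(v[0], 1.0):.4f}")
    if v[1] > 0:
        lines.append(
            f"- Heterogeneity share, interval: "
            f"{derived.variance_share(v[1], params.sigma_b ** 2):.4f}")
    if v[2] > 0:
        lines.append(
            f"- Heterogeneity share, fertility: "
            f"{derived.variance_share(v[2], 1.0):.4f}")
    if corr is not None:
        lines.append(
            f"- Heterogeneity correlations (m,b / m,f / b,f): "
            f"{corr[0, 1]:+.3f} / {corr[0, 2]:+.3f} / {corr[1, 2]:+.3f}")
    if table is not None:
        lines += ["", "## Counterfactual simulation", "",
                  table.to_markdown(floatfmt=".2f"), ""]
        mort = table.loc["infant_mortality_per_1000", "benchmark"]
        pct_births = -table.loc["mean_births", "replacement_off"]
        if mort > 0:
            lines.append(
                f"- Replacement effect: "
                f"{derived.replacement_per_death(pct_births, mort):.2f} births "
                f"per infant death (from {pct_births:+.2f}% births at "
                f"{mort:.1f}/1000 mortality)")
    return "\n".join(lines) + "\n"
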