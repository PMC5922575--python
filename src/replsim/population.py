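"""Synthetic mothers: exogenous covariates and first-birth timing.

The generator emulates the published covariate marginals of the Matlab
surveillance sample (1982--2005) for either study area, so that every
downstream stage -- forward simulation, likelihood, estimation -- can be
exercised without access to the (non-public) surveillance data.  Covariates
are drawn independently of each other and of all later outcomes, which makes
them strictly exogenous by construction, matching the model's assumption.
The mother's birth cohort is not drawn: it is derived from her age at first
birth and the first-birth date (cohort = calendar year of first birth minus
age at first birth), which rules out impossible combinations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import WINDOW_END_MONTHS, CovariateVector

#: Calendar year at the start of the observation window (months are counted
#: from 1 July of this year).
WINDOW_START_YEAR = 1982.5

_COHORT_EDGES = (1966.0, 1971.0, 1976.0)  # pre-1966 / 66-70 / 71-75 / post-75

AREAS = ("comparison", "icddrb")


@dataclass
class PopulationConfig:
    """Marginal distributions of the exogenous covariates for one area."""

    n_mothers: int = 1000
    area: str = "comparison"
    seed: int = 0
    muslim_p: float = 0.8985
    male_p: float = 0.5112              # drawn per birth, not per mother
    mother_edu_p: tuple = (0.5050, 0.2551, 0.2399)
    father_edu_p: tuple = (0.5628, 0.2415, 0.1957)
    day_labourer_p: float = 0.2096
    water_p: float = 0.7691
    distance_mean: float = 7.07         # km
    distance_sd: float = 4.04
    age_first_birth_mean: float = 21.08  # years
    age_first_birth_sd: float = 3.21
    window_end: float = WINDOW_END_MONTHS

    def __post_init__(self) -> None:
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        probs = [self.muslim_p, self.male_p, self.day_labourer_p, self.water_p]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("marginal probabilities must lie in [0, 1]")
        for name in ("mother_edu_p", "father_edu_p"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")


class MotherDraw(NamedTuple):
    mother_id: str
    covariates: CovariateVector
    age_at_first_birth: float
    first_birth_date: float  # months since window start


def default_config(area: str, n_mothers: int = 1000, seed: int = 0
                   ) -> PopulationConfig:
    """Published sample marginals for the requested area."""
    if area == "comparison":
        return PopulationConfig(n_mothers=n_mothers, area=area, seed=seed)
    if area == "icddrb":
        return PopulationConfig(
            n_mothers=n_mothers, area=area, seed=seed,
            muslim_p=0.8271, male_p=0.5097,
            mother_edu_p=(0.4848, 0.2486, 0.2666),
            father_edu_p=(0.5567, 0.2265, 0.2168),
            day_labourer_p=0.1961, water_p=0.8776,
            distance_mean=1.87, distance_sd=0.98,
            age_first_birth_mean=21.16, age_first_birth_sd=3.23,
        )
    raise ValueError(f"unknown area {area!r}; expected one of {AREAS}")


def cohort_of(age_at_first_birth: float, first_birth_date: float) -> int:
    """Mother's birth-cohort code from her age and first-birth date."""
    birth_year = WINDOW_START_YEAR + first_birth_date / 12.0 - age_at_first_birth
    code = 0
    for edge in _COHORT_EDGES:
        if birth_year >= edge:
            code += 1
    return code


def generate_mothers(config: PopulationConfig) -> list[MotherDraw]:
    """Independent draws from the configured marginals.

    Distance is normal truncated at 0; age at first birth is normal truncated
    to [15, 40]; the first-birth date is uniform on [0, window_end - 12] so
    every first-born child's infancy is fully observed.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mothers

    def trunc_normal(mean, sd, lo, hi):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                   random_state=rng)

    muslim = rng.random(n) < config.muslim_p
    m_edu = rng.choice(3, size=n, p=np.asarray(config.mother_edu_p))
    f_edu = rng.choice(3, size=n, p=np.asarray(config.father_edu_p))
    day_lab = rng.random(n) < config.day_labourer_p
    water = rng.random(n) < config.water_p
    dist = trunc_normal(config.distance_mean, config.distance_sd, 0.0, np.inf)
    age_fb = trunc_normal(config.age_first_birth_mean, config.age_first_birth_sd,
                          15.0, 40.0)
    first_date = rng.uniform(0.0, config.window_end - 12.0, size=n)

    width = len(str(n))
    mothers = []
    for i in range(n):
        cov = CovariateVector(
            muslim=int(muslim[i]),
            cohort=cohort_of(age_fb[i], first_date[i]),
            mother_edu=int(m_edu[i]),
            father_edu=int(f_edu[i]),
            day_labourer=int(day_lab[i]),
            hygienic_water=int(water[i]),
            distance_km=float(dist[i]),
        )
        mothers.append(MotherDraw(
            mother_id=f"m{i:0{width}d}",
            covariates=cov,
            age_at_first_birth=float(age_fb[i]),
            first_birth_date=float(first_date[i]),
        ))
    return mothers


MOTHERS_CSV_COLUMNS = [
    "mother_id", "ageFB", "first_birth_date_m", "muslim", "cohort",
    "m_edu", "f_edu", "day_lab", "water", "dist_km",
]


def write_mothers(mothers: list[MotherDraw], path) -> None:
    rows = [{
        "mother_id": m.mother_id,
        "ageFB": m.age_at_first_birth,
        "first_birth_date_m": m.first_birth_date,
        "muslim": m.covariates.muslim,
        "cohort": m.covariates.cohort,
        "m_edu": m.covariates.mother_edu,
        "f_edu": m.covariates.father_edu,
        "day_lab": m.covariates.day_labourer,
        "water": m.covariates.hygienic_water,
        "dist_km": m.covariates.distance_km,
    } for m in mothers]
    pd.DataFrame(rows, columns=MOTHERS_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_mothers(path) -> list[MotherDraw]:
    df = pd.read_csv(path, dtype={"mother_id": str},
                     float_precision="round_trip")
    missing = [c for c in MOTHERS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    out = []
    for _, r in df.iterrows():
        cov = CovariateVector(
            muslim=int(r["muslim"]), cohort=int(r["cohort"]),
            mother_edu=int(r["m_edu"]), father_edu=int(r["f_edu"]),
            day_labourer=int(r["day_lab"]), hygienic_water=int(r["water"]),
            distance_km=float(r["dist_km"]),
        )
        out.append(MotherDraw(str(r["mother_id"]), cov, float(r["ageFB"]),
                              float(r["first_birth_date_m"])))
    return out
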