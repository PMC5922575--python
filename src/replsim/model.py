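"""Model parameterization and design-row construction.

Four linked equations drive a mother's history:

* first-born infant mortality:    M*_1 = x1'b1 + theta*a_m + u          (probit)
* later-born infant mortality:    M*_t = xm'bm + a_m + u                (probit)
* log birth interval:             b_t  = xb'bb + a_b + e,  e ~ N(0, s^2)
* continuation (another birth):   F*_t = xf'bf + a_f + u                (probit)

with (a_m, a_b, a_f) ~ N(0, Sigma) shared by all of a mother's births.  This
module owns the fixed covariate layout of each equation (the column order of
the published estimates table) and builds the per-birth design rows from a
:class:`~replsim.datamodel.CovariateVector` and an endogenous state.

The spacing and continuation equations share a decision epoch: the interval
to birth t+1 and the continuation outcome F_t are both decided after birth t,
so both use the state at parity t (survival and sex of birth t, composition
over births 1..t, order t, and -- by default -- the mother's age at birth t).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .datamodel import CovariateVector, EndogenousState

# Column layouts; names double as documentation of the fixed coding.
_EXOG = [
    "muslim", "cohort_1966_70", "cohort_1971_75", "cohort_post_1975",
    "mother_edu_primary", "mother_edu_secondary",
    "father_edu_primary", "father_edu_secondary",
    "day_labourer", "hygienic_water", "distance_km",
]

MORTALITY_LATER_TERMS = (
    ["log_prev_interval", "log_prev_interval_sq", "logb_x_prev_died",
     "prev_sibling_died", "male"] + [_EXOG[0]] + ["birth_order", "birth_order_sq"]
    + _EXOG[1:4] + ["mother_age", "mother_age_sq"] + _EXOG[4:] + ["const"]
)
MORTALITY_FIRST_TERMS = (
    ["male"] + [_EXOG[0]] + _EXOG[1:4] + ["age_first_birth", "age_first_birth_sq"]
    + _EXOG[4:] + ["const"]
)
SPACING_FERTILITY_TERMS = (
    ["prev_sibling_died", "male"] + [_EXOG[0]] + ["birth_order", "birth_order_sq"]
    + _EXOG[1:4] + ["mother_age", "mother_age_sq"] + _EXOG[4:]
    + ["at_least_one_boy", "at_least_one_girl", "boys_excess_1", "girls_excess_1",
       "const"]
)

N_MORT_LATER = len(MORTALITY_LATER_TERMS)      # 21
N_MORT_FIRST = len(MORTALITY_FIRST_TERMS)      # 15
N_SPACING = len(SPACING_FERTILITY_TERMS)       # 22

VARIANTS = ("benchmark", "no_heterogeneity", "no_fertility_eq", "logistic_mortality")


def _exog_part(cov: CovariateVector) -> list[float]:
    return [
        cov.muslim,
        float(cov.cohort == 1), float(cov.cohort == 2), float(cov.cohort == 3),
        float(cov.mother_edu == 1), float(cov.mother_edu == 2),
        float(cov.father_edu == 1), float(cov.father_edu == 2),
        cov.day_labourer, cov.hygienic_water, cov.distance_km,
    ]


def mortality_first_row(cov: CovariateVector, age_first_birth: float,
                        male: int) -> np.ndarray:
    e = _exog_part(cov)
    return np.array(
        [male, e[0], *e[1:4], age_first_birth, age_first_birth ** 2, *e[4:], 1.0]
    )


def mortality_later_row(cov: CovariateVector, state: EndogenousState,
                        male: int, *, suppress_state_dependence: bool = False,
                        ) -> np.ndarray:
    """Design row of the later-born mortality equation at parity t >= 2.

    ``suppress_state_dependence`` zeroes the lagged-mortality main effect and
    its interaction with the log interval (the "no direct effect of lagged
    mortality on mortality" counterfactual)."""
    e = _exog_part(cov)
    died = 0 if suppress_state_dependence else state.prev_sibling_died
    logb = state.log_prev_interval
    return np.array([
        logb, logb ** 2, logb * died, died, male, e[0],
        state.birth_order, state.birth_order ** 2, *e[1:4],
        state.mother_age_at_birth, state.mother_age_at_birth ** 2, *e[4:], 1.0,
    ])


def decision_row(cov: CovariateVector, state: EndogenousState, *,
                 age: float | None = None) -> np.ndarray:
    """Shared design row of the spacing and continuation equations at the
    decision epoch after birth t (= ``state.parity``).

    ``age`` overrides the maternal age regressor (used by the configurable
    choice of which birth's age enters the interval equation).  Counterfactual
    scenarios are expressed upstream by passing a scenario-adjusted state."""
    e = _exog_part(cov)
    t = state.parity
    if age is None:
        age = state.mother_age_at_birth
    return np.array([
        state.last_child_died, state.last_child_male, e[0], t, t ** 2, *e[1:4],
        age, age ** 2, *e[4:],
        state.at_least_one_boy_surviving, state.at_least_one_girl_surviving,
        state.boys_surviving_excess_1, state.girls_surviving_excess_1, 1.0,
    ])


def psd_cholesky(a: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Lower Cholesky factor of a PSD matrix; pivots below ``tol`` (relative
    to the largest diagonal entry) are treated as exactly zero."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    L = np.zeros_like(a)
    scale = max(np.max(np.diag(a)), 1.0)
    for j in range(n):
        d = a[j, j] - L[j, :j] @ L[j, :j]
        if d <= tol * scale:
            continue
        L[j, j] = np.sqrt(d)
        for i in range(j + 1, n):
            L[i, j] = (a[i, j] - L[i, :j] @ L[j, :j]) / L[j, j]
    return L


@dataclass
class ParameterSet:
    """All coefficients of the four equations plus the heterogeneity structure.

    ``cov_alpha`` is the 3x3 covariance of (a_m, a_b, a_f); ``theta`` loads
    a_m into the first-born equation; ``sigma_b`` is the idiosyncratic s.d.
    of the log-interval equation.
    """

    beta_first: np.ndarray       # (15,)
    theta: float
    beta_mort: np.ndarray        # (21,)
    beta_interval: np.ndarray    # (22,)
    sigma_b: float
    beta_fert: np.ndarray        # (22,)
    cov_alpha: np.ndarray        # (3, 3) PSD

    def __post_init__(self) -> None:
        self.beta_first = np.asarray(self.beta_first, dtype=float)
        self.beta_mort = np.asarray(self.beta_mort, dtype=float)
        self.beta_interval = np.asarray(self.beta_interval, dtype=float)
        self.beta_fert = np.asarray(self.beta_fert, dtype=float)
        self.cov_alpha = np.asarray(self.cov_alpha, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.beta_first.shape != (N_MORT_FIRST,):
            raise ValueError(f"beta_first must have shape ({N_MORT_FIRST},)")
        if self.beta_mort.shape != (N_MORT_LATER,):
            raise ValueError(f"beta_mort must have shape ({N_MORT_LATER},)")
        if self.beta_interval.shape != (N_SPACING,):
            raise ValueError(f"beta_interval must have shape ({N_SPACING},)")
        if self.beta_fert.shape != (N_SPACING,):
            raise ValueError(f"beta_fert must have shape ({N_SPACING},)")
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be > 0")
        if self.cov_alpha.shape != (3, 3):
            raise ValueError("cov_alpha must be 3x3")
        if not np.allclose(self.cov_alpha, self.cov_alpha.T):
            raise ValueError("cov_alpha must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov_alpha)) < -1e-10:
            raise ValueError("cov_alpha must be positive semi-definite")

    def chol_alpha(self) -> np.ndarray:
        """Lower Cholesky factor of cov_alpha, tolerating zero rows/columns
        (semi-definite pivots are set to zero exactly, so a zero covariance
        yields exactly-zero heterogeneity draws)."""
        return psd_cholesky(self.cov_alpha)

    def coefficient_dict(self) -> dict[str, dict[str, float]]:
        """Named coefficients per equation (for reports and serialization)."""
        return {
            "mortality_first": dict(zip(MORTALITY_FIRST_TERMS, self.beta_first)),
            "mortality_later": dict(zip(MORTALITY_LATER_TERMS, self.beta_mort)),
            "interval": dict(zip(SPACING_FERTILITY_TERMS, self.beta_interval)),
            "fertility": dict(zip(SPACING_FERTILITY_TERMS, self.beta_fert)),
        }

    def to_json(self, path=None) -> str:
        obj = {
            "beta_first": self.beta_first.tolist(),
            "theta": self.theta,
            "beta_mort": self.beta_mort.tolist(),
            "beta_interval": self.beta_interval.tolist(),
            "sigma_b": self.sigma_b,
            "beta_fert": self.beta_fert.tolist(),
            "cov_alpha": self.cov_alpha.tolist(),
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "ParameterSet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            beta_first=np.array(obj["beta_first"]),
            theta=float(obj["theta"]),
            beta_mort=np.array(obj["beta_mort"]),
            beta_interval=np.array(obj["beta_interval"]),
            sigma_b=float(obj["sigma_b"]),
            beta_fert=np.array(obj["beta_fert"]),
            cov_alpha=np.array(obj["cov_alpha"]),
        )

    @classmethod
    def zeros(cls, sigma_b: float = 1.0) -> "ParameterSet":
        return cls(
            beta_first=np.zeros(N_MORT_FIRST), theta=1.0,
            beta_mort=np.zeros(N_MORT_LATER),
            beta_interval=np.zeros(N_SPACING), sigma_b=sigma_b,
            beta_fert=np.zeros(N_SPACING), cov_alpha=np.zeros((3, 3)),
        )
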