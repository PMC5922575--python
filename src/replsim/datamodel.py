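"""Domain types for mother-level birth histories.

The unit of analysis is a mother observed from her first live birth until the
end of a fixed observation window.  Time is measured in real-valued months
since the window start (1 July 1982 by convention); ages are in years.  Each
live birth carries its order (parity), date, sex and infant-death outcome
(death within the first 12 months).  A child whose 12-month follow-up extends
beyond the window end has ``death_observed = 0`` and contributes no mortality
information to the likelihood.

The endogenous state at parity t collects every function of the history
prefix that enters the model equations: the preceding (log) birth interval,
survival status of the preceding sibling, birth order, maternal age, and the
family-composition counts of surviving boys and girls.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import pandas as pd

#: Default observation window length in months (1 July 1982 -- 31 Dec 2005).
WINDOW_END_MONTHS = 282.0
#: Reproductive span upper bound (years); births beyond this age are not modelled.
REPRODUCTIVE_AGE_LIMIT = 45.0
#: Biological floor on a birth interval (months).
MIN_INTERVAL_MONTHS = 9.0
#: Infancy duration defining the mortality outcome (months).
INFANCY_MONTHS = 12.0

SEXES = ("M", "F")
N_COHORTS = 4  # pre-1966, 1966-70, 1971-75, post-1975
N_EDU = 3      # none, primary, secondary+


@dataclass(frozen=True)
class CovariateVector:
    """Strictly exogenous mother/household covariates with fixed coding.

    Reference categories: no education, pre-1966 cohort, non-labourer,
    non-hygienic water source.
    """

    muslim: int
    cohort: int          # 0: pre-1966, 1: 1966-70, 2: 1971-75, 3: post-1975
    mother_edu: int      # 0: none, 1: some primary, 2: at least some secondary
    father_edu: int
    day_labourer: int
    hygienic_water: int
    distance_km: float   # distance to nearest health facility

    def __post_init__(self) -> None:
        if self.muslim not in (0, 1):
            raise ValueError(f"muslim must be 0/1, got {self.muslim}")
        if not 0 <= self.cohort < N_COHORTS:
            raise ValueError(f"cohort must be in 0..3, got {self.cohort}")
        for name in ("mother_edu", "father_edu"):
            if not 0 <= getattr(self, name) < N_EDU:
                raise ValueError(f"{name} must be in 0..2")
        for name in ("day_labourer", "hygienic_water"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0/1")
        if self.distance_km < 0:
            raise ValueError("distance_km must be >= 0")


@dataclass(frozen=True)
class BirthEvent:
    order: int           # parity t >= 1
    birth_date: float    # months since window start
    sex: str             # "M" or "F"
    infant_death: int    # died within 12 months of birth
    death_observed: int = 1  # 12-month follow-up fits inside the window

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.birth_date < 0:
            raise ValueError("birth_date must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.infant_death not in (0, 1):
            raise ValueError("infant_death must be 0/1")
        if self.death_observed not in (0, 1):
            raise ValueError("death_observed must be 0/1")

    @property
    def male(self) -> int:
        return 1 if self.sex == "M" else 0


@dataclass
class MotherHistory:
    """Ordered sequence of a mother's live births plus her censoring bound."""

    mother_id: str
    covariates: CovariateVector
    age_at_first_birth: float  # years
    births: list[BirthEvent]
    window_end: float = WINDOW_END_MONTHS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        b = self.births
        if not b:
            raise ValueError(f"mother {self.mother_id}: empty birth list")
        orders = [e.order for e in b]
        if orders != list(range(1, len(b) + 1)):
            raise ValueError(
                f"mother {self.mother_id}: non-contiguous parity sequence {orders}"
            )
        dates = [e.birth_date for e in b]
        for t in range(1, len(dates)):
            gap = dates[t] - dates[t - 1]
            if gap < MIN_INTERVAL_MONTHS - 1e-9:
                raise ValueError(
                    f"mother {self.mother_id}: interval before birth {t + 1} is "
                    f"{gap:.2f} months (< {MIN_INTERVAL_MONTHS})"
                )
        if dates[-1] > self.window_end + 1e-9:
            raise ValueError(
                f"mother {self.mother_id}: birth after window end "
                f"({dates[-1]:.1f} > {self.window_end})"
            )
        if self.age_at_birth(self.n_births) > REPRODUCTIVE_AGE_LIMIT + 1e-9:
            raise ValueError(
                f"mother {self.mother_id}: maternal age at birth exceeds "
                f"{REPRODUCTIVE_AGE_LIMIT}"
            )

    @property
    def n_births(self) -> int:
        return len(self.births)

    def age_at_birth(self, t: int) -> float:
        """Maternal age (years) at birth t (1-based)."""
        d0 = self.births[0].birth_date
        return self.age_at_first_birth + (self.births[t - 1].birth_date - d0) / 12.0

    def interval_before(self, t: int) -> float:
        """Birth interval (months) between births t-1 and t, for t >= 2."""
        if t < 2:
            raise ValueError("interval_before requires t >= 2")
        return self.births[t - 1].birth_date - self.births[t - 2].birth_date

    def censor_bound(self) -> float:
        """Months from the last birth to the earlier of the window end and the
        date the mother turns 45 -- the right-censoring bound c for the next
        (unobserved) birth interval."""
        turns_45 = self.births[0].birth_date + (
            REPRODUCTIVE_AGE_LIMIT - self.age_at_first_birth
        ) * 12.0
        return min(self.window_end, turns_45) - self.births[-1].birth_date


@dataclass(frozen=True)
class EndogenousState:
    """Deterministic functions of the history prefix up to and including birth t.

    ``prev_sibling_died`` refers to birth t-1 (0 when t == 1, where it never
    enters any equation); ``last_child_died`` / ``last_child_male`` refer to
    birth t itself and feed the spacing/continuation equations whose decision
    epoch is birth t.  Composition counts run over births 1..t using final
    infant-survival status.
    """

    parity: int
    log_prev_interval: float         # nan when parity == 1
    prev_sibling_died: int
    birth_order: int
    mother_age_at_birth: float       # years, at birth t
    at_least_one_boy_surviving: int
    at_least_one_girl_surviving: int
    boys_surviving_excess_1: int
    girls_surviving_excess_1: int
    last_child_died: int
    last_child_male: int

    @property
    def log_prev_interval_sq(self) -> float:
        return self.log_prev_interval ** 2

    @property
    def interaction_logb_prev_died(self) -> float:
        return self.log_prev_interval * self.prev_sibling_died


def build_state(history: MotherHistory, t: int) -> EndogenousState:
    """Endogenous state (Z variables) at parity t, a pure function of the
    prefix births 1..t."""
    if not 1 <= t <= history.n_births:
        raise ValueError(f"t={t} out of range 1..{history.n_births}")
    births = history.births[:t]
    boys = sum(1 for b in births if b.male and not b.infant_death)
    girls = sum(1 for b in births if not b.male and not b.infant_death)
    if t >= 2:
        logb = math.log(history.interval_before(t))
        prev_died = births[t - 2].infant_death
    else:
        logb = float("nan")
        prev_died = 0
    return EndogenousState(
        parity=t,
        log_prev_interval=logb,
        prev_sibling_died=prev_died,
        birth_order=t,
        mother_age_at_birth=history.age_at_birth(t),
        at_least_one_boy_surviving=int(boys >= 1),
        at_least_one_girl_surviving=int(girls >= 1),
        boys_surviving_excess_1=max(0, boys - 1),
        girls_surviving_excess_1=max(0, girls - 1),
        last_child_died=births[t - 1].infant_death,
        last_child_male=births[t - 1].male,
    )


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "mother_id", "order", "birth_date_m", "sex", "infant_death", "ageFB",
    "muslim", "cohort", "m_edu", "f_edu", "day_lab", "water", "dist_km",
]


def read_histories(path, window_end: float = WINDOW_END_MONTHS) -> list[MotherHistory]:
    """Read mother histories from a long-format UTF-8 CSV (one row per live
    birth).  Rows are grouped by mother and sorted by order; any invariant
    violation raises ``ValueError`` naming the offending mother/row."""
    df = pd.read_csv(path, dtype={"mother_id": str, "sex": str},
                     float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    histories = []
    for mid, grp in df.groupby("mother_id", sort=True):
        grp = grp.sort_values("order")
        if grp["order"].duplicated().any():
            dup = int(grp["order"][grp["order"].duplicated()].iloc[0])
            raise ValueError(f"mother {mid}: duplicate (mother, order) for order {dup}")
        orders = grp["order"].tolist()
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError(
                f"mother {mid}: non-contiguous parity sequence {orders}"
            )
        first = grp.iloc[0]
        cov = CovariateVector(
            muslim=int(first["muslim"]),
            cohort=int(first["cohort"]),
            mother_edu=int(first["m_edu"]),
            father_edu=int(first["f_edu"]),
            day_labourer=int(first["day_lab"]),
            hygienic_water=int(first["water"]),
            distance_km=float(first["dist_km"]),
        )
        births = [
            BirthEvent(
                order=int(r["order"]),
                birth_date=float(r["birth_date_m"]),
                sex=str(r["sex"]),
                infant_death=int(r["infant_death"]),
                death_observed=int(
                    float(r["birth_date_m"]) + INFANCY_MONTHS <= window_end + 1e-9
                ),
            )
            for _, r in grp.iterrows()
        ]
        histories.append(
            MotherHistory(
                mother_id=str(mid),
                covariates=cov,
                age_at_first_birth=float(first["ageFB"]),
                births=births,
                window_end=window_end,
            )
        )
    return histories


def write_histories(histories: list[MotherHistory], path) -> None:
    """Write histories to the long-format CSV read back by read_histories."""
    rows = []
    for h in histories:
        c = h.covariates
        for b in h.births:
            rows.append({
                "mother_id": h.mother_id,
                "order": b.order,
                "birth_date_m": b.birth_date,
                "sex": b.sex,
                "infant_death": b.infant_death,
                "ageFB": h.age_at_first_birth,
                "muslim": c.muslim,
                "cohort": c.cohort,
                "m_edu": c.mother_edu,
                "f_edu": c.father_edu,
                "day_lab": c.day_labourer,
                "water": c.hygienic_water,
                "dist_km": c.distance_km,
            })
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False,
                                                   float_format="%.17g")
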