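"""Forward microsimulation of complete birth/death histories.

The simulator runs the data-generating process of the four-equation model
along the event timeline: for each mother, draw the heterogeneity triple
(a_m, a_b, a_f) once, then recursively draw child sex, infant mortality,
the continuation decision, and the next birth interval, advancing calendar
time and maternal age until the mother stops, reaches age 45, or hits the
end of the observation window.  It doubles as the synthetic-data engine for
estimation experiments and produces the counterfactual scenario table
(replacement off, state dependence off, all-boys).

Common random numbers: all stochastic inputs for a (mother, replication)
pair live in a :class:`DrawBundle` indexed by birth slot, regenerated
deterministically from ``(seed, mother index, replication)``.  Scenario
switches change only the linear indices, never the draws, so scenario
contrasts are free of Monte-Carlo noise from differing randomness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .datamodel import (
    INFANCY_MONTHS,
    MIN_INTERVAL_MONTHS,
    REPRODUCTIVE_AGE_LIMIT,
    WINDOW_END_MONTHS,
    BirthEvent,
    CovariateVector,
    EndogenousState,
    MotherHistory,
)
from .model import ParameterSet, decision_row, mortality_first_row, mortality_later_row
from .population import MotherDraw

#: Hard cap on birth slots per history; a 30-year reproductive span with the
#: 9-month interval floor cannot produce more than ~40 births.
MAX_BIRTHS = 48

DEFAULT_MALE_P = 0.5112  # comparison-area share of male births


@dataclass(frozen=True)
class ScenarioFlags:
    """Counterfactual switches; all off reproduces the benchmark process.

    ``replacement_off``: spacing and continuation behave as if every child
    survived its infancy (no effect of realized mortality on either).
    ``state_dependence_off``: the lagged-mortality main effect and its
    log-interval interaction are removed from the later-born mortality
    equation only.
    ``all_boys``: family composition and the child-sex regressor in the
    spacing/continuation equations are computed as if all children were boys;
    the drawn sex still enters the mortality equations.
    """

    replacement_off: bool = False
    state_dependence_off: bool = False
    all_boys: bool = False


@dataclass(frozen=True)
class SummaryStats:
    infant_mortality_per_1000: float
    median_interval_months: float
    mean_births: float
    mean_survivors: float

    def as_dict(self) -> dict[str, float]:
        return {
            "infant_mortality_per_1000": self.infant_mortality_per_1000,
            "median_interval_months": self.median_interval_months,
            "mean_births": self.mean_births,
            "mean_survivors": self.mean_survivors,
        }


@dataclass(frozen=True)
class DrawBundle:
    """All randomness for one simulated history, indexed by birth slot."""

    alpha_z: np.ndarray  # (3,) standard normal
    u_sex: np.ndarray    # (MAX_BIRTHS,) uniform
    u_mort: np.ndarray   # (MAX_BIRTHS,) uniform
    u_cont: np.ndarray   # (MAX_BIRTHS,) uniform
    z_interval: np.ndarray  # (MAX_BIRTHS,) standard normal

    @classmethod
    def from_rng(cls, rng: np.random.Generator) -> "DrawBundle":
        return cls(
            alpha_z=rng.standard_normal(3),
            u_sex=rng.random(MAX_BIRTHS),
            u_mort=rng.random(MAX_BIRTHS),
            u_cont=rng.random(MAX_BIRTHS),
            z_interval=rng.standard_normal(MAX_BIRTHS),
        )


def _scenario_state(births: list[BirthEvent], age: float,
                    flags: ScenarioFlags) -> EndogenousState:
    """Decision-epoch state after the latest birth, under scenario switches."""
    t = len(births)
    boys = girls = 0
    for b in births:
        alive = True if flags.replacement_off else not b.infant_death
        male = True if flags.all_boys else bool(b.male)
        if alive:
            if male:
                boys += 1
            else:
                girls += 1
    last = births[-1]
    return EndogenousState(
        parity=t,
        log_prev_interval=float("nan"),
        prev_sibling_died=0,
        birth_order=t,
        mother_age_at_birth=age,
        at_least_one_boy_surviving=int(boys >= 1),
        at_least_one_girl_surviving=int(girls >= 1),
        boys_surviving_excess_1=max(0, boys - 1),
        girls_surviving_excess_1=max(0, girls - 1),
        last_child_died=0 if flags.replacement_off else last.infant_death,
        last_child_male=1 if flags.all_boys else last.male,
    )


def simulate_history(covariates: CovariateVector, first_birth_date: float,
                     age_at_first_birth: float, params: ParameterSet,
                     flags: ScenarioFlags = ScenarioFlags(),
                     rng: np.random.Generator | None = None,
                     draws: DrawBundle | None = None, *,
                     male_p: float = DEFAULT_MALE_P,
                     window_end: float = WINDOW_END_MONTHS,
                     mortality_link: str = "probit",
                     mother_id: str = "sim") -> MotherHistory:
    """Generate one complete history from the model's data-generating process.

    Either ``rng`` or a pre-generated ``draws`` bundle must be supplied; the
    bundle form is what the counterfactual table uses to share randomness
    across scenarios.  ``mortality_link`` switches the mortality equations
    (only) to a logistic error distribution.
    """
    if draws is None:
        if rng is None:
            raise ValueError("supply rng or draws")
        draws = DrawBundle.from_rng(rng)
    if mortality_link == "probit":
        mort_cdf = ndtr
    elif mortality_link == "logistic":
        mort_cdf = expit
    else:
        raise ValueError("mortality_link must be 'probit' or 'logistic'")

    alpha = params.chol_alpha() @ draws.alpha_z
    bf, bm = params.beta_first, params.beta_mort
    bb, bff = params.beta_interval, params.beta_fert
    cov = covariates

    births: list[BirthEvent] = []
    date = first_birth_date
    last_logb = float("nan")
    for t in range(1, MAX_BIRTHS + 1):
        male = int(draws.u_sex[t - 1] < male_p)
        sex = "M" if male else "F"
        age = age_at_first_birth + (date - first_birth_date) / 12.0
        if t == 1:
            idx_m = float(
                mortality_first_row(cov, age_at_first_birth, male) @ bf
            ) + params.theta * alpha[0]
        else:
            st_m = EndogenousState(
                parity=t, log_prev_interval=last_logb,
                prev_sibling_died=births[-1].infant_death,
                birth_order=t, mother_age_at_birth=age,
                at_least_one_boy_surviving=0, at_least_one_girl_surviving=0,
                boys_surviving_excess_1=0, girls_surviving_excess_1=0,
                last_child_died=0, last_child_male=0,
            )
            idx_m = float(mortality_later_row(
                cov, st_m, male,
                suppress_state_dependence=flags.state_dependence_off) @ bm
            ) + alpha[0]
        died = int(draws.u_mort[t - 1] < mort_cdf(idx_m))
        births.append(BirthEvent(
            order=t, birth_date=date, sex=sex, infant_death=died,
            death_observed=int(date + INFANCY_MONTHS <= window_end + 1e-9),
        ))

        st = _scenario_state(births, age, flags)
        idx_f = float(decision_row(cov, st) @ bff) + alpha[2]
        if draws.u_cont[t - 1] >= ndtr(idx_f):
            break  # mother decides to stop
        idx_b = float(decision_row(cov, st) @ bb) + alpha[1]
        interval = math.exp(idx_b + params.sigma_b * draws.z_interval[t - 1])
        interval = max(interval, MIN_INTERVAL_MONTHS)
        next_date = date + interval
        next_age = age_at_first_birth + (next_date - first_birth_date) / 12.0
        if next_date > window_end or next_age > REPRODUCTIVE_AGE_LIMIT:
            break  # next birth censored by window or reproductive limit
        date = next_date
        last_logb = math.log(interval)

    return MotherHistory(
        mother_id=mother_id, covariates=covariates,
        age_at_first_birth=age_at_first_birth, births=births,
        window_end=window_end,
    )


def _mother_rng(seed: int, mother_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, mother_index, rep]))


def simulate_histories(mothers: list[MotherDraw], params: ParameterSet,
                       flags: ScenarioFlags = ScenarioFlags(), seed: int = 0, *,
                       male_p: float = DEFAULT_MALE_P,
                       window_end: float = WINDOW_END_MONTHS,
                       mortality_link: str = "probit",
                       rep: int = 0) -> list[MotherHistory]:
    """One replication of simulated histories for a list of mothers
    (the estimation-experiment entry point)."""
    return [
        simulate_history(
            m.covariates, m.first_birth_date, m.age_at_first_birth, params,
            flags, draws=DrawBundle.from_rng(_mother_rng(seed, i, rep)),
            male_p=male_p, window_end=window_end,
            mortality_link=mortality_link, mother_id=m.mother_id,
        )
        for i, m in enumerate(mothers)
    ]


def summarize(histories: list[MotherHistory]) -> SummaryStats:
    """Pooled summary statistics over a set of histories."""
    if not histories:
        raise ValueError("empty population")
    births = deaths = survivors = 0
    intervals: list[float] = []
    for h in histories:
        births += h.n_births
        deaths += sum(b.infant_death for b in h.births)
        survivors += sum(1 - b.infant_death for b in h.births)
        intervals.extend(h.interval_before(t) for t in range(2, h.n_births + 1))
    n = len(histories)
    return SummaryStats(
        infant_mortality_per_1000=1000.0 * deaths / births,
        median_interval_months=float(np.median(intervals)) if intervals
        else float("nan"),
        mean_births=births / n,
        mean_survivors=survivors / n,
    )


def simulate_population(mothers: list[MotherDraw], params: ParameterSet,
                        flags: ScenarioFlags = ScenarioFlags(),
                        n_reps: int = 25, seed: int = 0, *,
                        male_p: float = DEFAULT_MALE_P,
                        window_end: float = WINDOW_END_MONTHS,
                        median_per_replication: bool = False) -> SummaryStats:
    """Summary statistics pooled over mothers x replications.

    Infant mortality is per 1000 live births; the median interval is pooled
    over all intervals (or, optionally, computed per replication and
    averaged); births and survivors are means per mother.
    """
    if not mothers or n_reps < 1:
        raise ValueError("empty population")
    births = deaths = survivors = 0
    intervals: list[float] = []
    rep_medians: list[float] = []
    for rep in range(n_reps):
        rep_intervals: list[float] = []
        for i, m in enumerate(mothers):
            h = simulate_history(
                m.covariates, m.first_birth_date, m.age_at_first_birth,
                params, flags, draws=DrawBundle.from_rng(_mother_rng(seed, i, rep)),
                male_p=male_p, window_end=window_end, mother_id=m.mother_id,
            )
            births += h.n_births
            deaths += sum(b.infant_death for b in h.births)
            survivors += sum(1 - b.infant_death for b in h.births)
            rep_intervals.extend(
                h.interval_before(t) for t in range(2, h.n_births + 1))
        intervals.extend(rep_intervals)
        if median_per_replication and rep_intervals:
            rep_medians.append(float(np.median(rep_intervals)))
    n = len(mothers) * n_reps
    if median_per_replication:
        med = float(np.mean(rep_medians)) if rep_medians else float("nan")
    else:
        med = float(np.median(intervals)) if intervals else float("nan")
    return SummaryStats(
        infant_mortality_per_1000=1000.0 * deaths / births,
        median_interval_months=med,
        mean_births=births / n,
        mean_survivors=survivors / n,
    )


SCENARIOS = {
    "benchmark": ScenarioFlags(),
    "replacement_off": ScenarioFlags(replacement_off=True),
    "state_dependence_off": ScenarioFlags(state_dependence_off=True),
    "all_boys": ScenarioFlags(all_boys=True),
}


def counterfactual_table(mothers: list[MotherDraw], params: ParameterSet,
                         seed: int = 0, n_reps: int = 25, *,
                         male_p: float = DEFAULT_MALE_P,
                         window_end: float = WINDOW_END_MONTHS,
                         median_per_replication: bool = False) -> pd.DataFrame:
    """Benchmark levels and percent deviations for the three counterfactual
    scenarios, under common random numbers.

    Rows are the four summary statistics; the ``benchmark`` column holds
    levels, the scenario columns hold 100 * (scenario - benchmark)/benchmark.
    """
    stats = {
        name: simulate_population(
            mothers, params, flags, n_reps=n_reps, seed=seed, male_p=male_p,
            window_end=window_end,
            median_per_replication=median_per_replication).as_dict()
        for name, flags in SCENARIOS.items()
    }
    base = stats["benchmark"]
    table = {"benchmark": base}
    for name in ("replacement_off", "state_dependence_off", "all_boys"):
        table[name] = {
            k: 100.0 * (stats[name][k] - base[k]) / base[k] for k in base
        }
    return pd.DataFrame(table)
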