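"""Individual-level Monte-Carlo engine and deterministic cohort oracle.

The model is a first-order microsimulation: each person is walked
through annual cycles, sampling the destination state from the
transition row for their (arm, state, age).  Microsimulation rather
than a cohort-level chain is required because the utility weight
depends on each person's diabetes duration — a memory variable a
state-occupancy model cannot carry.

Accrual conventions (used identically by the microsimulation and the
oracle, so that they are comparable to Monte-Carlo error):

* The entry cycle is cycle 1; rewards of cycle t are discounted by
  ``(1+r)**-t``.
* Half-cycle correction credits a transition cycle with the mean of the
  origin- and destination-state rewards (death counts as zero reward,
  so a death cycle credits half the origin reward, and half a
  life-year).  With the correction disabled, a cycle credits the full
  origin-state reward if survived and nothing in the death cycle.
* Life-years are accumulated undiscounted; costs and QALYs are
  discounted at their respective rates.

Randomness: every individual owns a counter-based substream seeded by
``(master_seed, arm, person_id)``, so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .hecon import cycle_cost, discount_factor, icer, state_utility
from .lifetable import LifeTable
from .params import ParameterSet
from .transitions import (HealthState, TransitionContext,
                          build_transition_row)

logger = logging.getLogger("prediasim")

_ARM_CODE = {"control": 0, "intervention": 1}
_MAX_CYCLES = 200           # hard stop for the lifetime horizon
ONSET_RESTRICTION = 30      # restricted-mean window for onset delays, years


@dataclass
class Individual:
    """One simulated person: state, memory and accumulators."""

    id: int
    arm: str = "control"
    current_age: int = 45
    state: HealthState = HealthState.IGT
    dm2_duration: int = 0
    years_since_entry: int = 0
    alive: bool = True
    dm2_onset_cycle: Optional[int] = None
    cvd_onset_cycle: Optional[int] = None
    death_cycle: Optional[int] = None
    acc_cost_discounted: float = 0.0
    acc_qaly_discounted: float = 0.0
    acc_ly_undiscounted: float = 0.0


@dataclass
class ArmResult:
    """Per-arm summaries (means over the cohort, with standard errors)."""

    arm: str
    n: int
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    cum_incidence_dm2: float
    cum_incidence_death: float
    mean_dm2_onset_time: float
    mean_cvd_onset_time: float
    se_cost: float
    se_qaly: float
    se_ly: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RunResult:
    """Both arms plus incremental summaries."""

    control: ArmResult
    intervention: ArmResult
    horizon_mode: str
    seed: int
    incr_cost: float = field(init=False)
    incr_qaly: float = field(init=False)
    incr_ly: float = field(init=False)
    icer: Optional[float] = field(init=False)

    def __post_init__(self):
        self.incr_cost = self.intervention.mean_cost - self.control.mean_cost
        self.incr_qaly = self.intervention.mean_qaly - self.control.mean_qaly
        self.incr_ly = self.intervention.mean_ly - self.control.mean_ly
        self.icer = (self.incr_cost / self.incr_qaly
                     if self.incr_qaly != 0 else None)

    @property
    def delay_dm2(self) -> float:
        """Between-arm difference in restricted mean time to DM2 onset."""
        return (self.intervention.mean_dm2_onset_time
                - self.control.mean_dm2_onset_time)

    @property
    def delay_cvd(self) -> float:
        return (self.intervention.mean_cvd_onset_time
                - self.control.mean_cvd_onset_time)

    def summary(self, wtp: float = 37446.0):
        return icer(self.incr_cost, self.incr_qaly, wtp)

    def to_frame(self) -> pd.DataFrame:
        rows = [self.control.to_dict(), self.intervention.to_dict()]
        df = pd.DataFrame(rows)
        df["horizon_mode"] = self.horizon_mode
        df["seed"] = self.seed
        df["incr_cost"] = self.incr_cost
        df["incr_qaly"] = self.incr_qaly
        df["incr_ly"] = self.incr_ly
        df["icer"] = self.icer
        return df


class _RowCache:
    """Transition rows keyed by (arm, state, age), in sampling form."""

    def __init__(self, params: ParameterSet, lifetable: LifeTable):
        self.params = params
        self.lifetable = lifetable
        self._cache: dict = {}

    def get(self, arm: str, state: HealthState, age: int):
        key = (arm, state, age)
        hit = self._cache.get(key)
        if hit is None:
            ctx = TransitionContext(arm=arm, age=age, state=state)
            row = build_transition_row(ctx, self.params, self.lifetable)
            dests = [s for s, p in row.items() if p > 0.0]
            cum = np.cumsum([row[s] for s in dests])
            cum[-1] = 1.0  # guard rounding in the last bin
            hit = (dests, cum)
            self._cache[key] = hit
        return hit


def _horizon_cycles(params: ParameterSet) -> Optional[int]:
    return 30 if params.settings.horizon_mode == "thirty_year" else None


def simulate_individual(person: Individual, params: ParameterSet,
                        lifetable: LifeTable, rng: np.random.Generator,
                        row_cache: Optional[_RowCache] = None,
                        memoryless_utilities: bool = False) -> Individual:
    """Advance one person until death, the horizon, or the age cutoff.

    Mutates and returns ``person``.  ``memoryless_utilities`` forces the
    diabetes duration to zero in utility evaluation only (the variant
    the deterministic oracle can reproduce); transitions are unaffected.
    """
    cache = row_cache or _RowCache(params, lifetable)
    s = params.settings
    horizon = _horizon_cycles(params)
    hcc = s.half_cycle_correction
    t = person.years_since_entry
    while person.alive:
        if horizon is not None and t >= horizon:
            break
        if horizon is None and (person.current_age > s.max_age
                                or t >= _MAX_CYCLES):
            break
        t += 1
        state, age, dur = person.state, person.current_age, person.dm2_duration
        udur = 0 if memoryless_utilities else dur
        dests, cum = cache.get(person.arm, state, age)
        dest = dests[int(np.searchsorted(cum, rng.random(), side="right"))]

        u_o = state_utility(state, age, udur, params.utilities)
        c_o = cycle_cost(state, person.arm, t, params.costs)
        if dest == state:
            r_u, r_c, r_ly = u_o, c_o, 1.0
        elif hcc:
            # destination reward at the same age; a fresh DM2 entry has
            # duration 0, DM2->CVD carries the duration along
            ddur = 0 if (memoryless_utilities or state == HealthState.IGT) \
                else dur
            u_n = state_utility(dest, age, ddur, params.utilities)
            c_n = cycle_cost(dest, person.arm, t, params.costs)
            r_u, r_c = 0.5 * (u_o + u_n), 0.5 * (c_o + c_n)
            r_ly = 0.5 if dest == HealthState.DEATH else 1.0
        else:
            died = dest == HealthState.DEATH
            r_u = 0.0 if died else u_o
            r_c = 0.0 if died else c_o
            r_ly = 0.0 if died else 1.0

        person.acc_qaly_discounted += r_u * discount_factor(
            s.discount_rate_effects, t)
        person.acc_cost_discounted += r_c * discount_factor(
            s.discount_rate_costs, t)
        person.acc_ly_undiscounted += r_ly

        if dest == HealthState.DEATH:
            person.alive = False
            person.death_cycle = t
        else:
            if dest == HealthState.DM2 and person.dm2_onset_cycle is None:
                person.dm2_onset_cycle = t
            if dest == HealthState.CVD and person.cvd_onset_cycle is None:
                person.cvd_onset_cycle = t
            if dest in (HealthState.DM2, HealthState.CVD):
                person.dm2_duration += 1
            person.current_age += 1
        person.state = dest
        person.years_since_entry = t
    return person


def _restricted_mean(onsets: list[Optional[int]], window: int) -> float:
    return float(np.mean([min(o, window) if o is not None else window
                          for o in onsets]))


def _aggregate(arm: str, people: list[Individual]) -> ArmResult:
    n = len(people)
    cost = np.array([p.acc_cost_discounted for p in people])
    qaly = np.array([p.acc_qaly_discounted for p in people])
    ly = np.array([p.acc_ly_undiscounted for p in people])
    ever_dm2 = np.array([p.dm2_onset_cycle is not None
                         or p.cvd_onset_cycle is not None for p in people])
    dead = np.array([not p.alive for p in people])
    sqn = np.sqrt(n)
    return ArmResult(
        arm=arm, n=n,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        mean_ly=float(ly.mean()),
        cum_incidence_dm2=float(ever_dm2.mean()),
        cum_incidence_death=float(dead.mean()),
        mean_dm2_onset_time=_restricted_mean(
            [p.dm2_onset_cycle for p in people], ONSET_RESTRICTION),
        mean_cvd_onset_time=_restricted_mean(
            [p.cvd_onset_cycle for p in people], ONSET_RESTRICTION),
        se_cost=float(cost.std(ddof=1) / sqn) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / sqn) if n > 1 else 0.0,
        se_ly=float(ly.std(ddof=1) / sqn) if n > 1 else 0.0,
    )


def simulate_arm(arm: str, params: ParameterSet, lifetable: LifeTable,
                 seed: int, cohort: Optional[list[Individual]] = None,
                 memoryless_utilities: bool = False) -> ArmResult:
    """Simulate one arm over a cohort.

    If no cohort is passed, one is drawn from the default cohort
    specification (trial-like age structure) using ``seed``; pass the
    same cohort to both arms for common-random-number comparisons.
    Each person gets an independent RNG substream keyed by
    ``(seed, arm, id)``.
    """
    if cohort is None:
        from .synthetic import CohortSpec, generate_cohort
        cohort = generate_cohort(CohortSpec(n=params.settings.cohort_size,
                                            seed=seed))
    if not cohort:
        raise ValueError("cohort is empty")
    cache = _RowCache(params, lifetable)
    arm_code = _ARM_CODE[arm]
    people = []
    for proto in cohort:
        person = replace(proto, arm=arm)
        rng = np.random.default_rng((seed, arm_code, person.id))
        people.append(simulate_individual(
            person, params, lifetable, rng, cache, memoryless_utilities))
    result = _aggregate(arm, people)
    logger.info("simulated arm=%s n=%d horizon=%s seed=%d", arm,
                result.n, params.settings.horizon_mode, seed)
    return result


def run_base_case(params: ParameterSet, lifetable: LifeTable,
                  seed: int) -> RunResult:
    """Simulate both arms on a common cohort draw.

    The cohort ages are shared (common random numbers); the transition
    streams are independent between arms.
    """
    from .synthetic import CohortSpec, generate_cohort
    cohort = generate_cohort(CohortSpec(n=params.settings.cohort_size,
                                        seed=seed))
    ctl = simulate_arm("control", params, lifetable, seed, cohort=cohort)
    itv = simulate_arm("intervention", params, lifetable, seed,
                       cohort=cohort)
    return RunResult(control=ctl, intervention=itv,
                     horizon_mode=params.settings.horizon_mode, seed=seed)


# ---------------------------------------------------------------------------
# Deterministic cohort oracle (memoryless-utility variant)
# ---------------------------------------------------------------------------

def cohort_oracle(params: ParameterSet, lifetable: LifeTable,
                  fixed_age: int, arm: str = "control",
                  entry_state: HealthState = HealthState.IGT
                  ) -> tuple[float, float, float]:
    """Exact expected (mean_ly, mean_cost, mean_qaly) for a single-age
    cohort with memoryless utilities.

    Forward multiplication of the state-occupancy vector through the
    same transition rows, with the same half-cycle and discounting
    conventions as the microsimulation.  Utilities are evaluated with
    diabetes duration forced to zero, which is what makes a cohort-level
    expectation exact.
    """
    s = params.settings
    horizon = _horizon_cycles(params)
    hcc = s.half_cycle_correction
    occ = {st: 0.0 for st in HealthState}
    occ[entry_state] = 1.0
    age = fixed_age
    e_ly = e_cost = e_qaly = 0.0
    t = 0
    while True:
        if horizon is not None and t >= horizon:
            break
        if horizon is None and (age > s.max_age or t >= _MAX_CYCLES
                                or occ[HealthState.DEATH] > 1.0 - 1e-12):
            break
        t += 1
        df_u = discount_factor(s.discount_rate_effects, t)
        df_c = discount_factor(s.discount_rate_costs, t)
        new_occ = {st: 0.0 for st in HealthState}
        new_occ[HealthState.DEATH] = occ[HealthState.DEATH]
        for origin in HealthState:
            mass = occ[origin]
            if mass <= 0.0 or origin == HealthState.DEATH:
                continue
            ctx = TransitionContext(arm=arm, age=age, state=origin)
            row = build_transition_row(ctx, params, lifetable)
            u_o = state_utility(origin, age, 0, params.utilities)
            c_o = cycle_cost(origin, arm, t, params.costs)
            for dest, p in row.items():
                if p == 0.0:
                    continue
                flow = mass * p
                new_occ[dest] += flow
                if dest == origin:
                    r_u, r_c, r_ly = u_o, c_o, 1.0
                elif hcc:
                    u_n = state_utility(dest, age, 0, params.utilities)
                    c_n = cycle_cost(dest, arm, t, params.costs)
                    r_u, r_c = 0.5 * (u_o + u_n), 0.5 * (c_o + c_n)
                    r_ly = 0.5 if dest == HealthState.DEATH else 1.0
                else:
                    died = dest == HealthState.DEATH
                    r_u = 0.0 if died else u_o
                    r_c = 0.0 if died else c_o
                    r_ly = 0.0 if died else 1.0
                e_qaly += flow * r_u * df_u
                e_cost += flow * r_c * df_c
                e_ly += flow * r_ly
        total = sum(new_occ.values())
        if abs(total - 1.0) > 1e-12:
            raise AssertionError(f"occupancy drifted to {total} at cycle {t}")
        occ = new_occ
        age += 1
    return e_ly, e_cost, e_qaly


def validate(params: ParameterSet, lifetable: LifeTable,
             seed: int) -> pd.DataFrame:
    """Internal-validation report.

    Cumulative DM2 incidence and all-cause mortality over the run, onset
    delays between arms, and the model's own life expectancy for a
    disease-free run from age 0 against the life table's ``e(0)``.
    """
    run = run_base_case(params, lifetable, seed)
    rows = []
    for arm_res in (run.control, run.intervention):
        rows.append({
            "metric": "cum_incidence_dm2", "arm": arm_res.arm,
            "value": arm_res.cum_incidence_dm2})
        rows.append({
            "metric": "cum_incidence_death", "arm": arm_res.arm,
            "value": arm_res.cum_incidence_death})
    rows.append({"metric": "delay_dm2_onset", "arm": "difference",
                 "value": run.delay_dm2})
    rows.append({"metric": "delay_cvd_onset", "arm": "difference",
                 "value": run.delay_cvd})

    # mortality-only consistency: an NPG cohort with all disease flows
    # switched off must reproduce the life table's own life expectancy
    p0 = params.copy()
    p0.settings.horizon_mode = "lifetime"
    p0.settings.max_age = 120
    p0.epi.p_npg_to_igt = 0.0
    p0.validate()
    ly, _, _ = cohort_oracle(p0, lifetable, fixed_age=0,
                             entry_state=HealthState.NPG)
    rows.append({"metric": "model_life_expectancy_age0", "arm": "model",
                 "value": ly})
    rows.append({"metric": "lifetable_e0", "arm": "reference",
                 "value": lifetable.life_expectancy(0)})
    df = pd.DataFrame(rows)
    df["seed"] = seed
    return df
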