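"""Health-economic accrual rules and summary measures.

Utilities
---------
Utility weights are anchored at age 45 and decline by 0.003 per year of
age for the glucose-regulation states.  Once diabetes is established the
age decrement is carried to the age at onset and a further 0.003 is
subtracted per year of diabetes duration — for onset at or after age 45
the two formulations coincide, but the duration form is the one the
published worked example uses: a subject with diabetes base utility
0.832, ten years of DM2 and a cardiovascular complication scores
0.832 - 0.158 - 10*0.003 = 0.644.  The 0.012 DM2 decrement is effectively
embedded in the onset utility (0.936 - 0.012 ~ 0.925) and is therefore
not applied a second time.  Utilities never go below zero.

Costs
-----
Annual treatment costs attach to the disease states (DM2: 6436; CVD:
DM2 + 11680 yuan, the state being diabetes *with* cardiovascular
disease).  The intervention arm additionally accrues the one-time
program cost (amortized uniformly over the 6 intervention years by
default) and the annual screening/health-management cost every year
alive.  The control arm accrues treatment costs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .params import CostParams, UtilityParams
from .transitions import HealthState


@dataclass(frozen=True)
class CEASummary:
    """Incremental cost-effectiveness summary at a given WTP."""

    incr_cost: float
    incr_effect: float
    icer: Optional[float]      # None when incr_effect == 0
    nmb: float                 # WTP * incr_effect - incr_cost
    classification: str        # dominant | dominated | tradeoff | undefined


def state_utility(state: HealthState, age: float, dm2_duration: float,
                  up: UtilityParams,
                  dm2_base: Optional[float] = None) -> float:
    """Utility weight for one person-year.

    ``dm2_base`` overrides the computed diabetes base utility (the value
    before the duration and complication decrements); by default it is
    the onset utility age-adjusted to the age at onset.
    """
    d = up.age_decrement_per_year
    if state == HealthState.DEATH:
        return 0.0
    if state == HealthState.NPG:
        u = up.u_npg_at45 * up.npg_multiplier - d * max(age - 45.0, 0.0)
    elif state == HealthState.IGT:
        u = up.u_igt_at45 - d * max(age - 45.0, 0.0)
    else:
        if dm2_base is None:
            onset_age = age - dm2_duration
            dm2_base = up.u_dm2_onset_at45 - d * max(onset_age - 45.0, 0.0)
        u = dm2_base - d * dm2_duration
        if state == HealthState.CVD:
            u -= up.cvd_decrement
    return max(u, 0.0)


def cycle_cost(state: HealthState, arm: str, cycle_index: int,
               costs: CostParams) -> float:
    """Cost in yuan accrued for one person-year in ``state``.

    ``cycle_index`` is 1-based; the program cost lands in cycles 1..6
    (amortized) or cycle 1 (lump sum).  Death accrues nothing.
    """
    if state == HealthState.DEATH:
        return 0.0
    c = 0.0
    if state == HealthState.DM2:
        c += costs.dm2_treatment
    elif state == HealthState.CVD:
        c += costs.cvd_treatment
        if costs.cvd_cost_includes_dm2:
            c += costs.dm2_treatment
    if arm == "intervention":
        if costs.screening_full_horizon or \
                cycle_index <= costs.intervention_duration:
            c += costs.annual_screening
        if costs.amortize_intervention:
            if cycle_index <= costs.intervention_duration:
                c += costs.intervention_total / costs.intervention_duration
        elif cycle_index == 1:
            c += costs.intervention_total
    return c


def icer(incr_cost: float, incr_effect: float,
         wtp: float = 37446.0) -> CEASummary:
    """Classify an incremental (cost, effect) pair.

    Dominant means cheaper and more effective (negative ICER reported as
    the raw ratio); dominated the reverse.  A zero incremental effect
    yields no ratio, only a label.
    """
    nmb = wtp * incr_effect - incr_cost
    if incr_effect == 0.0:
        ratio = None
        cls = "dominated" if incr_cost > 0 else "undefined"
    else:
        ratio = incr_cost / incr_effect
        if incr_cost < 0 and incr_effect > 0:
            cls = "dominant"
        elif incr_cost > 0 and incr_effect < 0:
            cls = "dominated"
        else:
            cls = "tradeoff"
    return CEASummary(incr_cost=incr_cost, incr_effect=incr_effect,
                      icer=ratio, nmb=nmb, classification=cls)


def discount_factor(rate: float, cycle_index: int) -> float:
    """End-of-cycle discounting; the entry cycle is cycle 1."""
    return (1.0 + rate) ** (-cycle_index)
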