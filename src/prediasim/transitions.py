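"""Probability arithmetic and per-cycle transition distributions.

The model moves individuals annually among five states — NPG (normal
postprandial glucose), IGT (impaired glucose tolerance), DM2 (type 2
diabetes), CVD (diabetes with cardiovascular disease) and death.  The
allowed edges are NPG<->IGT, IGT->DM2, DM2->CVD, any living state ->
death, plus self-loops; death is absorbing.

All treatment-effect ratios act on the continuous hazard (rate) scale:
an annual probability p is converted to the rate -ln(1-p), multiplied,
and converted back.  This is consistent with the exponential formula
used to annualize cumulative risks, and materially different from
probability-scale multiplication once p exceeds ~0.1.

Composition of a transition row uses competing-risk ordering: death is
resolved first from background mortality (times the state's mortality
multiplier), and disease progression is distributed among survivors.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable

from .lifetable import LifeTable
from .params import Band, EpidemiologicalParams, ParameterSet

_MAX_P = 1.0 - 1e-9


class HealthState(IntEnum):
    NPG = 0
    IGT = 1
    DM2 = 2
    CVD = 3   # diabetes with cardiovascular disease
    DEATH = 4


LIVING_STATES = (HealthState.NPG, HealthState.IGT,
                 HealthState.DM2, HealthState.CVD)

#: allowed directed edges excluding self-loops and ->death
ALLOWED_PROGRESSION = {
    HealthState.NPG: (HealthState.IGT,),
    HealthState.IGT: (HealthState.DM2, HealthState.NPG),
    HealthState.DM2: (HealthState.CVD,),
    HealthState.CVD: (),
}


@dataclass(frozen=True)
class TransitionContext:
    """Where one person stands at the start of a cycle."""

    arm: str  # "intervention" | "control"
    age: int
    state: HealthState
    dm2_duration: int = 0

    def __post_init__(self):
        if self.arm not in ("intervention", "control"):
            raise ValueError(f"arm must be 'intervention' or 'control', "
                             f"got {self.arm!r}")
        if self.dm2_duration and self.state not in (HealthState.DM2,
                                                    HealthState.CVD):
            raise ValueError("dm2_duration > 0 outside DM2/CVD")


def annual_probability(cumulative_risk: float, years: float) -> float:
    """Annualize a cumulative risk: ``1 - exp(ln(1 - Pt)/t)``.

    Inverse of t-fold compounding: ``1 - (1 - p)**t`` recovers ``Pt``.
    """
    if not 0.0 <= cumulative_risk < 1.0:
        raise ValueError(f"cumulative risk {cumulative_risk} outside [0,1) "
                         "(risk 1 implies an infinite rate)")
    if years <= 0:
        raise ValueError(f"years must be > 0, got {years}")
    return -math.expm1(math.log1p(-cumulative_risk) / years)


def prob_to_rate(p: float) -> float:
    """Annual probability -> continuous rate, ``r = -ln(1-p)``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability {p} outside [0,1)")
    return -math.log1p(-p)


def rate_to_prob(r: float) -> float:
    """Continuous rate -> annual probability, ``p = 1 - exp(-r)``."""
    if r < 0:
        raise ValueError(f"rate {r} must be >= 0")
    return -math.expm1(-r)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale an annual probability by a hazard ratio on the rate scale."""
    if hr <= 0:
        raise ValueError(f"hazard ratio {hr} must be > 0")
    return rate_to_prob(hr * prob_to_rate(p))


def band_lookup(band_table: Iterable[Band], age: int) -> float:
    """Value of the band containing ``age`` (upper bounds inclusive)."""
    for (lo, hi, value) in band_table:
        if age >= lo and (hi is None or age <= hi):
            return value
    raise ValueError(f"age {age} not covered by band table")


def mortality_probability(ctx: TransitionContext, lifetable: LifeTable,
                          epi: EpidemiologicalParams) -> float:
    """Annual death probability for one person-cycle.

    Background life-table mortality, multiplied on the rate scale by the
    state's relative risk versus the general population (DM2, CVD), and
    in the intervention arm additionally by the state's mortality hazard
    ratio.  NPG and IGT carry background mortality in both arms.
    """
    if ctx.state == HealthState.DEATH:
        raise ValueError("no mortality probability for the death state")
    q = min(float(lifetable.qx_at(ctx.age)), _MAX_P)
    mult = 1.0
    if ctx.state == HealthState.DM2:
        mult = epi.rr_dm2_mortality
        if ctx.arm == "intervention":
            mult *= epi.hr_dm2_mortality
    elif ctx.state == HealthState.CVD:
        mult = epi.rr_cvd_mortality
        if ctx.arm == "intervention":
            mult *= epi.hr_cvd_mortality
    if mult == 1.0:
        return q
    return min(rate_to_prob(mult * prob_to_rate(q)), _MAX_P)


def _progression_probs(ctx: TransitionContext,
                       epi: EpidemiologicalParams) -> dict[HealthState, float]:
    """Marginal annual progression probabilities from ``ctx.state``."""
    s = ctx.state
    if s == HealthState.NPG:
        return {HealthState.IGT: epi.p_npg_to_igt}
    if s == HealthState.IGT:
        p = band_lookup(epi.p_igt_to_dm2_by_band, ctx.age)
        if ctx.arm == "intervention":
            p = apply_hazard_ratio(p, band_lookup(epi.hr_dm2_by_band,
                                                  ctx.age))
        return {HealthState.DM2: p, HealthState.NPG: epi.p_igt_to_npg}
    if s == HealthState.DM2:
        p = band_lookup(epi.p_dm2_to_cvd_by_band, ctx.age)
        if ctx.arm == "intervention":
            p = apply_hazard_ratio(p, band_lookup(epi.hr_cvd_by_band,
                                                  ctx.age))
        return {HealthState.CVD: p}
    return {}


def build_transition_row(ctx: TransitionContext, params: ParameterSet,
                         lifetable: LifeTable) -> dict[HealthState, float]:
    """One-cycle transition distribution for ``ctx``.

    Death first; the marginal progression probabilities are scaled by the
    survival probability; the residual mass stays on the current state.
    The returned row covers all five states, with exact zeros on
    disallowed edges, and sums to 1.
    """
    row = {s: 0.0 for s in HealthState}
    if ctx.state == HealthState.DEATH:
        row[HealthState.DEATH] = 1.0
        return row
    q_death = mortality_probability(ctx, lifetable, params.epi)
    row[HealthState.DEATH] = q_death
    surv = 1.0 - q_death
    moved = 0.0
    for dest, p in _progression_probs(ctx, params.epi).items():
        row[dest] = surv * p
        moved += p
    stay = surv * (1.0 - moved)
    if stay < -1e-12:
        raise ValueError(
            f"progression probabilities from {ctx.state.name} at age "
            f"{ctx.age} sum to {moved} > 1")
    row[ctx.state] = max(stay, 0.0)
    return row


def export_transition_table(params: ParameterSet, lifetable: LifeTable,
                            path: str | Path,
                            ages: Iterable[int] = range(25, 101)) -> None:
    """Audit dump of every transition row as CSV
    (``state,age,arm,dest,prob``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", "age", "arm", "dest", "prob"])
        for arm in ("control", "intervention"):
            for age in ages:
                for s in LIVING_STATES:
                    ctx = TransitionContext(arm=arm, age=age, state=s)
                    for dest, p in build_transition_row(
                            ctx, params, lifetable).items():
                        if p > 0.0:
                            w.writerow([s.name, age, arm, dest.name,
                                        f"{p:.6g}"])
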