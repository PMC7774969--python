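"""One-way, threshold, scenario and probabilistic sensitivity analyses.

One-way analyses re-run the base case with a single parameter moved to
a low and a high setting under a common seed, so the spread reflects
the parameter and not Monte-Carlo noise.  The probabilistic analysis
redraws all parameters with an assigned distribution each iteration
(beta for probabilities/utilities, gamma for costs, lognormal for
hazard/relative risks; the one-time program cost stays fixed) and
re-runs both arms, yielding the incremental scatter and the
cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult, run_base_case
from .lifetable import LifeTable
from .params import (DistributionSpec, ParameterError, ParameterSet,
                     PERTURBABLE, get_parameter, perturb)
from .transitions import HealthState

logger = logging.getLogger("prediasim")


@dataclass
class OneWayResult:
    parameter_name: str
    low_setting: float
    high_setting: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    incr_cost_low: float
    incr_cost_high: float
    incr_effect_low: float
    incr_effect_high: float

    @property
    def icer_range(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.inf
        return abs(self.icer_high - self.icer_low)


@dataclass
class PSAResult:
    iterations: np.ndarray        # shape (n_iter, 2): incr_cost, incr_qaly
    wtp_grid: np.ndarray
    ceac: np.ndarray              # P(cost-effective) per WTP grid point
    seed: int

    def scatter_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.iterations,
                          columns=["incr_cost", "incr_qaly"])
        df.insert(0, "iter", np.arange(1, len(df) + 1))
        return df

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "prob_ce": self.ceac})


def one_way(params: ParameterSet, lifetable: LifeTable,
            spec: Sequence[tuple[str, float, float]],
            seed: int) -> list[OneWayResult]:
    """Run each (name, low, high) setting with a common seed.

    Returns results in tornado order: descending ICER range.
    """
    results = []
    for name, low, high in spec:
        if name not in PERTURBABLE:
            raise ParameterError(f"unknown parameter name {name!r}")
        runs = {}
        for label, setting in (("low", low), ("high", high)):
            p = perturb(params, name, value=setting)
            runs[label] = run_base_case(p, lifetable, seed)
        results.append(OneWayResult(
            parameter_name=name, low_setting=low, high_setting=high,
            icer_low=runs["low"].icer, icer_high=runs["high"].icer,
            incr_cost_low=runs["low"].incr_cost,
            incr_cost_high=runs["high"].incr_cost,
            incr_effect_low=runs["low"].incr_qaly,
            incr_effect_high=runs["high"].incr_qaly))
        logger.info("one-way %s: low=%g high=%g", name, low, high)
    results.sort(key=lambda r: r.icer_range, reverse=True)
    return results


def default_one_way_spec(params: ParameterSet) -> list[tuple[str, float,
                                                             float]]:
    """The published one-way design: +/-20% on costs and the IGT utility,
    discount rate 1-5%, and the intervention-effect hazard ratios at
    their 95% CI bounds."""
    out = []
    for name in ("intervention_total", "annual_screening", "dm2_treatment",
                 "cvd_treatment"):
        base = get_parameter(params, name)
        out.append((name, 0.8 * base, 1.2 * base))
    u = get_parameter(params, "u_igt_at45")
    out.append(("u_igt_at45", 0.8 * u, min(1.2 * u, 1.0)))
    out.append(("discount_rate", 0.01, 0.05))
    ci = {s.parameter_name: (s.ci_low, s.ci_high) for s in params.psa_specs}
    for name in ("hr_dm2_onset_45_65", "hr_cvd_event", "hr_cvd_mortality"):
        if name in ci and ci[name][0] is not None:
            out.append((name, ci[name][0], ci[name][1]))
    return out


def threshold_search(params: ParameterSet, lifetable: LifeTable, name: str,
                     target_icer: float, bracket: tuple[float, float],
                     seed: int, rel_tol: float = 1e-3,
                     max_iter: int = 60) -> float:
    """Bisect for the parameter value at which the ICER crosses
    ``target_icer``, under common random numbers.

    Raises if the bracket is degenerate; returns the string-tagged
    sentinel ``nan`` never — a bracket without a sign change raises
    ``ValueError('threshold outside bracket')``.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError(f"degenerate bracket ({lo}, {hi})")

    def gap(v: float) -> float:
        run = run_base_case(perturb(params, name, value=v), lifetable, seed)
        if run.icer is None:
            raise ValueError(f"ICER undefined at {name}={v}")
        return run.icer - target_icer

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError("threshold outside bracket: ICER - target has the "
                         f"same sign at both endpoints ({g_lo:+.4g}, "
                         f"{g_hi:+.4g})")
    scale = abs(hi - lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if (hi - lo) < rel_tol * scale:
            return mid
        g_mid = gap(mid)
        if g_mid == 0.0:
            return mid
        if g_lo * g_mid < 0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
    return 0.5 * (lo + hi)


# -- PSA --------------------------------------------------------------------

def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.central
    sd = (spec.ci_high - spec.ci_low) / 3.92
    m = spec.central
    if spec.family == "beta":
        var = sd * sd
        common = m * (1.0 - m) / var - 1.0
        if common <= 0:  # CI wider than a beta allows; fall back on mean
            return m
        a, b = m * common, (1.0 - m) * common
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return float(rng.gamma(shape, scale))
    if spec.family == "lognormal":
        sigma = (math.log(spec.ci_high) - math.log(spec.ci_low)) / 3.92
        return float(rng.lognormal(math.log(m), sigma))
    raise ParameterError(f"unknown family {spec.family!r}")


def psa(params: ParameterSet, lifetable: LifeTable, n_iter: int = 1000,
        seed: int = 0, cohort_size: Optional[int] = None,
        wtp_grid: Optional[np.ndarray] = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per iteration: independently redraw every parameter with a
    distribution assignment, re-run both arms (n ``cohort_size``,
    default the run setting), record the incremental pair.  Iteration
    streams derive from ``seed`` and the iteration index, so scatter
    files are reproducible.
    """
    if wtp_grid is None:
        wtp_grid = np.concatenate([np.linspace(0, 150000, 61),
                                   [params.settings.wtp]])
        wtp_grid = np.unique(wtp_grid)
    missing = [s.parameter_name for s in params.psa_specs
               if s.parameter_name not in PERTURBABLE]
    if missing:
        raise ParameterError(f"PSA specs address unknown parameters: "
                             f"{missing}")
    base = params.copy()
    if cohort_size is not None:
        base.settings.cohort_size = cohort_size
    pairs = np.empty((n_iter, 2))
    for it in range(n_iter):
        rng = np.random.default_rng((seed, 1000003, it))
        p = base.copy()
        for spec in p.psa_specs:
            _, setter = PERTURBABLE[spec.parameter_name]
            setter(p, _draw(spec, rng))
        p.validate()
        # common random numbers across iterations: only the parameter
        # draw differs, so all-fixed specs reproduce the base case
        run = run_base_case(p, lifetable, seed=seed)
        pairs[it] = (run.incr_cost, run.incr_qaly)
    nmb = wtp_grid[None, :] * pairs[:, 1:2] - pairs[:, 0:1]
    ceac = (nmb > 0).mean(axis=0)
    logger.info("PSA: %d iterations, cohort %d, seed %d", n_iter,
                base.settings.cohort_size, seed)
    return PSAResult(iterations=pairs, wtp_grid=wtp_grid, ceac=ceac,
                     seed=seed)


def scenario_npg(params: ParameterSet, lifetable: LifeTable,
                 seed: int) -> RunResult:
    """The screening scenario: the whole cohort enters in NPG instead
    of IGT (universal screening of normoglycaemic individuals)."""
    from .synthetic import CohortSpec, generate_cohort
    cohort = generate_cohort(CohortSpec(
        n=params.settings.cohort_size, seed=seed,
        entry_state=HealthState.NPG))
    from .engine import simulate_arm
    ctl = simulate_arm("control", params, lifetable, seed, cohort=cohort)
    itv = simulate_arm("intervention", params, lifetable, seed,
                       cohort=cohort)
    return RunResult(control=ctl, intervention=itv,
                     horizon_mode=params.settings.horizon_mode, seed=seed)


def tornado_frame(results: list[OneWayResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter_name, "low": r.low_setting,
        "high": r.high_setting, "icer_low": r.icer_low,
        "icer_high": r.icer_high} for r in results])
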