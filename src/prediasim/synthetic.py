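"""Synthetic inputs: the trial-like cohort and bundled fixtures.

The cohort emulates the enrolment age structure of the underlying
prevention trial — mean 45, SD 9.3, truncated to ages 25-74 — with
everyone entering in the pre-diabetic IGT state.  Ages are integers
because every age-indexed input of the model (bands, life table) is
integer-year resolved.  The default cohort size is 10,000: the model
estimates cohort expectations, for which the original trial's 576
participants would leave excessive Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .engine import Individual
from .lifetable import fit_synthetic_lifetable
from .params import default_parameters
from .transitions import HealthState

DEFAULT_E0 = 76.5  # target life expectancy at birth for the bundled table


@dataclass(frozen=True)
class CohortSpec:
    """Age structure and entry state of a simulated cohort."""

    n: int = 10000
    age_mean: float = 45.0
    age_sd: float = 9.3
    age_min: int = 25
    age_max: int = 74
    entry_state: HealthState = HealthState.IGT
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"cohort size {self.n} < 1")
        if self.age_min >= self.age_max:
            raise ValueError(f"age_min {self.age_min} >= age_max "
                             f"{self.age_max}")


def generate_cohort(spec: CohortSpec) -> list[Individual]:
    """Draw a cohort with truncated-normal integer ages.

    Deterministic given ``spec.seed``; accumulators start at zero.
    """
    rng = np.random.default_rng(spec.seed)
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    b = (spec.age_max - spec.age_mean) / spec.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                               size=spec.n, random_state=rng)
    ages = np.rint(ages).astype(int)
    return [Individual(id=i, current_age=int(age), state=spec.entry_state)
            for i, age in enumerate(ages)]


def write_cohort_csv(cohort: list[Individual], path: str | Path,
                     female_fraction: float = 0.5, seed: int = 0) -> None:
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(len(cohort)) < female_fraction, "F", "M")
    with open(path, "w", newline="") as fh:
        fh.write("id,age,sex,entry_state\n")
        for person, sex in zip(cohort, sexes):
            fh.write(f"{person.id},{person.current_age},{sex},"
                     f"{person.state.name}\n")


def make_fixtures(output_dir: str | Path) -> list[Path]:
    """Write every file-based input the analysis needs.

    Produces the base-case parameter file, the synthetic life table
    calibrated to a life expectancy at birth of 76.5 years, and a
    50-person smoke-test cohort.  Idempotent: reruns are byte-identical.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    params_path = out / "base_case.yaml"
    default_parameters().save(params_path)
    paths.append(params_path)

    lt_path = out / "synthetic_lifetable.csv"
    fit_synthetic_lifetable(DEFAULT_E0).to_csv(lt_path)
    paths.append(lt_path)

    cohort_path = out / "cohort_smoke.csv"
    write_cohort_csv(generate_cohort(CohortSpec(n=50, seed=0)), cohort_path)
    paths.append(cohort_path)
    return paths
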