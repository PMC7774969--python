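"""Background (non-disease-specific) annual mortality by age.

A :class:`LifeTable` maps integer age to the annual probability of death
``qx``, with an open-ended terminal age at which ``qx = 1``.  Tables come
from a CSV (single-year ``age,qx`` or abridged ``age_low,age_high,qx``)
or from a synthetic Gompertz-Makeham table calibrated to a target life
expectancy at birth — the stand-in for period life tables that are not
shipped with the package.

Abridged bands are expanded assuming a constant hazard within the band:
the single-year probability is ``1 - (1 - q_band)**(1/width)``, which
conserves the band's survival probability exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Gompertz-Makeham constants for the synthetic table.  The Makeham term
#: lam is a small age-independent background hazard; b fixes the adult
#: mortality doubling time at ln(2)/b ~ 7.3 years.  Only the Gompertz
#: level `a` is calibrated, keeping the fit one-dimensional.
GM_LAMBDA = 5e-4
GM_B = 0.095
TERMINAL_AGE = 110


@dataclass(frozen=True)
class LifeTable:
    """Single-year annual death probabilities, terminal ``qx = 1``."""

    ages: np.ndarray  # contiguous integer years
    qx: np.ndarray

    def __post_init__(self):
        ages, qx = np.asarray(self.ages), np.asarray(self.qx)
        if ages.ndim != 1 or ages.shape != qx.shape or len(ages) == 0:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous single years")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx outside [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("terminal qx must be 1")

    def qx_at(self, age: int | np.ndarray) -> float | np.ndarray:
        """Annual death probability at ``age``.

        Ages above the terminal entry return 1; ages below the first
        entry return the first entry's value.
        """
        idx = np.clip(np.asarray(age) - self.ages[0], 0, len(self.ages) - 1)
        out = self.qx[idx.astype(int)]
        return float(out) if np.isscalar(age) else out

    def life_expectancy(self, from_age: int) -> float:
        """Expected further years of life at exact age ``from_age``.

        Uses the convention that deaths within a year occur mid-year on
        average, adding half a year to the sum of full-year survival
        probabilities.
        """
        if from_age < self.ages[0] or from_age > self.ages[-1]:
            raise ValueError(f"age {from_age} outside table "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        q = self.qx[from_age - self.ages[0]:]
        surv = np.cumprod(1.0 - q)
        return float(surv.sum()) + 0.5

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "qx"])
            for a, q in zip(self.ages, self.qx):
                w.writerow([int(a), repr(float(q))])


def read_lifetable(path: str | Path) -> LifeTable:
    """Read a single-year (``age,qx``) or abridged
    (``age_low,age_high,qx``) CSV life table, expanding abridged bands
    under a constant within-band hazard."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"empty life table file: {path}")
    header = [h.strip().lower() for h in rows[0]]
    ages, qxs = [], []
    if header == ["age", "qx"]:
        for row in rows[1:]:
            ages.append(int(row[0]))
            qxs.append(float(row[1]))
    elif header == ["age_low", "age_high", "qx"]:
        for row in rows[1:]:
            lo, hi, qb = int(row[0]), int(row[1]), float(row[2])
            if hi < lo:
                raise ValueError(f"abridged band [{lo},{hi}] inverted")
            if not 0 <= qb <= 1:
                raise ValueError(f"qx {qb} outside [0,1]")
            width = hi - lo + 1
            q1 = 1.0 - (1.0 - qb) ** (1.0 / width)
            for age in range(lo, hi + 1):
                ages.append(age)
                qxs.append(q1)
    else:
        raise ValueError(f"unrecognized life-table header: {header}")
    order = np.argsort(ages)
    ages_a = np.asarray(ages)[order]
    if np.any(np.diff(ages_a) <= 0):
        raise ValueError("non-monotone ages in life table")
    qx_a = np.asarray(qxs, dtype=float)[order]
    if qx_a[-1] != 1.0:  # append an explicit terminal age
        ages_a = np.append(ages_a, ages_a[-1] + 1)
        qx_a = np.append(qx_a, 1.0)
    return LifeTable(ages=ages_a, qx=qx_a)


def _gm_qx(a: float, ages: np.ndarray) -> np.ndarray:
    # hazard mu(x) = lam + a*exp(b*x); qx = 1 - exp(-integral over [x, x+1])
    H = GM_LAMBDA + (a / GM_B) * np.exp(GM_B * ages) * math.expm1(GM_B)
    return -np.expm1(-H)


def _gm_table(a: float) -> LifeTable:
    ages = np.arange(0, TERMINAL_AGE + 1)
    qx = _gm_qx(a, ages)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def fit_synthetic_lifetable(target_e0: float, seed: int | None = None,
                            tol: float = 0.05) -> LifeTable:
    """Calibrate a Gompertz-Makeham life table to a life expectancy at
    birth of ``target_e0`` years.

    Only the Gompertz level parameter is fitted, by bisection on the log
    scale, so the result is deterministic; ``seed`` is accepted for
    interface symmetry with the other generators and ignored.
    """
    if not 40.0 <= target_e0 <= 95.0:
        raise ValueError(f"target_e0 {target_e0} outside [40, 95]")
    lo, hi = 1e-9, 5e-2  # e0(lo) > 95, e0(hi) < 40
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        e0 = _gm_table(mid).life_expectancy(0)
        if abs(e0 - target_e0) < tol / 4:
            return _gm_table(mid)
        if e0 > target_e0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("life-table calibration did not converge after "
                       "200 bisection iterations")
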