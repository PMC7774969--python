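"""Model parameters: loading, validation and perturbation.

The single source of truth for a model run is a :class:`ParameterSet`
grouping run settings, epidemiological transition inputs, unit costs,
utility weights and the probabilistic-sensitivity distribution
assignments.  The published base case ships as a versioned YAML fixture
(``data/base_case.yaml``); nothing numeric is hard-coded here.

Age-dependent inputs are band tables — lists of ``(age_low, age_high,
value)`` with inclusive bounds and ``None`` for an open upper end.  The
CVD-onset table is stored as its two published anchor bands and expanded
at load time, filling ages 52-75 by log-linear interpolation of the
annual rate between the anchors.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Optional

import yaml

logger = logging.getLogger("prediasim")

Band = tuple[int, Optional[int], float]

FIXTURE_NAME = "base_case.yaml"


class ParameterError(ValueError):
    """A parameter value or config key violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Settings:
    """Run settings: horizon, discounting, WTP, cohort size, seed."""

    horizon_mode: str = "thirty_year"  # thirty_year | lifetime
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp: float = 37446.0
    cohort_size: int = 10000
    seed: int = 12345
    half_cycle_correction: bool = True
    max_age: int = 100

    def validate(self) -> None:
        if self.horizon_mode not in ("thirty_year", "lifetime"):
            raise ParameterError(
                f"settings.horizon_mode: {self.horizon_mode!r} is not "
                "'thirty_year' or 'lifetime'")
        for key in ("discount_rate_costs", "discount_rate_effects"):
            v = getattr(self, key)
            if not 0.0 <= v <= 0.2:
                raise ParameterError(f"settings.{key}: {v} outside [0, 0.2]")
        if self.cohort_size < 1:
            raise ParameterError(
                f"settings.cohort_size: {self.cohort_size} < 1")
        if self.cycle_length != 1.0:
            raise ParameterError("settings.cycle_length: only annual cycles "
                                 f"are supported, got {self.cycle_length}")
        if self.wtp < 0:
            raise ParameterError(f"settings.wtp: {self.wtp} < 0")


def _check_bands(bands: list[Band], name: str, lo: float = 0.0,
                 hi: float = math.inf) -> None:
    if not bands:
        raise ParameterError(f"{name}: empty band table")
    prev_hi = -1
    for (a, b, v) in bands:
        if b is not None and b < a:
            raise ParameterError(f"{name}: band [{a},{b}] inverted")
        if a != prev_hi + 1:
            raise ParameterError(f"{name}: bands not contiguous at age {a}")
        if not lo <= v <= hi:
            raise ParameterError(f"{name}: value {v} outside [{lo},{hi}]")
        prev_hi = b if b is not None else 10**9
    if bands[-1][1] is not None:
        raise ParameterError(f"{name}: last band must be open-ended")


@dataclass
class EpidemiologicalParams:
    """Annual transition probabilities and treatment-effect ratios.

    Probabilities are control-arm values; the intervention arm is derived
    by applying the hazard ratios on the rate scale.  Mortality RRs act
    on life-table background mortality for the DM2 and CVD states.
    """

    p_npg_to_igt: float = 0.193
    p_igt_to_npg: float = 0.192
    p_igt_to_dm2_by_band: list[Band] = field(default_factory=list)
    hr_dm2_by_band: list[Band] = field(default_factory=list)
    p_dm2_to_cvd_anchors: list[Band] = field(default_factory=list)
    cvd_onset_interpolation: str = "loglinear_rate"
    hr_cvd_event: float = 0.74
    hr_cvd_event_from_age: int = 52
    rr_dm2_mortality: float = 2.00
    hr_dm2_mortality: float = 0.74
    rr_cvd_mortality: float = 2.13
    hr_cvd_mortality: float = 0.67
    hr_all_cause: float = 0.74

    # Derived, rebuilt by validate(): anchors expanded over the gap.
    p_dm2_to_cvd_by_band: list[Band] = field(default_factory=list, repr=False)
    hr_cvd_by_band: list[Band] = field(default_factory=list, repr=False)

    def _expand_cvd_bands(self) -> None:
        (a0, b0, p_lo), (a1, b1, p_hi) = self.p_dm2_to_cvd_anchors
        assert b0 is not None and b1 is None
        bands: list[Band] = [(a0, b0, p_lo)]
        if self.cvd_onset_interpolation == "loglinear_rate":
            r_lo, r_hi = -math.log1p(-p_lo), -math.log1p(-p_hi)
            span = a1 - b0
            for age in range(b0 + 1, a1):
                w = (age - b0) / span
                if r_lo > 0.0 and r_hi > 0.0:
                    r = math.exp(math.log(r_lo)
                                 + w * (math.log(r_hi) - math.log(r_lo)))
                else:  # a zero anchor has no log; fall back to linear rate
                    r = r_lo + w * (r_hi - r_lo)
                bands.append((age, age, -math.expm1(-r)))
        else:
            raise ParameterError(
                "epi.cvd_onset_interpolation: unknown scheme "
                f"{self.cvd_onset_interpolation!r}")
        bands.append((a1, b1, p_hi))
        self.p_dm2_to_cvd_by_band = bands
        cut = self.hr_cvd_event_from_age
        self.hr_cvd_by_band = [(0, cut - 1, 1.0), (cut, None, self.hr_cvd_event)]

    def validate(self) -> None:
        for key in ("p_npg_to_igt", "p_igt_to_npg"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"epi.{key}: {v} outside [0,1]")
        for key in ("hr_cvd_event", "rr_dm2_mortality", "hr_dm2_mortality",
                    "rr_cvd_mortality", "hr_cvd_mortality", "hr_all_cause"):
            v = getattr(self, key)
            if v <= 0:
                raise ParameterError(f"epi.{key}: {v} must be > 0")
        _check_bands(self.p_igt_to_dm2_by_band, "epi.p_igt_to_dm2_by_band",
                     0.0, 1.0)
        _check_bands(self.hr_dm2_by_band, "epi.hr_dm2_by_band", 1e-12)
        if len(self.p_dm2_to_cvd_anchors) != 2:
            raise ParameterError("epi.p_dm2_to_cvd_anchors: expected exactly "
                                 "two anchor bands")
        for (_, _, v) in self.p_dm2_to_cvd_anchors:
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    f"epi.p_dm2_to_cvd_anchors: value {v} outside [0,1]")
        self._expand_cvd_bands()
        _check_bands(self.p_dm2_to_cvd_by_band, "epi.p_dm2_to_cvd_by_band",
                     0.0, 1.0)


@dataclass
class CostParams:
    """Unit costs in 2016 yuan and the cost-accrual switches."""

    intervention_total: float = 3374.0
    intervention_duration: int = 6
    annual_screening: float = 422.0
    dm2_treatment: float = 6436.0
    cvd_treatment: float = 11680.0
    amortize_intervention: bool = True
    screening_full_horizon: bool = True
    cvd_cost_includes_dm2: bool = True

    def validate(self) -> None:
        for key in ("intervention_total", "annual_screening",
                    "dm2_treatment", "cvd_treatment"):
            v = getattr(self, key)
            if v < 0:
                raise ParameterError(f"costs.{key}: {v} < 0")
        if self.intervention_duration < 1:
            raise ParameterError("costs.intervention_duration: "
                                 f"{self.intervention_duration} < 1")


@dataclass
class UtilityParams:
    """Utility weights anchored at age 45 plus decrement coefficients."""

    u_npg_at45: float = 0.936
    u_igt_at45: float = 0.931
    u_dm2_onset_at45: float = 0.925
    u_cvd_at45: float = 0.779
    dm2_decrement: float = 0.012
    cvd_decrement: float = 0.158
    age_decrement_per_year: float = 0.003
    dm2_base_for_duration_rule: float = 0.832
    npg_multiplier: float = 1.0

    def validate(self) -> None:
        for key in ("u_npg_at45", "u_igt_at45", "u_dm2_onset_at45",
                    "u_cvd_at45", "dm2_base_for_duration_rule"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"utilities.{key}: {v} outside [0,1]")
        for key in ("dm2_decrement", "cvd_decrement",
                    "age_decrement_per_year"):
            v = getattr(self, key)
            if v < 0:
                raise ParameterError(f"utilities.{key}: {v} < 0")
        if not 0.0 < self.npg_multiplier <= 1.0:
            raise ParameterError(
                f"utilities.npg_multiplier: {self.npg_multiplier} "
                "outside (0,1]")


@dataclass
class DistributionSpec:
    """PSA sampling description for one scalar parameter."""

    parameter_name: str
    family: str  # beta | gamma | lognormal | fixed
    central: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def validate(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ParameterError(
                f"psa_specs[{self.parameter_name}].family: "
                f"{self.family!r} unknown")
        if self.family == "fixed":
            return
        if self.ci_low is None or self.ci_high is None:
            raise ParameterError(
                f"psa_specs[{self.parameter_name}]: 95% CI required for "
                f"family {self.family}")
        if not self.ci_low < self.central < self.ci_high:
            raise ParameterError(
                f"psa_specs[{self.parameter_name}]: CI "
                f"({self.ci_low},{self.ci_high}) does not bracket "
                f"{self.central}")
        if self.family == "beta" and not (0 <= self.ci_low
                                          and self.ci_high <= 1):
            raise ParameterError(
                f"psa_specs[{self.parameter_name}]: beta CI outside [0,1]")


@dataclass
class ParameterSet:
    """Everything a model run needs, validated as a whole."""

    settings: Settings = field(default_factory=Settings)
    epi: EpidemiologicalParams = field(default_factory=EpidemiologicalParams)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    psa_specs: list[DistributionSpec] = field(default_factory=list)
    lifetable_source: str = "synthetic"
    version: int = 1

    def validate(self) -> "ParameterSet":
        self.settings.validate()
        self.epi.validate()
        self.costs.validate()
        self.utilities.validate()
        for spec in self.psa_specs:
            spec.validate()
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = {
            "version": self.version,
            "settings": asdict(self.settings),
            "epi": asdict(self.epi),
            "costs": asdict(self.costs),
            "utilities": asdict(self.utilities),
            "lifetable_source": self.lifetable_source,
            "psa_specs": [asdict(s) for s in self.psa_specs],
        }
        # derived tables are rebuilt on load
        d["epi"].pop("p_dm2_to_cvd_by_band", None)
        d["epi"].pop("hr_cvd_by_band", None)
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "settings": Settings,
    "epi": EpidemiologicalParams,
    "costs": CostParams,
    "utilities": UtilityParams,
}


def _coerce_bands(raw: Any, key: str) -> list[Band]:
    bands = []
    for row in raw:
        if len(row) != 3:
            raise ParameterError(f"{key}: band row {row!r} is not "
                                 "[age_low, age_high, value]")
        a, b, v = row
        bands.append((int(a), None if b is None else int(b), float(v)))
    return bands


def _build_section(cls: type, raw: dict[str, Any], section: str) -> Any:
    obj = cls()
    for key, value in raw.items():
        if not hasattr(obj, key) or key in ("p_dm2_to_cvd_by_band",
                                            "hr_cvd_by_band"):
            raise ParameterError(f"unknown config key {section}.{key}")
        if key.endswith(("_by_band", "_anchors")):
            value = _coerce_bands(value, f"{section}.{key}")
        setattr(obj, key, value)
    return obj


def from_dict(raw: dict[str, Any]) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from nested dicts.

    Unknown keys raise :class:`ParameterError` naming the offending key;
    missing keys fall back to the fixture defaults of their section.
    """
    ps = ParameterSet()
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            setattr(ps, section, _build_section(cls, raw[section], section))
    if "psa_specs" in raw:
        ps.psa_specs = [DistributionSpec(**s) for s in raw["psa_specs"]]
    if "lifetable_source" in raw:
        ps.lifetable_source = str(raw["lifetable_source"])
    if "version" in raw:
        ps.version = int(raw["version"])
    extra = set(raw) - set(_SECTION_TYPES) - {"psa_specs",
                                              "lifetable_source", "version"}
    if extra:
        raise ParameterError(f"unknown config section(s): {sorted(extra)}")
    return ps.validate()


def default_parameters() -> ParameterSet:
    """The published base case, loaded from the bundled fixture."""
    text = (resources.files("prediasim") / "data" / FIXTURE_NAME).read_text()
    return from_dict(yaml.safe_load(text))


def load_config(path: str | Path) -> ParameterSet:
    """Load a YAML/JSON config; unspecified fields fall back to defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config root must be a mapping, got "
                             f"{type(raw).__name__}")
    defaults = default_parameters().to_dict()
    merged = _deep_merge(defaults, raw, log=True)
    return from_dict(merged)


def _deep_merge(base: dict, override: dict, log: bool = False,
                prefix: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if (key in base and isinstance(base[key], dict)
                and isinstance(value, dict)):
            out[key] = _deep_merge(base[key], value, log, f"{prefix}{key}.")
        else:
            if log and base.get(key) != value:
                logger.info("config override: %s%s = %r", prefix, key, value)
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# Perturbation (one-way sensitivity / PSA plumbing)
# ---------------------------------------------------------------------------

def _band_setter(section: str, attr: str, index: int) -> Callable:
    def setter(ps: ParameterSet, v: float) -> None:
        bands = getattr(getattr(ps, section), attr)
        a, b, _ = bands[index]
        bands[index] = (a, b, v)
    return setter


def _band_getter(section: str, attr: str, index: int) -> Callable:
    return lambda ps: getattr(getattr(ps, section), attr)[index][2]


def _field(section: str, attr: str) -> tuple[Callable, Callable]:
    return (lambda ps: getattr(getattr(ps, section), attr),
            lambda ps, v: setattr(getattr(ps, section), attr, v))


def _all_dm2_hr(ps: ParameterSet, v: float) -> None:
    ps.epi.hr_dm2_by_band = [(a, b, v) for (a, b, _) in ps.epi.hr_dm2_by_band]


def _both_discounts(ps: ParameterSet, v: float) -> None:
    ps.settings.discount_rate_costs = v
    ps.settings.discount_rate_effects = v


#: name -> (getter, setter); the addressable scalar surface of the model
PERTURBABLE: dict[str, tuple[Callable, Callable]] = {
    "p_npg_to_igt": _field("epi", "p_npg_to_igt"),
    "p_igt_to_npg": _field("epi", "p_igt_to_npg"),
    "p_igt_dm2_45_65": (_band_getter("epi", "p_igt_to_dm2_by_band", 0),
                        _band_setter("epi", "p_igt_to_dm2_by_band", 0)),
    "p_igt_dm2_66": (_band_getter("epi", "p_igt_to_dm2_by_band", 1),
                     _band_setter("epi", "p_igt_to_dm2_by_band", 1)),
    "hr_dm2_onset_45_65": (_band_getter("epi", "hr_dm2_by_band", 0),
                           _band_setter("epi", "hr_dm2_by_band", 0)),
    "hr_dm2_onset_66": (_band_getter("epi", "hr_dm2_by_band", 1),
                        _band_setter("epi", "hr_dm2_by_band", 1)),
    "hr_dm2_onset": (_band_getter("epi", "hr_dm2_by_band", 0), _all_dm2_hr),
    "p_cvd_onset_45_51": (_band_getter("epi", "p_dm2_to_cvd_anchors", 0),
                          _band_setter("epi", "p_dm2_to_cvd_anchors", 0)),
    "p_cvd_onset_76": (_band_getter("epi", "p_dm2_to_cvd_anchors", 1),
                       _band_setter("epi", "p_dm2_to_cvd_anchors", 1)),
    "hr_cvd_event": _field("epi", "hr_cvd_event"),
    "rr_dm2_mortality": _field("epi", "rr_dm2_mortality"),
    "hr_dm2_mortality": _field("epi", "hr_dm2_mortality"),
    "rr_cvd_mortality": _field("epi", "rr_cvd_mortality"),
    "hr_cvd_mortality": _field("epi", "hr_cvd_mortality"),
    "intervention_total": _field("costs", "intervention_total"),
    "annual_screening": _field("costs", "annual_screening"),
    "dm2_treatment": _field("costs", "dm2_treatment"),
    "cvd_treatment": _field("costs", "cvd_treatment"),
    "u_npg_at45": _field("utilities", "u_npg_at45"),
    "u_igt_at45": _field("utilities", "u_igt_at45"),
    "u_dm2_onset_at45": _field("utilities", "u_dm2_onset_at45"),
    "u_cvd_at45": _field("utilities", "u_cvd_at45"),
    "discount_rate_costs": _field("settings", "discount_rate_costs"),
    "discount_rate_effects": _field("settings", "discount_rate_effects"),
    "discount_rate": (lambda ps: ps.settings.discount_rate_effects,
                      _both_discounts),
    "wtp": _field("settings", "wtp"),
}


def get_parameter(params: ParameterSet, name: str) -> float:
    if name not in PERTURBABLE:
        raise ParameterError(f"unknown parameter name {name!r}; known: "
                             f"{sorted(PERTURBABLE)}")
    return PERTURBABLE[name][0](params)


def perturb(params: ParameterSet, name: str, *,
            factor: Optional[float] = None,
            value: Optional[float] = None) -> ParameterSet:
    """Return a copy of ``params`` with one scalar changed.

    Exactly one of ``factor`` (multiplicative) or ``value`` (absolute)
    must be given.  The original is untouched; the copy is re-validated,
    so the derived CVD-onset bands track anchor perturbations.
    """
    if (factor is None) == (value is None):
        raise ParameterError("give exactly one of factor= or value=")
    if name not in PERTURBABLE:
        raise ParameterError(f"unknown parameter name {name!r}; known: "
                             f"{sorted(PERTURBABLE)}")
    out = params.copy()
    getter, setter = PERTURBABLE[name]
    new = getter(out) * factor if factor is not None else value
    setter(out, new)
    return out.validate()
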