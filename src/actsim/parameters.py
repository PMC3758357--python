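"""Domain types and parameterization for the tSCI care-continuum simulation.

The simulation consumes no patient-level data.  Everything it needs —
regression coefficient tables, arrival-rate factors, length-of-stay
distributions, complication constraints, bed capacities, cost schedules,
life tables and utility coefficients — lives in a *parameter pack*: a
directory of CSV tables plus one YAML manifest.  This module defines the
in-memory types (:class:`RegressionSpec`, :class:`ProfileKey`,
:class:`ParameterSet`, ...), evaluates regression specifications, and
reads/writes/validates packs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_BANDS", "AGE_BAND_LABELS", "GENDERS", "MECHANISMS", "NEURO_BANDS",
    "AIS_GRADES", "AIS_ORDER", "COMPLICATIONS", "REHAB_COMPLICATIONS",
    "PackError", "SpecError", "ProfileKey", "age_band_of", "all_profiles",
    "RegressionSpec", "predict_regression", "DistSpec", "LosModel",
    "ComplicationTable", "ConstraintSpec", "LifeTable", "CostSchedule",
    "UtilityModel", "ParameterSet", "load_parameter_pack",
    "write_parameter_pack",
]

# ---------------------------------------------------------------------------
# Fixed categorical vocabularies.
#
# The profile grid is deliberately exactly 4 x 2 x 4 x 4 x 5 = 640 cells so
# that the 640 x 5 = 3,200-entry acute complication table is well defined.

AGE_BANDS: tuple[tuple[int, int], ...] = ((0, 29), (30, 44), (45, 59), (60, 200))
AGE_BAND_LABELS: tuple[str, ...] = ("0-29", "30-44", "45-59", "60+")
GENDERS: tuple[str, ...] = ("male", "female")
MECHANISMS: tuple[str, ...] = ("transport", "fall", "sports", "other")
NEURO_BANDS: tuple[str, ...] = ("C1-C4", "C5-C8", "thoracic", "lumbosacral")
AIS_GRADES: tuple[str, ...] = ("A", "B", "C", "D", "E")
#: Cumulative-logit ordering for discharge AIS: E (best) below A (worst).
AIS_ORDER: tuple[str, ...] = ("E", "D", "C", "B", "A")
COMPLICATIONS: tuple[str, ...] = (
    "pressure_ulcer", "neuropathic_pain", "pneumonia", "uti", "delirium",
)
#: Complications tracked during in-patient rehabilitation.
REHAB_COMPLICATIONS: tuple[str, ...] = ("pressure_ulcer", "uti", "neuropathic_pain")

CERVICAL_BANDS = frozenset({"C1-C4", "C5-C8"})

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.0
HOURS_PER_YEAR = HOURS_PER_DAY * DAYS_PER_YEAR


class PackError(ValueError):
    """A parameter pack is incomplete or violates an invariant."""


class SpecError(ValueError):
    """A regression specification is malformed or evaluated incorrectly."""


def age_band_of(age: float) -> str:
    # bands are inclusive of the printed endpoints; fractional ages fall in
    # the band whose integer range contains floor(age)
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age < hi + 1:
            return label
    raise ValueError(f"age out of range: {age}")


class ProfileKey(NamedTuple):
    """One of the 640 patient profiles stratifying complication risk."""

    age_band: str
    gender: str
    mechanism: str
    neuro_band: str
    ais: str


def all_profiles() -> Iterator[ProfileKey]:
    """Iterate the full 640-cell profile grid in a fixed, documented order."""
    for ab in AGE_BAND_LABELS:
        for g in GENDERS:
            for m in MECHANISMS:
                for nb in NEURO_BANDS:
                    for a in AIS_GRADES:
                        yield ProfileKey(ab, g, m, nb, a)


# ---------------------------------------------------------------------------
# Regression specifications


def _expit(x: float) -> float:
    # overflow-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class RegressionSpec:
    """A fixed-coefficient regression used as a conditional sampler.

    Families
    --------
    ``linear``
        Returns the linear predictor; ``residual_sd`` gives Gaussian noise.
    ``binary-logit``
        Two ``outcome_categories`` (reference first); standard logit.
    ``multinomial-logit``
        Softmax over ``outcome_categories`` with the first as reference;
        coefficients are per non-reference category.
    ``ordinal-logit``
        Cumulative logits over ``outcome_categories`` in ascending order:
        ``P(Y <= category_j) = expit(alpha_j + x.beta)`` for the first
        K-1 categories.  For discharge AIS the order is E < D < C < B < A,
        the only convention under which published coefficient signs
        (admission grade A strongly negative, rehabilitation positive)
        are clinically coherent.

    ``terms`` maps ``(category, covariate, level)`` to a coefficient, with
    ``category == ""`` outside the multinomial family and ``level is None``
    for numeric covariates.  Categorical covariates must declare a
    reference level (coefficient 0).
    """

    family: str
    outcome_categories: tuple[str, ...] = ()
    terms: dict[tuple[str, str, str | None], float] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)
    residual_sd: float = 0.0

    # -- validation ---------------------------------------------------------

    def validate(self, path: str = "spec") -> None:
        fams = {"linear", "binary-logit", "multinomial-logit", "ordinal-logit"}
        if self.family not in fams:
            raise SpecError(f"invalid parameter: {path}.family ({self.family!r})")
        if self.family == "ordinal-logit":
            k = len(self.outcome_categories)
            if len(self.intercepts) != k - 1:
                raise SpecError(
                    f"invalid parameter: {path}.intercepts "
                    f"(ordinal-logit needs {k - 1} thresholds, got {len(self.intercepts)})"
                )
            alphas = [self.intercepts[c] for c in self.outcome_categories[:-1]]
            if any(b < a for a, b in zip(alphas, alphas[1:])):
                raise SpecError(f"invalid parameter: {path}.intercepts (thresholds not ordered)")
        if self.family == "binary-logit" and len(self.outcome_categories) != 2:
            raise SpecError(f"invalid parameter: {path}.outcome_categories")
        if self.residual_sd < 0:
            raise SpecError(f"invalid parameter: {path}.residual_sd")
        for (_cat, cov, level) in self.terms:
            if level is not None and cov not in self.reference_levels:
                raise SpecError(
                    f"invalid parameter: {path}.reference_levels (missing for {cov!r})"
                )

    # -- evaluation ---------------------------------------------------------

    def covariates(self) -> set[str]:
        return {cov for (_c, cov, _l) in self.terms}

    def linear_predictor(self, covariates: Mapping[str, Any], category: str = "") -> float:
        eta = 0.0
        for (cat, cov, level), coef in self.terms.items():
            if cat != category:
                continue
            if cov not in covariates:
                raise SpecError(f"covariate required: {cov}")
            value = covariates[cov]
            if level is None:  # numeric covariate
                eta += coef * float(value)
            else:
                ref = self.reference_levels.get(cov)
                if value == level:
                    eta += coef
                elif value != ref and not self._known_level(cov, value):
                    raise SpecError(f"level mismatch: {cov}={value!r}")
        return eta

    def _known_level(self, cov: str, value: Any) -> bool:
        for (_c, c2, lvl) in self.terms:
            if c2 == cov and lvl == value:
                return True
        return value == self.reference_levels.get(cov)

    def predict(self, covariates: Mapping[str, Any]) -> np.ndarray | float:
        """Category probabilities (categorical families) or the linear predictor."""
        if self.family == "linear":
            return self.intercepts.get("intercept", 0.0) + self.linear_predictor(covariates)
        if self.family == "binary-logit":
            eta = self.intercepts.get("intercept", 0.0) + self.linear_predictor(covariates)
            p1 = _expit(eta)
            return np.array([1.0 - p1, p1])
        if self.family == "multinomial-logit":
            etas = [0.0]  # reference category
            for cat in self.outcome_categories[1:]:
                etas.append(self.intercepts.get(cat, 0.0) + self.linear_predictor(covariates, cat))
            e = np.exp(np.asarray(etas) - max(etas))
            return e / e.sum()
        if self.family == "ordinal-logit":
            eta = self.linear_predictor(covariates)
            cum = [_expit(self.intercepts[c] + eta) for c in self.outcome_categories[:-1]]
            cum.append(1.0)
            cum = np.maximum.accumulate(np.asarray(cum))
            probs = np.diff(cum, prepend=0.0)
            return probs / probs.sum()
        raise SpecError(f"unknown family {self.family!r}")

    def sample(self, covariates: Mapping[str, Any], rng: np.random.Generator) -> Any:
        """Draw an outcome: a category label, or a noisy linear response."""
        out = self.predict(covariates)
        if self.family == "linear":
            return float(out) + (rng.normal(0.0, self.residual_sd) if self.residual_sd else 0.0)
        idx = rng.choice(len(self.outcome_categories), p=np.asarray(out))
        return self.outcome_categories[int(idx)]


def predict_regression(spec: RegressionSpec, covariates: Mapping[str, Any]) -> np.ndarray | float:
    """Evaluate ``spec`` at ``covariates`` (module-level convenience wrapper)."""
    return spec.predict(covariates)


# ---------------------------------------------------------------------------
# Distributions


@dataclass
class DistSpec:
    """A positive-valued duration distribution parameterized by mean and CV.

    ``lognormal`` is the default family (the right-skew convention for
    hospital durations); ``exponential`` ignores ``cv``; ``fixed`` is a
    degenerate point mass at ``mean``.
    """

    family: str = "lognormal"
    mean: float = 1.0
    cv: float = 0.5

    def validate(self, path: str = "dist") -> None:
        if self.family not in {"lognormal", "exponential", "fixed"}:
            raise PackError(f"invalid parameter: {path}.family")
        if self.mean < 0 or self.cv < 0:
            raise PackError(f"invalid parameter: {path}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.mean == 0 or self.family == "fixed":
            return np.full(size, self.mean) if size is not None else self.mean
        if self.family == "exponential":
            return rng.exponential(self.mean, size)
        sigma2 = math.log(1.0 + self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size)


@dataclass
class LosModel:
    """Length of stay: a linear spec for the conditional mean (days),
    log-normal spread around it, and a scalar calibration multiplier."""

    spec: RegressionSpec
    cv: float = 0.6
    scale: float = 1.0
    floor: float = 0.25

    def mean_for(self, covariates: Mapping[str, Any]) -> float:
        return max(self.floor, float(self.spec.predict(covariates)) * self.scale)

    def sample(self, covariates: Mapping[str, Any], rng: np.random.Generator) -> float:
        m = self.mean_for(covariates)
        if self.cv == 0:
            return m
        sigma2 = math.log(1.0 + self.cv**2)
        return float(rng.lognormal(math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Complications


@dataclass
class ComplicationTable:
    """Profile-stratified acute complication probabilities (640 x 5)."""

    entries: dict[tuple[ProfileKey, str], float]

    def validate(self, path: str = "complications.table") -> None:
        expected = {(p, c) for p in all_profiles() for c in COMPLICATIONS}
        if set(self.entries) != expected:
            raise PackError(
                f"invalid parameter: {path} (expected 3200 entries, got {len(self.entries)})"
            )
        for key, p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise PackError(f"invalid parameter: {path}[{key}]")

    def probability(self, profile: ProfileKey, complication: str) -> float:
        try:
            return self.entries[(profile, complication)]
        except KeyError:
            raise PackError(f"uncovered profile: {profile}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**p._asdict(), "complication": c, "probability": v}
            for (p, c), v in self.entries.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ComplicationTable":
        entries = {}
        for row in df.itertuples(index=False):
            key = ProfileKey(row.age_band, row.gender, row.mechanism, row.neuro_band, row.ais)
            entries[(key, row.complication)] = float(row.probability)
        return cls(entries)


@dataclass
class ConstraintSpec:
    """A literature-derived constraint on the complication table.

    ``kind`` is one of ``marginal_equality``, ``marginal_bound``, ``ratio``
    or ``box``.  ``selector`` is a dict of profile-field -> value filters
    (empty = all profiles).  For ``ratio``, ``ratio_field``/``ratio_num``/
    ``ratio_den`` define matched pairs differing only in that field, with
    ``p_num = target * p_den`` (on probabilities, not odds).
    """

    kind: str
    complication: str
    target: float
    selector: dict[str, str] = field(default_factory=dict)
    direction: str = "eq"  # eq | le | ge, for marginal_bound
    ratio_field: str = ""
    ratio_num: str = ""
    ratio_den: str = ""
    lower: float = 0.0
    upper: float = 1.0
    source: str = ""

    def validate(self, path: str = "constraint") -> None:
        if self.kind not in {"marginal_equality", "marginal_bound", "ratio", "box"}:
            raise PackError(f"invalid parameter: {path}.kind")
        if self.complication not in COMPLICATIONS:
            raise PackError(f"invalid parameter: {path}.complication")
        if self.kind == "marginal_bound" and self.direction not in {"le", "ge"}:
            raise PackError(f"invalid parameter: {path}.direction")
        if self.kind == "ratio" and not (self.ratio_field and self.ratio_num and self.ratio_den):
            raise PackError(f"invalid parameter: {path}.ratio_field")

    def selects(self, profile: ProfileKey) -> bool:
        return all(getattr(profile, k) == v for k, v in self.selector.items())


# ---------------------------------------------------------------------------
# Long-term outcome inputs


@dataclass
class LifeTable:
    """Remaining life expectancy, injured by (age band, neuro band, AIS)
    and uninjured by single year of age."""

    uninjured: dict[int, float]
    injured: dict[tuple[str, str, str], float]

    def validate(self, path: str = "outcomes.life_table") -> None:
        ages = sorted(self.uninjured)
        if not ages:
            raise PackError(f"invalid parameter: {path}.uninjured")
        les = [self.uninjured[a] for a in ages]
        if any(b > a for a, b in zip(les, les[1:])):
            raise PackError(f"invalid parameter: {path}.uninjured (LE must decrease with age)")
        for ab in AGE_BAND_LABELS:
            for nb in NEURO_BANDS:
                for g in AIS_GRADES:
                    if (ab, nb, g) not in self.injured:
                        raise PackError(f"invalid parameter: {path}.injured[{ab},{nb},{g}]")

    def uninjured_le(self, age: float) -> float:
        a = int(round(age))
        if a not in self.uninjured:
            raise PackError(f"age out of range: {age}")
        return self.uninjured[a]

    def injured_le(self, age: float, neuro_band: str, ais: str) -> float:
        entry = self.injured[(age_band_of(age), neuro_band, ais)]
        # band-level entries can slightly exceed the exact-age uninjured LE
        # near band edges; clip so life-years-lost is never negative
        return min(entry, self.uninjured_le(age))


@dataclass
class CostSchedule:
    """In-hospital and lifetime cost inputs (CAD at the pack's price year)."""

    per_admission: float
    per_day_acute: float
    per_day_rehab: float
    one_time_by_severity: dict[str, float]
    yearly_by_severity: dict[str, float]
    community_episode_costs: dict[str, float]  # uti / pressure_ulcer, per episode

    def validate(self, path: str = "outcomes.costs") -> None:
        for name in ("per_admission", "per_day_acute", "per_day_rehab"):
            if getattr(self, name) < 0:
                raise PackError(f"invalid parameter: {path}.{name}")
        for d, name in (
            (self.one_time_by_severity, "one_time_by_severity"),
            (self.yearly_by_severity, "yearly_by_severity"),
            (self.community_episode_costs, "community_episode_costs"),
        ):
            if any(v < 0 for v in d.values()):
                raise PackError(f"invalid parameter: {path}.{name}")


def severity_key(neuro_band: str, ais: str) -> str:
    """Cost-schedule severity stratum: cervical/non-cervical x AIS group."""
    region = "cervical" if neuro_band in CERVICAL_BANDS else "non-cervical"
    group = "ABC" if ais in ("A", "B", "C") else "DE"
    return f"{region}:{group}"


@dataclass
class UtilityModel:
    """SF-6D-style utility regression: intercept, cervical shift, and
    decrements for the three community complications; plus their annual
    probabilities (no covariates — equally likely for everyone)."""

    intercept: float
    cervical_coefficient: float
    complication_decrements: dict[str, float]
    community_rates: dict[str, float]

    def validate(self, path: str = "outcomes.utility") -> None:
        for k in ("uti", "neuropathic_pain", "depression"):
            if k not in self.complication_decrements:
                raise PackError(f"invalid parameter: {path}.complication_decrements.{k}")
            if k not in self.community_rates:
                raise PackError(f"invalid parameter: {path}.community_rates.{k}")
            if not (0.0 <= self.community_rates[k] <= 1.0):
                raise PackError(f"invalid parameter: {path}.community_rates.{k}")

    def base_utility(self, cervical: bool) -> float:
        u = self.intercept + (self.cervical_coefficient if cervical else 0.0)
        return min(1.0, max(0.0, u))


# ---------------------------------------------------------------------------
# Section containers


@dataclass
class ArrivalParams:
    base_annual_rate: float
    dow_factors: list[float]
    month_factors: list[float]
    start_weekday: int = 4  # Friday; pack calendar is anchored, not dated

    def validate(self, path: str = "arrival") -> None:
        if self.base_annual_rate < 0:
            raise PackError(f"invalid parameter: {path}.base_annual_rate")
        if len(self.dow_factors) != 7 or any(f <= 0 for f in self.dow_factors):
            raise PackError(f"invalid parameter: {path}.dow_factors")
        if len(self.month_factors) != 12 or any(f <= 0 for f in self.month_factors):
            raise PackError(f"invalid parameter: {path}.month_factors")

    def normalized(self) -> "ArrivalParams":
        d = np.asarray(self.dow_factors, float)
        m = np.asarray(self.month_factors, float)
        return replace(self, dow_factors=list(d / d.mean()), month_factors=list(m / m.mean()))


@dataclass
class DemographicsParams:
    age_weights: list[float]
    age_means: list[float]
    age_sds: list[float]
    age_min: float
    age_max: float
    p_male: float
    distance_minutes: DistSpec

    def validate(self, path: str = "demographics") -> None:
        if not (len(self.age_weights) == len(self.age_means) == len(self.age_sds)):
            raise PackError(f"invalid parameter: {path}.age_weights")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise PackError(f"invalid parameter: {path}.age_weights")
        if not (0.0 <= self.p_male <= 1.0):
            raise PackError(f"invalid parameter: {path}.p_male")
        self.distance_minutes.validate(f"{path}.distance_minutes")


@dataclass
class ChainStep:
    """One link of the patient-attribute regression chain."""

    name: str
    kind: str  # categorical | numeric
    spec: RegressionSpec
    clip: tuple[float, float] | None = None
    integer: bool = False

    def validate(self, path: str) -> None:
        if self.kind not in {"categorical", "numeric"}:
            raise PackError(f"invalid parameter: {path}.kind")
        self.spec.validate(f"{path}.spec")


@dataclass
class PrehospitalParams:
    direct_threshold_minutes: float
    p_paralysis_direct: float
    delay_direct_hours: DistSpec
    transfer_extra_hours: DistSpec
    autolaunch_probability: float
    autolaunch_delay_multiplier: float
    rotary_min_minutes: float = 90.0
    fixed_wing_min_minutes: float = 240.0

    def validate(self, path: str = "prehospital") -> None:
        if self.direct_threshold_minutes <= 0:
            raise PackError(f"invalid parameter: {path}.direct_threshold_minutes")
        for p, name in ((self.p_paralysis_direct, "p_paralysis_direct"),
                        (self.autolaunch_probability, "autolaunch_probability")):
            if not (0.0 <= p <= 1.0):
                raise PackError(f"invalid parameter: {path}.{name}")
        self.delay_direct_hours.validate(f"{path}.delay_direct_hours")
        self.transfer_extra_hours.validate(f"{path}.transfer_extra_hours")


@dataclass
class AcuteParams:
    surgery_spec: RegressionSpec
    time_to_surgery_hours: DistSpec
    or_duration_hours: DistSpec
    mortality_spec: RegressionSpec
    scu_los: LosModel
    ward_los: LosModel
    complication_los_multipliers: dict[str, float]
    p_home_alc: float
    home_alc_days: DistSpec
    repeat_cycle_probability: float = 0.0

    def validate(self, path: str = "acute") -> None:
        self.surgery_spec.validate(f"{path}.surgery_spec")
        self.mortality_spec.validate(f"{path}.mortality_spec")
        self.time_to_surgery_hours.validate(f"{path}.time_to_surgery_hours")
        self.or_duration_hours.validate(f"{path}.or_duration_hours")
        self.scu_los.spec.validate(f"{path}.scu_los.spec")
        self.ward_los.spec.validate(f"{path}.ward_los.spec")
        for c, f in self.complication_los_multipliers.items():
            if c not in COMPLICATIONS or f < 0:
                raise PackError(f"invalid parameter: {path}.complication_los_multipliers.{c}")
        if not (0.0 <= self.p_home_alc <= 1.0):
            raise PackError(f"invalid parameter: {path}.p_home_alc")
        self.home_alc_days.validate(f"{path}.home_alc_days")


@dataclass
class ComplicationParams:
    reference_table: ComplicationTable
    table: ComplicationTable
    constraints: list[ConstraintSpec]
    predisposition_multipliers: dict[str, float]
    profile_weights: dict[ProfileKey, float] = field(default_factory=dict)

    def validate(self, path: str = "complications") -> None:
        self.reference_table.validate(f"{path}.reference_table")
        self.table.validate(f"{path}.table")
        for i, c in enumerate(self.constraints):
            c.validate(f"{path}.constraints[{i}]")
        for c, m in self.predisposition_multipliers.items():
            if m < 0:
                raise PackError(f"invalid parameter: {path}.predisposition_multipliers.{c}")


@dataclass
class RehabParams:
    go_to_rehab_spec: RegressionSpec
    bed_capacity: int
    bed_hold_days: float
    rehab_los: LosModel
    readmission_probability: float
    interruption_days: DistSpec
    complication_base: dict[str, float]
    complication_los_multipliers: dict[str, float]
    discharge_alc_probability: float
    discharge_alc_days: DistSpec
    discharge_fim_spec: RegressionSpec = None  # type: ignore[assignment]

    def validate(self, path: str = "rehab") -> None:
        self.go_to_rehab_spec.validate(f"{path}.go_to_rehab_spec")
        if self.bed_capacity <= 0:
            raise PackError(f"invalid parameter: {path}.bed_capacity")
        if self.bed_hold_days < 0:
            raise PackError(f"invalid parameter: {path}.bed_hold_days")
        if not (0.0 <= self.readmission_probability <= 1.0):
            raise PackError(f"invalid parameter: {path}.readmission_probability")
        if not (0.0 <= self.discharge_alc_probability <= 1.0):
            raise PackError(f"invalid parameter: {path}.discharge_alc_probability")
        for c, p in self.complication_base.items():
            if not (0.0 <= p <= 1.0):
                raise PackError(f"invalid parameter: {path}.complication_base.{c}")
        self.rehab_los.spec.validate(f"{path}.rehab_los.spec")
        self.interruption_days.validate(f"{path}.interruption_days")
        self.discharge_alc_days.validate(f"{path}.discharge_alc_days")
        if self.discharge_fim_spec is not None:
            self.discharge_fim_spec.validate(f"{path}.discharge_fim_spec")


@dataclass
class OutcomesParams:
    discharge_ais_spec: RegressionSpec
    life_table: LifeTable
    costs: CostSchedule
    utility: UtilityModel
    community_complication_rates: dict[str, float]  # uti / pressure_ulcer, per year
    discount_rate: float = 0.0

    def validate(self, path: str = "outcomes") -> None:
        self.discharge_ais_spec.validate(f"{path}.discharge_ais_spec")
        self.life_table.validate(f"{path}.life_table")
        self.costs.validate(f"{path}.costs")
        self.utility.validate(f"{path}.utility")
        for k, v in self.community_complication_rates.items():
            if v < 0:
                raise PackError(f"invalid parameter: {path}.community_complication_rates.{k}")
        if self.discount_rate < 0:
            raise PackError(f"invalid parameter: {path}.discount_rate")


@dataclass
class ParameterSet:
    """The complete model parameterization (one loaded parameter pack)."""

    arrival: ArrivalParams
    demographics: DemographicsParams
    attribute_chain: list[ChainStep]
    prehospital: PrehospitalParams
    acute: AcuteParams
    complications: ComplicationParams
    rehab: RehabParams
    outcomes: OutcomesParams
    name: str = "default"

    def validate(self) -> None:
        self.arrival.validate("arrival")
        self.demographics.validate("demographics")
        for step in self.attribute_chain:
            step.validate(f"attribute_chain.{step.name}")
        self.prehospital.validate("prehospital")
        self.acute.validate("acute")
        self.complications.validate("complications")
        self.rehab.validate("rehab")
        self.outcomes.validate("outcomes")

    # -- dotted-path access (scenario overrides) ---------------------------

    def get_path(self, dotted: str) -> Any:
        obj: Any = self
        for part in dotted.split("."):
            if isinstance(obj, dict):
                obj = obj[part]
            elif hasattr(obj, part):
                obj = getattr(obj, part)
            else:
                raise KeyError(f"unknown parameter: {dotted}")
        return obj

    def set_path(self, dotted: str, value: Any) -> None:
        parts = dotted.split(".")
        obj: Any = self
        for part in parts[:-1]:
            if isinstance(obj, dict):
                obj = obj[part]
            elif hasattr(obj, part):
                obj = getattr(obj, part)
            else:
                raise KeyError(f"unknown parameter: {dotted}")
        last = parts[-1]
        if isinstance(obj, dict):
            if last not in obj:
                raise KeyError(f"unknown parameter: {dotted}")
            obj[last] = value
        elif hasattr(obj, last):
            setattr(obj, last, value)
        else:
            raise KeyError(f"unknown parameter: {dotted}")


# ---------------------------------------------------------------------------
# Pack serialization
#
# Layout: <dir>/manifest.yaml plus CSV tables.  Regression coefficient
# tables use fixed headers (category, term, level, estimate); `category`
# is blank outside the multinomial family and `term == "_intercept"` rows
# carry the threshold/category intercepts.

_MANIFEST = "manifest.yaml"


def _spec_to_files(spec: RegressionSpec, name: str, directory: Path) -> dict:
    rows = []
    for label, v in spec.intercepts.items():
        rows.append({"category": "", "term": "_intercept", "level": label, "estimate": v})
    for (cat, cov, level), coef in spec.terms.items():
        rows.append({"category": cat, "term": cov,
                     "level": "" if level is None else level, "estimate": coef})
    fname = f"regression_{name}.csv"
    pd.DataFrame(rows, columns=["category", "term", "level", "estimate"]).to_csv(
        directory / fname, index=False, float_format="%.17g")
    return {
        "file": fname,
        "family": spec.family,
        "outcome_categories": list(spec.outcome_categories),
        "reference_levels": dict(spec.reference_levels),
        "residual_sd": float(spec.residual_sd),
    }


def _spec_from_files(meta: dict, directory: Path, path: str) -> RegressionSpec:
    fpath = directory / meta["file"]
    if not fpath.exists():
        raise PackError(f"pack incomplete: missing {meta['file']}")
    df = pd.read_csv(fpath, dtype={"category": str, "term": str, "level": str},
                     keep_default_na=False, float_precision="round_trip")
    intercepts: dict[str, float] = {}
    terms: dict[tuple[str, str, str | None], float] = {}
    for row in df.itertuples(index=False):
        if row.term == "_intercept":
            intercepts[row.level] = float(row.estimate)
        else:
            level = None if row.level == "" else row.level
            terms[(row.category, row.term, level)] = float(row.estimate)
    spec = RegressionSpec(
        family=meta["family"],
        outcome_categories=tuple(meta.get("outcome_categories", [])),
        terms=terms,
        intercepts=intercepts,
        reference_levels=dict(meta.get("reference_levels", {})),
        residual_sd=float(meta.get("residual_sd", 0.0)),
    )
    spec.validate(path)
    return spec


def _dist_to_dict(d: DistSpec) -> dict:
    return {"family": d.family, "mean": float(d.mean), "cv": float(d.cv)}


def _dist_from_dict(d: dict, path: str) -> DistSpec:
    try:
        out = DistSpec(d["family"], float(d["mean"]), float(d["cv"]))
    except KeyError as e:
        raise PackError(f"invalid parameter: {path} (missing {e})") from None
    out.validate(path)
    return out


def _los_to_manifest(l: LosModel, name: str, directory: Path) -> dict:
    return {"spec": _spec_to_files(l.spec, name, directory),
            "cv": float(l.cv), "scale": float(l.scale), "floor": float(l.floor)}


def _los_from_manifest(d: dict, directory: Path, path: str) -> LosModel:
    return LosModel(_spec_from_files(d["spec"], directory, f"{path}.spec"),
                    cv=float(d["cv"]), scale=float(d["scale"]), floor=float(d["floor"]))


def write_parameter_pack(params: ParameterSet, directory: str | Path) -> Path:
    """Write ``params`` as a pack directory (YAML manifest + CSV tables)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    man: dict[str, Any] = {"name": params.name, "format": "actsim-pack-v1"}

    ar = params.arrival
    man["arrival"] = {
        "base_annual_rate": float(ar.base_annual_rate),
        "dow_factors": [float(x) for x in ar.dow_factors],
        "month_factors": [float(x) for x in ar.month_factors],
        "start_weekday": int(ar.start_weekday),
    }
    dm = params.demographics
    man["demographics"] = {
        "age_weights": [float(x) for x in dm.age_weights],
        "age_means": [float(x) for x in dm.age_means],
        "age_sds": [float(x) for x in dm.age_sds],
        "age_min": float(dm.age_min), "age_max": float(dm.age_max),
        "p_male": float(dm.p_male),
        "distance_minutes": _dist_to_dict(dm.distance_minutes),
    }
    man["attribute_chain"] = [
        {"name": s.name, "kind": s.kind,
         "clip": None if s.clip is None else [float(s.clip[0]), float(s.clip[1])],
         "integer": bool(s.integer),
         "spec": _spec_to_files(s.spec, f"chain_{s.name}", d)}
        for s in params.attribute_chain
    ]
    ph = params.prehospital
    man["prehospital"] = {
        "direct_threshold_minutes": float(ph.direct_threshold_minutes),
        "p_paralysis_direct": float(ph.p_paralysis_direct),
        "delay_direct_hours": _dist_to_dict(ph.delay_direct_hours),
        "transfer_extra_hours": _dist_to_dict(ph.transfer_extra_hours),
        "autolaunch_probability": float(ph.autolaunch_probability),
        "autolaunch_delay_multiplier": float(ph.autolaunch_delay_multiplier),
        "rotary_min_minutes": float(ph.rotary_min_minutes),
        "fixed_wing_min_minutes": float(ph.fixed_wing_min_minutes),
    }
    ac = params.acute
    man["acute"] = {
        "surgery_spec": _spec_to_files(ac.surgery_spec, "surgery", d),
        "time_to_surgery_hours": _dist_to_dict(ac.time_to_surgery_hours),
        "or_duration_hours": _dist_to_dict(ac.or_duration_hours),
        "mortality_spec": _spec_to_files(ac.mortality_spec, "mortality", d),
        "scu_los": _los_to_manifest(ac.scu_los, "scu_los", d),
        "ward_los": _los_to_manifest(ac.ward_los, "ward_los", d),
        "complication_los_multipliers": {k: float(v) for k, v in
                                         ac.complication_los_multipliers.items()},
        "p_home_alc": float(ac.p_home_alc),
        "home_alc_days": _dist_to_dict(ac.home_alc_days),
        "repeat_cycle_probability": float(ac.repeat_cycle_probability),
    }
    co = params.complications
    co.reference_table.to_frame().to_csv(d / "complications_reference.csv",
                                         index=False, float_format="%.17g")
    co.table.to_frame().to_csv(d / "complications_table.csv", index=False,
                              float_format="%.17g")
    cons_rows = []
    for c in co.constraints:
        cons_rows.append({
            "kind": c.kind, "complication": c.complication, "target": c.target,
            "selector": ";".join(f"{k}={v}" for k, v in c.selector.items()),
            "direction": c.direction, "ratio_field": c.ratio_field,
            "ratio_num": c.ratio_num, "ratio_den": c.ratio_den,
            "lower": c.lower, "upper": c.upper, "source": c.source,
        })
    pd.DataFrame(cons_rows, columns=["kind", "complication", "target", "selector",
                                     "direction", "ratio_field", "ratio_num",
                                     "ratio_den", "lower", "upper", "source"]
                 ).to_csv(d / "complication_constraints.csv", index=False,
                          float_format="%.17g")
    weights_rows = [{**p._asdict(), "weight": w} for p, w in co.profile_weights.items()]
    pd.DataFrame(weights_rows, columns=["age_band", "gender", "mechanism", "neuro_band",
                                        "ais", "weight"]).to_csv(
        d / "profile_weights.csv", index=False, float_format="%.17g")
    man["complications"] = {
        "reference_table": "complications_reference.csv",
        "table": "complications_table.csv",
        "constraints": "complication_constraints.csv",
        "profile_weights": "profile_weights.csv",
        "predisposition_multipliers": {k: float(v) for k, v in
                                       co.predisposition_multipliers.items()},
    }
    rh = params.rehab
    man["rehab"] = {
        "go_to_rehab_spec": _spec_to_files(rh.go_to_rehab_spec, "go_to_rehab", d),
        "bed_capacity": int(rh.bed_capacity),
        "bed_hold_days": float(rh.bed_hold_days),
        "rehab_los": _los_to_manifest(rh.rehab_los, "rehab_los", d),
        "readmission_probability": float(rh.readmission_probability),
        "interruption_days": _dist_to_dict(rh.interruption_days),
        "complication_base": {k: float(v) for k, v in rh.complication_base.items()},
        "complication_los_multipliers": {k: float(v) for k, v in
                                         rh.complication_los_multipliers.items()},
        "discharge_alc_probability": float(rh.discharge_alc_probability),
        "discharge_alc_days": _dist_to_dict(rh.discharge_alc_days),
        "discharge_fim_spec": _spec_to_files(rh.discharge_fim_spec, "discharge_fim", d),
    }
    ou = params.outcomes
    lt_rows = [{"age": a, "life_expectancy": v} for a, v in sorted(ou.life_table.uninjured.items())]
    pd.DataFrame(lt_rows).to_csv(d / "life_table_uninjured.csv", index=False,
                                 float_format="%.17g")
    inj_rows = [{"age_band": k[0], "neuro_band": k[1], "ais": k[2], "life_expectancy": v}
                for k, v in ou.life_table.injured.items()]
    pd.DataFrame(inj_rows).to_csv(d / "life_table_injured.csv", index=False,
                                  float_format="%.17g")
    cost_rows = (
        [{"field": "per_admission", "key": "", "value": ou.costs.per_admission},
         {"field": "per_day_acute", "key": "", "value": ou.costs.per_day_acute},
         {"field": "per_day_rehab", "key": "", "value": ou.costs.per_day_rehab}]
        + [{"field": "one_time_by_severity", "key": k, "value": v}
           for k, v in ou.costs.one_time_by_severity.items()]
        + [{"field": "yearly_by_severity", "key": k, "value": v}
           for k, v in ou.costs.yearly_by_severity.items()]
        + [{"field": "community_episode_costs", "key": k, "value": v}
           for k, v in ou.costs.community_episode_costs.items()]
    )
    pd.DataFrame(cost_rows).to_csv(d / "costs.csv", index=False,
                                   float_format="%.17g")
    man["outcomes"] = {
        "discharge_ais_spec": _spec_to_files(ou.discharge_ais_spec, "discharge_ais", d),
        "life_table_uninjured": "life_table_uninjured.csv",
        "life_table_injured": "life_table_injured.csv",
        "costs": "costs.csv",
        "utility": {
            "intercept": float(ou.utility.intercept),
            "cervical_coefficient": float(ou.utility.cervical_coefficient),
            "complication_decrements": {k: float(v) for k, v in
                                        ou.utility.complication_decrements.items()},
            "community_rates": {k: float(v) for k, v in ou.utility.community_rates.items()},
        },
        "community_complication_rates": {k: float(v) for k, v in
                                         ou.community_complication_rates.items()},
        "discount_rate": float(ou.discount_rate),
    }
    with open(d / _MANIFEST, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
    return d


def load_parameter_pack(directory: str | Path) -> ParameterSet:
    """Load and fully validate a parameter pack directory.

    Raises :class:`PackError` with the offending file name ("pack
    incomplete") or dotted field path ("invalid parameter") on failure.
    Loading is deterministic.
    """
    d = Path(directory)
    mpath = d / _MANIFEST
    if not mpath.exists():
        raise PackError(f"pack incomplete: missing {_MANIFEST}")
    with open(mpath) as fh:
        man = yaml.safe_load(fh)

    def need(section: str) -> dict:
        if section not in man:
            raise PackError(f"pack incomplete: missing section {section}")
        return man[section]

    a = need("arrival")
    arrival = ArrivalParams(float(a["base_annual_rate"]),
                            [float(x) for x in a["dow_factors"]],
                            [float(x) for x in a["month_factors"]],
                            int(a.get("start_weekday", 4)))
    dm = need("demographics")
    demographics = DemographicsParams(
        [float(x) for x in dm["age_weights"]], [float(x) for x in dm["age_means"]],
        [float(x) for x in dm["age_sds"]], float(dm["age_min"]), float(dm["age_max"]),
        float(dm["p_male"]), _dist_from_dict(dm["distance_minutes"],
                                             "demographics.distance_minutes"))
    chain = []
    for s in need("attribute_chain"):
        chain.append(ChainStep(
            name=s["name"], kind=s["kind"],
            spec=_spec_from_files(s["spec"], d, f"attribute_chain.{s['name']}.spec"),
            clip=None if s.get("clip") is None else (float(s["clip"][0]), float(s["clip"][1])),
            integer=bool(s.get("integer", False))))
    ph = need("prehospital")
    prehospital = PrehospitalParams(
        float(ph["direct_threshold_minutes"]), float(ph["p_paralysis_direct"]),
        _dist_from_dict(ph["delay_direct_hours"], "prehospital.delay_direct_hours"),
        _dist_from_dict(ph["transfer_extra_hours"], "prehospital.transfer_extra_hours"),
        float(ph["autolaunch_probability"]), float(ph["autolaunch_delay_multiplier"]),
        float(ph.get("rotary_min_minutes", 90.0)), float(ph.get("fixed_wing_min_minutes", 240.0)))
    ac = need("acute")
    acute = AcuteParams(
        _spec_from_files(ac["surgery_spec"], d, "acute.surgery_spec"),
        _dist_from_dict(ac["time_to_surgery_hours"], "acute.time_to_surgery_hours"),
        _dist_from_dict(ac["or_duration_hours"], "acute.or_duration_hours"),
        _spec_from_files(ac["mortality_spec"], d, "acute.mortality_spec"),
        _los_from_manifest(ac["scu_los"], d, "acute.scu_los"),
        _los_from_manifest(ac["ward_los"], d, "acute.ward_los"),
        {k: float(v) for k, v in ac["complication_los_multipliers"].items()},
        float(ac["p_home_alc"]),
        _dist_from_dict(ac["home_alc_days"], "acute.home_alc_days"),
        float(ac.get("repeat_cycle_probability", 0.0)))
    co = need("complications")
    for key in ("reference_table", "table", "constraints", "profile_weights"):
        if not (d / co[key]).exists():
            raise PackError(f"pack incomplete: missing {co[key]}")
    ref = ComplicationTable.from_frame(
        pd.read_csv(d / co["reference_table"], float_precision="round_trip"))
    tab = ComplicationTable.from_frame(
        pd.read_csv(d / co["table"], float_precision="round_trip"))
    cons_df = pd.read_csv(d / co["constraints"], keep_default_na=False,
                          float_precision="round_trip")
    constraints = []
    for row in cons_df.itertuples(index=False):
        selector = {}
        if row.selector:
            for part in str(row.selector).split(";"):
                k, v = part.split("=", 1)
                selector[k] = v
        constraints.append(ConstraintSpec(
            kind=row.kind, complication=row.complication, target=float(row.target),
            selector=selector, direction=row.direction or "eq",
            ratio_field=str(row.ratio_field), ratio_num=str(row.ratio_num),
            ratio_den=str(row.ratio_den), lower=float(row.lower), upper=float(row.upper),
            source=str(row.source)))
    wdf = pd.read_csv(d / co["profile_weights"], float_precision="round_trip")
    weights = {ProfileKey(r.age_band, r.gender, r.mechanism, r.neuro_band, r.ais): float(r.weight)
               for r in wdf.itertuples(index=False)}
    complications = ComplicationParams(
        ref, tab, constraints,
        {k: float(v) for k, v in co["predisposition_multipliers"].items()}, weights)
    rh = need("rehab")
    rehab = RehabParams(
        _spec_from_files(rh["go_to_rehab_spec"], d, "rehab.go_to_rehab_spec"),
        int(rh["bed_capacity"]), float(rh["bed_hold_days"]),
        _los_from_manifest(rh["rehab_los"], d, "rehab.rehab_los"),
        float(rh["readmission_probability"]),
        _dist_from_dict(rh["interruption_days"], "rehab.interruption_days"),
        {k: float(v) for k, v in rh["complication_base"].items()},
        {k: float(v) for k, v in rh["complication_los_multipliers"].items()},
        float(rh["discharge_alc_probability"]),
        _dist_from_dict(rh["discharge_alc_days"], "rehab.discharge_alc_days"),
        _spec_from_files(rh["discharge_fim_spec"], d, "rehab.discharge_fim_spec"))
    ou = need("outcomes")
    for key in ("life_table_uninjured", "life_table_injured", "costs"):
        if not (d / ou[key]).exists():
            raise PackError(f"pack incomplete: missing {ou[key]}")
    udf = pd.read_csv(d / ou["life_table_uninjured"], float_precision="round_trip")
    uninjured = {int(r.age): float(r.life_expectancy) for r in udf.itertuples(index=False)}
    idf = pd.read_csv(d / ou["life_table_injured"], float_precision="round_trip")
    injured = {(r.age_band, r.neuro_band, r.ais): float(r.life_expectancy)
               for r in idf.itertuples(index=False)}
    cdf = pd.read_csv(d / ou["costs"], keep_default_na=False,
                      float_precision="round_trip")
    scalars: dict[str, float] = {}
    maps: dict[str, dict[str, float]] = {"one_time_by_severity": {}, "yearly_by_severity": {},
                                         "community_episode_costs": {}}
    for row in cdf.itertuples(index=False):
        if row.field in maps:
            maps[row.field][str(row.key)] = float(row.value)
        else:
            scalars[row.field] = float(row.value)
    try:
        costs = CostSchedule(scalars["per_admission"], scalars["per_day_acute"],
                             scalars["per_day_rehab"], maps["one_time_by_severity"],
                             maps["yearly_by_severity"], maps["community_episode_costs"])
    except KeyError as e:
        raise PackError(f"invalid parameter: outcomes.costs (missing {e})") from None
    um = ou["utility"]
    utility = UtilityModel(float(um["intercept"]), float(um["cervical_coefficient"]),
                           {k: float(v) for k, v in um["complication_decrements"].items()},
                           {k: float(v) for k, v in um["community_rates"].items()})
    outcomes = OutcomesParams(
        _spec_from_files(ou["discharge_ais_spec"], d, "outcomes.discharge_ais_spec"),
        LifeTable(uninjured, injured), costs, utility,
        {k: float(v) for k, v in ou["community_complication_rates"].items()},
        float(ou.get("discount_rate", 0.0)))

    params = ParameterSet(arrival.normalized(), demographics, chain, prehospital,
                          acute, complications, rehab, outcomes,
                          name=str(man.get("name", "pack")))
    params.validate()
    return params
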