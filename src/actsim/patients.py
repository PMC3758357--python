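"""Simulated patient arrivals and injury-attribute assignment.

Arrivals follow a non-homogeneous Poisson process whose rate is the base
annual incidence modulated by day-of-week and month factors.  Each arrival
then receives its attributes from a chained sequence of regressions
(mechanism given age/gender/distance, energy given mechanism, neurological
level, ISS, GCS, admission AIS, ...), building the simulated "patient
chart" that subsequent care phases extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .parameters import (
    AIS_GRADES,
    CERVICAL_BANDS,
    DAYS_PER_YEAR,
    HOURS_PER_DAY,
    HOURS_PER_YEAR,
    ArrivalParams,
    ChainStep,
    DemographicsParams,
    PackError,
    ProfileKey,
    age_band_of,
)

__all__ = ["PatientRecord", "sample_arrival_times", "create_patient", "profile_of"]

#: Cumulative days at the start of each month (365-day model year).
_MONTH_STARTS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])


@dataclass
class PatientRecord:
    """The simulated patient chart: grows with events as care proceeds."""

    id: int
    injury_time: float  # hours from simulation start
    age: float = 0.0
    gender: str = ""
    distance_to_centre: float = 0.0  # minutes of road travel
    mechanism: str = ""
    energy: str = ""
    neuro_band: str = ""
    iss: int = 0
    gcs: int = 15
    ais_admission: str = "D"
    event_log: list[tuple[float, str, str]] = field(default_factory=list)
    complications_acute: set[str] = field(default_factory=set)
    complications_rehab: set[str] = field(default_factory=set)
    ais_discharge: str = ""
    fim_discharge: float = float("nan")
    had_surgery: bool = False
    early_surgery: bool = False
    went_to_rehab: bool = False
    died: bool = False
    outcome_block: dict[str, float] = field(default_factory=dict)

    def log(self, time_h: float, event: str, detail: str = "") -> None:
        """Append a chart entry, keeping timestamps non-decreasing.

        Entries may be recorded out of order (a complication noted on day
        one, surgery sampled for hour five); they are inserted in
        timestamp order, later insertions after equal timestamps."""
        entry = (time_h, event, detail)
        if self.event_log and time_h < self.event_log[-1][0]:
            import bisect
            pos = bisect.bisect_right([e[0] for e in self.event_log], time_h)
            self.event_log.insert(pos, entry)
        else:
            self.event_log.append(entry)

    @property
    def cervical(self) -> bool:
        return self.neuro_band in CERVICAL_BANDS

    @property
    def neuro_level(self) -> str:
        """Three-level grouping used by the discharge-AIS regression:
        High = C1-C4, Medium = C5-C8, Low = thoracic/lumbosacral."""
        if self.neuro_band == "C1-C4":
            return "High"
        if self.neuro_band == "C5-C8":
            return "Medium"
        return "Low"

    def covariates(self) -> dict[str, Any]:
        """Attribute map consumed by downstream regression specs."""
        return {
            "age": self.age, "gender": self.gender,
            "distance": self.distance_to_centre, "mechanism": self.mechanism,
            "energy": self.energy, "neuro_band": self.neuro_band,
            "neuro_level": self.neuro_level, "iss": self.iss, "gcs": self.gcs,
            "ais_admission": self.ais_admission,
        }


def profile_of(patient: PatientRecord) -> ProfileKey:
    """Map a patient to its complication-risk profile cell (always defined)."""
    return ProfileKey(age_band_of(patient.age), patient.gender, patient.mechanism,
                      patient.neuro_band, patient.ais_admission)


def _rate_factor(t_hours: float, arrival: ArrivalParams) -> float:
    day = int(t_hours // HOURS_PER_DAY)
    dow = (arrival.start_weekday + day) % 7
    doy = day % int(DAYS_PER_YEAR)
    month = int(np.searchsorted(_MONTH_STARTS, doy, side="right") - 1)
    return arrival.dow_factors[dow] * arrival.month_factors[month]


def sample_arrival_times(
    horizon_years: float, arrival: ArrivalParams, rng: np.random.Generator
) -> np.ndarray:
    """Arrival timestamps (hours) over ``horizon_years`` by Poisson thinning.

    The instantaneous rate is ``base_annual_rate x dow_factor(t) x
    month_factor(t)``; factors are normalized to mean 1 on load so the
    base rate is also the long-run annual mean.
    """
    if horizon_years <= 0:
        raise ValueError("invalid rate: horizon must be positive")
    if arrival.base_annual_rate < 0:
        raise ValueError("invalid rate: negative arrival rate")
    if arrival.base_annual_rate == 0:
        return np.zeros(0)
    arrival = arrival.normalized()
    lam_hour = arrival.base_annual_rate / HOURS_PER_YEAR
    lam_max = lam_hour * max(arrival.dow_factors) * max(arrival.month_factors)
    horizon_h = horizon_years * HOURS_PER_YEAR
    # thinning: candidate stream at the envelope rate, accept with ratio
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= horizon_h:
            break
        if rng.random() <= lam_hour * _rate_factor(t, arrival) / lam_max:
            times.append(t)
    return np.asarray(times)


def _sample_age(dem: DemographicsParams, rng: np.random.Generator) -> float:
    comp = rng.choice(len(dem.age_weights), p=np.asarray(dem.age_weights))
    age = rng.normal(dem.age_means[comp], dem.age_sds[comp])
    return float(np.clip(age, dem.age_min, dem.age_max))


def create_patient(
    patient_id: int,
    arrival_time: float,
    demographics: DemographicsParams,
    attribute_chain: list[ChainStep],
    rng: np.random.Generator,
) -> PatientRecord:
    """Create one patient: base attributes, then the regression chain.

    Age comes from a two-component normal mixture (the bimodal injury-age
    pattern: a young peak and an older peak), gender from a Bernoulli and
    distance-to-centre (minutes, the rural/urban proxy) from a log-normal.
    Chain steps then sample each attribute from its spec given earlier
    outputs; a step whose covariates are not yet available is an error.
    """
    p = PatientRecord(id=patient_id, injury_time=arrival_time)
    p.age = _sample_age(demographics, rng)
    p.gender = "male" if rng.random() < demographics.p_male else "female"
    p.distance_to_centre = float(demographics.distance_minutes.sample(rng))
    p.log(arrival_time, "injury", f"mechanism pending; distance {p.distance_to_centre:.0f} min")

    known = p.covariates()
    for step in attribute_chain:
        missing = step.spec.covariates() - set(known)
        if missing:
            raise PackError(f"unresolved covariate: {sorted(missing)} in chain step {step.name}")
        value = step.spec.sample(known, rng)
        if step.kind == "numeric":
            v = float(value)
            if step.clip is not None:
                v = float(np.clip(v, *step.clip))
            if step.integer:
                v = int(round(v))
            value = v
        _assign(p, step.name, value)
        known = p.covariates()
    if p.ais_admission not in AIS_GRADES:
        raise PackError(f"level mismatch: ais_admission={p.ais_admission!r}")
    return p


_FIELD_MAP = {
    "mechanism": "mechanism", "energy": "energy", "neuro_band": "neuro_band",
    "iss": "iss", "gcs": "gcs", "ais_admission": "ais_admission",
}


def _assign(p: PatientRecord, name: str, value: Any) -> None:
    try:
        setattr(p, _FIELD_MAP[name], value)
    except KeyError:
        raise PackError(f"invalid parameter: attribute_chain.{name} (unknown attribute)") from None
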