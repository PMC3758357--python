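"""Long-term outcomes: discharge AIS, life expectancy, costs and QALYs.

Discharge neurological status comes from the published ordinal logistic
regression (cumulative logits over E < D < C < B < A on admission grade,
neurological level and rehabilitation).  Life expectancy is a table
lookup by age band, neurological level band and discharge AIS, with
life-years lost measured against the uninjured table.  Costs split into
in-hospital (per admission + per day), long-term (one-time + yearly by
severity stratum over remaining life) and the avoidable community cost of
urinary tract infections and pressure ulcers.  QALYs are computed under
five accounting variants for future community complications.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    AIS_ORDER,
    LifeTable,
    CostSchedule,
    OutcomesParams,
    RegressionSpec,
    UtilityModel,
    severity_key,
)
from .patients import PatientRecord

__all__ = [
    "sample_discharge_ais", "life_expectancy_and_lyl", "compute_costs",
    "qaly_scenarios", "attach_outcomes",
]


def sample_discharge_ais(
    patient: PatientRecord,
    spec: RegressionSpec,
    rng: np.random.Generator,
    linear_shift: float = 0.0,
) -> str:
    """Draw the discharge AIS grade from the ordinal model.

    Admission grade E (neurologically normal) is an identity: discharge E
    with no draw.  ``linear_shift`` is the early-surgery policy increment
    to the linear predictor (positive values move mass toward E).
    """
    if patient.ais_admission == "E":
        return "E"
    cov = {
        "ais_admission": patient.ais_admission,
        "neuro_level_grouped": "Low" if patient.neuro_level == "Low" else "HighMedium",
        "rehabilitation": "Yes" if patient.went_to_rehab else "No",
    }
    u = rng.random()  # one uniform per patient: CRN-aligned across scenarios
    probs = np.asarray(spec.predict(cov))
    if linear_shift:
        cum = np.cumsum(probs)[:-1]
        with np.errstate(divide="ignore"):
            logits = np.log(cum / (1.0 - cum)) + linear_shift
        cum = 1.0 / (1.0 + np.exp(-logits))
        probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    idx = int(np.searchsorted(np.cumsum(probs), u))
    return spec.outcome_categories[min(idx, len(probs) - 1)]


def life_expectancy_and_lyl(
    age: float, neuro_band: str, ais_discharge: str, table: LifeTable
) -> tuple[float, float]:
    """Remaining life expectancy and life-years lost versus uninjured."""
    le = table.injured_le(age, neuro_band, ais_discharge)
    lyl = table.uninjured_le(age) - le
    return le, max(0.0, lyl)


def _annuity(years: float, rate: float) -> float:
    """Present value of one unit per year over ``years`` (rate 0 => years)."""
    if rate <= 0:
        return years
    whole = int(years)
    pv = sum((1.0 + rate) ** -(t + 1) for t in range(whole))
    pv += (years - whole) * (1.0 + rate) ** -(whole + 1)
    return pv


def compute_costs(
    patient: PatientRecord,
    schedule: CostSchedule,
    le_years: float,
    acute_days: float,
    rehab_days: float,
    community_rates: dict[str, float],
    discount_rate: float = 0.0,
) -> dict[str, float]:
    """In-hospital, long-term and avoidable community complication costs."""
    sev = severity_key(patient.neuro_band, patient.ais_discharge or patient.ais_admission)
    in_hospital = (schedule.per_admission
                   + schedule.per_day_acute * acute_days
                   + schedule.per_day_rehab * rehab_days)
    years = _annuity(le_years, discount_rate)
    long_term = schedule.one_time_by_severity[sev] + schedule.yearly_by_severity[sev] * years
    avoidable = sum(
        community_rates.get(comp, 0.0) * schedule.community_episode_costs.get(comp, 0.0)
        for comp in ("uti", "pressure_ulcer")
    ) * years
    return {"in_hospital": in_hospital, "long_term": long_term,
            "avoidable_community": avoidable}


def qaly_scenarios(
    patient: PatientRecord,
    utility: UtilityModel,
    le_years: float,
    discount_rate: float = 0.0,
) -> dict[str, float]:
    """Quality-adjusted life years under five complication futures.

    (i) no complications ever; (ii) all three every year; (iii) each at
    its average annual probability; (iv) average neuropathic pain and
    depression, never urinary tract infections; (v) as (iv) but UTIs in
    every year for patients with a UTI before discharge.  Utilities are
    clipped to [0, 1]; QALY never exceeds remaining life years.
    """
    base = utility.base_utility(patient.cervical)
    dec = utility.complication_decrements
    rates = utility.community_rates
    years = _annuity(le_years, discount_rate)

    def u(drop: float) -> float:
        return min(1.0, max(0.0, base - drop))

    all_three = sum(dec.values())
    avg_all = sum(rates[k] * dec[k] for k in dec)
    avg_pd = rates["neuropathic_pain"] * dec["neuropathic_pain"] + \
        rates["depression"] * dec["depression"]
    had_uti = "uti" in (patient.complications_acute | patient.complications_rehab)
    return {
        "qaly_i": u(0.0) * years,
        "qaly_ii": u(all_three) * years,
        "qaly_iii": u(avg_all) * years,
        "qaly_iv": u(avg_pd) * years,
        "qaly_v": u(avg_pd + (dec["uti"] if had_uti else 0.0)) * years,
    }


def attach_outcomes(
    patient: PatientRecord,
    params: OutcomesParams,
    rng: np.random.Generator,
    acute_days: float,
    rehab_days: float,
    ais_shift: float = 0.0,
) -> None:
    """Fill the patient's outcome block at final discharge."""
    patient.ais_discharge = sample_discharge_ais(
        patient, params.discharge_ais_spec, rng, linear_shift=ais_shift)
    le, lyl = life_expectancy_and_lyl(
        patient.age, patient.neuro_band, patient.ais_discharge, params.life_table)
    costs = compute_costs(patient, params.costs, le, acute_days, rehab_days,
                          params.community_complication_rates, params.discount_rate)
    qalys = qaly_scenarios(patient, params.utility, le, params.discount_rate)
    patient.outcome_block = {"le_years": le, "life_years_lost": lyl, **costs, **qalys}
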