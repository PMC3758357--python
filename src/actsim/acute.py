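"""Acute-care phase: surgery, secondary complications, length of stay.

Patients pass through the emergency department into surgery, the special
care unit (SCU) or the spine ward.  Three event types accrue to the chart
here: surgery (time to surgery, OR time, post-op SCU stay, operative
mortality), the five acute secondary complications (profile-stratified
probabilities from the calibrated table), and length of stay (ward +
SCU, extended multiplicatively by complications).  The alternative-level-
of-care wait after clinical readiness is owned by the simulation engine,
which knows the rehabilitation bed state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import COMPLICATIONS, AcuteParams, ComplicationTable, ProfileKey
from .patients import PatientRecord, profile_of

__all__ = ["AcuteEpisode", "assign_acute_complications", "acute_pathway"]


@dataclass
class AcuteEpisode:
    """Outcome of the acute phase, before any bed-wait (ALC) is known."""

    surgery: bool = False
    time_to_surgery_h: float = 0.0
    or_duration_h: float = 0.0
    scu_days: float = 0.0
    ward_days: float = 0.0
    complications: set[str] = field(default_factory=set)
    died: bool = False
    death_time_h: float = 0.0  # offset from admission
    clinical_days: float = 0.0  # scu + ward; OR hours excluded from bed-days
    alc_days: float = 0.0  # filled by the engine
    discharge_destination: str = ""  # rehab | home | other | death


def assign_acute_complications(
    profile: ProfileKey,
    table: ComplicationTable,
    rng: np.random.Generator,
    multipliers: Mapping[str, float] | None = None,
) -> set[str]:
    """Five independent Bernoulli draws at the profile's probabilities.

    Scenario ``multipliers`` (e.g. pressure ulcer x 0.3) scale each
    probability before the draw, clipped to [0, 1].  One uniform draw per
    complication keeps the random-number stream aligned across scenario
    arms (common random numbers).
    """
    out: set[str] = set()
    for comp in COMPLICATIONS:
        p = table.probability(profile, comp)
        if multipliers:
            p = min(1.0, max(0.0, p * multipliers.get(comp, 1.0)))
        if rng.random() < p:
            out.add(comp)
    return out


def acute_pathway(
    patient: PatientRecord,
    params: AcuteParams,
    table: ComplicationTable,
    rng: np.random.Generator,
    admission_time_h: float,
    complication_multipliers: Mapping[str, float] | None = None,
    early_surgery_threshold_h: float | None = None,
) -> AcuteEpisode:
    """Simulate the acute episode for one admitted patient.

    When ``early_surgery_threshold_h`` is set (the early-surgery policy
    scenario), eligible patients — cervical injuries receiving surgery —
    have their time to surgery capped at the threshold.
    """
    ep = AcuteEpisode()
    cov = patient.covariates()

    p_surg = float(params.surgery_spec.predict(cov)[1])
    ep.surgery = rng.random() < p_surg
    u_mort = rng.random()  # drawn unconditionally to keep streams aligned
    tts = float(params.time_to_surgery_hours.sample(rng))
    or_h = float(params.or_duration_hours.sample(rng))
    scu = float(params.scu_los.sample(cov, rng))
    if ep.surgery:
        if (early_surgery_threshold_h is not None and patient.cervical
                and tts > early_surgery_threshold_h):
            tts = early_surgery_threshold_h
        ep.time_to_surgery_h = tts
        ep.or_duration_h = or_h
        ep.scu_days = scu
        patient.had_surgery = True
        patient.early_surgery = tts <= 24.0
        patient.log(admission_time_h + tts, "surgery", f"OR {or_h:.1f} h")
        if u_mort < float(params.mortality_spec.predict(cov)[1]):
            ep.died = True
            ep.death_time_h = tts + or_h
    else:
        ep.scu_days = 0.0
        if u_mort < float(params.mortality_spec.predict(cov)[1]):
            ep.died = True

    ep.complications = assign_acute_complications(
        profile_of(patient), table, rng, complication_multipliers)
    patient.complications_acute = set(ep.complications)
    for comp in sorted(ep.complications):
        patient.log(admission_time_h + 24.0, "acute_complication", comp)

    ward = float(params.ward_los.sample(cov, rng))
    for comp in ep.complications:
        ward *= params.complication_los_multipliers.get(comp, 1.0)
    ep.ward_days = ward
    ep.clinical_days = ep.scu_days + ep.ward_days

    # drawn unconditionally so the per-patient draw count is scenario-invariant
    e_death = rng.exponential(1.0)
    if ep.died:
        patient.died = True
        if not ep.surgery:
            # exponential hazard over the stay, censored just before discharge
            ep.death_time_h = min(e_death * ep.clinical_days * 12.0,
                                  ep.clinical_days * 24.0 * 0.95)
        ep.discharge_destination = "death"
        patient.log(admission_time_h + ep.death_time_h, "death", "acute care")
    return ep
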