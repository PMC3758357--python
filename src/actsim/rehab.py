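"""In-patient rehabilitation: complications, interruptions, stay, FIM.

The rehabilitation centre is the single capacitated resource in the model
(24 staffed beds by default).  This module samples everything about a
rehabilitation episode that does not depend on the bed state — the
complication set (with predisposition to recurrence after the same
complication in acute care), the length of stay, a possible acute
readmission (service interruption), the discharge-destination wait
(housing ALC, spent in the bed) and the discharge FIM score.  The engine
owns bed grants, the 3-day bed-hold rule and the FIFO wait list, calling
:func:`handle_acute_readmission` to decide whether an interruption keeps
the bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import RehabParams
from .patients import PatientRecord

__all__ = ["Interruption", "RehabEpisode", "plan_rehab_episode", "handle_acute_readmission"]


@dataclass
class Interruption:
    at_fraction: float  # position within the (complication-adjusted) stay
    duration_days: float
    returned_to_same_bed: bool | None = None  # decided against the hold window


@dataclass
class RehabEpisode:
    wait_for_bed_days: float = 0.0  # mirrored acute-side ALC wait
    complications: set[str] = field(default_factory=set)
    interruptions: list[Interruption] = field(default_factory=list)
    rehab_days: float = 0.0
    discharge_alc_days: float = 0.0
    fim_discharge: float = 0.0


def plan_rehab_episode(
    patient: PatientRecord,
    params: RehabParams,
    rng: np.random.Generator,
    predisposition_multipliers: dict[str, float] | None = None,
) -> RehabEpisode:
    """Sample the bed-independent parts of a rehabilitation episode.

    Complication probabilities are the pack's base rates, multiplied by
    the predisposition factor when the same complication occurred during
    acute care (clipped to 1).  Complications extend the stay
    multiplicatively, mirroring the acute-phase convention.
    """
    predis = predisposition_multipliers or {}
    ep = RehabEpisode()
    for comp, base in params.complication_base.items():
        p = base
        if comp in patient.complications_acute:
            p = min(1.0, p * predis.get(comp, 1.0))
        if rng.random() < p:
            ep.complications.add(comp)
    patient.complications_rehab = set(ep.complications)

    los = float(params.rehab_los.sample(patient.covariates(), rng))
    for comp in ep.complications:
        los *= params.complication_los_multipliers.get(comp, 1.0)
    ep.rehab_days = los

    u_readmit = rng.random()
    frac = rng.uniform(0.05, 0.95)
    dur = float(params.interruption_days.sample(rng))
    if u_readmit < params.readmission_probability:
        ep.interruptions.append(Interruption(at_fraction=frac, duration_days=dur))

    u_alc = rng.random()
    alc = float(params.discharge_alc_days.sample(rng))
    if u_alc < params.discharge_alc_probability:
        ep.discharge_alc_days = alc

    fim = float(params.discharge_fim_spec.predict(patient.covariates()))
    if params.discharge_fim_spec.residual_sd:
        fim += rng.normal(0.0, params.discharge_fim_spec.residual_sd)
    ep.fim_discharge = float(np.clip(fim, 18.0, 126.0))
    return ep


def handle_acute_readmission(
    interruption: Interruption, bed_hold_days: float
) -> bool:
    """Apply the bed-hold rule to an acute readmission from rehabilitation.

    The bed is held for up to ``bed_hold_days`` (3 by default): an
    interruption no longer than the hold resumes the same bed; a longer
    one releases it and the patient rejoins the wait list when acute
    treatment completes.  Returns True when the same bed is kept.
    """
    same_bed = interruption.duration_days <= bed_hold_days
    interruption.returned_to_same_bed = same_bed
    return same_bed
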