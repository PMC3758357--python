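"""Pre-hospital routing and transport to the spine centre.

Patients injured within the direct-transport road-time threshold (40
minutes by default) go straight to the trauma centre; beyond it they are
stabilized at a first hospital unless suspected paralysis triggers a
direct transfer.  Transport mode follows a simple distance/severity rule
and an air "Autolaunch" protocol can shorten the transfer delay for
severe remote cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import PrehospitalParams
from .patients import PatientRecord

__all__ = ["RouteAssignment", "route_and_transport"]

_SEVERE_GRADES = frozenset({"A", "B"})


@dataclass
class RouteAssignment:
    route: str  # direct | via_first_hospital
    transport_mode: str  # road_ambulance | rotary_wing | fixed_wing
    admission_delay: float  # hours, injury -> spine-centre admission


def route_and_transport(
    patient: PatientRecord, params: PrehospitalParams, rng: np.random.Generator
) -> RouteAssignment:
    """Assign route, transport mode and admission delay; log the events."""
    severe = patient.ais_admission in _SEVERE_GRADES
    direct = patient.distance_to_centre <= params.direct_threshold_minutes
    if not direct and severe and rng.random() < params.p_paralysis_direct:
        direct = True  # paralysis suspected at the scene: straight to the spine centre

    if patient.distance_to_centre >= params.fixed_wing_min_minutes:
        mode = "fixed_wing"
    elif patient.distance_to_centre >= params.rotary_min_minutes and severe:
        mode = "rotary_wing"
    else:
        mode = "road_ambulance"

    delay = float(params.delay_direct_hours.sample(rng))
    if not direct:
        extra = float(params.transfer_extra_hours.sample(rng))
        if severe and rng.random() < params.autolaunch_probability:
            extra *= params.autolaunch_delay_multiplier
            patient.log(patient.injury_time, "autolaunch", "air ambulance expedite")
        delay += extra
    delay = max(delay, 1e-3)

    route = "direct" if direct else "via_first_hospital"
    if not direct:
        patient.log(patient.injury_time + delay * 0.5, "first_hospital", "stabilization")
    patient.log(patient.injury_time + delay, "admission",
                f"route={route} mode={mode}")
    return RouteAssignment(route=route, transport_mode=mode, admission_delay=delay)
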