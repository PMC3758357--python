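"""Discrete-event core: one replication of the care-continuum simulation.

The acute hospital is uncapacitated in the baseline configuration (the
binding constraint of the system is rehabilitation beds), so each
patient's pre-rehabilitation path is sampled at arrival; the event
calendar then resolves the only interacting resource — the rehabilitation
bed pool with its FIFO wait list, the 3-day bed hold across acute
readmissions, and the discharge (housing) wait spent in the bed.  Events
are processed in non-decreasing time order with deterministic
(priority, insertion order) tie-breaking.

Runs use a warm-up period before a measurement window; occupancy metrics
are time averages over the window and patient metrics attribute a patient
to the window by the event that completes the metric (discharge for LOS,
clinical readiness for ALC designation), which avoids censoring bias at
the window edge.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .acute import AcuteEpisode, acute_pathway
from .outcomes import attach_outcomes
from .parameters import (
    AIS_GRADES,
    COMPLICATIONS,
    HOURS_PER_DAY,
    HOURS_PER_YEAR,
    REHAB_COMPLICATIONS,
    ParameterSet,
)
from .patients import PatientRecord, create_patient, sample_arrival_times
from .prehospital import route_and_transport
from .rehab import RehabEpisode, handle_acute_readmission, plan_rehab_episode
from .scenarios import ScenarioSpec

__all__ = ["STREAM_NAMES", "rng_streams", "ReplicationResult", "run_replication",
           "summarize_metrics"]

#: Independent named RNG streams, one per sampling module, so adding a
#: sampling site in one module never perturbs the draws of another.
STREAM_NAMES = ("arrivals", "attributes", "prehospital", "acute", "rehab", "outcomes")

_EPS_DAYS = 1e-9


def rng_streams(base_seed: int, replication: int) -> dict[str, np.random.Generator]:
    """Splittable per-(replication, module) streams from a base seed."""
    return {
        name: np.random.default_rng(np.random.SeedSequence((base_seed, replication, i)))
        for i, name in enumerate(STREAM_NAMES)
    }


@dataclass
class _PatientPath:
    patient: PatientRecord
    admission_h: float
    acute: AcuteEpisode
    rehab_bound: bool
    rehab_plan: RehabEpisode | None
    ready_h: float = 0.0
    acute_exit_h: float = float("inf")  # leaves acute (death, home, or rehab grant)
    rehab_discharge_h: float = float("nan")  # physical rehab discharge (bed release)
    interruption_wait_days: float = 0.0


@dataclass
class ReplicationResult:
    paths: list[_PatientPath]
    bed_intervals: list[tuple[float, float, int]]  # (start, end, patient id)
    occupancy_area_bed_hours: float
    window: tuple[float, float]
    capacity: int
    metrics: dict[str, float]
    occupancy_trace: list[tuple[float, int, int]] = field(default_factory=list)


class _BedPool:
    """Rehabilitation beds: counter, FIFO wait list, occupancy integral."""

    def __init__(self, capacity: int, window: tuple[float, float]):
        if capacity <= 0:
            raise ValueError("invalid resource: bed capacity must be positive")
        self.capacity = capacity
        self.busy = 0
        self.queue: list = []  # FIFO via index; engine appends/pops
        self.window = window
        self._t_last = 0.0
        self.area = 0.0  # busy-bed hours within the window
        self.trace: list[tuple[float, int, int]] = []

    def _integrate(self, t: float) -> None:
        w0, w1 = self.window
        lo, hi = max(self._t_last, w0), min(t, w1)
        if hi > lo:
            self.area += self.busy * (hi - lo)
        self._t_last = t

    def seize(self, t: float) -> None:
        self._integrate(t)
        self.busy += 1
        if self.busy > self.capacity:
            raise RuntimeError("bed conservation violated")

    def release(self, t: float) -> None:
        self._integrate(t)
        self.busy -= 1
        if self.busy < 0:
            raise RuntimeError("bed conservation violated")

    def close(self, t: float) -> None:
        self._integrate(t)


# event priorities: releases before requests at equal times
_P_RELEASE, _P_REQUEST = 0, 1


def run_replication(
    params: ParameterSet,
    scenario: ScenarioSpec | None = None,
    seed: int = 0,
    replication: int = 0,
    warmup_years: float = 5.0,
    measure_years: float = 5.0,
) -> ReplicationResult:
    """Run one replication; deterministic given (params, scenario, seed, replication)."""
    if warmup_years < 0 or measure_years <= 0:
        raise ValueError("invalid parameter: warmup/measure years")
    scenario = scenario or ScenarioSpec()
    params = scenario.apply(params)
    streams = rng_streams(seed, replication)
    horizon_h = (warmup_years + measure_years) * HOURS_PER_YEAR
    window = (warmup_years * HOURS_PER_YEAR, horizon_h)

    es = scenario.early_surgery
    threshold = es.threshold_hours if es.enabled else None
    ais_shift = es.ais_shift if es.enabled else 0.0

    # ---- phase 1: sample every patient's non-interacting path -------------
    arrivals = sample_arrival_times(warmup_years + measure_years,
                                    params.arrival, streams["arrivals"])
    paths: list[_PatientPath] = []
    for i, t in enumerate(arrivals):
        p = create_patient(i, float(t), params.demographics, params.attribute_chain,
                           streams["attributes"])
        route = route_and_transport(p, params.prehospital, streams["prehospital"])
        adm = float(t) + route.admission_delay
        ep = acute_pathway(p, params.acute, params.complications.table, streams["acute"],
                           adm, complication_multipliers=scenario.complication_multipliers,
                           early_surgery_threshold_h=threshold)
        # destination decision + home-side ALC draws (counts kept constant)
        rng_r = streams["rehab"]
        p_rehab = float(params.rehab.go_to_rehab_spec.predict(p.covariates())[1])
        u_rehab = rng_r.random()
        u_home_alc = rng_r.random()
        home_alc = float(params.acute.home_alc_days.sample(rng_r))
        u_dest = rng_r.random()
        rehab_bound = (not ep.died) and (u_rehab < p_rehab)
        plan = plan_rehab_episode(p, params.rehab, rng_r,
                                  params.complications.predisposition_multipliers) \
            if rehab_bound else _consume_rehab_draws(params, p, rng_r)
        path = _PatientPath(patient=p, admission_h=adm, acute=ep,
                            rehab_bound=rehab_bound,
                            rehab_plan=plan if rehab_bound else None)
        if ep.died:
            path.acute_exit_h = adm + ep.death_time_h
            path.ready_h = float("nan")
        else:
            path.ready_h = adm + ep.clinical_days * HOURS_PER_DAY
            p.log(path.ready_h, "clinically_ready",
                  "rehab" if rehab_bound else "home/other")
            if not rehab_bound:
                ep.discharge_destination = "home" if u_dest < 0.8 else "other"
                if u_home_alc < params.acute.p_home_alc:
                    ep.alc_days = home_alc
                path.acute_exit_h = path.ready_h + ep.alc_days * HOURS_PER_DAY
                if path.acute_exit_h <= horizon_h:
                    p.log(path.acute_exit_h, "acute_discharge", ep.discharge_destination)
        paths.append(path)

    # ---- phase 2: event calendar for the rehabilitation bed pool ----------
    beds = _BedPool(params.rehab.bed_capacity, window)
    heap: list[tuple[float, int, int, str, tuple]] = []
    seq = 0

    def push(time_h: float, priority: int, kind: str, data: tuple) -> None:
        nonlocal seq
        heapq.heappush(heap, (time_h, priority, seq, kind, data))
        seq += 1

    wait_list: list[tuple[int, str, float]] = []  # (pid, phase, request time)
    bed_intervals: list[tuple[float, float, int]] = []
    active_grants: dict[int, float] = {}  # pid -> grant time of the open stay

    for pid, path in enumerate(paths):
        if path.rehab_bound and path.ready_h <= horizon_h:
            push(path.ready_h, _P_REQUEST, "request", (pid, "initial"))

    def grant(t: float, pid: int, phase: str, requested_at: float) -> None:
        path = paths[pid]
        plan = path.rehab_plan
        assert plan is not None
        p = path.patient
        beds.seize(t)
        hold = params.rehab.bed_hold_days
        if phase == "initial":
            plan.wait_for_bed_days = (t - requested_at) / HOURS_PER_DAY
            path.acute.alc_days = plan.wait_for_bed_days
            path.acute.discharge_destination = "rehab"
            path.acute_exit_h = t
            p.went_to_rehab = True
            p.log(t, "rehab_admission", f"waited {plan.wait_for_bed_days:.1f} d")
            los_h = plan.rehab_days * HOURS_PER_DAY
            if plan.interruptions:
                intr = plan.interruptions[0]
                t_dep = t + intr.at_fraction * los_h
                if handle_acute_readmission(intr, hold):
                    # bed held through the interruption; stay extended by it
                    end = t + los_h + intr.duration_days * HOURS_PER_DAY \
                        + plan.discharge_alc_days * HOURS_PER_DAY
                    p.log(t_dep, "acute_readmission", f"{intr.duration_days:.1f} d, bed held")
                    push(end, _P_RELEASE, "release", (pid, "final"))
                else:
                    p.log(t_dep, "acute_readmission",
                          f"{intr.duration_days:.1f} d, bed released")
                    push(t_dep + hold * HOURS_PER_DAY, _P_RELEASE, "release", (pid, "hold"))
                    resume_at = t_dep + intr.duration_days * HOURS_PER_DAY
                    remaining = (1.0 - intr.at_fraction) * plan.rehab_days
                    push(resume_at, _P_REQUEST, "request", (pid, f"resume:{remaining}"))
            else:
                end = t + los_h + plan.discharge_alc_days * HOURS_PER_DAY
                push(end, _P_RELEASE, "release", (pid, "final"))
        else:  # resume after a bed-releasing interruption
            remaining = float(phase.split(":", 1)[1])
            path.interruption_wait_days += (t - requested_at) / HOURS_PER_DAY
            p.log(t, "rehab_resumed", f"waited {path.interruption_wait_days:.1f} d")
            end = t + remaining * HOURS_PER_DAY + plan.discharge_alc_days * HOURS_PER_DAY
            push(end, _P_RELEASE, "release", (pid, "final"))
        active_grants[pid] = t

    while heap:
        t, _prio, _s, kind, data = heapq.heappop(heap)
        if t > horizon_h:
            break
        pid, phase = data
        path = paths[pid]
        if kind == "request":
            if beds.busy < beds.capacity:
                grant(t, pid, phase, t)
            else:
                wait_list.append((pid, phase, t))
            beds.trace.append((t, beds.busy, len(wait_list)))
        else:  # release
            t0 = active_grants.pop(pid, t)
            beds.release(t)
            bed_intervals.append((t0, t, pid))
            if phase == "final":
                path.rehab_discharge_h = t
                path.patient.log(t, "rehab_discharge",
                                 f"FIM {path.rehab_plan.fim_discharge:.0f}")
            if wait_list:
                npid, nphase, nreq = wait_list.pop(0)  # FIFO grant order
                grant(t, npid, nphase, nreq)
            beds.trace.append((t, beds.busy, len(wait_list)))

    beds.close(horizon_h)
    # stays still open at the horizon contribute their clipped bed-days
    for pid, t0 in active_grants.items():
        bed_intervals.append((t0, horizon_h, pid))
    # patients still waiting at the horizon: their ALC wait is censored there
    for pid, phase, req in wait_list:
        if phase == "initial":
            paths[pid].acute.alc_days = (horizon_h - req) / HOURS_PER_DAY

    # ---- phase 3: outcomes for patients fully discharged ------------------
    for path in paths:
        p = path.patient
        if p.died:
            continue
        if path.rehab_bound:
            if not np.isfinite(path.rehab_discharge_h) or path.rehab_discharge_h > horizon_h:
                continue
            rehab_days = path.rehab_plan.rehab_days
        else:
            if path.acute_exit_h > horizon_h:
                continue
            rehab_days = 0.0
        shift = ais_shift if (es.enabled and p.cervical and p.had_surgery) else 0.0
        acute_days = path.acute.clinical_days + path.acute.alc_days
        attach_outcomes(p, params.outcomes, streams["outcomes"], acute_days,
                        rehab_days, ais_shift=shift)
        if path.rehab_plan is not None:
            p.fim_discharge = path.rehab_plan.fim_discharge

    metrics = summarize_metrics(paths, bed_intervals, beds.area,
                                params.rehab.bed_capacity, window)
    return ReplicationResult(paths=paths, bed_intervals=bed_intervals,
                             occupancy_area_bed_hours=beds.area, window=window,
                             capacity=params.rehab.bed_capacity, metrics=metrics,
                             occupancy_trace=beds.trace)


def _consume_rehab_draws(params: ParameterSet, p: PatientRecord,
                         rng: np.random.Generator) -> None:
    """Burn the same number of draws a rehab plan would use, keeping the
    rehab stream aligned across scenario arms (common random numbers)."""
    for _comp in params.rehab.complication_base:
        rng.random()
    params.rehab.rehab_los.sample(p.covariates(), rng)
    rng.random()
    rng.uniform(0.05, 0.95)
    params.rehab.interruption_days.sample(rng)
    rng.random()
    params.rehab.discharge_alc_days.sample(rng)
    if params.rehab.discharge_fim_spec.residual_sd:
        rng.normal(0.0, 1.0)
    return None


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else 0.0


def summarize_metrics(
    paths: list[_PatientPath],
    bed_intervals: list[tuple[float, float, int]],
    occupancy_area_bed_hours: float,
    capacity: int,
    window: tuple[float, float],
) -> dict[str, float]:
    """Compute the per-replication metric set over the measurement window.

    LOS and outcome means are over patients whose completing event falls
    inside the window; occupancy is the time average of busy beds over the
    window; the ALC-designated fraction is the share of patients reaching
    clinical readiness in the window who then waited at least part of a
    day in an acute bed.
    """
    w0, w1 = window
    years = (w1 - w0) / HOURS_PER_YEAR
    m: dict[str, float] = {}

    arrived = [p for p in paths if w0 <= p.patient.injury_time < w1]
    m["annual_patients"] = len(arrived) / years

    acute_exits = [p for p in paths
                   if not p.patient.died and w0 <= p.acute_exit_h < w1]
    m["acute_los_clinical"] = _mean([p.acute.clinical_days for p in acute_exits])
    m["acute_los_total"] = _mean([p.acute.clinical_days + p.acute.alc_days
                                  for p in acute_exits])
    m["acute_scu_days"] = _mean([p.acute.scu_days for p in acute_exits])
    m["acute_ward_days"] = _mean([p.acute.ward_days for p in acute_exits])
    ready = [p for p in paths if not p.patient.died
             and np.isfinite(p.ready_h) and w0 <= p.ready_h < w1]
    m["alc_fraction_pct"] = 100.0 * _mean(
        [1.0 if p.acute.alc_days > _EPS_DAYS else 0.0 for p in ready])
    m["mean_alc_days"] = _mean([p.acute.alc_days for p in ready])
    m["rehab_bound_fraction"] = _mean([1.0 if p.rehab_bound else 0.0 for p in ready])
    m["alc_rehab_pct"] = 100.0 * _mean(
        [1.0 if (p.rehab_bound and p.acute.alc_days > _EPS_DAYS) else 0.0 for p in ready])
    m["alc_home_pct"] = 100.0 * _mean(
        [1.0 if (not p.rehab_bound and p.acute.alc_days > _EPS_DAYS) else 0.0
         for p in ready])
    m["mean_rehab_wait_days"] = _mean(
        [p.acute.alc_days for p in ready if p.rehab_bound])

    rehab_done = [p for p in paths
                  if np.isfinite(p.rehab_discharge_h) and w0 <= p.rehab_discharge_h < w1]
    m["rehab_los"] = _mean([p.rehab_plan.rehab_days for p in rehab_done])
    m["rehab_discharge_alc_days"] = _mean(
        [p.rehab_plan.discharge_alc_days for p in rehab_done])
    m["mean_fim_discharge"] = _mean([p.rehab_plan.fim_discharge for p in rehab_done])
    admitted_rehab = [p for p in paths if p.rehab_bound
                      and np.isfinite(p.acute_exit_h) and w0 <= p.acute_exit_h < w1]
    m["rehab_admissions_per_year"] = len(admitted_rehab) / years
    m["rehab_occupancy_pct"] = 100.0 * occupancy_area_bed_hours / ((w1 - w0) * capacity)

    # acute census (uncapacitated): time-average via an event sweep
    events: list[tuple[float, int]] = []
    for p in paths:
        exit_h = p.acute_exit_h
        events.append((p.admission_h, 1))
        events.append((exit_h, -1))
    events.sort()
    census, area, t_last = 0, 0.0, 0.0
    for t, d in events:
        lo, hi = max(t_last, w0), min(t, w1)
        if hi > lo:
            area += census * (hi - lo)
        census += d
        t_last = t
    lo, hi = max(t_last, w0), w1
    if hi > lo:
        area += census * (hi - lo)
    m["acute_beds_used"] = area / (w1 - w0)

    admitted = [p for p in paths if w0 <= p.admission_h < w1]
    for comp in COMPLICATIONS:
        m[f"acute_{comp}_incidence"] = _mean(
            [1.0 if comp in p.acute.complications else 0.0 for p in admitted])
    for comp in REHAB_COMPLICATIONS:
        m[f"rehab_{comp}_incidence"] = _mean(
            [1.0 if comp in p.rehab_plan.complications else 0.0 for p in rehab_done])

    finished = [p for p in paths if p.patient.outcome_block]
    finished = [p for p in finished
                if w0 <= (p.rehab_discharge_h if p.rehab_bound else p.acute_exit_h) < w1]
    for grade in AIS_GRADES:
        m[f"discharge_ais_{grade}_pct"] = 100.0 * _mean(
            [1.0 if p.patient.ais_discharge == grade else 0.0 for p in finished])
    for key in ("le_years", "life_years_lost", "in_hospital", "long_term",
                "avoidable_community", "qaly_i", "qaly_ii", "qaly_iii",
                "qaly_iv", "qaly_v"):
        m[f"mean_{key}"] = _mean([p.patient.outcome_block[key] for p in finished])
    m["n_discharged"] = float(len(finished))
    m["n_clinically_ready"] = float(len(ready))
    return m
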