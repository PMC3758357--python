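# Methods

`actsim` is a discrete-event simulation (DES) of the care continuum for
traumatic spinal cord injury (tSCI) in a single-centre system: one
quaternary acute spine program and one rehabilitation centre, joined by
the rehabilitation bed pool that is the system's binding constraint.
Simulated patients are created by a chain of regressions, travel through
pre-hospital transport, acute care (surgery, complications, length of
stay), an alternative-level-of-care (ALC) wait when downstream capacity
is lacking, in-patient rehabilitation with service interruptions and a
bed-hold rule, and finally receive long-term outcomes (discharge
neurology, life expectancy, costs, five QALY variants).  Its purpose is
what-if experimentation: change a policy or clinical parameter and
measure the direct and indirect effects across the whole system.

## Model structure

**Arrivals.** A non-homogeneous Poisson process sampled by thinning.
The rate is `base_annual_rate x dow_factor(t) x month_factor(t)`; both
factor vectors are normalized to mean 1 on load, so the base rate is
also the long-run annual mean (default 100 patients/year).  The calendar
is a 365-day year anchored at a configurable weekday.

**Patient creation.** Age is drawn from a two-component normal mixture
(weights 0.55/0.45, means 24/58, SDs 6/13, clipped to 15–89 years),
reflecting the bimodal injury-age pattern of a young high-energy peak
and an older low-energy (fall) peak.  Gender is Bernoulli (80% male);
distance to the spine centre, the rural/urban proxy, is log-normal in
road-minutes (mean 45, CV 1.2).  The remaining attributes come from a
configurable chain of fixed-coefficient regressions, each consuming
earlier outputs: mechanism | (age, gender, distance); energy |
(mechanism, age); neurological level band; ISS; GCS; admission AIS.
Coefficients live in the parameter pack, never in code; the shipped
values are synthetic but produce a clinically plausible casemix
(~30% grade A, ~50% cervical, ISS ~18).

**Regression families.** Linear (with Gaussian residual), binary logit,
multinomial logit, and cumulative-logit ordinal.  The ordinal convention
is `P(Y <= j) = expit(alpha_j + x.beta)` with discharge grades ordered
E < D < C < B < A.  Under this convention the published discharge-AIS
coefficients are clinically coherent: the large negative admission-A
coefficient pushes mass toward discharge A, and the positive
rehabilitation coefficient pushes mass toward E.  The discharge model's
neurological level enters as Low versus a joint High/Medium reference,
because only a "Low" coefficient is reported; admission grade E
bypasses the model entirely (discharge E with certainty).

**Pre-hospital.** Patients within 40 road-minutes go directly to the
spine centre; farther patients are stabilized at a first hospital unless
a suspected-paralysis direct transfer fires (default probability 0.5 for
severe grades A/B — an assumption, the share is not published).
Transport mode is a distance/severity rule (road, rotary wing beyond 90
minutes for severe cases, fixed wing beyond 240); an "Autolaunch" air
protocol multiplies the transfer delay by 0.6 with probability 0.4 for
severe remote cases.  Admission delay is log-normal per route.

**Acute care.** Surgery probability, operative mortality, post-op SCU
stay and ward stay come from pack regressions; lengths of stay are
log-normal around a covariate-dependent mean (CV 0.65 for the ward —
the right-skew convention for hospital stays).  The five acute
complications (pressure ulcer, neuropathic pain, pneumonia, urinary
tract infection, delirium) are independent Bernoulli draws at the
patient's profile-specific probabilities from the calibrated table.
Each complication multiplies the ward stay (pressure ulcer 1.6,
pneumonia 1.25, delirium 1.2, UTI 1.15, pain 1.1); the pressure-ulcer
factor is the lever that makes a 70% pressure-ulcer reduction shorten
the mean acute stay by a few days, consistent with the published
cascade.  Acute beds are uncapacitated by default: the system's
congestion lives downstream.

**ALC and the bed queue.** When a rehab-bound patient becomes
clinically ready and no rehabilitation bed is free, the patient waits in
an acute bed (ALC state) in a FIFO queue.  Non-rehab discharges can
also be ALC-designated while waiting for housing or placement; this
non-queueing component is a model necessity, not an embellishment: at
76% occupancy of 24 beds, Erlang-type queueing delays designate only
~9–10% of patients, while the published baseline is 12.7% with 6.8%
remaining after two beds are added — evidence that roughly half the
baseline designations are not rehab-bed waits.  The housing component's
probability is a calibration dial; its duration is log-normal (mean 9
days).

**Rehabilitation.** One bed pool (24 beds).  Rehab complications use
base rates multiplied by a predisposition factor when the same
complication occurred in acute care (pressure ulcer 1.9, UTI 1.5 —
the recurrence channel).  Length of stay is log-normal (CV 0.6) around
a severity-dependent mean.  With probability 0.18 a stay is interrupted
by an acute readmission of log-normal duration (mean 3.5 days, CV 0.9):
the bed is held up to 3 days; longer interruptions release the bed and
the patient rejoins the wait list when acute treatment completes.  Held
days count as occupied — the bed is unavailable either way.  A
discharge ALC wait for housing (probability 0.25, mean 12 days) is
spent in the bed before physical discharge.  Reported rehabilitation
LOS is the clinical stay excluding the discharge wait; occupancy
includes it.

**Outcomes.** Discharge AIS from the published ordinal model; life
expectancy by (age band, neuro band, discharge AIS) from a synthetic
life table anchored to published values (uninjured at 40: 39.9 years;
injured at 40: 33.9 down to 8.0 across severity), linear in a combined
severity score between those anchors; entries are clipped to the
exact-age uninjured value so life-years-lost is never negative.  Costs:
in-hospital = per-admission + per-day x days (acute 3,000/day, rehab
1,100/day, admission 20,000 CAD); long-term = one-time + yearly by
severity stratum (cervical/non-cervical x AIS A–C/D–E) over remaining
life; avoidable community cost = expected annual UTI and pressure-ulcer
episodes x episode cost x remaining years.  QALYs use a utility
regression (intercept 0.68, cervical −0.05, decrements UTI 0.05, pain
0.11, depression 0.09, annual probabilities 0.35/0.45/0.35) under five
futures: (i) never complications, (ii) all three every year,
(iii) average complications, (iv) average pain and depression with no
UTIs, (v) as (iv) but certain UTIs for patients with a pre-discharge
UTI.  No discounting by default (a configurable rate exists); the
original work never states one.

## The complication calibration

No registry provides the 640-profile x 5-complication probability
table, so it is estimated as a constrained least-squares projection:
minimize the prevalence-weighted squared deviation from a reference
(literature-prior) table subject to linear constraints encoding
published evidence — overall incidences per complication (0.25, 0.35,
0.20, 0.30, 0.12), a male:female pressure-ulcer ratio of 2 (on
probabilities, not odds), stratum bounds, and the box [0, 1].  The
original work never writes the objective; weighted squared deviation
from a prior is the most direct reading of a least-squares projection
onto literature constraints, and it makes the update rule transparent:
new evidence becomes a new row and the solve is rerun.

Constraints never couple complications, so the quadratic program is
block-separable: five 640-variable QPs with diagonal Hessians.  Each
block is solved by a primal active-set method (feasible start from a
zero-objective LP; equality-KKT subproblem over the working set;
longest feasible step; blocking constraints enter, wrong-signed
multipliers leave) to a KKT residual below 1e-6.  Infeasible constraint
sets fail loudly (inconsistent-equality rank test, LP phase-1
certificate); a slack-relaxation mode is deliberately absent — silent
constraint violation would defeat the purpose of the table.  Tests
check the solver against a closed-form two-cell case, a projected
grid-search minimizer, and an independent convex solver.  Each
complication is constrained independently; whether the original
estimation coupled complications is not stated, and block-separability
is the assumption made here.

## Replication protocol and metrics

An experiment is 50 replications, each five warm-up years (discarded)
plus five measured years; metrics are reported as cross-replication
means with 95% t-intervals (49 df).  Patient metrics attribute a
patient to the window by the event completing the metric (discharge for
LOS, clinical readiness for ALC designation), avoiding edge censoring;
occupancy metrics are pure time averages over the window.  Replication
r of an experiment draws from named RNG streams keyed on
`(base_seed, r, module)`, one stream per sampling module, so adding a
sampling site in one module never perturbs another, and two scenarios
run with the same base seed are paired (common random numbers) —
the default for scenario comparison, with an unpaired Welch comparison
available.  Draw counts per patient are kept scenario-invariant
(unused draws are burned) so streams stay aligned across arms.

A replication simulates ~1,000 patients (10 years x ~100/year) and runs
in well under a second; a full 50-replication experiment takes ~20 s on
one CPU, and the calibrated pack build ~2 minutes.  These sizes are the
package defaults, chosen to match the published protocol exactly.

## Baseline calibration

`make_default_pack` moment-matches five dials to the published baseline:
arrival rate → 100 arrivals/year; ward-LOS scale → 48.7 days total
acute stay; rehab-LOS scale → 99.5 days; the go-to-rehab intercept →
76.1% occupancy of 24 beds (the offered-load dial); the housing-ALC
probability → 12.7% ALC-designated.  Each iteration (four, plus a final
housing-ALC trim) runs the full 50-replication protocol and applies
multiplicative updates clipped to a factor of 2; matching under the
same protocol that later evaluates the pack makes the calibrated
moments estimates of the steady-state targets rather than of one run's
noise.  Infeasible targets (zero arrivals, offered load beyond
capacity at the requested occupancy) raise an error rather than
silently failing to converge.  With the bed capacity raised to 26, the
post-intervention occupancy and ALC share follow from queueing
structure alone — offered load ~18.3 beds / 26 ≈ 70%, and the queue
wait nearly vanishes — which is why the two-extra-beds experiment is
reproducible without any published-scenario inputs.

## What the synthetic pack does and does not show

The synthetic pack emulates the *system*: arrival intensity, casemix
composition, stay distributions, the capacity interaction and the
published baseline metrics.  It does not reproduce the original
regression coefficients (fitted to a non-public registry and printed
only for the discharge-AIS model, which is used verbatim), so
patient-level conditional relationships — e.g. exactly how mechanism
varies with age — are plausible inventions.  Passing tests therefore
demonstrate correct mechanics and faithful system-level reproduction,
not registry-level validity.  Scenario experiments whose published
values depend on those non-public fits (the pressure-ulcer and
early-surgery scenarios) are checked for direction and order of
magnitude only.

## Numerical choices and edge cases

- Time unit: hours internally; durations reported in days (24 h/day).
- Thinning envelope: `max(dow) x max(month)` after normalization.
- Event calendar: binary heap keyed (time, priority, insertion order);
  bed releases process before requests at equal times.
- Ties and degenerates: zero arrival rate yields an idle, error-free
  run with zeroed metrics; empty measurement windows report zeros with
  count 0; patients still waiting at the horizon have their ALC wait
  censored at the horizon; stays open at the horizon contribute their
  clipped bed-days to occupancy.
- Distributions are parameterized by mean and CV; log-normal parameters
  derive as `sigma^2 = ln(1 + CV^2)`, `mu = ln(mean) - sigma^2/2`.
- The QP working-set tolerance is 1e-11 on the step, 1e-6 on the final
  KKT residual; pack validation rejects probabilities outside [0, 1],
  non-positive capacities and malformed factor vectors with the dotted
  path of the offending field.

## Known limitations

- The two-extra-beds experiment reproduces the published occupancy and
  ALC share, but its published 3.4-day drop in total acute stay implies
  more baseline queueing delay than an M/G/c-like system at 76%
  occupancy generates; this model yields a ~1.5-day drop.  The likely
  origin is congestion mechanisms the publication does not specify
  (e.g. batched discharges or the rehab-LOS feedback below).
- Adding rehabilitation beds does not shorten the rehabilitation stay
  here; the published two-day reduction implies a wait-dependent
  rehab-LOS coupling (e.g. deconditioning during long acute waits)
  that is not described and therefore not modelled.
- "First hospital" is one abstract stabilization stage, not five
  distinct trauma centres; there is no GIS model — location is a road
  time.
- Repeat surgical cycles are supported but off by default; the ED is a
  fixed-delay stage; out-patient rehabilitation is a discharge
  attribute, not a capacitated stage.
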