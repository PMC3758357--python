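"""Discharge AIS sampling, life expectancy, costs and QALY variants."""

import numpy as np
import pytest

from actsim.outcomes import (
    compute_costs,
    life_expectancy_and_lyl,
    qaly_scenarios,
    sample_discharge_ais,
)
from actsim.parameters import AIS_ORDER, CostSchedule, UtilityModel
from actsim.patients import PatientRecord


def _patient(**kw):
    p = PatientRecord(id=0, injury_time=0.0, age=40.0, gender="male",
                      mechanism="transport", neuro_band="C1-C4",
                      ais_admission="A")
    for k, v in kw.items():
        setattr(p, k, v)
    return p


class TestDischargeAis:
    def test_admission_e_is_identity(self, table1_spec, rng):
        p = _patient(ais_admission="E")
        assert sample_discharge_ais(p, table1_spec, rng) == "E"

    def test_sampling_frequencies_match_analytic_probabilities(self, table1_spec):
        """Admission A, high level, rehabilitation: P(A) ~ 0.595 governs draws."""
        rng = np.random.default_rng(12)
        p = _patient(went_to_rehab=True)
        n = 10_000
        hits = sum(sample_discharge_ais(p, table1_spec, rng) == "A"
                   for _ in range(n))
        assert hits / n == pytest.approx(0.595, abs=3 * np.sqrt(0.595 * 0.405 / n))

    def test_rehabilitation_improves_discharge_distribution(self, table1_spec):
        """The positive rehabilitation coefficient shifts mass toward E."""
        rng = np.random.default_rng(13)
        n = 6_000
        order = {g: i for i, g in enumerate(AIS_ORDER)}  # E best .. A worst
        mean_rank = {}
        for rehab in (True, False):
            p = _patient(ais_admission="C", neuro_band="thoracic",
                         went_to_rehab=rehab)
            ranks = [order[sample_discharge_ais(p, table1_spec, rng)]
                     for _ in range(n)]
            mean_rank[rehab] = np.mean(ranks)
        assert mean_rank[True] < mean_rank[False]

    def test_positive_shift_moves_mass_toward_recovery(self, table1_spec):
        rng = np.random.default_rng(14)
        p = _patient(ais_admission="B", went_to_rehab=True)
        n = 6_000
        good = {s: sum(sample_discharge_ais(p, table1_spec, rng, linear_shift=s)
                       in ("D", "E") for _ in range(n)) / n for s in (0.0, 1.5)}
        assert good[1.5] > good[0.0]


class TestLifeExpectancy:
    def test_published_anchor_values(self, uncal_pack):
        """Uninjured at 40: 39.9 years; injured at 40 spans 33.9 to 8.0."""
        lt = uncal_pack.outcomes.life_table
        assert lt.uninjured_le(40) == pytest.approx(39.9)
        best, _ = life_expectancy_and_lyl(40, "lumbosacral", "D", lt)
        worst, _ = life_expectancy_and_lyl(40, "C1-C4", "A", lt)
        assert best == pytest.approx(33.9, abs=0.05)
        assert worst == pytest.approx(8.0, abs=0.05)

    def test_lyl_non_negative_everywhere(self, uncal_pack):
        lt = uncal_pack.outcomes.life_table
        rng = np.random.default_rng(9)
        for _ in range(500):
            age = rng.uniform(15, 89)
            nb = rng.choice(["C1-C4", "C5-C8", "thoracic", "lumbosacral"])
            g = rng.choice(list("ABCDE"))
            le, lyl = life_expectancy_and_lyl(age, nb, g, lt)
            assert lyl >= 0.0
            assert le <= lt.uninjured_le(age) + 1e-9

    def test_age_out_of_range_rejected(self, uncal_pack):
        with pytest.raises(Exception, match="age out of range"):
            life_expectancy_and_lyl(150, "C1-C4", "A",
                                    uncal_pack.outcomes.life_table)


def _schedule(**kw):
    base = dict(per_admission=20_000.0, per_day_acute=3_000.0,
                per_day_rehab=0.0,
                one_time_by_severity={"cervical:ABC": 0.0, "cervical:DE": 0.0,
                                      "non-cervical:ABC": 0.0, "non-cervical:DE": 0.0},
                yearly_by_severity={"cervical:ABC": 0.0, "cervical:DE": 0.0,
                                    "non-cervical:ABC": 0.0, "non-cervical:DE": 0.0},
                community_episode_costs={"uti": 0.0, "pressure_ulcer": 0.0})
    base.update(kw)
    return CostSchedule(**base)


class TestCosts:
    def test_in_hospital_arithmetic(self):
        """44 acute days at 3,000/day plus a 20,000 admission = 152,000."""
        p = _patient(ais_discharge="C")
        costs = compute_costs(p, _schedule(), 0.0, acute_days=44.0,
                              rehab_days=0.0, community_rates={})
        assert costs["in_hospital"] == pytest.approx(152_000.0)

    def test_zero_stay_zero_le_leaves_only_admission_fee(self):
        p = _patient(ais_discharge="D")
        costs = compute_costs(p, _schedule(), 0.0, 0.0, 0.0, community_rates={})
        assert costs["in_hospital"] == pytest.approx(20_000.0)
        assert costs["long_term"] == 0.0
        assert costs["avoidable_community"] == 0.0

    def test_zero_complication_rates_mean_zero_avoidable_cost(self):
        p = _patient(ais_discharge="A")
        sched = _schedule(community_episode_costs={"uti": 5000.0,
                                                   "pressure_ulcer": 9000.0})
        costs = compute_costs(p, sched, 30.0, 10.0, 10.0,
                              community_rates={"uti": 0.0, "pressure_ulcer": 0.0})
        assert costs["avoidable_community"] == 0.0


def _utility(**kw):
    base = dict(intercept=0.7, cervical_coefficient=-0.05,
                complication_decrements={"uti": 0.05, "neuropathic_pain": 0.11,
                                         "depression": 0.09},
                community_rates={"uti": 0.3, "neuropathic_pain": 0.4,
                                 "depression": 0.35})
    base.update(kw)
    return UtilityModel(**base)


class TestQaly:
    def test_zero_decrements_collapse_all_variants(self):
        u = _utility(complication_decrements={"uti": 0.0, "neuropathic_pain": 0.0,
                                              "depression": 0.0})
        p = _patient(neuro_band="thoracic")
        q = qaly_scenarios(p, u, 20.0)
        assert all(v == pytest.approx(0.7 * 20.0) for v in q.values())

    def test_variant_ordering(self):
        """No-complication years dominate averaged years dominate
        every-year complications; variant (v) never beats (iv)."""
        p = _patient(complications_acute={"uti"})
        q = qaly_scenarios(p, _utility(), 25.0)
        assert q["qaly_i"] >= q["qaly_iii"] >= q["qaly_ii"]
        assert q["qaly_i"] >= q["qaly_iv"] >= q["qaly_v"]
        assert all(0.0 <= v <= 25.0 for v in q.values())

    def test_variant_v_equals_iv_without_prior_uti(self):
        p = _patient(complications_acute=set(), complications_rehab=set())
        q = qaly_scenarios(p, _utility(), 25.0)
        assert q["qaly_v"] == pytest.approx(q["qaly_iv"])

    def test_prior_uti_penalizes_variant_v(self):
        p = _patient(complications_rehab={"uti"})
        q = qaly_scenarios(p, _utility(), 25.0)
        assert q["qaly_v"] < q["qaly_iv"]
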