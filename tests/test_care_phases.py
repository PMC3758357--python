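"""Pre-hospital routing, acute pathway and rehabilitation episode logic."""

import copy

import numpy as np
import pytest

from actsim.acute import acute_pathway, assign_acute_complications
from actsim.parameters import COMPLICATIONS, ComplicationTable, all_profiles
from actsim.patients import PatientRecord, create_patient, profile_of
from actsim.prehospital import route_and_transport
from actsim.rehab import Interruption, handle_acute_readmission, plan_rehab_episode


def _patient(uncal_pack, rng, **overrides):
    p = create_patient(0, 0.0, uncal_pack.demographics,
                       uncal_pack.attribute_chain, rng)
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


def _flat_table(prob):
    return ComplicationTable({(p, c): prob for p in all_profiles()
                              for c in COMPLICATIONS})


class TestPrehospital:
    def test_boundary_distances(self, uncal_pack, rng):
        ph = copy.deepcopy(uncal_pack.prehospital)
        ph.p_paralysis_direct = 0.0
        for dist, route in ((0.0, "direct"), (39.0, "direct"),
                            (41.0, "via_first_hospital")):
            p = _patient(uncal_pack, rng, distance_to_centre=dist)
            assert route_and_transport(p, ph, rng).route == route

    def test_direct_fraction_matches_total_probability(self, uncal_pack):
        """Fraction routed direct = P(d <= 40) + P(d > 40) x P(paralysis
        shortcut | severe) x P(severe), within Monte-Carlo error."""
        rng = np.random.default_rng(17)
        ph = uncal_pack.prehospital
        n = 10_000
        direct = 0
        expected = 0.0
        for _ in range(n):
            p = _patient(uncal_pack, rng)
            severe = p.ais_admission in ("A", "B")
            close = p.distance_to_centre <= ph.direct_threshold_minutes
            expected += 1.0 if close else (ph.p_paralysis_direct if severe else 0.0)
            if route_and_transport(p, ph, rng).route == "direct":
                direct += 1
        expected /= n
        se = np.sqrt(expected * (1 - expected) / n)
        assert direct / n == pytest.approx(expected, abs=3 * se)

    def test_longer_distance_never_shortens_expected_delay(self, uncal_pack):
        rng = np.random.default_rng(3)
        delays = {}
        for dist in (10.0, 200.0):
            d = []
            for _ in range(2000):
                p = _patient(uncal_pack, rng, distance_to_centre=dist)
                d.append(route_and_transport(p, uncal_pack.prehospital, rng)
                         .admission_delay)
            delays[dist] = np.mean(d)
        assert delays[200.0] >= delays[10.0]


class TestAcuteComplications:
    def test_all_zero_table_gives_empty_subset(self, rng):
        prof = next(iter(all_profiles()))
        assert assign_acute_complications(prof, _flat_table(0.0), rng) == set()

    def test_certain_complication_always_present(self, rng):
        prof = next(iter(all_profiles()))
        table = _flat_table(0.0)
        for p in all_profiles():
            table.entries[(p, "pressure_ulcer")] = 1.0
        for _ in range(50):
            assert "pressure_ulcer" in assign_acute_complications(prof, table, rng)

    def test_binomial_incidence_within_three_se(self, rng):
        prof = next(iter(all_profiles()))
        table = _flat_table(0.25)
        n = 10_000
        hits = sum("uti" in assign_acute_complications(prof, table, rng)
                   for _ in range(n))
        assert hits / n == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / n))

    def test_scenario_multiplier_scales_probability(self, rng):
        prof = next(iter(all_profiles()))
        table = _flat_table(0.5)
        n = 8_000
        hits = sum("pneumonia" in assign_acute_complications(
            prof, table, rng, {"pneumonia": 0.3}) for _ in range(n))
        assert hits / n == pytest.approx(0.15, abs=3 * np.sqrt(0.15 * 0.85 / n))


class TestAcutePathway:
    def test_certain_mortality_kills_every_surgical_patient(self, uncal_pack):
        params = copy.deepcopy(uncal_pack.acute)
        params.mortality_spec.intercepts["intercept"] = 50.0
        params.surgery_spec.intercepts["intercept"] = 50.0
        rng = np.random.default_rng(1)
        for i in range(100):
            p = _patient(uncal_pack, rng)
            ep = acute_pathway(p, params, uncal_pack.complications.table, rng, 0.0)
            assert ep.died and ep.discharge_destination == "death"

    def test_mean_los_matches_distribution_with_complications_off(self, uncal_pack):
        """With the complication table zeroed and multipliers at 1, the mean
        clinical stay equals the SCU + ward distribution mean."""
        params = copy.deepcopy(uncal_pack.acute)
        params.complication_los_multipliers = {c: 1.0 for c in COMPLICATIONS}
        table = _flat_table(0.0)
        rng = np.random.default_rng(2)
        n = 5_000
        los, expected = [], []
        for i in range(n):
            p = _patient(uncal_pack, rng)
            cov = p.covariates()
            p_surg = params.surgery_spec.predict(cov)[1]
            expected.append(p_surg * params.scu_los.mean_for(cov)
                            + params.ward_los.mean_for(cov))
            ep = acute_pathway(p, params, table, rng, 0.0)
            los.append(ep.clinical_days)
        se = np.std(los, ddof=1) / np.sqrt(n)
        assert np.mean(los) == pytest.approx(np.mean(expected), abs=3 * se)


class TestRehabEpisode:
    def test_predisposition_multiplier_doubles_incidence(self, uncal_pack):
        """Base 0.2 with multiplier 2 yields incidence 0.4 among patients
        with the same complication in acute care."""
        params = copy.deepcopy(uncal_pack.rehab)
        params.complication_base = {"pressure_ulcer": 0.2}
        rng = np.random.default_rng(4)
        n = 10_000
        hits = 0
        for i in range(n):
            p = _patient(uncal_pack, rng)
            p.complications_acute = {"pressure_ulcer"}
            ep = plan_rehab_episode(p, params, rng, {"pressure_ulcer": 2.0})
            hits += "pressure_ulcer" in ep.complications
        assert hits / n == pytest.approx(0.4, abs=3 * np.sqrt(0.4 * 0.6 / n))

    def test_neutral_multiplier_keeps_incidence_at_base(self, uncal_pack):
        params = copy.deepcopy(uncal_pack.rehab)
        params.complication_base = {"uti": 0.2}
        rng = np.random.default_rng(6)
        n = 10_000
        by_history = {True: [0, 0], False: [0, 0]}
        for i in range(n):
            p = _patient(uncal_pack, rng)
            had = i % 2 == 0
            p.complications_acute = {"uti"} if had else set()
            ep = plan_rehab_episode(p, params, rng, {"uti": 1.0})
            by_history[had][0] += "uti" in ep.complications
            by_history[had][1] += 1
        for had, (h, tot) in by_history.items():
            assert h / tot == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / tot))

    def test_fim_within_instrument_range(self, uncal_pack):
        rng = np.random.default_rng(8)
        for i in range(500):
            p = _patient(uncal_pack, rng)
            ep = plan_rehab_episode(p, uncal_pack.rehab, rng)
            assert 18.0 <= ep.fim_discharge <= 126.0

    @pytest.mark.parametrize("duration,hold,same_bed", [
        (2.0, 3.0, True),   # short interruption: bed held
        (4.0, 3.0, False),  # beyond the hold window: bed released
        (3.0, 3.0, True),   # boundary: exactly the hold
        (0.5, 0.0, False),  # zero hold releases every interruption
    ])
    def test_bed_hold_rule(self, duration, hold, same_bed):
        intr = Interruption(at_fraction=0.5, duration_days=duration)
        assert handle_acute_readmission(intr, hold) is same_bed
        assert intr.returned_to_same_bed is same_bed
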