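"""Regression-spec evaluation and parameter-pack validation/serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actsim.parameters import (
    AIS_ORDER,
    PackError,
    RegressionSpec,
    SpecError,
    all_profiles,
    load_parameter_pack,
    predict_regression,
    write_parameter_pack,
)


class TestOrdinalLogit:
    def test_discharge_probabilities_match_hand_evaluation(self, table1_spec):
        """Cumulative-logit evaluation of the published coefficients.

        For admission grade A, high neurological level and rehabilitation,
        the top-category cumulative logit is 5.769 - 7.311 + 1.157 = -0.385,
        so P(discharge = A) = 1 - expit(-0.385) ~= 0.595; for admission D,
        low level, no rehabilitation, P(E) = expit(-3.036 - 0.454) ~= 0.0296.
        """
        p = predict_regression(table1_spec, {
            "ais_admission": "A", "neuro_level_grouped": "HighMedium",
            "rehabilitation": "Yes"})
        assert p[AIS_ORDER.index("A")] == pytest.approx(0.595, abs=5e-4)
        p2 = predict_regression(table1_spec, {
            "ais_admission": "D", "neuro_level_grouped": "Low",
            "rehabilitation": "No"})
        assert p2[AIS_ORDER.index("E")] == pytest.approx(0.0296, abs=5e-4)

    @given(eta_a=st.floats(-6, 6), eta_b=st.floats(-6, 6), low=st.booleans(),
           rehab=st.booleans())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_probabilities_normalized_and_monotone(self, table1_spec, eta_a,
                                                   eta_b, low, rehab):
        """Any covariate setting yields a proper distribution, and raising
        the linear predictor shifts cumulative mass toward the low end."""
        cov = {"ais_admission": "B", "rehabilitation": "Yes" if rehab else "No",
               "neuro_level_grouped": "Low" if low else "HighMedium"}
        p = np.asarray(predict_regression(table1_spec, cov))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((p >= 0) & (p <= 1))
        # finite-difference monotonicity on a synthetic two-covariate spec
        spec = RegressionSpec(
            family="ordinal-logit", outcome_categories=("lo", "mid", "hi"),
            intercepts={"lo": -1.0, "mid": 1.0},
            terms={("", "x", None): 1.0}, reference_levels={})
        lo_eta = min(eta_a, eta_b)
        hi_eta = max(eta_a, eta_b)
        cum_lo = np.cumsum(spec.predict({"x": lo_eta}))
        cum_hi = np.cumsum(spec.predict({"x": hi_eta}))
        assert np.all(cum_hi >= cum_lo - 1e-9)

    def test_admission_a_stochastically_worse_than_c(self, table1_spec):
        """Worse admission grade puts more cumulative mass on the bad end."""
        base = {"neuro_level_grouped": "HighMedium", "rehabilitation": "Yes"}
        p_a = np.cumsum(predict_regression(table1_spec, {**base, "ais_admission": "A"}))
        p_c = np.cumsum(predict_regression(table1_spec, {**base, "ais_admission": "C"}))
        # categories ordered E..A: admission A has less mass at/below each grade
        assert np.all(p_a[:-1] <= p_c[:-1] + 1e-12)

    def test_missing_covariate_and_unknown_level_errors(self, table1_spec):
        with pytest.raises(SpecError, match="covariate required"):
            predict_regression(table1_spec, {"ais_admission": "A",
                                             "rehabilitation": "Yes"})
        with pytest.raises(SpecError, match="level mismatch"):
            predict_regression(table1_spec, {
                "ais_admission": "Z", "neuro_level_grouped": "Low",
                "rehabilitation": "Yes"})

    def test_ordinal_intercept_count_enforced(self):
        spec = RegressionSpec(family="ordinal-logit",
                              outcome_categories=("a", "b", "c"),
                              intercepts={"a": 0.0})
        with pytest.raises(SpecError, match="intercepts"):
            spec.validate()


class TestFamilies:
    def test_binary_and_multinomial_probabilities(self):
        binary = RegressionSpec(family="binary-logit",
                                outcome_categories=("no", "yes"),
                                intercepts={"intercept": 0.3},
                                terms={("", "x", None): 0.5})
        p = binary.predict({"x": 1.0})
        assert p[1] == pytest.approx(1.0 / (1.0 + math.exp(-0.8)))
        assert p.sum() == pytest.approx(1.0)
        multi = RegressionSpec(family="multinomial-logit",
                               outcome_categories=("a", "b", "c"),
                               intercepts={"b": 0.2, "c": -0.4},
                               terms={("b", "x", None): 1.0})
        q = multi.predict({"x": 0.5})
        e = np.array([1.0, math.exp(0.7), math.exp(-0.4)])
        assert np.allclose(q, e / e.sum())

    def test_linear_returns_predictor(self):
        spec = RegressionSpec(family="linear", intercepts={"intercept": 2.0},
                              terms={("", "x", None): 3.0}, residual_sd=1.0)
        assert spec.predict({"x": 2.0}) == pytest.approx(8.0)


class TestProfiles:
    def test_grid_has_exactly_640_cells(self):
        cells = list(all_profiles())
        assert len(cells) == 640
        assert len(set(cells)) == 640


class TestPackIO:
    def test_default_pack_has_24_beds_and_validates(self, uncal_pack):
        assert uncal_pack.rehab.bed_capacity == 24
        assert uncal_pack.rehab.bed_hold_days == 3.0
        assert uncal_pack.prehospital.direct_threshold_minutes == 40.0
        uncal_pack.validate()

    def test_round_trip_is_lossless(self, uncal_pack, tmp_path):
        d = write_parameter_pack(uncal_pack, tmp_path / "pack")
        loaded = load_parameter_pack(d)
        assert loaded == uncal_pack

    def test_wrong_dow_factor_length_rejected(self, uncal_pack, tmp_path):
        import yaml
        d = write_parameter_pack(uncal_pack, tmp_path / "pack")
        man = yaml.safe_load((d / "manifest.yaml").read_text())
        man["arrival"]["dow_factors"] = man["arrival"]["dow_factors"][:6]
        (d / "manifest.yaml").write_text(yaml.safe_dump(man, sort_keys=False))
        with pytest.raises(PackError, match=r"invalid parameter: arrival\.dow_factors"):
            load_parameter_pack(d)

    def test_missing_file_reported_by_name(self, uncal_pack, tmp_path):
        d = write_parameter_pack(uncal_pack, tmp_path / "pack")
        (d / "complications_table.csv").unlink()
        with pytest.raises(PackError, match="pack incomplete.*complications_table"):
            load_parameter_pack(d)

    def test_dotted_path_access(self, uncal_pack):
        assert uncal_pack.get_path("rehab.bed_capacity") == 24
        with pytest.raises(KeyError, match="unknown parameter"):
            uncal_pack.get_path("rehab.nonexistent")
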