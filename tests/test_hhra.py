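"""Exposure dose and risk computation."""

import numpy as np
import pandas as pd
import pytest

import soilrisk as sr
from soilrisk.hhra import cr_category

from reference_values import PRINTED_RISK_TABLE


class TestScenarios:
    def test_builtin_parameter_conventions(self):
        # AT_nc = ED*365 and AT_ca = LT*365 for both built-in receptors
        for s in (sr.ADULT, sr.CHILD):
            assert s.AT_nc == s.ED * 365
            assert s.AT_ca == 70 * 365 == 25550

    def test_invalid_parameter_rejected(self):
        with pytest.raises(ValueError, match="BW"):
            sr.ExposureScenario("x", IngR=100, EF=350, ED=24, BW=0,
                                AT_nc=8760, SA=4350, AF=0.07)


class TestAverageDailyDose:
    def test_ingestion_adult_nc_hand_value(self):
        # 0.87*100*350*24/(65*8760)*1e-6
        assert sr.add_ingestion(0.87, sr.ADULT, "nc") == pytest.approx(
            1.2835e-6, rel=1e-4)

    def test_ingestion_child_ca_hand_value(self):
        # 0.87*200*350*6/(15.9*25550)*1e-6
        assert sr.add_ingestion(0.87, sr.CHILD, "ca") == pytest.approx(
            8.995e-7, rel=1e-3)

    def test_dermal_hand_values(self):
        # c*SA*AF*ABS*EF*ED/(BW*AT)*1e-6
        assert sr.add_dermal(0.87, sr.ADULT, 0.001, "nc") == pytest.approx(
            3.908e-9, rel=1e-3)
        assert sr.add_dermal(69.0, sr.CHILD, 0.001, "nc") == pytest.approx(
            1.3316e-6, rel=1e-3)

    def test_zero_concentration_gives_zero(self):
        assert sr.add_ingestion(0.0, sr.ADULT, "ca") == 0.0
        assert sr.add_dermal(0.0, sr.CHILD, 0.5, "nc") == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sr.add_ingestion(-1.0, sr.ADULT)


class TestHazardAndCancerRisk:
    def test_baganuur_adult_cd_hq(self):
        hq_ing, hq_derm, hi = sr.hazard_index(0.87, "Cd", sr.ADULT)
        assert hq_ing == pytest.approx(1.28e-3, rel=0.01)
        assert hq_derm == pytest.approx(3.90e-4, rel=0.01)
        assert hi == pytest.approx(1.67e-3, rel=0.01)

    def test_sharyn_gol_child_pb_hi(self):
        *_, hi = sr.hazard_index(69.0, "Pb", sr.CHILD)
        assert hi == pytest.approx(2.40e-1, rel=0.01)

    def test_hi_is_sum_of_pathway_quotients(self):
        hq_ing, hq_derm, hi = sr.hazard_index(42.0, "Zn", sr.CHILD)
        assert hi == hq_ing + hq_derm

    def test_zero_concentration(self):
        assert sr.hazard_index(0.0, "Cu", sr.ADULT) == (0.0, 0.0, 0.0)

    def test_cr_baganuur_child_cd(self):
        cr = sr.carcinogenic_risk(0.87, "Cd", sr.CHILD)
        assert cr == pytest.approx(1.35e-5, rel=0.01)
        assert cr_category(cr) == "acceptable"

    def test_cr_sharyn_gol_adult_pb(self):
        cr = sr.carcinogenic_risk(69.0, "Pb", sr.ADULT)
        assert cr == pytest.approx(2.97e-7, rel=0.01)
        assert cr_category(cr) == "virtually_safe"

    def test_non_carcinogen_errors_not_zero(self):
        for metal in ("Cu", "Zn"):
            with pytest.raises(ValueError, match="not a carcinogen"):
                sr.carcinogenic_risk(10.0, metal, sr.ADULT)

    @pytest.mark.parametrize("cr, cat", [
        (1e-7, "virtually_safe"), (1e-6, "virtually_safe"),
        (5e-5, "acceptable"), (1e-4, "unacceptable"), (1e-3, "unacceptable"),
    ])
    def test_cr_category_bands(self, cr, cat):
        assert cr_category(cr) == cat


class TestLinearityProperties:
    def test_linearity_in_concentration(self):
        """ADD, HQ, HI and CR scale exactly with c_soil."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = rng.uniform(0.01, 500)
            k = rng.uniform(0.1, 1000)
            for scen in (sr.ADULT, sr.CHILD):
                assert sr.add_ingestion(k * c, scen) == pytest.approx(
                    k * sr.add_ingestion(c, scen), rel=1e-12)
                base = sr.hazard_index(c, "Pb", scen)
                scaled = sr.hazard_index(k * c, "Pb", scen)
                for b, s in zip(base, scaled):
                    assert s == pytest.approx(k * b, rel=1e-12)
                assert sr.carcinogenic_risk(k * c, "Cd", scen) == \
                    pytest.approx(k * sr.carcinogenic_risk(c, "Cd", scen),
                                  rel=1e-12)

    def test_mean_of_risks_equals_risk_of_mean(self):
        rng = np.random.default_rng(17)
        concs = rng.lognormal(1.0, 0.8, size=200)
        his = np.array([sr.hazard_index(c, "Cd", sr.CHILD)[2] for c in concs])
        risk_of_mean = sr.hazard_index(float(concs.mean()), "Cd", sr.CHILD)[2]
        assert his.mean() == pytest.approx(risk_of_mean, rel=1e-12)

    def test_child_ingestion_exceeds_adult(self):
        """The built-in child scenario ingests more soil per kg body weight:
        HQ_ing ratio child/adult is (200/15.9/2190)/(100/65/8760) ~ 8.18."""
        hq_child = sr.hazard_index(10.0, "Cd", sr.CHILD)[0]
        hq_adult = sr.hazard_index(10.0, "Cd", sr.ADULT)[0]
        assert hq_child > hq_adult
        assert hq_child / hq_adult == pytest.approx(8.176, rel=1e-3)

    def test_unit_scaling(self):
        out1 = sr.hazard_index(0.5, "Zn", sr.ADULT)
        out2 = sr.hazard_index(500.0, "Zn", sr.ADULT)
        for a, b in zip(out1, out2):
            assert b == pytest.approx(1e3 * a, rel=1e-12)


class TestRiskTable:
    def test_full_grid_matches_printed_values(self, town_means):
        """Every published HQ_ing/HQ_derm/HI/CR cell is reproduced within
        1% relative from the rounded town means."""
        table = sr.risk_table(town_means)
        assert len(table) == 24
        for _, row in table.iterrows():
            expected = PRINTED_RISK_TABLE[
                (row["town"], row["receptor"], row["metal"])]
            for value, ref in zip(
                    (row["HQ_ing"], row["HQ_derm"], row["HI"], row["CR"]),
                    expected):
                if ref is None:
                    assert np.isnan(value) or value is None
                else:
                    assert value == pytest.approx(ref, rel=0.01)

    def test_no_risk_flags_raised(self, town_means):
        table = sr.risk_table(town_means)
        assert not table["HI_above_1"].any()
        assert set(table.loc[table["CR"].notna(), "CR_category"]) <= {
            "virtually_safe", "acceptable"}

    def test_per_sample_input_equals_means_input(self, fixture_survey,
                                                 town_means):
        """By linearity the table from 142 samples equals the table from
        the three town means."""
        t_samples = sr.risk_table(fixture_survey).set_index(
            ["town", "receptor", "metal"]).sort_index()
        t_means = sr.risk_table(town_means).set_index(
            ["town", "receptor", "metal"]).sort_index()
        for col in ("HQ_ing", "HQ_derm", "HI"):
            assert np.allclose(t_samples[col], t_means[col], rtol=1e-9)

    def test_identical_samples_match_single_sample(self):
        one = pd.DataFrame([{"town": "T", "Cd": 1.0, "Cu": 10.0,
                             "Pb": 20.0, "Zn": 30.0}])
        many = pd.concat([one] * 7, ignore_index=True)
        pd.testing.assert_frame_equal(sr.risk_table(one), sr.risk_table(many))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sr.risk_table(pd.DataFrame())
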