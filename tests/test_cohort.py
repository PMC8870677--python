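"""Virtual-cohort dose construction: calibration, combination, dose tables."""

import dataclasses

import numpy as np
import pytest

from alphalq import (
    MechanisticRN,
    ParameterDomainError,
    build_dose_table,
    calibrate_rn_model,
    dose_table_frame,
    eqd2_tot,
    injected_activity_per_cycle,
)
from alphalq.cohort import CohortConfigurationError

# Published per-arm EQD2 columns (Gy, 1 decimal) for the three EBRT
# scenarios; arm order: A/50, A/0, B/25, B/50, B/80, C/50, C/0, D/55.
EQD2_RN_COLUMN = [103.2, 0.0, 34.2, 77.4, 140.7, 154.8, 0.0, 174.0]
PUBLISHED = {
    "8 Gy in 1 fr": {
        "weighted": [12.0, 12.0, 3.5, 5.3, 4.3, 1.9, 1.9, 3.5],
        "total": [115.2, 12.0, 37.7, 82.7, 145.0, 156.7, 1.9, 177.5],
    },
    "20 Gy in 5 fr": {
        "weighted": [23.3, 23.3, 6.8, 10.3, 8.4, 3.7, 3.7, 6.8],
        "total": [126.5, 23.3, 41.0, 87.7, 149.1, 158.5, 3.7, 180.8],
    },
    "30 Gy in 10 fr": {
        "weighted": [32.5, 32.5, 9.4, 14.3, 11.7, 5.2, 5.2, 9.4],
        "total": [135.7, 32.5, 43.6, 91.7, 152.4, 160.0, 5.2, 183.4],
    },
}


class TestInjectedActivity:
    @pytest.mark.parametrize(
        "per_kg, weight, expected", [(25, 70, 1.75), (80, 70, 5.6), (0, 120, 0.0)]
    )
    def test_conversion(self, per_kg, weight, expected):
        assert injected_activity_per_cycle(per_kg, weight) == pytest.approx(expected)

    def test_printed_value_takes_precedence(self):
        # 55 kBq/kg at the 70 kg reference would give 3.85 MBq, but the
        # published per-cycle activity implies a 75 kg reference
        assert injected_activity_per_cycle(55, 70, printed_mbq=4.125) == 4.125


class TestCalibration:
    def test_two_point_solve_matches_linear_algebra_oracle(self):
        cal = calibrate_rn_model([(25.0, 3, 34.2), (50.0, 3, 77.4)])
        # independent closed-form 2x2 solve on the per-cycle system
        oracle = np.linalg.solve(
            np.array([[25.0, 625.0], [50.0, 2500.0]]), np.array([34.2 / 3, 77.4 / 3])
        )
        assert cal.c1 == pytest.approx(oracle[0], rel=1e-10)
        assert cal.c2 == pytest.approx(oracle[1], rel=1e-10)
        # source arms reproduced exactly
        assert cal.eqd2_rn(25.0, 3) == pytest.approx(34.2, abs=1e-9)
        assert cal.eqd2_rn(50.0, 3) == pytest.approx(77.4, abs=1e-9)

    def test_extrapolation_to_highest_activity_arm(self):
        cal = calibrate_rn_model([(25.0, 3, 34.2), (50.0, 3, 77.4)])
        assert cal.per_cycle_eqd2(80.0) == pytest.approx(140.7 / 3, abs=0.5)

    def test_exact_recovery_from_its_own_generator(self):
        c1, c2 = 0.4, 0.002
        arms = [(a, 3, 3 * (c1 * a + c2 * a * a)) for a in (20.0, 45.0, 75.0)]
        cal = calibrate_rn_model(arms)
        assert cal.c1 == pytest.approx(c1, rel=1e-9)
        assert cal.c2 == pytest.approx(c2, rel=1e-9)

    def test_linear_data_yields_zero_quadratic_term(self):
        arms = [(a, 2, 2 * 0.5 * a) for a in (10.0, 30.0, 60.0)]
        cal = calibrate_rn_model(arms)
        assert cal.c2 == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_activities_rejected(self):
        with pytest.raises(CohortConfigurationError):
            calibrate_rn_model([(50.0, 3, 77.4), (50.0, 6, 154.8)])


class TestEQD2Tot:
    @pytest.mark.parametrize(
        "rn, f, ebrt, expected",
        [(34.2, 0.29, 12.0, 37.7), (103.2, 1.00, 32.5, 135.7), (42.0, 0.0, 99.0, 42.0)],
    )
    def test_affine_combination(self, rn, f, ebrt, expected):
        from alphalq import round_half_up

        assert round_half_up(eqd2_tot(rn, f, ebrt)) == pytest.approx(expected)

    def test_fraction_domain(self):
        with pytest.raises(ParameterDomainError):
            eqd2_tot(10.0, 1.2, 5.0)


class TestDoseTables:
    def test_reproduces_all_published_cells(self, arms, scenarios):
        """All 24 EQD2_TOT cells (and weighted-EBRT columns) match print."""
        for scenario in scenarios:
            frame = dose_table_frame(build_dose_table(arms, scenario))
            expect = PUBLISHED[scenario.label]
            assert list(frame["eqd2_rn_gy"]) == pytest.approx(EQD2_RN_COLUMN)
            assert list(frame["eqd2_ebrt_weighted_gy"]) == pytest.approx(expect["weighted"])
            assert list(frame["eqd2_tot_gy"]) == pytest.approx(expect["total"])

    def test_rn_column_invariant_across_scenarios(self, arms, scenarios):
        columns = [
            list(dose_table_frame(build_dose_table(arms, sc))["eqd2_rn_gy"])
            for sc in scenarios
        ]
        assert columns[0] == columns[1] == columns[2]

    def test_additivity_before_rounding(self, arms, scenarios):
        for sc in scenarios:
            for s in build_dose_table(arms, sc):
                assert s.eqd2_tot == pytest.approx(
                    s.eqd2_rn + s.f_ebrt * sc.eqd2_ebrt, rel=1e-14
                )
                assert s.eqd2_ebrt_weighted == pytest.approx(s.f_ebrt * sc.eqd2_ebrt)

    def test_doubling_cycles_doubles_calibrated_rn_dose(self, arms, scenarios):
        cal = calibrate_rn_model([(25.0, 3, 34.2), (50.0, 3, 77.4)])
        arm_b50 = next(a for a in arms if a.study_id == "B" and a.activity_per_kg == 50)
        arm_6c = dataclasses.replace(arm_b50, n_cycles=6)
        (row3,) = build_dose_table([arm_b50], scenarios[0], cal)
        (row6,) = build_dose_table([arm_6c], scenarios[0], cal)
        assert row6.eqd2_rn == pytest.approx(2 * row3.eqd2_rn, rel=1e-12)
        assert row3.eqd2_rn == pytest.approx(77.4, abs=1e-9)
        assert row6.eqd2_rn == pytest.approx(154.8, abs=1e-9)

    def test_total_monotone_in_activity_f_and_scenario(self, arms, scenarios):
        cal = calibrate_rn_model([(25.0, 3, 34.2), (50.0, 3, 77.4)])
        base = next(a for a in arms if a.study_id == "B" and a.activity_per_kg == 50)
        (row,) = build_dose_table([base], scenarios[0], cal)
        (more_activity,) = build_dose_table(
            [dataclasses.replace(base, activity_per_kg=60.0)], scenarios[0], cal
        )
        (more_f,) = build_dose_table(
            [dataclasses.replace(base, f_ebrt=0.9, f_ebrt_count=None)], scenarios[0], cal
        )
        (bigger_ebrt,) = build_dose_table([base], scenarios[2], cal)
        assert more_activity.eqd2_tot > row.eqd2_tot
        assert more_f.eqd2_tot > row.eqd2_tot
        assert bigger_ebrt.eqd2_tot > row.eqd2_tot

    def test_placebo_arms_have_zero_rn_dose(self, arms, scenarios):
        for s in build_dose_table(arms, scenarios[0]):
            if s.activity_per_kg == 0:
                assert s.eqd2_rn == 0.0
                assert s.eqd2_tot == pytest.approx(s.f_ebrt * scenarios[0].eqd2_ebrt)

    def test_mechanistic_pathway_used_per_arm(self, arms, scenarios, params):
        mech = MechanisticRN({"Ra-223": 5000.0}, 0.0025)
        rows = build_dose_table(arms, scenarios[0], mech, params)
        treated = [r for r in rows if r.activity_per_kg > 0]
        assert all(r.eqd2_rn > 0 for r in treated)
        # scales with activity x cycles: study C (3.5 MBq x 6) vs A (3.5 x 4)
        c = next(r for r in rows if r.study_id == "C" and r.activity_per_kg == 50)
        a = next(r for r in rows if r.study_id == "A")
        assert c.eqd2_rn == pytest.approx(a.eqd2_rn * 6 / 4, rel=1e-9)

    def test_missing_reference_dose_is_configuration_error(self, arms, scenarios):
        stripped = [dataclasses.replace(a, eqd2_rn_reference=None) for a in arms]
        with pytest.raises(CohortConfigurationError, match="reference"):
            build_dose_table(stripped, scenarios[0], "reference")

    def test_empty_arm_table_rejected(self, scenarios):
        with pytest.raises(CohortConfigurationError):
            build_dose_table([], scenarios[0])


def test_fixture_arm_table_shape(arms):
    assert len(arms) == 8
    d = next(a for a in arms if a.study_id == "D")
    assert d.tox_events is None and d.n_cycles == 6
    assert {a.study_id for a in arms} == {"A", "B", "C", "D"}
    # count-derived EBRT fraction is retained alongside the printed percentage
    c = next(a for a in arms if a.study_id == "C" and a.activity_per_kg == 50)
    assert c.f_ebrt == pytest.approx(0.16)
    assert c.f_ebrt_from_count == pytest.approx(98 / 614)
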