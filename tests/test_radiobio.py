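"""Closed-form LQ radiobiology: BED/EQD2, RBE_max, mixture BED."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from alphalq import (
    EBRTSchedule,
    LQParameters,
    ParameterDomainError,
    RNDoseModel,
    bed_ebrt,
    bed_rn,
    bed_rn_double_loop,
    decay_constant_from_half_life,
    dose_rate,
    effective_half_life,
    eqd2_from_bed,
    eqd2_rn,
    rbe_max,
    residence_time,
    round_half_up,
)

PARAMS = LQParameters()

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


class TestEBRT:
    @pytest.mark.parametrize(
        "total, nf, expected_bed, expected_eqd2",
        [
            (8.0, 1, 14.4, 12.0),
            (20.0, 5, 28.0, 23.3),
            (30.0, 10, 39.0, 32.5),
            (0.0, 1, 0.0, 0.0),
        ],
    )
    def test_published_schedules(self, total, nf, expected_bed, expected_eqd2):
        bed = bed_ebrt(EBRTSchedule(total, nf), PARAMS)
        assert round_half_up(bed) == pytest.approx(expected_bed)
        assert round_half_up(eqd2_from_bed(bed, PARAMS)) == pytest.approx(expected_eqd2)

    @given(st.floats(0.0, 200.0), st.integers(1, 40))
    def test_bed_never_below_physical_dose(self, total, nf):
        bed = bed_ebrt(EBRTSchedule(total, nf), PARAMS)
        assert bed >= total
        if total == 0.0:
            assert bed == 0.0
        elif total >= 1e-3:  # below this the quadratic term is sub-ulp
            assert bed > total

    @given(st.floats(0.1, 200.0))
    def test_two_gray_fractions_are_their_own_eqd2(self, d_total):
        """A schedule already delivered in d_ref fractions round-trips."""
        nf = 7
        sched = EBRTSchedule(PARAMS.d_ref * nf, nf)
        eqd2 = eqd2_from_bed(bed_ebrt(sched, PARAMS), PARAMS)
        assert eqd2 == pytest.approx(sched.total_dose, rel=1e-12)

    @given(st.floats(0.0, 500.0), st.floats(0.1, 10.0))
    def test_eqd2_conversion_is_linear(self, bed, scale):
        assert eqd2_from_bed(scale * bed, PARAMS) == pytest.approx(
            scale * eqd2_from_bed(bed, PARAMS), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterDomainError):
            LQParameters(alpha_beta=-1.0)
        with pytest.raises(ParameterDomainError):
            EBRTSchedule(-5.0, 1)
        with pytest.raises(ParameterDomainError):
            EBRTSchedule(8.0, 0)
        with pytest.raises(ParameterDomainError):
            eqd2_from_bed(-1.0, PARAMS)


class TestRBEMax:
    @pytest.mark.parametrize(
        "rbe_exp, d_ref, alpha_beta, expected",
        [
            (5.0, 2.0, 10.0, 5.96),
            (1.0, 2.0, 10.0, 1.0),  # correction term vanishes
            (5.0, 2.0, 1e12, 5.0),  # d/(a/b) -> 0 removes the correction
        ],
    )
    def test_values(self, rbe_exp, d_ref, alpha_beta, expected):
        p = LQParameters(alpha_beta=alpha_beta, rbe_exp=rbe_exp, d_ref=d_ref)
        assert rbe_max(p) == pytest.approx(expected, abs=1e-9)


class TestDoseRate:
    @pytest.mark.parametrize(
        "coeff, act, lam, expected",
        [(1.0, 1.0, 1.0, 1.0), (0.7, 0.0, 0.3, 0.0), (0.5, 3.5, 0.00253, 0.0044275)],
    )
    def test_product(self, coeff, act, lam, expected):
        assert dose_rate(coeff, act, lam) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ParameterDomainError):
            dose_rate(-1.0, 1.0, 1.0)


class TestMixtureBED:
    @given(
        st.lists(st.floats(0.0, 2000.0), min_size=1, max_size=7),
        st.floats(0.1, 10.0),
        st.integers(0, 8),
        st.floats(1e-4, 0.1),
    )
    def test_double_sum_identity(self, coeffs, activity, n_cycles, lam):
        """The nested-loop mixture double sum equals the squared-sum closed form."""
        model = RNDoseModel(
            dose_coefficients={f"N{i}": c for i, c in enumerate(coeffs)},
            decay_constant=lam,
            injected_activity=activity,
            n_cycles=n_cycles,
        )
        closed = bed_rn(model, PARAMS)
        looped = bed_rn_double_loop(model, PARAMS)
        assert looped == pytest.approx(closed, rel=1e-12, abs=1e-15)

    def test_low_decay_rate_limit_is_pure_linear_term(self):
        """As lambda -> 0 the quadratic term vanishes: BED -> n_c RBE_max D_tot."""
        model = RNDoseModel(
            dose_coefficients={"Ra-223": 1000.0},  # 1 Gy per cycle at 1 MBq
            decay_constant=1e-9,
            injected_activity=1.0,
            n_cycles=3,
        )
        expected = 3 * rbe_max(PARAMS) * 1.0
        assert bed_rn(model, PARAMS) == pytest.approx(expected, rel=1e-6)

    @given(st.integers(0, 10), st.floats(0.5, 5.0))
    def test_linear_in_cycles(self, n_cycles, activity):
        def bed_at(nc):
            return bed_rn(
                RNDoseModel({"Ra-223": 700.0}, 0.0025, activity, nc), PARAMS
            )

        assert bed_at(n_cycles) == pytest.approx(n_cycles * bed_at(1), rel=1e-12)

    def test_doubling_cycles_doubles_eqd2(self):
        m3 = RNDoseModel({"Ra-223": 700.0}, 0.0025, 3.5, 3)
        m6 = RNDoseModel({"Ra-223": 700.0}, 0.0025, 3.5, 6)
        assert eqd2_rn(m6, PARAMS) == pytest.approx(2.0 * eqd2_rn(m3, PARAMS), rel=1e-12)

    def test_monotone_in_coefficients_and_activity(self):
        base = bed_rn(RNDoseModel({"Ra-223": 500.0}, 0.0025, 3.5, 3), PARAMS)
        assert bed_rn(RNDoseModel({"Ra-223": 600.0}, 0.0025, 3.5, 3), PARAMS) > base
        assert bed_rn(RNDoseModel({"Ra-223": 500.0}, 0.0025, 4.0, 3), PARAMS) > base

    def test_empty_chain_returns_zero_with_warning(self):
        model = RNDoseModel({}, 0.0025, 3.5, 3)
        with pytest.warns(UserWarning, match="empty"):
            assert bed_rn(model, PARAMS) == 0.0

    def test_photon_emitters_can_bypass_rbe_max(self):
        """With emission metadata, beta/gamma dose gets weight rbe_photon."""
        model = RNDoseModel({"Pb-211": 1000.0}, 1e-9, 1.0, 1)
        weighted = bed_rn(model, PARAMS, emission_by_nuclide={"Pb-211": "beta"})
        unweighted = bed_rn(model, PARAMS)
        assert weighted == pytest.approx(PARAMS.rbe_photon * 1.0, rel=1e-6)
        assert unweighted == pytest.approx(rbe_max(PARAMS) * 1.0, rel=1e-6)

    def test_invalid_decay_constant(self):
        with pytest.raises(ParameterDomainError):
            RNDoseModel({"Ra-223": 1.0}, decay_constant=0.0)


class TestResidenceTime:
    def test_full_uptake_physical_decay(self):
        t_half = 274.32
        lam = decay_constant_from_half_life(t_half)
        assert residence_time(1.0, lam) == pytest.approx(t_half / math.log(2))
        assert effective_half_life(lam) == pytest.approx(t_half)

    @pytest.mark.parametrize(
        "frac, lam, expected", [(0.0, 0.5, 0.0), (0.5, 0.00253, 197.6285)]
    )
    def test_quotient(self, frac, lam, expected):
        assert residence_time(frac, lam) == pytest.approx(expected, rel=1e-4)

    def test_out_of_range_fraction(self):
        with pytest.raises(ParameterDomainError):
            residence_time(1.5, 0.01)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(5.25) == 5.3
    assert round_half_up(5.24999) == 5.2
    assert round_half_up(-5.25) == -5.3
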