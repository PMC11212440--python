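"""Unit and property tests for the three prediction equations."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from natriuria import (
    Anthropometry,
    SpotSample,
    convert_creatinine,
    estimate_intersalt,
    estimate_kawasaki,
    estimate_tanaka,
    na_to_salt,
    NA_MG_PER_MMOL,
)
from natriuria.equations import IneligibleTimingError

from conftest import intersalt_oracle, kawasaki_oracle, random_physiological_inputs, tanaka_oracle


def spot(una=100.0, ucrea=100.0, uk=50.0, timing="AM"):
    return SpotSample(timing=timing, una=una, ucrea_mg_dl=ucrea, uk=uk)


class TestKawasaki:
    def test_zero_sodium_gives_zero(self, male_60):
        assert estimate_kawasaki(spot(una=0.0), male_60).na_mg_per_day == 0.0

    def test_reference_male(self, male_60):
        # body term 15.12*80 + 7.39*170 - 12.63*60 - 79.9 = 1628.2;
        # 23 * 16.3 * sqrt(0.1 * 1628.2)
        est = estimate_kawasaki(spot(), male_60)
        assert est.na_mg_per_day == pytest.approx(23 * 16.3 * math.sqrt(162.82))
        assert est.na_mg_per_day == pytest.approx(4784, abs=1)

    def test_pm_rejected_without_override(self, male_60):
        with pytest.raises(IneligibleTimingError):
            estimate_kawasaki(spot(timing="PM"), male_60)

    def test_pm_override_flags_estimate(self, male_60):
        est = estimate_kawasaki(spot(timing="PM"), male_60, allow_pm=True)
        assert "ineligible_timing" in est.flags

    def test_nonpositive_body_term_rejected(self):
        tiny = Anthropometry(sex="male", age=70, weight=1, height=10)
        with pytest.raises(ValueError):
            estimate_kawasaki(spot(), tiny)


class TestTanaka:
    def test_zero_sodium_gives_zero(self, male_60):
        assert estimate_tanaka(spot(una=0.0), male_60).na_mg_per_day == 0.0

    def test_reference_male(self, male_60):
        # body term -2.04*60 + 14.89*80 + 16.14*170 - 2244.45 = 1568.15
        est = estimate_tanaka(spot(), male_60)
        assert est.na_mg_per_day == pytest.approx(23 * 21.98 * 156.815**0.392)
        assert est.na_mg_per_day == pytest.approx(3667, abs=1)

    def test_creatinine_doubling_scales_by_power(self, male_60):
        base = estimate_tanaka(spot(), male_60).na_mg_per_day
        halved = estimate_tanaka(spot(ucrea=200.0), male_60).na_mg_per_day
        assert halved == pytest.approx(base * 0.5**0.392)
        assert halved == pytest.approx(2795, abs=1)

    def test_applies_to_pm(self, male_60):
        assert estimate_tanaka(spot(timing="PM"), male_60).timing == "PM"


class TestIntersalt:
    def test_intercept_only_male(self):
        # all urine predictors ~0, BMI ~0, age ~0 leaves the 25.46 intercept
        a = Anthropometry(sex="male", age=1e-12, weight=1, height=100, bmi=0.0)
        s = SpotSample(timing="AM", una=0.0, ucrea_mg_dl=1e-12, uk=0.0)
        assert estimate_intersalt(s, a).na_mg_per_day == pytest.approx(23 * 25.46)

    @pytest.mark.parametrize(
        "sex,expected_mmol",
        [("male", 178.02), ("female", 119.4586)],
    )
    def test_reference_subjects(self, sex, expected_mmol):
        a = Anthropometry(sex=sex, age=60, weight=80, height=164, bmi=29.7)
        ucrea_mg_dl = 8.84 * 113.12 / 10.0  # exactly 8.84 mmol/l
        s = SpotSample(timing="AM", una=100.0, ucrea_mg_dl=ucrea_mg_dl, uk=50.0)
        est = estimate_intersalt(s, a)
        assert est.na_mmol_per_day == pytest.approx(expected_mmol, abs=1e-6)
        assert est.na_mg_per_day == pytest.approx(23 * expected_mmol, abs=1e-4)

    def test_negative_estimate_flagged_not_clamped(self):
        a = Anthropometry(sex="male", age=20, weight=50, height=180, bmi=15.0)
        s = SpotSample(timing="AM", una=0.0, ucrea_mg_dl=300.0, uk=150.0)
        est = estimate_intersalt(s, a)
        assert est.na_mg_per_day < 0
        assert "negative_estimate" in est.flags

    def test_missing_potassium_rejected(self, male_60):
        with pytest.raises(ValueError, match="potassium"):
            estimate_intersalt(SpotSample("AM", 100.0, 100.0), male_60)

    def test_supplied_bmi_wins_over_derived(self):
        a = Anthropometry(sex="male", age=60, weight=80, height=170, bmi=35.0)
        b = Anthropometry(sex="male", age=60, weight=80, height=170)
        ea = estimate_intersalt(spot(), a).na_mg_per_day
        eb = estimate_intersalt(spot(), b).na_mg_per_day
        assert ea - eb == pytest.approx(23 * 4.10 * (35.0 - b.bmi_value))


class TestConversions:
    def test_salt_factor(self):
        assert na_to_salt(1.0) == pytest.approx(2.54, abs=0.005)
        assert na_to_salt(0.0) == 0.0
        assert na_to_salt(2.0) == pytest.approx(5.08, abs=0.01)

    def test_negative_sodium_rejected(self):
        with pytest.raises(ValueError):
            na_to_salt(-0.1)

    def test_creatinine_conversion(self):
        assert convert_creatinine(100.0, "mg/dl", "mmol/l") == pytest.approx(8.84, abs=0.005)
        assert convert_creatinine(0.0, "mg/dl", "mmol/l") == 0.0
        x = 137.5
        assert convert_creatinine(
            convert_creatinine(x, "mg/dl", "mmol/l"), "mmol/l", "mg/dl"
        ) == pytest.approx(x, rel=1e-15)
        with pytest.raises(ValueError):
            convert_creatinine(1.0, "mg/dl", "g/l")


physio = dict(
    una=st.floats(0.1, 300),
    ucrea=st.floats(20, 300),
    uk=st.floats(0, 150),
    age=st.floats(20, 75),
    weight=st.floats(45, 120),
    height=st.floats(145, 200),
    sex=st.sampled_from(["male", "female"]),
)


@settings(derandomize=True, max_examples=100)
@given(**physio, delta=st.floats(1, 50))
def test_estimates_strictly_increase_in_sodium(una, ucrea, uk, age, weight, height, sex, delta):
    a = Anthropometry(sex=sex, age=age, weight=weight, height=height)
    lo, hi = spot(una, ucrea, uk), spot(una + delta, ucrea, uk)
    assert estimate_kawasaki(hi, a).na_mg_per_day > estimate_kawasaki(lo, a).na_mg_per_day
    assert estimate_tanaka(hi, a).na_mg_per_day > estimate_tanaka(lo, a).na_mg_per_day
    assert estimate_intersalt(hi, a).na_mg_per_day > estimate_intersalt(lo, a).na_mg_per_day


@settings(derandomize=True, max_examples=100)
@given(**physio, factor=st.floats(1.1, 5))
def test_estimates_strictly_decrease_in_creatinine(una, ucrea, uk, age, weight, height, sex, factor):
    a = Anthropometry(sex=sex, age=age, weight=weight, height=height)
    lo, hi = spot(una, ucrea, uk), spot(una, ucrea * factor, uk)
    assert estimate_kawasaki(hi, a).na_mg_per_day < estimate_kawasaki(lo, a).na_mg_per_day
    assert estimate_tanaka(hi, a).na_mg_per_day < estimate_tanaka(lo, a).na_mg_per_day
    assert estimate_intersalt(hi, a).na_mg_per_day < estimate_intersalt(lo, a).na_mg_per_day


@settings(derandomize=True, max_examples=100)
@given(**physio)
def test_mg_is_exactly_23_times_mmol(una, ucrea, uk, age, weight, height, sex):
    a = Anthropometry(sex=sex, age=age, weight=weight, height=height)
    s = spot(una, ucrea, uk)
    for est in (estimate_kawasaki(s, a), estimate_tanaka(s, a), estimate_intersalt(s, a)):
        assert est.na_mg_per_day == pytest.approx(
            NA_MG_PER_MMOL * est.na_mmol_per_day, rel=1e-14, abs=1e-12
        )


@settings(derandomize=True, max_examples=50)
@given(**physio, c=st.floats(0.1, 10))
def test_ratio_scaling_powers(una, ucrea, uk, age, weight, height, sex, c):
    """Kawasaki scales as c^0.5 and Tanaka as c^0.392 in the Na/crea ratio."""
    a = Anthropometry(sex=sex, age=age, weight=weight, height=height)
    s, sc = spot(una, ucrea, uk), spot(una * c, ucrea, uk)
    k, kc = estimate_kawasaki(s, a), estimate_kawasaki(sc, a)
    t, tc = estimate_tanaka(s, a), estimate_tanaka(sc, a)
    assert kc.na_mg_per_day == pytest.approx(k.na_mg_per_day * c**0.5, rel=1e-10)
    assert tc.na_mg_per_day == pytest.approx(t.na_mg_per_day * c**0.392, rel=1e-10)


def test_matches_arbitrary_precision_oracle_sample(male_60):
    """Spot check against the sympy 50-digit oracle (full sweep in acceptance)."""
    rng = random.Random(7)
    for inp in random_physiological_inputs(rng, 50):
        a = Anthropometry(inp["sex"], inp["age"], inp["weight"], inp["height"])
        s = spot(inp["una"], inp["ucrea_mg_dl"], inp["uk"])
        assert estimate_kawasaki(s, a).na_mg_per_day == pytest.approx(
            kawasaki_oracle(inp["sex"], inp["age"], inp["weight"], inp["height"],
                            inp["una"], inp["ucrea_mg_dl"]), rel=1e-10)
        assert estimate_tanaka(s, a).na_mg_per_day == pytest.approx(
            tanaka_oracle(inp["age"], inp["weight"], inp["height"],
                          inp["una"], inp["ucrea_mg_dl"]), rel=1e-10)
        assert estimate_intersalt(s, a).na_mg_per_day == pytest.approx(
            intersalt_oracle(inp["sex"], inp["age"], a.bmi_value,
                             inp["una"], inp["uk"], inp["ucrea_mg_dl"]), rel=1e-10)
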