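"""Program costs, ICERs, ROI break-even, and their ordering properties."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from medcea import (
    DomainError,
    ProgramCosts,
    annual_program_cost,
    benefit_per_admin,
    breakeven_administrations,
    icer_per_ade,
    icer_per_error,
    roi_at_volume,
)
from medcea.economics import derive_maintenance

TRAINING = (("nurses", 885.5), ("physicians", 522.7))


class TestAnnualCost:
    def test_published_components_sum_to_annual_cost(self):
        costs = ProgramCosts(37205.3, TRAINING)
        assert annual_program_cost(costs) == pytest.approx(38613.5)

    def test_device_scenario_adds_600(self):
        costs = ProgramCosts(37205.3, TRAINING, device_annual=600.0)
        assert annual_program_cost(costs) == pytest.approx(39213.5)

    def test_maintenance_only(self):
        assert annual_program_cost(ProgramCosts(1000.0)) == 1000.0

    def test_development_cost_never_included(self):
        with_dev = ProgramCosts(37205.3, TRAINING, development_cost=186026.0)
        without = ProgramCosts(37205.3, TRAINING)
        assert annual_program_cost(with_dev) == annual_program_cost(without)

    def test_maintenance_is_a_fifth_of_development(self):
        assert derive_maintenance(186026.0) == pytest.approx(37205.2)


class TestIcers:
    @pytest.mark.parametrize(
        "cost,n,err,expected",
        [
            (38613.5, 100, 0.500, 772.27),
            (38613.5, 250, 0.671, 230.18),
            (1000.0, 10, 1.0, 100.0),
        ],
    )
    def test_cost_per_error(self, cost, n, err, expected):
        assert icer_per_error(cost, n, err) == pytest.approx(expected, abs=0.01)

    def test_cost_per_error_undefined_without_prevented_errors(self):
        with pytest.raises(DomainError, match="err_per_admin"):
            icer_per_error(38613.5, 100, 0.0)

    def test_cost_per_ade_divides_by_ade_probability(self):
        assert icer_per_ade(534.0, 0.111) == pytest.approx(4810.8, abs=0.1)
        assert icer_per_ade(230.0, 0.111) == pytest.approx(2072.1, abs=0.1)
        assert icer_per_ade(123.4, 1.0) == pytest.approx(123.4)

    def test_cost_per_ade_rejects_zero_probability(self):
        with pytest.raises(DomainError):
            icer_per_ade(534.0, 0.0)

    @given(
        cpe=st.floats(min_value=0.01, max_value=1e6),
        p=st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_cost_per_ade_never_below_cost_per_error(self, cpe, p):
        assert icer_per_ade(cpe, p) >= cpe


class TestBenefit:
    @pytest.mark.parametrize(
        "unit_cost,expected",
        [(21422.01, 1220.2), (44742.57, 2548.6)],
    )
    def test_avoided_ade_value_at_published_means(self, unit_cost, expected):
        got = benefit_per_admin(39 / 76, 0.111, unit_cost)
        assert got == pytest.approx(expected, abs=0.1)

    def test_no_errors_no_benefit(self):
        assert benefit_per_admin(0.0, 0.111, 21422.0) == 0.0

    def test_time_saved_adds_wage_value(self):
        base = benefit_per_admin(0.5, 0.111, 21422.0)
        with_time = benefit_per_admin(0.5, 0.111, 21422.0, time_saved_s=9.5,
                                      wage_per_second=0.01)
        assert with_time == pytest.approx(base + 0.095)


class TestBreakeven:
    def test_exact_division(self):
        r = breakeven_administrations(1000.0, 100.0)
        assert r.breakeven_real == pytest.approx(10.0)
        assert r.breakeven_int == 10

    def test_fractional_break_even_rounds_up(self):
        r = breakeven_administrations(38613.5, 2548.56)
        assert r.breakeven_real == pytest.approx(15.15, abs=0.01)
        assert r.breakeven_int == 16

    def test_nonpositive_benefit_is_a_signal_not_an_exception(self):
        r = breakeven_administrations(1000.0, 0.0)
        assert r.never_profitable
        assert r.breakeven_real == math.inf
        assert r.breakeven_int is None

    @given(
        cost=st.floats(min_value=1.0, max_value=1e6),
        benefit=st.floats(min_value=0.01, max_value=1e5),
    )
    def test_integer_threshold_property(self, cost, benefit):
        r = breakeven_administrations(cost, benefit)
        n = r.breakeven_int
        assert roi_at_volume(cost, benefit, n) >= 1.0
        if n > 0:
            assert roi_at_volume(cost, benefit, n - 1) < 1.0

    @given(
        cost=st.floats(min_value=1.0, max_value=1e6),
        b1=st.floats(min_value=0.01, max_value=1e5),
        b2=st.floats(min_value=0.01, max_value=1e5),
    )
    def test_break_even_decreasing_in_benefit_increasing_in_cost(self, cost, b1, b2):
        lo, hi = sorted([b1, b2])
        if lo < hi:
            assert (
                breakeven_administrations(cost, hi).breakeven_real
                <= breakeven_administrations(cost, lo).breakeven_real
            )
        assert (
            breakeven_administrations(cost * 2, b1).breakeven_real
            > breakeven_administrations(cost, b1).breakeven_real
        )


class TestRoiAtVolume:
    def test_break_even_volume_gives_roi_of_one(self):
        r = breakeven_administrations(38613.5, 2548.56)
        assert roi_at_volume(38613.5, 2548.56, r.breakeven_real) == pytest.approx(1.0)

    def test_published_2019_volume(self):
        assert roi_at_volume(38613.5, 2548.56, 40) == pytest.approx(2.64, abs=0.01)

    def test_zero_volume_gives_zero(self):
        assert roi_at_volume(1000.0, 50.0, 0) == 0.0
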