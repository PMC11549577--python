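"""ADE cascade arithmetic, costing formulations, and the event-level oracle."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medcea import AdeModel, cascade, expected_cost_per_ade
from medcea.decision_model import (
    ade_per_admin,
    cost_cat_e,
    cost_cat_f,
    split_categories,
)
from medcea.errors import DomainError

TABLE_MODEL = dict(
    p_ade=0.111,
    p_cat_f=0.03,
    clos_days=0.64,
    daily_cost=229.7,
    excess_complication_cost=22080.0,
    excess_fraction=0.9184,
)


class TestCascadeArithmetic:
    @pytest.mark.parametrize(
        "err,p,expected",
        [(0.513, 0.111, 0.056943), (0.0, 0.111, 0.0), (1.0, 0.111, 0.111)],
    )
    def test_ade_per_admin(self, err, p, expected):
        assert ade_per_admin(err, p) == pytest.approx(expected)

    def test_published_rounded_value(self):
        assert round(ade_per_admin(39 / 76, 0.111), 3) == 0.057

    @pytest.mark.parametrize(
        "n,p,expected",
        [(1.0, 0.97, (0.97, 0.03)), (0.0, 0.5, (0.0, 0.0)), (2.0, 0.5, (1.0, 1.0))],
    )
    def test_split_categories(self, n, p, expected):
        e, f = split_categories(n, p)
        assert (e, f) == pytest.approx(expected)

    @given(
        n=st.floats(min_value=-10, max_value=10, allow_nan=False),
        p=st.floats(min_value=0, max_value=1),
    )
    def test_category_split_conserves_the_total(self, n, p):
        e, f = split_categories(n, p)
        assert e + f == pytest.approx(n, abs=1e-12)

    def test_cascade_conservation_from_model(self):
        c = cascade(0.513, AdeModel(**TABLE_MODEL))
        assert c.n_cat_e + c.n_cat_f == pytest.approx(c.n_ade)

    def test_zero_ade_probability_zeroes_the_cascade(self):
        c = cascade(0.513, AdeModel(**{**TABLE_MODEL, "p_ade": 0.0}))
        assert c.n_ade == c.n_cat_e == c.n_cat_f == c.avoided_cost == 0.0


class TestCosting:
    @pytest.mark.parametrize(
        "clos,daily,expected",
        [(0.64, 229.7, 147.008), (0.0, 229.7, 0.0), (1.0, 229.7, 229.7)],
    )
    def test_cat_f_cost(self, clos, daily, expected):
        assert cost_cat_f(clos, daily) == pytest.approx(expected)

    def test_cat_e_excess_only_is_the_excess_amount(self):
        assert cost_cat_e(22080.0, 0.9184, "excess_only") == pytest.approx(22080.0)

    def test_cat_e_stay_plus_excess_adds_the_implied_base_stay(self):
        got = cost_cat_e(22080.0, 0.9184, "stay_plus_excess")
        assert got == pytest.approx(22080.0 / 0.9184 + 22080.0)
        assert got == pytest.approx(46121.8, abs=0.1)

    def test_zero_excess_gives_zero_under_both_formulations(self):
        assert cost_cat_e(0.0, 0.9184, "excess_only") == 0.0
        assert cost_cat_e(0.0, 0.9184, "stay_plus_excess") == 0.0

    def test_stay_plus_excess_requires_positive_fraction(self):
        with pytest.raises(DomainError):
            cost_cat_e(22080.0, 0.0, "stay_plus_excess")

    @pytest.mark.parametrize(
        "formulation,expected",
        [
            ("excess_only", 0.97 * 22080.0 + 0.03 * 0.64 * 229.7),
            ("stay_plus_excess", 0.97 * (22080.0 / 0.9184 + 22080.0) + 0.03 * 0.64 * 229.7),
        ],
    )
    def test_expected_cost_per_ade_at_published_means(self, formulation, expected):
        model = AdeModel(**TABLE_MODEL, cat_e_cost_formulation=formulation)
        assert expected_cost_per_ade(model) == pytest.approx(expected)

    def test_certain_cat_e_returns_the_cat_e_cost_exactly(self):
        model = AdeModel(**{**TABLE_MODEL, "p_cat_f": 0.0})
        assert expected_cost_per_ade(model) == pytest.approx(22080.0)

    @given(scale=st.floats(min_value=1.0, max_value=3.0))
    def test_expected_cost_monotone_in_every_cost_input(self, scale):
        base = AdeModel(**TABLE_MODEL)
        for field in ("daily_cost", "excess_complication_cost", "clos_days", "p_cat_f"):
            kwargs = dict(TABLE_MODEL)
            kwargs[field] = min(kwargs[field] * scale, 1.0 if field == "p_cat_f" else kwargs[field] * scale)
            bumped = AdeModel(**kwargs)
            if field == "p_cat_f":
                # raising Cat F weight shifts mass to the cheaper category
                assert expected_cost_per_ade(bumped) <= expected_cost_per_ade(base) + 1e-9
            else:
                assert expected_cost_per_ade(bumped) >= expected_cost_per_ade(base) - 1e-9


class TestEventLevelOracle:
    def test_closed_form_matches_discrete_event_simulation(self):
        """Brute-force per-administration event draws (error -> ADE -> category,
        with sampled Cat F stay costs) agree with the expected-value cascade
        within three standard errors at one million administrations."""
        rng = np.random.default_rng(20190101)
        n = 1_000_000
        model = AdeModel(**TABLE_MODEL, cat_e_cost_formulation="stay_plus_excess")
        err = 39 / 76

        prevented = rng.random(n) < err
        has_ade = prevented & (rng.random(n) < model.p_ade)
        is_cat_f = rng.random(n) < model.p_cat_f
        ce = cost_cat_e(model.excess_complication_cost, model.excess_fraction,
                        "stay_plus_excess")
        cf = cost_cat_f(model.clos_days, model.daily_cost)
        costs = np.where(has_ade, np.where(is_cat_f, cf, ce), 0.0)

        sim_mean = costs.mean()
        sim_se = costs.std(ddof=1) / np.sqrt(n)
        closed_form = cascade(err, model).avoided_cost
        assert abs(sim_mean - closed_form) < 3 * sim_se
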