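"""Distribution specs, currency handling, config loading and sampling."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcea import (
    ConfigError,
    DistributionSpec,
    DomainError,
    Money,
    load_config,
    sample_parameter,
    save_config,
    to_usd,
)
from medcea.parameters import ParamField, packaged_config_path


class TestPackagedConfig:
    def test_epinephrine_scenario_loads_with_published_values(self, epi_config):
        assert epi_config.trial.control.n_administrations == 76
        assert epi_config.trial.app.n_administrations == 74
        assert epi_config.costs.maintenance_annual.value == pytest.approx(37205.3)
        assert epi_config.ade.p_ade.value == pytest.approx(0.111)
        assert epi_config.exchange_rate.value == pytest.approx(1.03)

    def test_missing_trial_block_is_a_validation_error(self, epi_config, tmp_path):
        raw = epi_config.model_dump(mode="json")
        del raw["trial"]
        import yaml

        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigError, match="trial"):
            load_config(path)

    def test_malformed_text_names_the_parse_failure(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("drug: [unclosed")
        with pytest.raises(ConfigError, match="parse"):
            load_config(path)

    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_round_trip_preserves_the_scenario(self, epi_config, tmp_path, fmt):
        path = tmp_path / f"copy.{fmt}"
        save_config(epi_config, path)
        again = load_config(path)
        assert again.model_dump(mode="json") == epi_config.model_dump(mode="json")


class TestUniformPm20Rule:
    def test_uniform_without_bounds_gets_pm20_support(self):
        pf = ParamField.model_validate(
            {"value": 7.0, "distribution": {"kind": "uniform"}}
        )
        dist = pf.to_parameter("control_overdoses").distribution
        assert dist.low == pytest.approx(5.6)
        assert dist.high == pytest.approx(8.4)

    @given(mean=st.floats(min_value=0.01, max_value=1e6, allow_nan=False))
    def test_pm20_support_is_forty_percent_of_the_mean(self, mean):
        d = DistributionSpec.uniform_pm20(mean)
        assert (d.high - d.low) / d.mean == pytest.approx(0.4, rel=1e-12)

    def test_uniform_support_must_contain_the_mean(self):
        with pytest.raises(ConfigError, match="contain mean"):
            DistributionSpec(kind="uniform", low=1.0, high=2.0).bind(5.0)


class TestCurrency:
    def test_chf_converted_at_the_2019_rate(self):
        assert to_usd(Money(100.0, "CHF"), 1.03) == Money(103.0, "USD")
        assert to_usd(Money(1.0, "CHF"), 1.03).amount == pytest.approx(1.03)

    def test_usd_passes_through_unchanged(self):
        assert to_usd(Money(103.0, "USD"), 1.03) == Money(103.0, "USD")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            to_usd(Money(1.0, "CHF"), 0.0)

    def test_chf_parameter_rescales_its_whole_distribution(self):
        pf = ParamField.model_validate(
            {
                "value": 100.0,
                "currency": "CHF",
                "distribution": {"kind": "uniform", "low": 80.0, "high": 120.0},
            }
        )
        p = pf.to_parameter("cost", rate=1.03)
        assert p.value == pytest.approx(103.0)
        assert p.distribution.low == pytest.approx(82.4)
        assert p.distribution.high == pytest.approx(123.6)


class TestSampling:
    def test_fixed_always_returns_its_mean(self):
        d = DistributionSpec.fixed(1.03)
        rng = np.random.default_rng(0)
        assert all(sample_parameter(d, rng) == 1.03 for _ in range(100))

    def test_uniform_pm20_draws_stay_in_support(self):
        d = DistributionSpec.uniform_pm20(7.0)
        rng = np.random.default_rng(1)
        draws = np.array([d.sample(rng) for _ in range(2000)])
        assert draws.min() >= 5.6 and draws.max() <= 8.4

    def test_truncated_normal_respects_bounds_and_mean(self):
        d = DistributionSpec.normal(0.111, 0.011, lower_bound=0.0, upper_bound=1.0)
        rng = np.random.default_rng(7)
        draws = np.array([d.sample(rng) for _ in range(10_000)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0
        assert abs(draws.mean() - 0.111) < 0.003

    def test_identical_seed_gives_identical_draw_sequence(self, epi_config):
        a = epi_config.sample_values(np.random.default_rng(42))
        b = epi_config.sample_values(np.random.default_rng(42))
        assert a == b

    @given(
        mean=st.floats(min_value=-50, max_value=50),
        sd=st.floats(min_value=0.1, max_value=20),
        half=st.floats(min_value=0.5, max_value=30),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_truncation_never_violated(self, mean, sd, half, seed):
        d = DistributionSpec.normal(
            mean, sd, lower_bound=mean - half, upper_bound=mean + half
        )
        rng = np.random.default_rng(seed)
        x = d.sample(rng)
        assert mean - half <= x <= mean + half

    def test_impossible_truncation_raises_not_hangs(self):
        d = DistributionSpec.normal(0.0, 0.001, lower_bound=100.0, upper_bound=101.0)
        with pytest.raises(DomainError, match="rejection"):
            d.sample(np.random.default_rng(0))


class TestTornadoBounds:
    def test_uniform_uses_support_endpoints(self):
        d = DistributionSpec.uniform_pm20(10.0)
        assert d.tornado_bounds() == (8.0, 12.0)

    def test_normal_prefers_published_ci(self):
        d = DistributionSpec.normal(0.111, 0.011, ci_low=0.091, ci_high=0.135)
        assert d.tornado_bounds() == (0.091, 0.135)

    def test_normal_without_ci_uses_1_96_sd_truncated(self):
        d = DistributionSpec.normal(1.0, 1.0, lower_bound=0.0)
        lo, hi = d.tornado_bounds()
        assert lo == 0.0
        assert hi == pytest.approx(1.0 + 1.96)

    def test_fixed_is_a_zero_width_bar(self):
        lo, hi = DistributionSpec.fixed(3.0).tornado_bounds()
        assert lo == hi == 3.0
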