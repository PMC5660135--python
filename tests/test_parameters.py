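"""Parameter derivation: conversions, distributions, samplers, config loading."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from btc_cea.parameters import (
    ConfigurationError,
    DistributionSpec,
    beta_moment_params,
    beta_sd_from_mean_n,
    load_parameters,
    make_sampler,
    median_to_monthly_probability,
    monthly_discount,
    probability_to_rate,
    rate_to_probability,
    round_yen,
    triangular_bounds,
    triangular_density,
)


class TestRateProbability:
    @pytest.mark.parametrize(
        "r, t, expected",
        [
            (0.0, 1.0, 0.0),
            (math.log(2), 1.0, 0.5),
            (0.0900426, 1.0, 0.0861),  # G-arm monthly mortality hazard
        ],
    )
    def test_rate_to_probability(self, r, t, expected):
        assert rate_to_probability(r, t) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "p, t, expected",
        [(0.0, 1.0, 0.0), (0.5, 1.0, math.log(2)), (0.06, 1.0, 0.0618754)],
    )
    def test_probability_to_rate(self, p, t, expected):
        assert probability_to_rate(p, t) == pytest.approx(expected, abs=5e-7)

    @given(p=st.floats(0.0, 0.999), t=st.floats(0.01, 120.0))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_is_identity(self, p, t):
        assert rate_to_probability(probability_to_rate(p, t), t) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, 1.0), (0.1, -1.0)])
    def test_negative_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            rate_to_probability(*bad)

    def test_probability_one_rejected(self):
        with pytest.raises(ValueError):
            probability_to_rate(1.0)


class TestMedianDerivation:
    """Trial medians must reproduce every monthly transition probability."""

    @pytest.mark.parametrize(
        "median, expected",
        [(5.8, 0.1126), (3.7, 0.1708), (11.2, 0.0600), (7.7, 0.0861), (1.0, 0.5)],
    )
    def test_reproduces_transition_probabilities(self, median, expected):
        assert round(median_to_monthly_probability(median), 4) == pytest.approx(expected)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            median_to_monthly_probability(0.0)


class TestBetaSd:
    def test_binomial_variant_matches_published_sd(self):
        assert round(beta_sd_from_mean_n(0.0861, 42, "binomial"), 4) == 0.0433

    def test_eq3_variant_differs_from_published(self):
        # beta-distribution SD: sqrt(n/(n+1)) smaller than the binomial SD
        assert beta_sd_from_mean_n(0.1708, 42, "eq3") == pytest.approx(0.0574, abs=5e-5)
        assert round(beta_sd_from_mean_n(0.1708, 42, "eq3"), 4) != 0.0581

    def test_variants_related_by_n_over_n_plus_1(self):
        b = beta_sd_from_mean_n(0.3, 50, "binomial")
        e = beta_sd_from_mean_n(0.3, 50, "eq3")
        assert e == pytest.approx(b * math.sqrt(50 / 51), rel=1e-12)

    def test_large_n_limit_vanishes(self):
        assert beta_sd_from_mean_n(0.5, 10**9, "eq3") == pytest.approx(0.0, abs=1e-4)

    def test_mean_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_sd_from_mean_n(1.2, 42)


class TestTriangular:
    @pytest.mark.parametrize(
        "mode, lo, hi",
        [(27_613, 24_852, 30_374), (43_947, 39_552, 48_342), (44_574, 40_117, 49_031), (10, 9, 11)],
    )
    def test_bounds_reproduce_published_rows(self, mode, lo, hi):
        assert triangular_bounds(mode) == (lo, hi)

    def test_nonpositive_mode_rejected(self):
        with pytest.raises(ValueError):
            triangular_bounds(0)

    def test_peak_height_and_support(self):
        a, m, b = 39_552, 43_947, 48_342
        assert triangular_density(m, a, m, b) == pytest.approx(2 / (b - a))
        assert triangular_density(a - 1, a, m, b) == 0.0
        assert triangular_density(b + 1, a, m, b) == 0.0

    def test_density_integrates_to_one_published_row(self):
        a, m, b = 39_552, 43_947, 48_342
        total, _ = integrate.quad(triangular_density, a, b, args=(a, m, b))
        assert total == pytest.approx(1.0, abs=1e-6)

    @given(
        a=st.floats(0.1, 1e6),
        da=st.floats(0.1, 1e6),
        db=st.floats(0.1, 1e6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_density_integrates_to_one(self, a, da, db):
        m, b = a + da, a + da + db
        # split at the mode: the density has a kink there that trips quad on
        # strongly skewed supports
        total, _ = integrate.quad(
            triangular_density, a, b, args=(a, m, b), points=(m,), limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError):
            triangular_density(1.0, 1.0, 1.0, 1.0)


class TestRoundYen:
    @pytest.mark.parametrize("x, expected", [(0.5, 1), (1.4, 1), (-0.5, -1), (2.5, 3)])
    def test_half_away_from_zero(self, x, expected):
        assert round_yen(x) == expected


class TestMonthlyDiscount:
    def test_compound_conversion(self):
        assert monthly_discount(0.0) == 0.0
        assert monthly_discount(0.03) == pytest.approx(0.0024663, abs=5e-8)
        # closed form: 1.0424**(1/12) - 1
        assert monthly_discount(0.0424) == pytest.approx(0.0034665, abs=5e-7)

    def test_three_percent_lies_in_published_dsa_range(self):
        assert 8.0e-4 <= monthly_discount(0.03) <= 0.0043

    def test_below_negative_one_rejected(self):
        with pytest.raises(ValueError):
            monthly_discount(-1.5)


class TestSamplers:
    def test_fixed_returns_constant(self):
        spec = DistributionSpec(param="x", kind="fixed", mean=42.0)
        draws = make_sampler(spec, np.random.default_rng(0))(100)
        assert np.all(draws == 42.0)

    def test_gamma_mean_recovered(self):
        # surveyed monthly inpatient cost
        spec = DistributionSpec(param="costs.inpatient", kind="gamma", mean=212_990, sd=104_633)
        draws = make_sampler(spec, np.random.default_rng(1))(100_000)
        se = 104_633 / math.sqrt(100_000)
        assert abs(draws.mean() - 212_990) < 4 * se
        assert np.all(draws >= 0)

    @pytest.mark.parametrize("beta_by", ["counts", "moments"])
    def test_beta_support_and_mean(self, beta_by):
        spec = DistributionSpec(
            param="gc.p_ae", kind="beta", mean=0.707, sd=0.071, n=206, beta_by=beta_by
        )
        draws = make_sampler(spec, np.random.default_rng(2))(10_000)
        assert np.all((draws > 0) & (draws < 1))
        sd = {"counts": beta_sd_from_mean_n(0.707, 206, "eq3"), "moments": 0.071}[beta_by]
        assert abs(draws.mean() - 0.707) < 4 * sd / math.sqrt(10_000)

    def test_triangular_support_and_mean(self):
        spec = DistributionSpec(
            param="costs.gcsf", kind="triangular", minimum=24_852, mode=27_613, maximum=30_374
        )
        draws = make_sampler(spec, np.random.default_rng(3))(100_000)
        assert np.all((draws >= 24_852) & (draws <= 30_374))
        expected_mean = (24_852 + 27_613 + 30_374) / 3
        assert draws.mean() == pytest.approx(expected_mean, rel=1e-2)

    def test_oversized_sd_rejected_for_beta_moments(self):
        with pytest.raises(ConfigurationError):
            beta_moment_params(0.5, 0.9)


class TestLoadParameters:
    def test_fixture_round_trips_published_values(self, bt22):
        params, specs = bt22
        assert params.gc.p_death == 0.0600
        assert params.g.p_death == 0.0861
        assert params.costs.palliative == 1_501_200
        assert params.analysis.horizon_months == 36
        assert params.analysis.wtp_per_qaly == 6_000_000
        assert len(specs) == 15
        assert {s.kind for s in specs} == {"beta", "gamma", "triangular"}

    def test_palliative_cost_construction(self, params):
        # daily palliative tariff plus meals, over a 30-day month
        assert (49_260 + 780) * 30 == params.costs.palliative

    def test_out_of_range_probability_rejected(self, tmp_path):
        import yaml

        from btc_cea.cli import default_config

        with open(default_config()) as fh:
            raw = yaml.safe_load(fh)
        raw["arms"]["gc"]["p_death"] = 1.2
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError, match="p_death"):
            load_parameters(bad)

    def test_missing_cost_row_rejected_by_name(self, tmp_path):
        import yaml

        from btc_cea.cli import default_config

        with open(default_config()) as fh:
            raw = yaml.safe_load(fh)
        del raw["costs"]["palliative"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError, match="palliative"):
            load_parameters(bad)

    def test_unknown_key_rejected(self, tmp_path):
        import yaml

        from btc_cea.cli import default_config

        with open(default_config()) as fh:
            raw = yaml.safe_load(fh)
        raw["costs"]["heliport"] = 1
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError, match="heliport"):
            load_parameters(bad)

    def test_unmatched_distribution_param_rejected(self, tmp_path):
        import yaml

        from btc_cea.cli import default_config

        with open(default_config()) as fh:
            raw = yaml.safe_load(fh)
        raw["distributions"][0]["param"] = "gc.p_levitation"
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError, match="p_levitation"):
            load_parameters(bad)

    def test_with_value_unknown_id_raises(self, params):
        with pytest.raises(KeyError):
            params.with_value("gc.p_levitation", 0.5)

    def test_with_value_returns_validated_copy(self, params):
        updated = params.with_value("gc.p_death", 0.07)
        assert updated.gc.p_death == 0.07
        assert params.gc.p_death == 0.0600  # original untouched
        with pytest.raises(ConfigurationError):
            params.with_value("gc.p_death", 1.5)
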