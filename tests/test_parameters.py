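import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcprev.parameters import (ParameterSpec, beta_from_mean_range,
                                default_parameters, gamma_from_mean_range,
                                load_trial_two_year, prob_to_rate,
                                rate_to_prob, sample_parameter_set,
                                two_year_to_annual)


class TestRateConversions:
    @pytest.mark.parametrize("p, t, expected", [
        (0.0, 2, 0.0),
        # oracle: -ln(1-p)/t evaluated directly
        (0.33, 2, -math.log(0.67) / 2),   # = 0.2002388...
        (0.41, 2, -math.log(0.59) / 2),   # = 0.2638165...
    ])
    def test_prob_to_rate(self, p, t, expected):
        assert prob_to_rate(p, t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r, t, expected", [
        (0.0, 1, 0.0),
        (-math.log(0.67) / 2, 1, 0.18146),  # annual LRA recurrence, berberine
    ])
    def test_rate_to_prob(self, r, t, expected):
        assert rate_to_prob(r, t) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("bad", [(-0.1, 1), (1.0, 1), (0.5, 0), (0.5, -2)])
    def test_prob_to_rate_domain(self, bad):
        with pytest.raises(ValueError):
            prob_to_rate(*bad)

    def test_rate_to_prob_domain(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1, 1)

    @given(st.floats(0, 0.999), st.floats(0.1, 20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_identity(self, p, t):
        assert rate_to_prob(prob_to_rate(p, t), t) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p2, annual_pct", [
        # the four trial-derived recurrence rows, two-year -> annual percent
        (0.33, 18.15), (0.41, 23.19), (0.03, 1.51), (0.06, 3.05),
    ])
    def test_two_year_recurrence_annualization(self, p2, annual_pct):
        assert round(100 * two_year_to_annual(p2), 2) == annual_pct


class TestDistributionConstruction:
    def test_beta_moments(self):
        # oracle: analytic Beta mean a/(a+b) and variance ab/((a+b)^2 (a+b+1))
        a, b = beta_from_mean_range(0.5, 0.402, 0.598)
        assert a / (a + b) == pytest.approx(0.5, abs=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(0.05, rel=1e-9)

    def test_beta_infeasible_moments(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_range(0.001, 0.0, 1.0)

    def test_gamma_moments(self):
        shape, scale = gamma_from_mean_range(100, 80, 120)
        assert shape == pytest.approx(96.04, rel=1e-9)
        assert scale == pytest.approx((40 / 3.92) ** 2 / 100, rel=1e-9)
        # drug-cost row: sd = (148.80 - 99.20)/3.92
        shape, scale = gamma_from_mean_range(124.0, 99.2, 148.8)
        assert shape * scale == pytest.approx(124.0, rel=1e-12)
        assert math.sqrt(shape) * scale == pytest.approx(49.6 / 3.92, rel=1e-9)

    def test_gamma_domain(self):
        with pytest.raises(ValueError):
            gamma_from_mean_range(-5, 1, 2)

    def test_degenerate_range_falls_back_to_fixed(self):
        spec = ParameterSpec("x", 0.5, 0.5, 0.5, "beta", "probability")
        with pytest.warns(UserWarning, match="degenerate"):
            assert spec.distribution() is None

    def test_beta_sampling_recovers_mean(self):
        a, b = beta_from_mean_range(0.5, 0.402, 0.598)
        draws = np.random.default_rng(5).beta(a, b, 100_000)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se


class TestParameterSet:
    def test_every_distribution_mean_matches_baseline(self, params):
        for name in params.names():
            spec = params.spec(name)
            if spec.is_fixed:
                continue
            dist = spec.distribution()
            if dist is None:
                continue
            kind, (p1, p2) = dist
            mean = p1 / (p1 + p2) if kind == "beta" else p1 * p2
            assert mean == pytest.approx(spec.base, abs=1e-9), name

    def test_invariants_hold_in_default_config(self, params):
        assert params.violations() == []
        assert params.discount_rate == pytest.approx(0.03)

    def test_payer_resolution(self, params):
        assert params.cost("cost_colonoscopy", 64) == pytest.approx(1385.55)
        assert params.cost("cost_colonoscopy", 65) == pytest.approx(786.27)

    def test_with_values_rejects_unknown(self, params):
        with pytest.raises(KeyError):
            params.with_values(not_a_parameter=1.0)

    def test_trial_two_year_inputs(self):
        trial = load_trial_two_year()
        assert trial == {"lra_berberine": 0.33, "hra_berberine": 0.03,
                         "lra_placebo": 0.41, "hra_placebo": 0.06}


class TestSampleParameterSet:
    def test_same_seed_identical(self, params):
        s1 = sample_parameter_set(params, 42)
        s2 = sample_parameter_set(params, 42)
        assert s1.values() == s2.values()

    def test_discount_rate_fixed_across_draws(self, params):
        for seed in range(20):
            assert sample_parameter_set(params, seed).discount_rate == \
                params.discount_rate

    def test_draws_satisfy_invariants(self, params):
        for seed in range(10):
            assert sample_parameter_set(params, seed).violations() == []

    def test_empirical_means_recover_baselines(self, params):
        n = 2000
        draws = {name: np.empty(n) for name in params.names()}
        root = np.random.SeedSequence(123)
        for i, child in enumerate(root.spawn(n)):
            s = sample_parameter_set(params, child)
            for name in params.names():
                draws[name][i] = s[name]
        for name, x in draws.items():
            if params.spec(name).is_fixed:
                assert np.all(x == params[name])
                continue
            se = x.std(ddof=1) / np.sqrt(n)
            assert abs(x.mean() - params[name]) < 4 * se, name
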