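"""Parameter loading, moment matching and PSA sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sarcocea as sc
from sarcocea.parameters import (
    PARAMETER_NAMES,
    ConfigurationError,
    InfeasibleMomentsError,
    RangeError,
    ValidationError,
    sample_parameter_set_counted,
)


class TestDefaultSDRule:
    @pytest.mark.parametrize(
        "base,fraction,expected",
        [
            (1119.048, 0.125, 139.881),
            (0.27, 0.10, 0.027),
            (0.0, 0.125, 0.0),
        ],
    )
    def test_fraction_of_mean(self, base, fraction, expected):
        assert sc.default_sd_rule(base, fraction) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("fraction", [0.05, 0.2, -0.1])
    def test_fraction_outside_band_rejected(self, fraction):
        with pytest.raises(ConfigurationError):
            sc.default_sd_rule(1.0, fraction)


class TestMomentMatching:
    def test_beta_uniform_case(self):
        a, b = sc.fit_beta_moments(0.5, math.sqrt(1 / 12))
        assert a == pytest.approx(1.0, rel=1e-9)
        assert b == pytest.approx(1.0, rel=1e-9)

    def test_beta_prevalence_fit(self):
        # frozen from the moment equations: k = m(1-m)/sd^2 - 1 = 27.9023...
        a, b = sc.fit_beta_moments(0.245, 0.08)
        assert a == pytest.approx(6.83607421875, rel=1e-12)
        assert b == pytest.approx(21.06626953125, rel=1e-12)

    def test_beta_infeasible_variance(self):
        with pytest.raises(InfeasibleMomentsError):
            sc.fit_beta_moments(0.5, 0.6)

    @pytest.mark.parametrize(
        "mean,sd,shape,scale",
        [
            (1119.048, 119.047, 88.36097911180372, 12.66450430097726),
            (3599.048, 695.074, 26.811010980585767, 134.2376832640187),
        ],
    )
    def test_gamma_cost_fits(self, mean, sd, shape, scale):
        k, th = sc.fit_gamma_moments(mean, sd)
        assert k == pytest.approx(shape, rel=1e-12)
        assert th == pytest.approx(scale, rel=1e-12)

    def test_gamma_exponential_case(self):
        k, _ = sc.fit_gamma_moments(7.5, 7.5)
        assert k == pytest.approx(1.0, rel=1e-12)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(RangeError):
            sc.fit_gamma_moments(-1.0, 1.0)

    @given(
        mean=st.floats(0.01, 0.99),
        sd_frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_moment_round_trip(self, mean, sd_frac):
        """The fitted Beta's analytic mean/sd equal the inputs to 1e-9 relative."""
        sd = sd_frac * math.sqrt(mean * (1 - mean))
        a, b = sc.fit_beta_moments(mean, sd)
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(v) == pytest.approx(sd, rel=1e-9)

    @given(mean=st.floats(1e-3, 1e5), sd=st.floats(1e-3, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_gamma_moment_round_trip(self, mean, sd):
        k, th = sc.fit_gamma_moments(mean, sd)
        assert k * th == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(k) * th == pytest.approx(sd, rel=1e-9)


class TestLoading:
    def test_canonical_document(self, base_params):
        assert base_params.value("prevalence") == 0.245
        assert base_params.value("discount_rate") == 0.05
        assert base_params.horizon_cycles == 25
        assert base_params.cohort_size == 1000
        assert base_params.wtp == pytest.approx(5520.311)

    def test_default_sd_report(self, base_params):
        # parameters with no printed uncertainty get the default-SD rule
        assert "u_healthy" in base_params.defaulted_sds
        assert "cost_dxa" in base_params.defaulted_sds
        assert "prevalence" not in base_params.defaulted_sds
        up = base_params.params["u_healthy"]
        assert up.resolved_sd(0.125) == pytest.approx(0.125 * 0.76)

    def test_efficacy_sd_is_absolute(self, base_params):
        assert base_params.params["efficacy"].resolved_sd() == pytest.approx(0.15)

    def test_ci_to_sd_conversion(self, base_params):
        up = base_params.params["sens_sarsamod"]
        assert up.resolved_sd() == pytest.approx((0.842 - 0.767) / (2 * 1.96))

    def test_perfect_sensitivity_held_fixed(self, base_params):
        assert base_params.params["sens_ewgsop"].family == "fixed"

    def test_missing_key_is_named(self, base_params):
        doc = base_params.to_dict()
        del doc["parameters"]["efficacy"]
        with pytest.raises(ValidationError, match="efficacy"):
            sc.load_parameters(doc)

    def test_out_of_range_utility(self, base_params):
        doc = base_params.to_dict()
        doc["parameters"]["u_sarc"] = {"base": 1.2, "family": "beta"}
        with pytest.raises(RangeError):
            sc.load_parameters(doc)

    def test_serialize_round_trip(self, base_params):
        again = sc.load_parameters(base_params.to_dict())
        for name in PARAMETER_NAMES:
            assert again.params[name] == base_params.params[name]
        assert again.wtp == base_params.wtp
        assert again.mortality_vector == base_params.mortality_vector
        # and through YAML text
        third = sc.load_parameters(again.to_yaml())
        assert third.params == again.params


class TestSampling:
    def test_seed_determinism(self, base_params):
        a = sc.sample_parameter_set(base_params, 123)
        b = sc.sample_parameter_set(base_params, 123)
        for name in PARAMETER_NAMES:
            assert a.value(name) == b.value(name)

    def test_fixed_parameters_unchanged(self, base_params):
        drawn = sc.sample_parameter_set(base_params, 5)
        assert drawn.value("sens_ewgsop") == 1.0

    def test_prevalence_mean_recovery(self, base_params):
        """Sample mean of many prevalence draws sits within 3 SE of 0.245."""
        n = 100_000
        fam, (a, b) = base_params.params["prevalence"].fit()
        assert fam == "beta"
        draws = np.random.default_rng(0).beta(a, b, n)
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - 0.245) < 3 * se

    def test_support_bounds(self, base_params):
        """Probabilities stay in [0,1] and costs stay >= 0 over many draws."""
        rng = np.random.default_rng(42)
        for name in ("p_fall", "u_sarc", "cost_fracture", "cost_treatment_annual"):
            spec = base_params.params[name].fit()
            fam, (a, b) = spec
            x = rng.beta(a, b, 1_000_000) if fam == "beta" else rng.gamma(a, b, 1_000_000)
            if fam == "beta":
                assert np.all((x >= 0) & (x <= 1))
            else:
                assert np.all(x >= 0)

    def test_joint_draw_respects_structure(self, base_params):
        """Accepted joint draws always satisfy the utility-ordering invariants."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            s, _ = sample_parameter_set_counted(base_params, rng)
            assert s.value("u_healthy") >= s.value("u_sarc")
            assert s.value("u_sarc_cvd_fracture") <= min(
                s.value("u_sarc_cvd"), s.value("u_sarc_fracture")
            )
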