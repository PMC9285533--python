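"""Unit and property tests for the seasonal count model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from phenocount.errors import (
    InvalidParameterError,
    InvalidScalerError,
    MissingSiteError,
)
from phenocount.model_core import (
    MEAN_FLOOR,
    ElevationScaler,
    ModelSpec,
    ParameterSet,
    SurveyDataset,
    expected_count,
    expected_peak_day,
    nbd_log_probability,
    normalize_elevation,
    phenology_weight,
    total_log_likelihood,
)

from conftest import random_small_dataset


class TestElevationScaler:
    def test_center_maps_to_zero(self, scaler):
        assert normalize_elevation(scaler.center, scaler) == 0.0

    def test_population_sd_scaling(self, scaler):
        # sites at 1000/1500/2000 m: population SD = sqrt(5e5/3) = 408.25 m
        assert normalize_elevation(2000.0, scaler) == pytest.approx(1.2247, abs=1e-4)

    def test_equal_elevations_rejected(self):
        with pytest.raises(InvalidScalerError):
            ElevationScaler.from_elevations([1500.0, 1500.0, 1500.0])

    def test_inverse_round_trip(self, scaler):
        assert scaler.inverse(scaler.transform(1234.0)) == pytest.approx(1234.0)


class TestExpectedPeakDay:
    def test_zero_z_returns_d_star(self, simple_params):
        assert expected_peak_day(0.0, simple_params) == simple_params.peak_day

    def test_linear_shift(self):
        p = ParameterSet({"a": 1.0}, peak_day=224.6, duration_sd=12.3,
                         overdispersion=1.0, h1=0.0254)
        assert expected_peak_day(1.0, p) == pytest.approx(230.3, abs=0.05)

    def test_negative_quadratic_vertex_is_maximum(self):
        p = ParameterSet({"a": 1.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0, h1=0.0368, h2=-0.0247)
        z_star = -p.h1 / (2 * p.h2)
        peak = expected_peak_day(z_star, p)
        assert peak > expected_peak_day(z_star - 0.2, p)
        assert peak > expected_peak_day(z_star + 0.2, p)


class TestPhenologyWeight:
    def test_unity_at_shifted_peak(self, simple_params):
        day = expected_peak_day(0.0, simple_params) + simple_params.Q[2004]
        assert phenology_weight(day, 0.0, 2004, simple_params) == pytest.approx(1.0)

    def test_one_sd_value(self, simple_params):
        peak = expected_peak_day(0.0, simple_params) + simple_params.Q[2004]
        w = phenology_weight(peak + simple_params.duration_sd, 0.0, 2004, simple_params)
        assert w == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_direct_evaluation(self):
        p = ParameterSet({"a": 1.0}, peak_day=185.2, duration_sd=14.2,
                         overdispersion=1.0)
        assert phenology_weight(190, 0.0, 2004, p) == pytest.approx(0.94447, abs=1e-4)

    def test_nonpositive_effective_sd_raises(self):
        p = ParameterSet({"a": 1.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0, g=-1.2)
        with pytest.raises(InvalidParameterError):
            phenology_weight(200, 1.0, 2004, p)

    @settings(deadline=None, derandomize=True)
    @given(
        day=st.floats(1, 366),
        offset=st.floats(-80, 80, allow_nan=False),
    )
    def test_bounded_and_symmetric(self, day, offset):
        p = ParameterSet({"a": 1.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0, Q={2004: 5.0, 2005: -5.0})
        w = phenology_weight(day, 0.0, 2004, p)
        assert 0.0 < w <= 1.0
        peak = 205.0  # d* + Q_2004
        left = phenology_weight(peak - offset, 0.0, 2004, p)
        right = phenology_weight(peak + offset, 0.0, 2004, p)
        assert left == pytest.approx(right, rel=1e-12)


class TestExpectedCount:
    def test_peak_identity(self, simple_params, scaler):
        p = simple_params
        peak = expected_peak_day(0.0, p)
        val = expected_count("a", scaler.center, 2004, peak + p.Q[2004], p, scaler)
        assert val == pytest.approx(p.site_peaks["a"] * math.exp(p.U[2004]))

    def test_abundance_effect_doubles(self, scaler):
        p = ParameterSet({"a": 50.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0, U={2004: math.log(2), 2005: -math.log(2)})
        assert expected_count("a", scaler.center, 2004, 200, p, scaler) == pytest.approx(100.0)

    def test_one_sd_after_peak(self, scaler):
        p = ParameterSet({"a": 50.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0)
        val = expected_count("a", scaler.center, 2004, 214, p, scaler)
        assert val == pytest.approx(50 * math.exp(-0.5), abs=1e-9)

    def test_unknown_site_raises(self, simple_params, scaler):
        with pytest.raises(MissingSiteError):
            expected_count("nope", 1500.0, 2004, 200, simple_params, scaler)

    def test_linear_in_site_peak(self, scaler):
        kwargs = dict(peak_day=200.0, duration_sd=14.0, overdispersion=1.0, h1=0.02)
        p1 = ParameterSet({"a": 10.0}, **kwargs)
        p3 = ParameterSet({"a": 30.0}, **kwargs)
        v1 = expected_count("a", 1800.0, 2004, 190, p1, scaler)
        v3 = expected_count("a", 1800.0, 2004, 190, p3, scaler)
        assert v3 == pytest.approx(3 * v1, rel=1e-12)


class TestNbdLogProbability:
    @pytest.mark.parametrize("mean", [0.5, 3.0, 20.0])
    @pytest.mark.parametrize("phi", [0.1, 1.0, 2.0])
    def test_matches_textbook_parameterization(self, mean, phi):
        """NB with shape mean/phi and success prob 1/(1+phi)."""
        n = np.arange(0, 51)
        ours = nbd_log_probability(n, mean, phi)
        ref = stats.nbinom.logpmf(n, mean / phi, 1.0 / (1.0 + phi))
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_poisson_limit(self):
        assert nbd_log_probability(0, 2.0, 0.0) == pytest.approx(-2.0, abs=1e-9)
        # just above the switch threshold the NB form is already Poisson-like
        assert nbd_log_probability(3, 2.0, 1e-7) == pytest.approx(
            stats.poisson.logpmf(3, 2.0), abs=1e-6
        )

    def test_normalization(self):
        for mean, phi in [(3.0, 1.0), (0.5, 0.2), (20.0, 2.0)]:
            n = np.arange(0, 3000)
            total = np.exp(nbd_log_probability(n, mean, phi)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_mean_variance_contract(self):
        """Sampled mean ~ nbar and variance ~ (1+phi)*nbar."""
        rng = np.random.default_rng(7)
        mean, phi = 3.0, 1.0
        draws = rng.negative_binomial(mean / phi, 1 / (1 + phi), size=100_000)
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.var() == pytest.approx((1 + phi) * mean, rel=0.05)

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            nbd_log_probability(-1, 2.0, 1.0)
        with pytest.raises(InvalidParameterError):
            nbd_log_probability(1.5, 2.0, 1.0)
        with pytest.raises(InvalidParameterError):
            nbd_log_probability(1, 0.0, 1.0)


def _oracle_loglik(data, params, scaler):
    """Naive per-record loop: scalar expected count -> NB log-pmf -> sum."""
    total = 0.0
    for row in data.frame.itertuples():
        mean = expected_count(
            row.site_id, data.site_elevations[row.site_id], row.year, row.day,
            params, scaler,
        )
        mean = max(mean, MEAN_FLOOR)
        phi = params.overdispersion
        n, a, b = row.count, mean / phi, 1.0 / phi
        total += (
            gammaln(n + a) - gammaln(n + 1) - gammaln(a)
            + a * math.log(b / (1 + b)) - n * math.log(1 + b)
        )
    return total


class TestTotalLogLikelihood:
    def test_single_zero_count_poisson(self):
        data = SurveyDataset.from_records(
            [("a", 2004, 200, 0), ], {"a": 1500.0, "b": 1000.0}
        )
        p = ParameterSet({"a": 1.0, "b": 1.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=0.0)
        scaler = ElevationScaler.from_elevations([1500.0, 1000.0])
        assert total_log_likelihood(data, p, scaler) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            data, params, scaler = random_small_dataset(rng)
            fast = total_log_likelihood(data, params, scaler)
            slow = _oracle_loglik(data, params, scaler)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_duplicating_records_doubles(self, scaler, simple_params):
        records = [("a", 2004, 190, 4), ("b", 2005, 210, 0), ("a", 2005, 200, 7)]
        elev = {"a": 1000.0, "b": 2000.0}
        single = SurveyDataset.from_records(records, elev)
        double = SurveyDataset.from_records(records * 2, elev)
        ll1 = total_log_likelihood(single, simple_params, scaler)
        ll2 = total_log_likelihood(double, simple_params, scaler)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)


class TestDatasetAndSpec:
    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            SurveyDataset.from_records([("a", 2004, 100, -1)], {"a": 1000.0})
        with pytest.raises(InvalidParameterError):
            SurveyDataset.from_records([("a", 2004, 400, 1)], {"a": 1000.0})
        with pytest.raises(MissingSiteError):
            SurveyDataset.from_records([("b", 2004, 100, 1)], {"a": 1000.0})

    def test_year_effects_must_sum_to_zero(self):
        with pytest.raises(InvalidParameterError):
            ParameterSet({"a": 1.0}, peak_day=200, duration_sd=14,
                         overdispersion=1.0, Q={2004: 1.0, 2005: 1.0})

    def test_null_spec_reduces_to_shared_gaussian(self, scaler):
        """With all optional groups off, every site/year shares one curve."""
        p = ParameterSet({"a": 10.0, "b": 10.0}, peak_day=200.0, duration_sd=14.0,
                         overdispersion=1.0)
        days = np.arange(150, 250, 5)
        curve_a = [expected_count("a", 1000.0, 2004, d, p, scaler) for d in days]
        curve_b = [expected_count("b", 2000.0, 2010, d, p, scaler) for d in days]
        np.testing.assert_allclose(curve_a, curve_b, rtol=1e-12)

    def test_spec_param_count(self):
        spec = ModelSpec("quadratic", duration_elevation=True, year_peak=True,
                         year_duration=True, year_abundance=True)
        # 20 peaks + d*, s_d, phi + h1 + h2 + g + 3*(10-1)
        assert spec.n_params(20, 10) == 20 + 3 + 3 + 27
        assert ModelSpec().n_params(20, 10) == 23
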