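import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from budburst.climate import (JAN1, JUN30, NOV1, ClimateConfig,
                              DailyTemperatureSeries, apply_treatment,
                              schedule_from_label, synthesize_daily_temperature)
from budburst.errors import ParameterError, RangeError
from budburst.models import (MODEL_IDS, MODEL_SPECS, forcing_requirement_am,
                             forcing_requirement_um, get_model_spec,
                             predict_budburst, predict_budburst_reference,
                             rate_chilling_chill_day, rate_chilling_triangular,
                             rate_chilling_unified, rate_forcing_linear,
                             rate_forcing_sigmoid, rate_forcing_unified)

REL = 1e-9


class TestRateFunctions:
    @pytest.mark.parametrize("T,Tb,expected", [
        (5.0, 5.0, 0.0), (7.0, 5.0, 2.0), (0.0, 5.0, 0.0),
    ])
    def test_linear_forcing(self, T, Tb, expected):
        assert rate_forcing_linear(T, Tb) == pytest.approx(expected, rel=REL)

    @pytest.mark.parametrize("T,expected", [
        (3.0, 1.0), (-4.0, 0.0), (10.0, 0.0),
        (-0.5, 0.5),          # linear rise: (-0.5 - (-4)) / (3 - (-4))
        (6.5, 0.5),           # linear fall: (10 - 6.5) / (10 - 3)
        (-10.0, 0.0), (20.0, 0.0),
    ])
    def test_triangular_chilling(self, T, expected):
        assert rate_chilling_triangular(T, -4.0, 3.0, 10.0) \
            == pytest.approx(expected, rel=REL, abs=1e-12)

    def test_triangular_ordering_enforced(self):
        with pytest.raises(ParameterError):
            rate_chilling_triangular(0.0, 3.0, 3.0, 10.0)

    def test_sigmoid_forcing(self):
        assert rate_forcing_sigmoid(10.0, 0.2, 10.0, 1.0) \
            == pytest.approx(0.5, rel=REL)
        assert rate_forcing_sigmoid(20.0, 0.2, 10.0, 1.0) \
            == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=REL)
        assert rate_forcing_sigmoid(1e4, 0.2, 10.0, 2.5) \
            == pytest.approx(2.5, rel=REL)
        assert rate_forcing_sigmoid(-1e4, 0.2, 10.0, 2.5) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("T,Tc,expected", [
        (2.0, 5.0, 1.0), (5.0, 5.0, 0.0), (7.0, 5.0, 0.0),
    ])
    def test_chill_day_strict_inequality(self, T, Tc, expected):
        assert rate_chilling_chill_day(T, Tc) == expected

    def test_am_forcing_requirement(self):
        assert forcing_requirement_am(0.0, 20.0, 100.0, -0.05) \
            == pytest.approx(120.0, rel=REL)
        assert forcing_requirement_am(50.0, 20.0, 100.0, -0.05) \
            == pytest.approx(20.0 + 100.0 * math.exp(-2.5), rel=REL)
        assert forcing_requirement_am(1e7, 20.0, 100.0, -0.05) \
            == pytest.approx(20.0, rel=REL)

    def test_unified_chilling(self):
        assert rate_chilling_unified(2.0, 0.1, 0.0, 2.0) \
            == pytest.approx(0.5, rel=REL)
        assert rate_chilling_unified(4.0, 0.1, 0.0, 2.0) \
            == pytest.approx(1.0 / (1.0 + math.exp(0.4)), rel=REL)
        assert rate_chilling_unified(100.0, 0.5, 0.0, 2.0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_unified_forcing(self):
        assert rate_forcing_unified(8.0, 0.5, 8.0) == pytest.approx(0.5, rel=REL)
        assert rate_forcing_unified(12.0, 0.5, 8.0) \
            == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=REL)
        assert rate_forcing_unified(1e4, 0.5, 8.0) == pytest.approx(1.0, rel=REL)

    def test_um_forcing_requirement(self):
        assert forcing_requirement_um(0.0, 200.0, -0.01) \
            == pytest.approx(200.0, rel=REL)
        assert forcing_requirement_um(123.0, 200.0, 0.0) \
            == pytest.approx(200.0, rel=REL)
        assert forcing_requirement_um(100.0, 200.0, -0.01) \
            == pytest.approx(200.0 * math.exp(-1.0), rel=REL)

    def test_overflow_guard(self):
        # huge exponents must not overflow to nan/inf
        assert np.isfinite(rate_chilling_unified(1e6, 1.0, 1.0, 0.0))
        assert np.isfinite(rate_forcing_unified(-1e6, 2.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(T=st.floats(-40, 40), b=st.floats(-5, 20), a=st.floats(0.01, 2),
           c=st.floats(0.05, 3))
    def test_sigmoid_bounded_and_midpoint_ordered(self, T, b, a, c):
        r = float(rate_forcing_sigmoid(T, a, b, c))
        assert 0.0 <= r <= c
        if T > b:
            assert r > c / 2


class TestRegistry:
    def test_parameter_counts(self):
        counts = {m: MODEL_SPECS[m].n_params for m in MODEL_IDS}
        assert counts == {"TTM": 3, "SM": 8, "PM": 9, "AM": 8, "UM": 9}

    def test_fixed_calendar_anchors(self):
        assert MODEL_SPECS["AM"].fixed_days == {"t1f": JAN1, "t1c": NOV1}
        assert MODEL_SPECS["UM"].fixed_days == {"t1c": 1}

    def test_bounds_cover_every_parameter(self):
        for spec in MODEL_SPECS.values():
            assert set(spec.parameter_names) <= set(spec.bounds)

    def test_validation_rejects_out_of_bounds_and_misordered(self):
        spec = get_model_spec("SM")
        good = {"Tmin": -5.0, "Topt": 2.0, "Tmax": 10.0, "a": 0.2, "b": 8.0,
                "c": 1.0, "Cstar": 50.0, "Fstar": 20.0}
        spec.validate(good)
        with pytest.raises(ParameterError):
            spec.validate({**good, "Fstar": 1e9})
        with pytest.raises(ParameterError):
            spec.validate({**good, "Topt": -7.0, "Tmin": -5.0})

    def test_unknown_model_rejected(self):
        with pytest.raises(ParameterError):
            get_model_spec("XYZ")


class TestPredictSemantics:
    def test_ttm_day_counting_convention(self, constant_series):
        # constant T = Tb + 1, F* = 10: Sf reaches 10 on the 10th forcing day,
        # the start day contributing its full rate
        s = constant_series(6.0)
        params = {"t1f": 100.0, "Tb": 5.0, "Fstar": 10.0}
        pred = predict_budburst(get_model_spec("TTM"), params, s)
        assert pred.day == 109

    def test_sm_no_chilling_possible_gives_none(self, constant_series):
        s = constant_series(25.0)  # always above Tmax: no chilling ever
        params = {"Tmin": -4.0, "Topt": 3.0, "Tmax": 10.0, "a": 0.5, "b": 8.0,
                  "c": 1.0, "Cstar": 10.0, "Fstar": 5.0}
        pred = predict_budburst(get_model_spec("SM"), params, s)
        assert pred.day is None
        assert pred.sc_final == 0.0

    def test_ttm_warming_never_delays(self, noisy_series):
        params = {"t1f": 123.0, "Tb": 5.0, "Fstar": 150.0}
        spec = get_model_spec("TTM")
        control = predict_budburst(spec, params, noisy_series)
        warmed = predict_budburst(
            spec, params, apply_treatment(noisy_series, schedule_from_label("W6S6")))
        assert warmed.day is not None and control.day is not None
        assert warmed.day <= control.day

    def test_sm_uniform_warming_can_nullify_budburst(self, noise_free_series):
        # the central chilling mechanism: enough warming abolishes dormancy
        # release, so budburst never happens even though forcing abounds
        params = {"Tmin": -4.0, "Topt": 3.0, "Tmax": 10.0, "a": 0.5, "b": 8.0,
                  "c": 1.0, "Cstar": 60.0, "Fstar": 10.0}
        spec = get_model_spec("SM")
        control = predict_budburst(spec, params, noise_free_series)
        assert control.day is not None
        hot = apply_treatment(noise_free_series,
                              schedule_from_label("W9S9",))
        warmed = predict_budburst(spec, params, hot)
        assert warmed.day is None or warmed.day > control.day

    def test_forcing_starts_same_day_chilling_met(self, constant_series):
        # constant T gives 0.5 CU/day: C*=5 met on day 10, forcing starts then
        s = constant_series(6.5)
        params = {"Tmin": -4.0, "Topt": 3.0, "Tmax": 10.0, "a": 2.0, "b": 0.0,
                  "c": 1.0, "Cstar": 5.0, "Fstar": 0.99}
        pred = predict_budburst(get_model_spec("SM"), params, s)
        assert pred.day == 10  # Rf = 1 on the gate day itself

    def test_pm_km_one_equals_ungated_sigmoid(self, noisy_series):
        # with Km = 1 competence is always 1: PM reduces to pure sigmoid forcing
        base = {"Tmin": -4.0, "Topt": 3.0, "Tmax": 10.0, "a": 0.4, "b": 8.0,
                "c": 1.0, "Cstar": 50.0, "Fstar": 25.0}
        pm = predict_budburst(get_model_spec("PM"), {**base, "Km": 1.0},
                              noisy_series)
        T = noisy_series.temps
        from budburst.models import rate_forcing_sigmoid

        sf = np.cumsum(rate_forcing_sigmoid(T, 0.4, 8.0, 1.0))
        expected = noisy_series.start_index + int(np.searchsorted(sf, 25.0))
        assert pm.day == expected

    def test_am_b_zero_reduces_to_ttm_from_january(self, noisy_series):
        am_params = {"Tb": 5.0, "Tc": 5.0, "a": 150.0, "b": 1e-6, "c": -0.5}
        ttm_params = {"t1f": float(JAN1), "Tb": 5.0, "Fstar": 150.0}
        am = predict_budburst(get_model_spec("AM"), am_params, noisy_series)
        ttm = predict_budburst(get_model_spec("TTM"), ttm_params, noisy_series)
        assert am.day == ttm.day

    def test_budburst_crossing_bracket(self, noisy_series):
        params = {"t1f": 123.0, "Tb": 5.0, "Fstar": 150.0}
        pred = predict_budburst(get_model_spec("TTM"), params, noisy_series,
                                return_state=True)
        i = pred.day - pred.state.start_index
        assert pred.state.sf[i] >= 150.0
        assert pred.state.sf[i - 1] < 150.0

    def test_states_non_decreasing_rates_non_negative(self, noisy_series):
        for mid, params in _EXAMPLE_PARAMS.items():
            pred = predict_budburst(get_model_spec(mid), params, noisy_series,
                                    return_state=True)
            st_ = pred.state
            assert np.all(np.diff(st_.sc) >= 0)
            assert np.all(np.diff(st_.sf) >= 0)
            assert np.all(st_.rc >= 0) and np.all(st_.rf >= 0)

    def test_series_too_short_raises(self, constant_series):
        short = constant_series(6.0, n_days=100, start=1)
        with pytest.raises(RangeError):
            predict_budburst(get_model_spec("TTM"),
                             {"t1f": 123.0, "Tb": 5.0, "Fstar": 10.0}, short)


_EXAMPLE_PARAMS = {
    "TTM": {"t1f": 123.0, "Tb": 5.0, "Fstar": 150.0},
    "SM": {"Tmin": -25.0, "Topt": 4.0, "Tmax": 34.0, "a": 0.4, "b": 8.0,
           "c": 1.0, "Cstar": 120.0, "Fstar": 45.0},
    "PM": {"Tmin": -25.0, "Topt": 4.0, "Tmax": 34.0, "a": 0.4, "b": 8.0,
           "c": 1.0, "Cstar": 120.0, "Fstar": 45.0, "Km": 0.2},
    "AM": {"Tb": 5.0, "Tc": 5.0, "a": 50.0, "b": 500.0, "c": -0.03},
    "UM": {"Ca": 0.05, "Cb": 0.1, "Cc": 4.0, "Fb": 0.4, "Fc": 10.0,
           "Cstar": 60.0, "k": -0.005, "w": 60.0, "t2c": 175.0},
}


class TestOracleAgreement:
    """The vectorized day loop must match the naive reference loop."""

    @pytest.mark.parametrize("mid", MODEL_IDS)
    def test_example_parameters_agree(self, mid, noisy_series, noise_free_series):
        spec = get_model_spec(mid)
        for series in (noisy_series, noise_free_series):
            fast = predict_budburst(spec, _EXAMPLE_PARAMS[mid], series).day
            slow = predict_budburst_reference(spec, _EXAMPLE_PARAMS[mid], series)
            assert fast == slow

    @pytest.mark.parametrize("mid", MODEL_IDS)
    def test_random_draws_agree(self, mid):
        # a smaller version of the full equivalence sweep in the acceptance
        # suite: 20 random parameter draws x 3 random weather years
        from conftest import draw_params

        rng = np.random.default_rng(123)
        spec = get_model_spec(mid)
        series_pool = [
            synthesize_daily_temperature(ClimateConfig(seed=s), n_days=303)
            for s in range(3)
        ]
        for _ in range(20):
            params = draw_params(spec, rng)
            for series in series_pool:
                assert predict_budburst(spec, params, series).day \
                    == predict_budburst_reference(spec, params, series)
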