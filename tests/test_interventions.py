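"""Indicator construction and transfer-function responses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itsarima import (InterventionSpec, TimeSeries, TransferParams,
                      apply_transfer, indicator, load_intervention_specs,
                      pulse_indicator, ramp_indicator, step_indicator,
                      theoretical_response)


def _timeline(n=8):
    return TimeSeries(np.zeros(n), period=1)


class TestIndicators:
    def test_step_basic(self):
        out = step_indicator(_timeline(), onset=4)
        np.testing.assert_array_equal(out.values, [0, 0, 0, 0, 1, 1, 1, 1])

    def test_step_at_first_observation(self):
        out = step_indicator(_timeline(), onset=0)
        assert np.all(out.values == 1)

    def test_step_after_end_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="after the series end"):
            out = step_indicator(_timeline(), onset=50)
        assert np.all(out.values == 0)

    def test_pulse_basic_and_sums_to_one(self):
        out = pulse_indicator(_timeline(), onset=4)
        np.testing.assert_array_equal(out.values, [0, 0, 0, 0, 1, 0, 0, 0])
        assert out.values.sum() == 1

    def test_ramp_basic(self):
        out = ramp_indicator(_timeline(), onset=4)
        np.testing.assert_array_equal(out.values, [0, 0, 0, 0, 1, 2, 3, 4])

    @pytest.mark.parametrize("t0", [0, 3, 7, 11])
    def test_pulse_is_step_difference(self, t0):
        tl = _timeline(12)
        pulse = pulse_indicator(tl, t0).values
        step0 = step_indicator(tl, t0).values
        step1 = step_indicator(tl, t0 + 1).values
        np.testing.assert_array_equal(pulse, step0 - step1)

    @pytest.mark.parametrize("t0", [0, 5, 11])
    def test_ramp_is_cumulative_step(self, t0):
        tl = _timeline(12)
        np.testing.assert_array_equal(
            ramp_indicator(tl, t0).values,
            np.cumsum(step_indicator(tl, t0).values))

    def test_calendar_onset_on_four_year_monthly_series(self):
        ts = TimeSeries.monthly(np.zeros(48), start="2011-01")
        step = step_indicator(ts, "2014-01")
        assert np.all(step.values[:36] == 0) and np.all(step.values[36:] == 1)
        ramp = ramp_indicator(ts, "2014-01")
        assert ramp.values[ts.position_of("2014-12")] == 12

    def test_delay_shifts_onset(self):
        spec = InterventionSpec("step", 4, delay=2)
        out = indicator(_timeline(), spec)
        np.testing.assert_array_equal(out.values, [0, 0, 0, 0, 0, 0, 1, 1])


class TestTransferFunctions:
    def test_decaying_pulse(self):
        x = pulse_indicator(_timeline(6), 0)
        y = apply_transfer(x, TransferParams([10.0], [0.5]))
        np.testing.assert_allclose(y.values, [10, 5, 2.5, 1.25, 0.625, 0.3125])

    def test_gradual_step_approaches_new_level(self):
        x = step_indicator(_timeline(40), 0)
        y = apply_transfer(x, TransferParams([1.0], [0.5]))
        np.testing.assert_allclose(y.values[:3], [1.0, 1.5, 1.75])
        assert y.values[-1] == pytest.approx(1.0 / (1 - 0.5), abs=1e-6)

    def test_ramp_with_pure_gain(self):
        x = ramp_indicator(_timeline(6), 2)
        y = apply_transfer(x, TransferParams([3.0]))
        np.testing.assert_allclose(y.values, [0, 0, 3, 6, 9, 12])

    def test_unstable_delta_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            TransferParams([1.0], [1.01])

    def test_r0_transfer_is_pure_scaling(self, rng):
        x = TimeSeries(rng.normal(size=30), period=1)
        w0 = -4.2
        out = apply_transfer(x, TransferParams([w0]))
        np.testing.assert_allclose(out.values, w0 * x.values, atol=1e-12)

    def test_delay_commutes_with_filtering(self, rng):
        params = TransferParams([2.5], [0.6])
        tl = _timeline(30)
        base = apply_transfer(step_indicator(tl, 5), params).values
        delayed = apply_transfer(step_indicator(tl, 5, delay=3), params).values
        np.testing.assert_allclose(delayed[3:], base[:-3], atol=1e-12)
        np.testing.assert_allclose(delayed[:3], 0.0)


class TestTheoreticalResponse:
    def test_permanent_step_level(self):
        params = TransferParams([-3285.0])
        for k in (0, 1, 5, 40):
            assert theoretical_response("step", params, k) == -3285.0

    def test_decaying_pulse_value(self):
        assert theoretical_response(
            "pulse", TransferParams([8.0], [0.25]), 2) == pytest.approx(0.5)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            theoretical_response("step", TransferParams([1.0]), -1)

    def test_unsupported_combination(self):
        with pytest.raises(ValueError, match="ramp with r=1"):
            theoretical_response("ramp", TransferParams([1.0], [0.5]), 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(shape=st.sampled_from(["step", "pulse", "ramp"]),
           w0=st.floats(-10, 10, allow_nan=False),
           d1=st.one_of(st.none(), st.floats(-0.95, 0.95)),
           )
    def test_filter_matches_closed_form(self, shape, w0, d1):
        """The recursive filter and the closed-form response table agree
        at every post-onset horizon (zero pre-onset baseline)."""
        if shape == "ramp" and d1 is not None:
            return
        params = TransferParams([w0], [] if d1 is None else [d1])
        t0, n = 4, 55
        tl = _timeline(n)
        builder = {"step": step_indicator, "pulse": pulse_indicator,
                   "ramp": ramp_indicator}[shape]
        filtered = apply_transfer(builder(tl, t0), params).values
        for k in range(n - t0):
            expected = theoretical_response(shape, params, k)
            assert filtered[t0 + k] == pytest.approx(expected, abs=1e-10)


class TestSpecIO:
    def test_experimental_orders_warn(self):
        with pytest.warns(UserWarning, match="experimental"):
            InterventionSpec("step", 0, r=2)

    def test_yaml_and_json_round_trip(self, tmp_path):
        yml = tmp_path / "iv.yaml"
        yml.write_text(
            "interventions:\n"
            "  - {shape: step, onset: 2014-01, label: subsidy}\n"
            "  - {shape: ramp, onset: 2014-01, delay: 1}\n")
        specs = load_intervention_specs(yml)
        assert [s.shape for s in specs] == ["step", "ramp"]
        assert specs[0].label == "subsidy"
        jsn = tmp_path / "iv.json"
        jsn.write_text('[{"shape": "pulse", "onset": 12, "r": 1}]')
        specs = load_intervention_specs(jsn)
        assert specs[0].r == 1 and specs[0].onset == 12
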