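"""Field-potential sweep metrics, baseline normalization and outcome rule."""

import math

import numpy as np
import pandas as pd
import pytest

from synglu import ephys
from synglu.synth import (
    SweepShape,
    alpha_epsp,
    alpha_epsp_slope_oracle,
    gen_experiment,
    gen_sweep,
)


@pytest.fixture(scope="module")
def clean_sweep():
    return gen_sweep(noise_mV=0.0, seed=0)


class TestFiberVolley:
    def test_noiseless_round_trip_within_2pct(self, clean_sweep):
        sweep, truth = clean_sweep
        amp, hwhm, delay, missing = ephys.fiber_volley_metrics(sweep)
        assert not missing
        assert amp == pytest.approx(truth["fv_amplitude_mV"], rel=0.02)
        assert hwhm == pytest.approx(truth["fv_hwhm_ms"], rel=0.02)
        assert delay == pytest.approx(truth["fv_delay_ms"], rel=0.02)

    def test_flat_trace_flags_missing(self):
        sweep = ephys.Sweep(np.zeros(3000))
        amp, hwhm, delay, missing = ephys.fiber_volley_metrics(sweep)
        assert missing and math.isnan(amp)

    def test_gain_doubles_amplitude_only(self, clean_sweep):
        sweep, _ = clean_sweep
        doubled = ephys.Sweep(sweep.voltage_mV * 2.0, sweep.sampling_rate_hz, sweep.stimulus_times_s)
        a1, h1, d1, _ = ephys.fiber_volley_metrics(sweep)
        a2, h2, d2, _ = ephys.fiber_volley_metrics(doubled)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-9)
        assert h2 == pytest.approx(h1, rel=1e-9)
        assert d2 == d1

    def test_offset_invariance(self, clean_sweep):
        sweep, _ = clean_sweep
        shifted = ephys.Sweep(sweep.voltage_mV + 3.3, sweep.sampling_rate_hz, sweep.stimulus_times_s)
        a1, h1, d1, _ = ephys.fiber_volley_metrics(sweep)
        a2, h2, d2, _ = ephys.fiber_volley_metrics(shifted)
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert h2 == pytest.approx(h1, rel=1e-9)

    def test_hwhm_matches_oversampled_crossing_search(self, clean_sweep):
        sweep, truth = clean_sweep
        _, hwhm, _, _ = ephys.fiber_volley_metrics(sweep)
        # brute force on a 100x oversampled analytic rebuild of the waveform
        fs = sweep.sampling_rate_hz * 100.0
        t = np.arange(int(0.3 * fs)) / fs
        shape = SweepShape()
        sigma_ms = shape.fv_hwhm_ms * 2.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        t_ms = (t - 0.05) * 1e3
        v = -shape.fv_amplitude_mV * np.exp(-0.5 * ((t_ms - shape.fv_delay_ms) / sigma_ms) ** 2)
        half = -shape.fv_amplitude_mV / 2.0
        below = np.nonzero(v <= half)[0]
        fwhm_ms = (t_ms[below[-1]] - t_ms[below[0]])
        assert hwhm == pytest.approx(fwhm_ms / 2.0, rel=0.01)


class TestFepspSlope:
    def test_exact_linear_ramp(self):
        # a pure negative ramp of 0.5 mV/ms within the fEPSP window
        fs = 10000.0
        n = 3000
        v = np.zeros(n)
        t_ms = (np.arange(n) / fs - 0.05) * 1e3
        ramp = (t_ms > 4.0) & (t_ms < 14.0)
        v[ramp] = -0.5 * (t_ms[ramp] - 4.0)
        v[t_ms >= 14.0] = -5.0
        sweep = ephys.Sweep(v, fs)
        slope, low_conf = ephys.fepsp_slope(sweep)
        assert not low_conf
        assert slope == pytest.approx(0.5, rel=1e-6)

    def test_flat_trace_reports_zero_low_confidence(self):
        slope, low_conf = ephys.fepsp_slope(ephys.Sweep(np.zeros(3000)))
        assert slope == 0.0 and low_conf

    def test_alpha_epsp_matches_dense_analytic_oracle(self, clean_sweep):
        sweep, truth = clean_sweep
        slope, _ = ephys.fepsp_slope(sweep)
        assert slope == pytest.approx(truth["epsp_chord_slope_mV_ms"], rel=0.05)

    def test_gain_scales_slope(self, clean_sweep):
        sweep, _ = clean_sweep
        doubled = ephys.Sweep(sweep.voltage_mV * 2.0, sweep.sampling_rate_hz, sweep.stimulus_times_s)
        s1, _ = ephys.fepsp_slope(sweep)
        s2, _ = ephys.fepsp_slope(doubled)
        assert s2 == pytest.approx(2.0 * s1, rel=0.02)


class TestPairedPulseRatio:
    def test_trivial_ratios(self):
        assert ephys.paired_pulse_ratio(1.0, 1.0) == 1.0
        assert ephys.paired_pulse_ratio(0.5, 1.0) == 2.0
        assert math.isnan(ephys.paired_pulse_ratio(0.0, 1.0))

    def test_generator_round_trip(self):
        sweep, truth = gen_sweep(SweepShape(ppr=1.5), noise_mV=0.005, seed=3)
        m = ephys.analyze_sweep(sweep)
        assert m.ppr == pytest.approx(1.5, rel=0.05)


class TestNormalizeAndClassify:
    @staticmethod
    def _timeline(values, dt=20.0):
        metrics = [
            ephys.SweepMetrics(
                fv_amplitude_mV=(v, v),
                fv_hwhm_ms=(0.6, 0.6),
                fv_delay_ms=(1.2, 1.2),
                fepsp_slope_mV_ms=(v, v),
                ppr=1.0,
            )
            for v in values
        ]
        t = np.arange(len(values)) * dt
        return ephys.ExperimentTimeline(t, metrics)

    def test_constant_series_normalizes_to_one(self):
        tl = self._timeline(np.full(180, 0.42))
        norm = ephys.normalize_to_baseline(tl)
        np.testing.assert_allclose(norm["fepsp_slope_mV_ms"], 1.0)

    def test_baseline_mean_exactly_one(self):
        vals = np.linspace(0.3, 0.6, 180)
        norm = ephys.normalize_to_baseline(self._timeline(vals))
        in_base = norm["time_s"] < 600.0
        assert norm.loc[in_base, "fepsp_slope_mV_ms"].mean() == pytest.approx(1.0, rel=1e-12)

    def test_series_doubling_after_baseline(self):
        vals = np.r_[np.full(60, 0.4), np.full(120, 0.8)]
        norm = ephys.normalize_to_baseline(self._timeline(vals))
        assert norm["fepsp_slope_mV_ms"].iloc[-1] == pytest.approx(2.0)

    def test_too_few_baseline_sweeps_rejected(self):
        with pytest.raises(ValueError):
            ephys.normalize_to_baseline(self._timeline(np.full(180, 1.0), dt=90.0))

    @pytest.mark.parametrize(
        "end_mean,expected",
        [(0.05, "failure"), (1.2, "recovered"), (0.5, "failure"), (0.5001, "recovered")],
    )
    def test_threshold_rule_is_strict(self, end_mean, expected):
        t = np.arange(0.0, 3600.0, 20.0)
        series = np.where(t < 3000.0, 1.0, end_mean)
        norm = pd.DataFrame({"time_s": t, "fepsp_slope_mV_ms": series})
        out = ephys.classify_outcome(norm, (3000.0, 3600.0))
        assert out.classification == expected

    def test_programmed_potentiation_recovered(self):
        tl, _, truth = gen_experiment("ischemia", seed=9)
        norm = ephys.normalize_to_baseline(tl)
        out = ephys.classify_outcome(norm, tl.end_epoch_s)
        assert out.classification == "recovered"
        assert out.fepsp_end_over_baseline == pytest.approx(
            truth["potentiation_factor"], rel=0.05
        )

    def test_failure_scenario_keeps_fv_recovered(self):
        tl, _, _ = gen_experiment("ischemia_failure", seed=10)
        norm = ephys.normalize_to_baseline(tl)
        out = ephys.classify_outcome(norm, tl.end_epoch_s)
        assert out.classification == "failure"
        assert out.fv_end_over_baseline == pytest.approx(1.0, abs=0.05)
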