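"""Threshold calibration, rise-time estimation and fate classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonefate import classify as cls
from clonefate import synthetic as syn
from clonefate.containers import CloneTrace, ResponseThreshold

from .oracles import brute_force_rise_time, welch_t


def trace_from(values_G, values_R=None, interval=0.5, **kw):
    values_G = np.asarray(values_G, float)
    if values_R is None:
        values_R = np.zeros_like(values_G)
    times = np.arange(len(values_G)) * interval
    return CloneTrace(well_id="w", times=times, total_G=values_G,
                      total_R=np.asarray(values_R, float), **kw)


class TestThreshold:
    def test_constant_signals_give_threshold_equal_to_value(self):
        thr = cls.compute_response_threshold([7.0] * 20, [7.0] * 20, k=3)
        assert thr.threshold_G == 7.0 and thr.threshold_R == 7.0

    def test_threshold_formula_on_seeded_sample(self):
        rng = np.random.default_rng(42)
        g = rng.normal(100, 10, 200)
        r = rng.normal(100, 10, 200)
        thr = cls.compute_response_threshold(g, r, k=3)
        assert thr.threshold_G == pytest.approx(g.mean() + 3 * g.std(ddof=1))
        assert 125 < thr.threshold_G < 135
        assert thr.calibration_G[2] == 3

    def test_k_zero_gives_threshold_at_mean(self):
        rng = np.random.default_rng(1)
        g = rng.normal(100, 10, 50)
        thr = cls.compute_response_threshold(g, g, k=0)
        assert thr.threshold_G == pytest.approx(g.mean())

    def test_too_few_calibration_wells_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            cls.compute_response_threshold([1.0] * 5, [1.0] * 5)


class TestRiseTime:
    THR = ResponseThreshold(threshold_G=10.0, threshold_R=10.0)

    def test_trace_always_below_threshold_has_no_rise(self):
        assert cls.compute_rise_time(trace_from([5.0] * 20), self.THR, "G") is None

    def test_noise_free_step_at_frame_40_rises_at_20_hours(self):
        values = np.where(np.arange(105) >= 40, 20.0, 0.0)
        rt = cls.compute_rise_time(trace_from(values), self.THR, "G")
        assert rt == 20.0

    def test_single_frame_spike_suppressed_by_persistence(self):
        values = np.zeros(50)
        values[10] = 100.0
        values[30:] = 100.0
        assert cls.compute_rise_time(trace_from(values), self.THR, "G",
                                     persistence_frames=2) == 15.0
        assert cls.compute_rise_time(trace_from(values), self.THR, "G",
                                     persistence_frames=1) == 5.0

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            cls.compute_rise_time(trace_from([0.0] * 5), self.THR, "B")

    def test_noisy_sigmoid_estimate_close_to_onset(self):
        # mean absolute error of the estimator under defaults stays < 1 hr
        spec = syn.th17_spec()
        errors = []
        for seed in range(20):
            params = syn.CloneParams(
                fate="SPR", onset_time_G=21.8, onset_time_R=53,
                amplitude_G=150, amplitude_R=0, baseline=100,
                rise_width=0.5, noise_sd=25.0, seed=seed)
            trace = syn.simulate_clone_trace(params, spec)
            thr = ResponseThreshold(threshold_G=175.0, threshold_R=175.0)
            rt = cls.compute_rise_time(trace, thr, "G")
            errors.append(abs(rt - 21.8))
        assert np.mean(errors) < 1.0

    def test_matches_brute_force_scan_on_random_traces(self):
        rng = np.random.default_rng(7)
        thr = ResponseThreshold(threshold_G=0.5, threshold_R=0.5)
        for _ in range(300):
            n = int(rng.integers(4, 60))
            values = rng.random(n)
            persistence = int(rng.integers(1, 4))
            trace = trace_from(values)
            got = cls.compute_rise_time(trace, thr, "G", persistence)
            want = brute_force_rise_time(trace.times, values, 0.5, persistence)
            assert got == want


class TestClassify:
    def make_threshold(self):
        return ResponseThreshold(threshold_G=175.0, threshold_R=175.0)

    def trace(self, onset_G=None, onset_R=None, divisions=()):
        spec = syn.th17_spec()
        params = syn.CloneParams(
            fate="DP" if onset_G and onset_R else
                 "SPR" if onset_G else "SPF" if onset_R else "DN",
            onset_time_G=onset_G if onset_G else 53.0,
            onset_time_R=onset_R if onset_R else 53.0,
            amplitude_G=150.0 if onset_G else 0.0,
            amplitude_R=150.0 if onset_R else 0.0,
            baseline=100.0, rise_width=0.5, division_times=divisions,
            noise_sd=0.0, seed=0)
        return syn.simulate_clone_trace(params, spec)

    def test_single_and_double_positive_calls(self):
        thr = self.make_threshold()
        assert cls.classify_clone(self.trace(onset_G=20), thr).fate == "SPR"
        call = cls.classify_clone(self.trace(onset_G=20, onset_R=40), thr)
        assert call.fate == "DP"
        assert call.rise_time_G < call.rise_time_R
        assert cls.classify_clone(self.trace(), thr).fate == "DN"

    def test_endpoint_mfi_is_mean_of_last_five_frames(self):
        thr = self.make_threshold()
        trace = self.trace(onset_G=20)
        call = cls.classify_clone(trace, thr)
        assert call.endpoint_MFI_G == pytest.approx(trace.total_G[-5:].mean())

    def test_every_clone_gets_exactly_one_fate(self, th17_population,
                                               calibrated_threshold):
        _, records = th17_population
        calls = [cls.classify_clone(r.trace, calibrated_threshold)
                 for r in records]
        counts = cls.calls_frame(calls)["fate"].value_counts()
        assert counts.sum() == len(records)

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_raising_threshold_never_decreases_rise_time(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        values = np.cumsum(rng.normal(0.3, 1.0, 40)).clip(0)
        lo = data.draw(st.floats(0.1, 5.0))
        hi = lo + data.draw(st.floats(0.1, 5.0))
        trace = trace_from(values, values)
        rt_lo = cls.compute_rise_time(
            trace, ResponseThreshold(lo, lo), "G")
        rt_hi = cls.compute_rise_time(
            trace, ResponseThreshold(hi, hi), "G")
        if rt_hi is not None:
            assert rt_lo is not None and rt_lo <= rt_hi

    def test_fate_recovery_on_synthetic_th17_population(
            self, th17_population, calibrated_threshold):
        _, records = th17_population
        calls = cls.calls_frame([
            cls.classify_clone(r.trace, calibrated_threshold) for r in records])
        truth = pd.Series([r.params.fate for r in records])
        agreement = (calls["fate"].to_numpy() == truth.to_numpy()).mean()
        assert agreement > 0.97


class TestSummaries:
    def test_identical_groups_are_not_significantly_different(self):
        rng = np.random.default_rng(2)
        g = rng.normal(20, 5, 100)
        out = cls.summarize_rise_times({"a": g, "b": g.copy()},
                                       pairs=[("a", "b")])
        assert out["tests"][0]["p"] > 0.99

    def test_group_mean_recovers_generating_mean(self):
        rng = np.random.default_rng(3)
        rts = rng.normal(21.8, 9.4, 200)
        out = cls.summarize_rise_times({"SPR/G": rts})
        g = out["groups"]["SPR/G"]
        assert abs(g["mean"] - 21.8) < 3 * 9.4 / np.sqrt(200)

    def test_separated_groups_yield_tiny_p_value(self):
        rng = np.random.default_rng(4)
        a = rng.normal(21.8, 9.0, 200)
        b = rng.normal(39.3, 9.0, 200)
        out = cls.summarize_rise_times({"a": a, "b": b}, pairs=[("a", "b")])
        assert out["tests"][0]["p"] < 1e-10
        # statistic agrees with the closed-form Welch t
        assert out["tests"][0]["t"] == pytest.approx(welch_t(a, b))

    def test_underfilled_group_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = cls.summarize_rise_times({"a": [1.0], "b": [1.0, 2.0, 3.0]})
        assert "a" not in out["groups"] and "b" in out["groups"]


class TestDivisionVsRise:
    def frame(self, rise_G, rise_R, division, condition="Th17"):
        n = len(division)
        return pd.DataFrame({
            "condition": [condition] * n, "rise_time_G": rise_G,
            "rise_time_R": rise_R, "first_division_time": division,
        })

    def test_all_rises_after_division_gives_fraction_one(self):
        calls = self.frame([None] * 4, [40.0] * 4, [30.0] * 4)
        out = cls.division_vs_rise(calls)
        assert out["fraction_rise_after_division"]["R"] == 1.0

    def test_all_rises_before_division_gives_fraction_zero(self):
        calls = self.frame([20.0] * 4, [None] * 4, [30.0] * 4)
        assert cls.division_vs_rise(calls)["fraction_rise_after_division"]["G"] == 0.0

    def test_no_division_annotations_yield_absent_result(self):
        calls = self.frame([20.0], [None], [None])
        out = cls.division_vs_rise(calls)
        assert out["fraction_rise_after_division"]["G"] is None

    def test_default_populations_show_foxp3_after_and_rorgt_before_division(
            self, th17_population, treg_population, calibrated_threshold):
        records = th17_population[1] + treg_population[1]
        calls = cls.calls_frame([
            cls.classify_clone(r.trace, calibrated_threshold) for r in records])
        out = cls.division_vs_rise(calls)
        assert out["fraction_rise_after_division"]["R"] > 0.5
        assert out["fraction_rise_after_division"]["G"] < 0.5
        assert out["median_division"]["Th17"] > out["median_division"]["Treg"]
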