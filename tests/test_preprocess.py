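"""Preprocessing chains: filters, peak detection, artifact and outlier rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import preprocess as pp
from dyadsync import simulate
from dyadsync.simulate import DyadSimConfig
from dyadsync.types import SignalRecording

from conftest import detection_metrics


def _rec(x, fs, channel="rsp"):
    return SignalRecording(channel=channel, fs=fs, samples=np.asarray(x, dtype=float))


class TestBandpass:
    def test_dc_rejection(self):
        rec = _rec(np.full(5000, 3.7), 500.0, "ecg")
        out = pp.bandpass(rec, 1.0, 100.0, order=4)
        assert abs(out.samples.mean()) < 1e-6 * 3.7

    def test_passband_and_stopband_gain(self):
        fs = 20.0
        t = np.arange(0, 600, 1 / fs)
        mid = slice(2000, -2000)  # steady state away from edges
        for f, min_gain, max_gain in [(0.2, 0.95, 1.05), (5.0, 0.0, 0.01)]:
            rec = _rec(np.sin(2 * np.pi * f * t), fs)
            out = pp.bandpass(rec, 0.04, 0.4, order=4)
            gain = out.samples[mid].std() / rec.samples[mid].std()
            assert min_gain <= gain <= max_gain, f"gain {gain} at {f} Hz"

    def test_cutoff_above_nyquist_rejected(self):
        rec = _rec(np.random.default_rng(0).standard_normal(1000), 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass(rec, 1.0, 60.0)

    def test_passband_idempotence(self):
        """A signal already confined to the passband is nearly unchanged."""
        fs = 20.0
        rng = np.random.default_rng(1)
        x = simulate.band_limited_noise(12000, fs, 0.08, 0.3, rng)
        out = pp.bandpass(_rec(x, fs), 0.04, 0.4, order=4)
        mid = slice(1000, -1000)
        assert abs(out.samples[mid].std() / x[mid].std() - 1.0) < 0.05


class TestRPeakDetection:
    def test_noiseless_recovery_within_2ms(self, noiseless_ecg_truth):
        ibi, _, filtered, truth = noiseless_ecg_truth
        peaks, template = pp.detect_r_peaks(filtered)
        assert peaks.size == truth.size
        assert np.abs(peaks - truth).max() <= 0.002
        # detected IBIs match generating IBIs beat by beat
        det_ibis = np.diff(peaks) * 1000.0
        true_ibis = np.diff(truth) * 1000.0
        assert np.abs(det_ibis - true_ibis).max() <= 2.0
        assert template.size > 0

    def test_flat_signal_raises_no_template(self):
        rec = _rec(np.zeros(10_000), 1000.0, "ecg")
        with pytest.raises(ValueError, match="no QRS template"):
            pp.detect_r_peaks(rec)

    def test_snr10_sensitivity_precision(self):
        cfg = DyadSimConfig(duration_s=60.0, seed=17)
        ibi = simulate.simulate_ibi_process(cfg)
        clean, _ = simulate.simulate_ecg(ibi, 1000.0)
        sd = simulate.noise_sd_for_snr(clean.samples, 10.0)
        noisy, truth = simulate.simulate_ecg(ibi, 1000.0, noise_sd=sd, seed=99)
        filtered = pp.bandpass(noisy, 1.0, 100.0, order=4)
        peaks, _ = pp.detect_r_peaks(filtered)
        sens, prec = detection_metrics(peaks, truth, 0.010)
        assert sens >= 0.97 and prec >= 0.97

    def test_refractory_blocks_double_detection(self, noiseless_ecg_truth):
        _, _, filtered, _ = noiseless_ecg_truth
        peaks, _ = pp.detect_r_peaks(filtered)
        assert np.diff(peaks).min() >= pp.REFRACTORY_S


class TestBuildIbi:
    def test_simple_intervals(self):
        series = pp.build_ibi(np.array([0.0, 0.8, 1.6, 2.4]))
        np.testing.assert_allclose(series.ibis_ms, [800.0, 800.0, 800.0])
        assert series.mean_ibi_ms == pytest.approx(800.0)
        # 800 ms mean IBI corresponds to 75 bpm heart rate
        assert 60_000.0 / series.mean_ibi_ms == pytest.approx(75.0)

    def test_modulation_frequency_preserved(self):
        """0.1 Hz sinusoidal IBI modulation dominates the interpolated trace."""
        from scipy.signal import periodogram

        t, peaks = 0.0, [0.0]
        while t < 300.0:
            t += (800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * t)) / 1000.0
            peaks.append(t)
        series = pp.build_ibi(np.array(peaks))
        f, pxx = periodogram(series.interp_trace, fs=series.interp_fs)
        assert abs(f[np.argmax(pxx)] - 0.10) <= 0.01

    @pytest.mark.parametrize("peaks", [[0.0, 0.8], [0.0, 0.8, 0.5]])
    def test_bad_peaks_rejected(self, peaks):
        with pytest.raises(ValueError):
            pp.build_ibi(np.array(peaks))


class TestExpirations:
    def test_pure_sinusoid_count(self):
        fs = 50.0
        t = np.arange(0, 60, 1 / fs)
        rec = _rec(np.sin(2 * np.pi * 0.35 * t), fs)
        onsets, rate = pp.detect_expirations(rec)
        assert abs(onsets.size - 21) <= 1
        assert rate == pytest.approx(onsets.size, abs=0.01)

    def test_generator_rate_recovered(self):
        cfg = DyadSimConfig(duration_s=300.0, fs_rsp=50.0, rsp_rate_bpm=21.1, seed=8)
        rec, _ = simulate.simulate_respiration(cfg)
        _, rate = pp.detect_expirations(rec)
        assert abs(rate - 20.0) <= 0.5

    def test_flat_signal_rejected(self):
        rec = _rec(np.ones(3000), 50.0)
        with pytest.raises(ValueError):
            pp.detect_expirations(rec)


class TestPhasicSc:
    def test_linear_drift_removed(self):
        fs = 50.0
        drift = np.linspace(0.0, 2.0, int(300 * fs))
        out = pp.extract_phasic_sc(_rec(drift, fs, "sc"))
        assert abs(out.samples.mean()) < 0.01 * 2.0

    def test_scr_kernel_peak_preserved(self):
        fs = 50.0
        x = np.zeros(int(60 * fs))
        kern = simulate.scr_kernel(fs)
        x[int(10 * fs):int(10 * fs) + kern.size] = 0.5 * kern
        out = pp.extract_phasic_sc(_rec(x, fs, "sc"))
        t_true = 10.0 + np.argmax(kern) / fs
        t_det = np.argmax(out.samples) / fs
        assert abs(t_det - t_true) <= 0.5

    def test_zero_in_zero_out(self):
        out = pp.extract_phasic_sc(_rec(np.zeros(3000), 50.0, "sc"))
        assert np.abs(out.samples).max() == 0.0

    def test_wrong_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.extract_phasic_sc(_rec(np.zeros(3000), 50.0, "rsp"))


def _rsp_fixture_set(null_run_s=0.0, fs=10.0, duration_s=300.0, var_boost=None):
    """Sample of respiration recordings; one participant optionally corrupted."""
    rng = np.random.default_rng(42)
    recs = {}
    for p in range(6):
        per_video = []
        for _ in range(3):
            t = np.arange(0, duration_s, 1 / fs)
            x = 300.0 * np.sin(2 * np.pi * 0.33 * t) + rng.normal(0, 5, t.size)
            per_video.append(_rec(x, fs))
        recs[f"p{p}"] = per_video
    if null_run_s > 0:
        x = recs["p0"][0].samples.copy()
        x[: int(null_run_s * fs)] = 0.0
        recs["p0"][0] = _rec(x, fs)
    if var_boost is not None:
        recs["p1"][1] = _rec(recs["p1"][1].samples * var_boost, fs)
    return recs


class TestRspArtifacts:
    def test_null_run_above_5pct_fires(self):
        reports = pp.flag_rsp_artifacts(_rsp_fixture_set(null_run_s=16.0))
        assert reports["p0"].excluded
        assert reports["p0"].rules_fired["rsp_null_run"] == [0]

    def test_null_run_below_5pct_passes(self):
        reports = pp.flag_rsp_artifacts(_rsp_fixture_set(null_run_s=14.0))
        assert not reports["p0"].excluded

    def test_variance_rule_fires_on_inflated_recording(self):
        reports = pp.flag_rsp_artifacts(_rsp_fixture_set(var_boost=6.0))
        assert reports["p1"].excluded
        assert 1 in reports["p1"].rules_fired["rsp_variance"]
        assert all(not reports[f"p{p}"].excluded for p in (0, 2, 3, 4, 5))

    def test_single_participant_rejected(self):
        recs = {"p0": _rsp_fixture_set()["p0"]}
        with pytest.raises(ValueError):
            pp.flag_rsp_artifacts(recs)


def _sc_fixture(duration_s=300.0, fs=20.0, scrs=(3, 3, 3), slope_frac=0.0):
    rng = np.random.default_rng(7)
    per_video = []
    kern = simulate.scr_kernel(fs)
    for v in range(3):
        x = np.full(int(duration_s * fs), 5.0)
        times = np.linspace(20, duration_s - 30, max(scrs[v], 1))[: scrs[v]]
        for et in times:
            idx = int(et * fs)
            x[idx:idx + kern.size] += 0.5 * kern[: x.size - idx]
        if slope_frac > 0 and v == 0:
            n_ramp = int(slope_frac * duration_s * fs)
            x[-n_ramp:] += np.arange(n_ramp) / fs * 3.0  # 3 uS/s ramp
        x += rng.normal(0, 0.002, x.size)
        per_video.append(_rec(x, fs, "sc"))
    return per_video


class TestScArtifacts:
    def test_unresponsive_requires_all_three_videos(self):
        recs = {"p0": _sc_fixture(scrs=(0, 0, 3)), "p1": _sc_fixture(scrs=(0, 0, 0)),
                "p2": _sc_fixture()}
        reports = pp.flag_sc_artifacts(recs)
        assert not reports["p0"].excluded
        assert reports["p1"].excluded
        assert reports["p1"].rules_fired["sc_unresponsive"] == [0, 1, 2]
        assert not reports["p2"].excluded

    def test_slope_rule_fires_above_5pct(self):
        reports = pp.flag_sc_artifacts({"p0": _sc_fixture(slope_frac=0.06),
                                        "p1": _sc_fixture()})
        assert reports["p0"].excluded
        assert reports["p0"].rules_fired["sc_slope"] == [0]
        assert not reports["p1"].excluded

    def test_clean_generator_output_passes(self):
        cfg = DyadSimConfig(duration_s=120.0, fs_sc=20.0, seed=3)
        recs = {"p0": [simulate.simulate_sc(cfg.for_condition(c))[0]
                       for c in ("negative", "neutral", "positive")]}
        reports = pp.flag_sc_artifacts(recs)
        assert not reports["p0"].excluded


class TestStatisticalOutliers:
    def test_documented_bounds(self):
        # quartiles Q1=10, Q3=20 -> bounds [-20, 50]
        values = [10, 10, 10, 10, 20, 20, 20, 20, 49, -19, 55, -21]
        mask = pp.flag_statistical_outliers(values)
        assert mask.tolist() == [False] * 10 + [True, True]

    def test_constant_vector_flags_nothing(self):
        assert not pp.flag_statistical_outliers([5.0] * 8).any()
        mask = pp.flag_statistical_outliers([5.0] * 7 + [6.0])
        assert mask.tolist() == [False] * 7 + [True]

    def test_gaussian_flag_rate_negligible(self):
        x = np.random.default_rng(0).standard_normal(20_000)
        assert pp.flag_statistical_outliers(x).mean() < 0.001

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pp.flag_statistical_outliers([1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40),
           st.floats(0.1, 10.0), st.floats(-100.0, 100.0))
    def test_affine_equivariance(self, values, a, b):
        """Flags are unchanged under affine transforms of the whole vector."""
        base = pp.flag_statistical_outliers(values)
        transformed = pp.flag_statistical_outliers([a * v + b for v in values])
        assert base.tolist() == transformed.tolist()
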