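import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ecgseg as es
from ecgseg.pantompkins import PanTompkinsDetector


class TestBandpass:
    def test_zero_in_zero_out(self):
        assert np.allclose(es.bandpass(np.zeros(2000), 360.0), 0.0)

    @pytest.mark.parametrize("freq,bound,mode", [
        (10.0, 0.7, "ge"),   # passband center
        (0.3, 0.1, "le"),    # baseline-wander stop band
    ])
    def test_frequency_response(self, freq, bound, mode):
        fs = 360.0
        t = np.arange(int(10 * fs)) / fs
        y = es.bandpass(np.sin(2 * np.pi * freq * t), fs)
        amp = np.max(np.abs(y[int(3 * fs): int(7 * fs)]))
        assert (amp >= bound) if mode == "ge" else (amp <= bound)

    def test_length_preserved_and_delay_reported(self):
        x = np.random.default_rng(0).standard_normal(1500)
        y, delay = es.bandpass(x, 360.0, return_delay=True)
        assert y.size == x.size
        assert delay == (361 - 1) // 2

    def test_rejects_low_fs(self):
        with pytest.raises(ValueError):
            es.bandpass(np.zeros(500), 99.0)


class TestDerivative:
    def test_constant_gives_zero_interior(self):
        y = es.derivative(np.full(50, 7.0), 360.0)
        assert np.allclose(y[4:], 0.0)

    def test_ramp_gives_constant_slope_response(self):
        # plugging x[k] = m*k into (fs/8)(2x[n]+x[n-1]-x[n-3]-2x[n-4])
        # leaves (fs/8) * 10m in the interior
        fs, m = 360.0, 0.5
        y = es.derivative(m * np.arange(100), fs)
        assert np.allclose(y[10:], m * fs * 10 / 8)

    def test_impulse_reproduces_kernel(self):
        fs = 360.0
        x = np.zeros(20)
        x[5] = 1.0
        y = es.derivative(x, fs)
        assert np.allclose(y[5:10], np.array([2, 1, 0, -1, -2]) * fs / 8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            es.derivative(np.zeros(4), 360.0)


class TestSquare:
    def test_definition(self):
        assert np.array_equal(es.square(np.array([-1.0, 2.0, 0.0])), [1.0, 4.0, 0.0])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(1, 50),
                      elements=st.floats(-1e3, 1e3)))
    def test_even_and_nonnegative(self, x):
        assert np.array_equal(es.square(x), es.square(-x))
        assert np.all(es.square(x) >= 0)


class TestMovingWindowIntegrate:
    def test_constant_steady_state(self):
        y = es.moving_window_integrate(np.full(500, 2.5), 360.0)
        assert np.allclose(y[60:], 2.5)

    def test_impulse_plateau(self):
        x = np.zeros(300)
        x[100] = 1.0
        y = es.moving_window_integrate(x, 360.0, width_ms=150)
        n = round(0.150 * 360)  # 54 samples
        assert n == 54
        plateau = y[100: 100 + n]
        assert np.allclose(plateau, 1.0 / n)
        assert np.allclose(y[100 + n:], 0.0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            es.moving_window_integrate(np.zeros(10), 360.0, width_ms=150)


class TestDetect:
    def test_flat_record_yields_nothing(self):
        rec = es.ECGRecord(samples=np.zeros(3000), fs=360.0)
        assert len(es.detect(rec)) == 0

    def test_clean_record_all_beats_within_10_samples(self, clean_record):
        res = es.detect(clean_record)
        assert len(res) == clean_record.r_peaks.size
        for p in res.peaks:
            assert np.min(np.abs(clean_record.r_peaks - p)) <= 10

    def test_impulse_pair_within_refractory_gives_one_detection(self, clean_record):
        x = clean_record.samples.copy()
        fs = clean_record.fs
        # two large impulses 50 ms apart in mid-diastole
        mid = int((clean_record.r_peaks[5] + clean_record.r_peaks[6]) / 2)
        gap = int(round(0.050 * fs))
        x[mid] += 3.0
        x[mid + gap] += 3.0
        res = es.detect(es.ECGRecord(samples=x, fs=fs))
        near = [p for p in res.peaks if abs(p - mid) <= int(0.1 * fs) + gap]
        assert len(near) <= 1

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            es.detect(es.ECGRecord(samples=np.zeros(500), fs=360.0))

    def test_scale_equivariance(self, clean_record):
        base = es.detect(clean_record).peaks
        for c in (0.01, 3.7, 1e4):
            scaled = es.ECGRecord(samples=c * clean_record.samples, fs=clean_record.fs)
            assert np.array_equal(es.detect(scaled).peaks, base)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_refractory_invariant_on_noise(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(4000) * rng.uniform(0.1, 10)
        res = es.detect(es.ECGRecord(samples=x, fs=360.0))
        if len(res) > 1:
            assert np.min(np.diff(res.peaks)) >= round(0.2 * 360)

    def test_noisy_records_high_se_and_pp(self):
        rng = np.random.default_rng(11)
        TP = FP = FN = 0
        for _ in range(5):
            rec = es.generate_record(
                15, fs=360, mean_rr=float(rng.uniform(0.7, 1.1)), rr_jitter=0.05,
                noise=[es.NoiseSpec("baseline_wander", 0.15),
                       es.NoiseSpec("highfreq", 0.05)],
                seed=int(rng.integers(0, 2**31)))
            tp, fp, fn = es.match_detections(es.detect(rec).peaks, rec.r_peaks, tol=15)
            TP, FP, FN = TP + tp, FP + fp, FN + fn
        m = es.compute_metrics(TP, FP, FN)
        assert m.se >= 95.0 and m.pp >= 95.0


class TestDetectorEstimator:
    def test_get_set_params_roundtrip(self):
        det = PanTompkinsDetector(searchback_factor=1.5)
        params = det.get_params()
        assert params["searchback_factor"] == 1.5
        det.set_params(integration_width_ms=120.0)
        assert det.integration_width_ms == 120.0
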