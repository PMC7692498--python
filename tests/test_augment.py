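import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgseg as es
from ecgseg.augment import window_ms_to_samples, window_samples_to_ms


def _ramp_record(n=1000, fs=360.0, peaks=()):
    return es.ECGRecord(samples=np.arange(n, dtype=float), fs=fs,
                        r_peaks=np.asarray(peaks, dtype=np.int64), record_id="ramp")


class TestExtractWindow:
    def test_centered_slice_arithmetic(self):
        w = es.extract_window(_ramp_record(), center=500, length=300)
        assert np.array_equal(w, np.arange(350, 650, dtype=float))

    def test_out_of_bounds_is_distinguishable(self):
        with pytest.raises(es.WindowOutOfBounds):
            es.extract_window(_ramp_record(), center=100, length=300)

    def test_degenerate_single_sample(self):
        w = es.extract_window(_ramp_record(), center=42, length=1)
        assert np.array_equal(w, [42.0])


class TestAttenuateWave:
    def test_frac_zero_is_identity(self):
        x = np.random.default_rng(0).standard_normal(300)
        assert np.array_equal(es.attenuate_wave(x, "p_wave", 0.0, 375, 360), x)

    def test_p_wave_region_indices(self):
        x = np.ones(300)
        out = es.attenuate_wave(x, "p_wave", 0.30, 375, 360)
        # round(0.375 * 360) = 135 samples strictly before center 150
        assert np.allclose(out[15:150], 0.70)
        assert np.allclose(out[:15], 1.0)
        assert np.allclose(out[150:], 1.0)

    def test_t_wave_region_indices(self):
        out = es.attenuate_wave(np.ones(300), "t_wave", 0.30, 375, 360)
        assert np.allclose(out[151:286], 0.70)
        assert out[150] == 1.0
        assert np.allclose(out[286:], 1.0)

    def test_extent_clipped_to_segment(self):
        out = es.attenuate_wave(np.ones(100), "t_wave", 0.5, 375, 360)
        assert np.allclose(out[51:], 0.5)

    def test_bad_frac_rejected(self):
        with pytest.raises(ValueError):
            es.attenuate_wave(np.ones(10), "p_wave", 1.0, 375, 360)


class TestGlobalAttenuate:
    def test_examples(self):
        assert np.allclose(es.global_attenuate(np.array([1.0, -2.0]), 0.40),
                           [0.6, -1.2])
        x = np.arange(5.0)
        assert np.array_equal(es.global_attenuate(x, 0.0), x)

    def test_composition(self):
        x = np.random.default_rng(1).standard_normal(50)
        twice = es.global_attenuate(es.global_attenuate(x, 0.2), 0.25)
        assert np.allclose(twice, es.global_attenuate(x, 0.4))


class TestPositiveVariants:
    def test_eleven_variants_per_eligible_beat(self, clean_record):
        segs = es.positive_variants(clean_record, int(clean_record.r_peaks[5]))
        assert len(segs) == 11
        tags = {s.variant for s in segs}
        assert tags == {"centered", "shift+5", "shift-5", "shift+10", "shift-10",
                        "shift+15", "shift-15", "p_atten", "t_atten",
                        "global20", "global40"}
        assert all(s.label == "beat" for s in segs)
        assert all(s.values.size == 300 for s in segs)

    def test_degenerate_config_keeps_only_centered(self, clean_record):
        cfg = es.AugmentationConfig(shifts=(), global_atten_fracs=(),
                                    wave_atten_frac=0.0)
        segs = es.positive_variants(clean_record, int(clean_record.r_peaks[5]), cfg)
        assert len(segs) == 1
        assert segs[0].variant == "centered"
        assert cfg.variants_per_beat == 1

    def test_edge_beat_skipped_entirely(self):
        rec = _ramp_record(n=1000, peaks=[10, 500])
        assert es.positive_variants(rec, 10) == []

    def test_shift_convention_positive_means_r_right_of_center(self, clean_record):
        r = int(clean_record.r_peaks[5])
        segs = {s.variant: s for s in es.positive_variants(clean_record, r)}
        plus = segs["shift+15"].values
        # R sits 15 samples right of center: argmax at 150 + 15
        assert int(np.argmax(plus)) == 150 + 15
        minus = segs["shift-15"].values
        assert int(np.argmax(minus)) == 150 - 15

    def test_total_count_is_multiplier_times_eligible(self, clean_record):
        total = sum(len(es.positive_variants(clean_record, int(r)))
                    for r in clean_record.r_peaks)
        eligible = sum(
            1 for r in clean_record.r_peaks
            if r - 15 - 150 >= 0 and r + 15 + 150 <= len(clean_record))
        assert total == 11 * eligible

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(c=st.floats(0.1, 10))
    def test_amplitude_linearity(self, c, clean_record):
        r = int(clean_record.r_peaks[5])
        base = es.positive_variants(clean_record, r)
        scaled_rec = es.ECGRecord(samples=c * clean_record.samples,
                                  fs=clean_record.fs, r_peaks=clean_record.r_peaks,
                                  record_id="scaled")
        scaled = es.positive_variants(scaled_rec, r)
        for a, b in zip(base, scaled):
            assert np.allclose(c * a.values, b.values, rtol=1e-12)


class TestNegativeWindows:
    def test_enumerated_window_count(self):
        rec = _ramp_record(n=1400, peaks=[0, 1000])
        segs = es.negative_windows(rec, window_len=300)
        starts = [s.center - 150 for s in segs]
        assert starts == list(range(50, 651, 5))
        assert len(segs) == 121
        assert all(s.label == "non_beat" for s in segs)

    def test_interval_too_short_yields_none(self):
        rec = _ramp_record(n=800, peaks=[100, 400])
        assert es.negative_windows(rec, window_len=300) == []

    def test_two_window_boundary_case(self):
        rec = _ramp_record(n=800, peaks=[0, 405])
        segs = es.negative_windows(rec, window_len=300)
        assert [s.center - 150 for s in segs] == [50, 55]

    def test_needs_two_beats(self):
        with pytest.raises(ValueError):
            es.negative_windows(_ramp_record(peaks=[500]), window_len=300)

    def test_no_negative_center_near_any_r_peak(self):
        rec = es.generate_record(10, fs=360, mean_rr=1.3, rr_jitter=0.1, seed=3)
        segs = es.negative_windows(rec, window_len=300)
        assert segs  # the slow rhythm leaves room
        for s in segs:
            assert np.min(np.abs(rec.r_peaks - s.center)) > 15


class TestBuildSegments:
    def test_windows_resampled_to_model_length(self):
        rec = es.generate_record(6, fs=1000, mean_rr=1.3, rr_jitter=0.0, seed=2)
        segs = es.build_segments([rec], model_len=300)
        assert segs
        assert all(s.values.size == 300 for s in segs)
        # 833 ms at 1000 Hz is 833 native samples
        assert window_ms_to_samples(833, 1000) == 833

    def test_no_augment_keeps_one_positive_per_beat(self, clean_record):
        segs = es.build_segments([clean_record], augment=False)
        pos = [s for s in segs if s.label == "beat"]
        assert all(s.variant == "centered" for s in pos)


def test_window_arithmetic():
    assert window_ms_to_samples(833, 360) == 300
    assert window_samples_to_ms(300, 360) == 833
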