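import itertools

import numpy as np
import pytest

import ecgseg as es
from ecgseg.records import DetectionResult
from ecgseg.validator import BEAT

from conftest import SMALL_NET


class TestMatchDetections:
    def test_perfect_match(self):
        truth = np.array([100, 400, 700])
        assert es.match_detections(truth, truth, tol=0) == (3, 0, 0)
        assert es.match_detections(truth, truth, tol=15) == (3, 0, 0)

    def test_one_to_one_rule(self):
        # two detections near one truth peak: only one may claim it
        assert es.match_detections([110, 112], [100], tol=15) == (1, 1, 0)

    def test_empty_detector(self):
        assert es.match_detections([], [10, 20, 30], tol=15) == (0, 0, 3)

    def test_count_identities(self):
        rng = np.random.default_rng(0)
        truth = np.sort(rng.choice(10000, 40, replace=False))
        det = np.sort(rng.choice(10000, 55, replace=False))
        tp, fp, fn = es.match_detections(det, truth, tol=15)
        assert tp + fp == det.size
        assert tp + fn == truth.size

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            es.match_detections([20, 10], [5], tol=15)
        with pytest.raises(ValueError):
            es.match_detections([5], [20, 10], tol=15)

    def test_equal_distance_ties_give_stable_totals(self):
        # detection equidistant between two truth peaks and vice versa:
        # totals must not depend on tie ordering
        truth = [100, 130]
        det = [115]
        assert es.match_detections(det, truth, tol=15) == (1, 0, 1)
        truth2 = [115]
        det2 = [100, 130]
        assert es.match_detections(det2, truth2, tol=15) == (1, 1, 0)


class TestComputeMetrics:
    def test_perfection(self):
        m = es.compute_metrics(10, 0, 0)
        assert (m.se, m.pp) == (100.0, 100.0)
        assert m.f == 1.0

    @pytest.mark.parametrize("se,pp,expected", [
        (95.79, 97.84, 0.97),
        (92.98, 100.00, 0.96),
        (96.95, 90.28, 0.93),
        (95.71, 96.77, 0.96),
    ])
    def test_fscore_worked_examples(self, se, pp, expected):
        assert round(es.fscore_from_se_pp(se, pp), 2) == expected

    def test_zero_denominators_are_explicit_none(self):
        m = es.compute_metrics(0, 0, 0)
        assert m.se is None and m.pp is None and m.f is None
        m2 = es.compute_metrics(0, 5, 0)
        assert m2.se is None and m2.pp == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            es.compute_metrics(-1, 0, 0)

    def test_exact_rational_formulas(self):
        m = es.compute_metrics(191, 7, 9)
        assert m.se == 100 * 191 / 200
        assert m.pp == 100 * 191 / 198
        assert m.f == 2 * (m.pp * m.se) / (m.pp + m.se) / 100


class _StubValidator:
    """Fixed-decision stand-in for the CNN (accept-all / reject-all)."""

    def __init__(self, accept: bool, input_len: int = 300):
        self.input_len = input_len
        self._accept = accept

    def predict(self, X):
        v = BEAT if self._accept else 1 - BEAT
        return np.full(np.asarray(X).shape[0], v)


class TestValidateDetections:
    def test_accept_all_returns_interior_detections(self, clean_record):
        det = DetectionResult(peaks=clean_record.r_peaks.copy())
        out = es.validate_detections(clean_record, det, _StubValidator(True))
        # every window fits (beats are one RR from the edges)
        assert np.array_equal(out, det.peaks)

    def test_reject_all_returns_empty(self, clean_record):
        det = DetectionResult(peaks=clean_record.r_peaks.copy())
        out = es.validate_detections(clean_record, det, _StubValidator(False))
        assert out.size == 0

    def test_boundary_detection_rejected(self, clean_record):
        det = DetectionResult(peaks=np.array([5, int(clean_record.r_peaks[3])]))
        out = es.validate_detections(clean_record, det, _StubValidator(True))
        assert list(out) == [int(clean_record.r_peaks[3])]

    def test_trained_model_suppresses_injected_fps(self, end_to_end_report):
        """In the scaled experiment the validator must reject >= 80% of the
        injected spurious peaks while discarding <= 10% of the true ones."""
        rejected_fp = total_fp = rejected_tp = total_tp = 0
        for row in end_to_end_report["per_record"]:
            truth = np.asarray(row["truth_peaks"])
            accepted = set(row["accepted_peaks"])
            for p in row["detected_peaks"]:
                is_true = int(np.min(np.abs(truth - p))) <= 15
                if is_true:
                    total_tp += 1
                    rejected_tp += p not in accepted
                else:
                    total_fp += 1
                    rejected_fp += p not in accepted
        assert total_fp > 0
        assert rejected_fp / total_fp >= 0.8
        assert rejected_tp / total_tp <= 0.1


@pytest.fixture(scope="module")
def tiny_report():
    cfg = es.ExperimentConfig(
        n_train_records=4, n_test_records=3, beats_per_record=10,
        epochs=4, validator_params=dict(SMALL_NET), seed=11)
    return es.run_experiment(cfg)


class TestRunExperiment:
    def test_validator_improves_positive_predictivity(self, tiny_report):
        assert tiny_report["validated"]["pp"] > tiny_report["raw"]["pp"]

    def test_subset_theorem(self, tiny_report):
        raw, val = tiny_report["raw"], tiny_report["validated"]
        assert val["tp"] <= raw["tp"]
        assert val["fp"] <= raw["fp"]
        assert val["se"] <= raw["se"]

    def test_per_record_breakdown_present(self, tiny_report):
        assert len(tiny_report["per_record"]) == 3
        for row in tiny_report["per_record"]:
            assert row["n_accepted"] <= row["n_detections"]

    def test_subject_overlap_is_hard_error(self):
        cfg = es.ExperimentConfig(n_train_records=2, n_test_records=2,
                                  beats_per_record=6, epochs=1, seed=0)
        recs = [es.generate_record(6, mean_rr=1.2, seed=i, record_id=f"r{i}",
                                   subject_id="same") for i in range(2)]
        from unittest import mock
        with mock.patch("ecgseg.evaluate._generate_set", return_value=recs):
            with pytest.raises(ValueError, match="overlap"):
                es.run_experiment(cfg)
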