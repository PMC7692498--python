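"""Detector-vs-validated evaluation: tolerance matching and Se / +P / F.

A detection is a true positive when it lies within ±`tol` samples of an
annotated R-peak under greedy one-to-one matching (the tolerance equals
the largest shift used in data augmentation, 15 samples at 360 Hz).
Metrics are

    Se = 100 * TP / (TP + FN)      (sensitivity, %)
    +P = 100 * TP / (TP + FP)      (positive predictivity, %)
    F  = 2 * (+P * Se) / (+P + Se) / 100   (harmonic mean, unitless)

pooled over all test records (micro-average).  The validated pipeline
accepts only detections whose centered window the CNN labels as a beat,
so validated TP, FP and Se can never exceed the raw detector's — the
subset theorem asserted on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .augment import WindowOutOfBounds, extract_window, window_ms_to_samples
from .io import resample_to_length
from .records import DetectionResult, ECGRecord
from .synthetic import NoiseSpec, corrupt_detections, generate_record
from .validator import BEAT, BeatValidatorCNN

__all__ = [
    "EvalMetrics",
    "compute_metrics",
    "fscore_from_se_pp",
    "match_detections",
    "validate_detections",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass(frozen=True)
class EvalMetrics:
    """Counts and derived segmentation metrics; ``None`` marks an
    undefined ratio (zero denominator)."""

    tp: int
    fp: int
    fn: int
    se: float | None
    pp: float | None
    f: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(tp: int, fp: int, fn: int) -> EvalMetrics:
    """Exact Se / +P / F from counts; zero denominators yield ``None``."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    pp = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    f = fscore_from_se_pp(se, pp)
    return EvalMetrics(tp=tp, fp=fp, fn=fn, se=se, pp=pp, f=f)


def fscore_from_se_pp(se: float | None, pp: float | None) -> float | None:
    """Harmonic mean of sensitivity and positive predictivity (in %),
    returned on the unit scale."""
    if se is None or pp is None or (se + pp) == 0:
        return None
    return 2.0 * (pp * se) / (pp + se) / 100.0


def match_detections(detected, truth, tol: int = 15) -> tuple[int, int, int]:
    """Greedy one-to-one matching by increasing distance.

    Pairs within ``±tol`` samples are considered, closest first (ties
    broken by earlier detection index, then earlier truth index); each
    detection and each truth peak may be claimed once.  Returns
    ``(TP, FP, FN)`` with ``TP + FP == len(detected)`` and
    ``TP + FN == len(truth)``.
    """
    detected = np.asarray(detected, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if detected.size and np.any(np.diff(detected) < 0):
        raise ValueError("detected indices must be sorted")
    if truth.size and np.any(np.diff(truth) < 0):
        raise ValueError("truth indices must be sorted")
    if tol < 0:
        raise ValueError("tolerance must be >= 0")

    pairs = []
    for i, d in enumerate(detected):
        # truth peaks within tolerance of this detection
        lo = np.searchsorted(truth, d - tol, side="left")
        hi = np.searchsorted(truth, d + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(int(d) - int(truth[j])), i, j))
    pairs.sort()

    used_d = np.zeros(detected.size, dtype=bool)
    used_t = np.zeros(truth.size, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            tp += 1
    return tp, int(detected.size - tp), int(truth.size - tp)


def validate_detections(record: ECGRecord, detections: DetectionResult,
                        model: BeatValidatorCNN,
                        window_ms: float = 833.0) -> np.ndarray:
    """Keep only the detections whose centered window the CNN calls a beat.

    A window of ``window_ms`` at the record's native rate is cut around
    each detection, resampled to the model's input length when the rates
    differ, and fed forward.  Detections whose window does not fit inside
    the record are rejected.
    """
    L = window_ms_to_samples(window_ms, record.fs)
    windows, keepable = [], []
    for p in detections.peaks:
        try:
            w = extract_window(record, int(p), L)
        except WindowOutOfBounds:
            continue
        if w.size != model.input_len:
            w = resample_to_length(w, model.input_len)
        windows.append(w)
        keepable.append(int(p))
    if not windows:
        return np.empty(0, dtype=np.int64)
    X = np.stack(windows)
    accepted = model.predict(X) == BEAT
    return np.asarray([p for p, a in zip(keepable, accepted) if a], dtype=np.int64)


# ---------------------------------------------------------------------------
# End-to-end synthetic experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Configuration of the synthetic end-to-end experiment.

    Training records are generated with one set of subject ids and test
    records with another, so the split is subject-disjoint by
    construction.  ``mean_rr`` defaults to 1.2 s: with an 833-ms window
    and 50-sample margins, inter-beat negative windows only exist when
    the RR interval exceeds ~1.11 s at 360 Hz, so a slower rhythm is what
    makes the published negative-sampling rule productive.

    ``fp_rate``/``fn_rate``/``det_jitter`` corrupt the detector output on
    test records, emulating a detector with a known false-positive
    burden whose suppression the validator is measured on.
    """

    n_train_records: int = 20
    n_test_records: int = 10
    beats_per_record: int = 20
    fs: float = 360.0
    mean_rr: float = 1.2
    rr_jitter: float = 0.05
    train_noise: tuple = (("baseline_wander", 0.10, 0.3), ("highfreq", 0.03, 25.0))
    test_noise: tuple = (("baseline_wander", 0.15, 0.3), ("highfreq", 0.05, 25.0))
    fp_rate: float = 0.10
    fn_rate: float = 0.0
    det_jitter: int = 0
    window_ms: float = 833.0
    model_len: int = 300
    epochs: int = 10
    validator_params: dict = field(default_factory=dict)
    seed: int = 0

    def noise_specs(self, which: str) -> list[NoiseSpec]:
        src = self.train_noise if which == "train" else self.test_noise
        return [NoiseSpec(kind=k, amplitude=a, freq_hz=f) for k, a, f in src]


def _generate_set(cfg: ExperimentConfig, which: str, n: int,
                  rng: np.random.Generator) -> list[ECGRecord]:
    recs = []
    for i in range(n):
        seed = int(rng.integers(0, 2**31 - 1))
        recs.append(generate_record(
            n_beats=cfg.beats_per_record, fs=cfg.fs, mean_rr=cfg.mean_rr,
            rr_jitter=cfg.rr_jitter, noise=cfg.noise_specs(which), seed=seed,
            record_id=f"{which}{i:03d}", subject_id=f"subj-{which}-{i:03d}"))
    return recs


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Train the validator on augmented synthetic records and compare the
    raw (corrupted) detector against the validated pipeline on held-out
    records.

    Returns a report with pooled ``raw`` and ``validated`` metric rows,
    per-record breakdowns and the accepted peak lists.  Raises if the
    subset theorem (validated TP/FP/Se never exceed raw) is violated —
    that would indicate an implementation defect, not a modelling choice.
    """
    from .augment import AugmentationConfig, build_segments
    from .pantompkins import PanTompkinsDetector
    from .validator import train_validator

    rng = np.random.default_rng(cfg.seed)
    train_records = _generate_set(cfg, "train", cfg.n_train_records, rng)
    test_records = _generate_set(cfg, "test", cfg.n_test_records, rng)

    train_subj = {r.subject_id for r in train_records}
    test_subj = {r.subject_id for r in test_records}
    if train_subj & test_subj:
        raise ValueError(f"subject overlap between train and test: {train_subj & test_subj}")

    aug_cfg = AugmentationConfig(window_ms=cfg.window_ms)
    segments = build_segments(train_records, aug_cfg, model_len=cfg.model_len,
                              augment=True)
    params = {"input_len": cfg.model_len, "epochs": cfg.epochs,
              "random_state": int(rng.integers(0, 2**31 - 1))}
    params.update(cfg.validator_params)
    model = train_validator(segments, **params)

    detector = PanTompkinsDetector()
    tol = int(round(15 / 360 * cfg.fs))
    raw_tp = raw_fp = raw_fn = 0
    val_tp = val_fp = val_fn = 0
    per_record = []
    for rec in test_records:
        det = detector.detect(rec)
        if cfg.fp_rate or cfg.fn_rate or cfg.det_jitter:
            det = corrupt_detections(det.peaks, cfg.fp_rate, cfg.fn_rate,
                                     cfg.det_jitter, len(rec),
                                     seed=int(rng.integers(0, 2**31 - 1)),
                                     min_gap_from_truth=int(round(0.2 * cfg.fs)))
        accepted = validate_detections(rec, det, model, window_ms=cfg.window_ms)

        r = match_detections(det.peaks, rec.r_peaks, tol=tol)
        v = match_detections(accepted, rec.r_peaks, tol=tol)
        raw_tp += r[0]; raw_fp += r[1]; raw_fn += r[2]
        val_tp += v[0]; val_fp += v[1]; val_fn += v[2]
        per_record.append({
            "record_id": rec.record_id,
            "raw": compute_metrics(*r).as_dict(),
            "validated": compute_metrics(*v).as_dict(),
            "n_detections": int(det.peaks.size),
            "n_accepted": int(accepted.size),
            "detected_peaks": [int(p) for p in det.peaks],
            "accepted_peaks": [int(p) for p in accepted],
            "truth_peaks": [int(p) for p in rec.r_peaks],
        })

    raw = compute_metrics(raw_tp, raw_fp, raw_fn)
    val = compute_metrics(val_tp, val_fp, val_fn)

    # subset theorem: acceptance is a subset of detections
    if not (val.tp <= raw.tp and val.fp <= raw.fp):
        raise AssertionError("subset theorem violated: validated counts exceed raw")
    if raw.se is not None and val.se is not None and val.se > raw.se + 1e-9:
        raise AssertionError("subset theorem violated: validated Se exceeds raw Se")

    return {
        "config": {**asdict(cfg), "validator_params": dict(cfg.validator_params)},
        "tolerance_samples": tol,
        "raw": raw.as_dict(),
        "validated": val.as_dict(),
        "per_record": per_record,
        "n_train_segments": len(segments),
        "final_val_err": model.history_[-1]["val_err"] if model.history_ else None,
    }
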