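"""Synthetic annotated ECG generation.

Beats are modelled as a sum of five Gaussian waves (P, Q, R, S, T) placed
at quasi-periodic R times, in the spirit of ECGSYN-style simulators.  The
generator returns ground-truth R-peak annotations, so every downstream
stage (detector, augmentation, validator, evaluation) is testable without
downloading an annotated database.  A companion helper corrupts a truth
annotation set with false positives / false negatives to emulate a faulty
third-party detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import DetectionResult, ECGRecord

__all__ = [
    "Wave",
    "BeatTemplate",
    "NoiseSpec",
    "DEFAULT_TEMPLATE",
    "generate_record",
    "corrupt_detections",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian fiducial wave: ``amp * exp(-(t - center)^2 / (2 width^2))``."""

    amplitude: float
    center_s: float  # offset relative to the R peak, seconds
    width_s: float  # Gaussian sigma, seconds

    def __post_init__(self) -> None:
        if not self.width_s > 0:
            raise ValueError("wave width must be > 0")


@dataclass(frozen=True)
class BeatTemplate:
    """Per-wave morphology of one heartbeat.

    The R wave is centered at offset 0 and must dominate every other wave
    in absolute amplitude; P and Q precede it (negative offsets), S and T
    follow it (positive offsets).  Default proportions are textbook values
    relative to R = 1.0.
    """

    p: Wave = Wave(0.15, -0.22, 0.05)
    q: Wave = Wave(-0.10, -0.04, 0.01)
    r: Wave = Wave(1.00, 0.0, 0.02)
    s: Wave = Wave(-0.20, +0.04, 0.01)
    t: Wave = Wave(0.30, +0.30, 0.08)

    def __post_init__(self) -> None:
        for name in ("p", "q", "s", "t"):
            w: Wave = getattr(self, name)
            if abs(w.amplitude) >= self.r.amplitude:
                raise ValueError(f"R amplitude must exceed |{name}| amplitude")
        if not (self.p.center_s < self.q.center_s < 0 < self.s.center_s < self.t.center_s):
            raise ValueError("wave offsets must satisfy P < Q < 0 < S < T")

    @property
    def waves(self) -> tuple[Wave, ...]:
        return (self.p, self.q, self.r, self.s, self.t)

    @property
    def footprint_s(self) -> float:
        """Half-width of the beat: largest |offset| + 3 sigma of that wave."""
        return max(abs(w.center_s) + 3.0 * w.width_s for w in self.waves)


DEFAULT_TEMPLATE = BeatTemplate()

_NOISE_KINDS = ("baseline_wander", "highfreq", "powerline")


@dataclass(frozen=True)
class NoiseSpec:
    """One additive noise component.

    ``amplitude`` is a fraction of the template's R amplitude: the peak
    amplitude for the sinusoidal kinds (baseline wander, powerline) and
    the RMS for band-limited high-frequency noise.  ``freq_hz`` is the
    sinusoid frequency, or the lower band edge for ``highfreq``.
    """

    kind: str
    amplitude: float
    freq_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_NOISE_KINDS}")
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        defaults = {"baseline_wander": 0.3, "highfreq": 25.0, "powerline": 50.0}
        if self.freq_hz == 0.0:
            object.__setattr__(self, "freq_hz", defaults[self.kind])
        if self.freq_hz <= 0:
            raise ValueError("noise frequency must be > 0")


def _render_noise(spec: NoiseSpec, t: np.ndarray, fs: float, r_amp: float,
                  rng: np.random.Generator) -> np.ndarray:
    if spec.freq_hz >= fs / 2:
        raise ValueError(f"noise frequency {spec.freq_hz} Hz at or above Nyquist ({fs / 2} Hz)")
    amp = spec.amplitude * r_amp
    if amp == 0:
        return np.zeros_like(t)
    if spec.kind in ("baseline_wander", "powerline"):
        phase = rng.uniform(0, 2 * np.pi)
        return amp * np.sin(2 * np.pi * spec.freq_hz * t + phase)
    # highfreq: white Gaussian noise high-passed above the band edge,
    # rescaled so its standard deviation equals `amp`
    white = rng.standard_normal(t.size)
    sos = sps.butter(4, spec.freq_hz, btype="highpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    sd = shaped.std()
    if sd > 0:
        shaped *= amp / sd
    return shaped


def generate_record(
    n_beats: int,
    fs: float = 360.0,
    mean_rr: float = 0.8,
    rr_jitter: float = 0.0,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    noise: list[NoiseSpec] | None = None,
    seed: int = 0,
    record_id: str = "",
    subject_id: str = "",
) -> ECGRecord:
    """Generate an annotated synthetic single-lead record.

    R times are ``t_i = mean_rr + sum of jittered RR intervals``; each RR
    interval is ``mean_rr + U(-rr_jitter, +rr_jitter)``.  A lead-in and
    lead-out of one mean RR interval keeps the first and last beats away
    from the record boundary.  Annotations are ``round(t_i * fs)``, the
    ground-truth beat centers.

    Raises
    ------
    ValueError
        If ``mean_rr`` is too short for the template footprint (beats
        would overlap), or any precondition fails.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if rr_jitter < 0:
        raise ValueError("rr_jitter must be >= 0")
    footprint = template.footprint_s
    if not mean_rr - rr_jitter > footprint:
        raise ValueError(
            f"mean_rr={mean_rr:.3f} s (minus jitter {rr_jitter:.3f} s) too short "
            f"for the beat template footprint ({footprint:.3f} s half-width): "
            f"consecutive beats would overlap and R annotations would no longer "
            f"be local maxima; need mean_rr - rr_jitter > {footprint:.3f} s"
        )

    rng = np.random.default_rng(seed)
    rr = np.full(n_beats - 1, mean_rr)
    if rr_jitter > 0:
        rr = rr + rng.uniform(-rr_jitter, rr_jitter, size=n_beats - 1)
    beat_times = mean_rr + np.concatenate([[0.0], np.cumsum(rr)])
    duration = beat_times[-1] + mean_rr
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs

    x = np.zeros(n_samples)
    # evaluate each Gaussian only on its local support (6 sigma each side)
    for bt in beat_times:
        for w in template.waves:
            c = bt + w.center_s
            lo = max(0, int(np.floor((c - 6 * w.width_s) * fs)))
            hi = min(n_samples, int(np.ceil((c + 6 * w.width_s) * fs)) + 1)
            if hi > lo:
                tt = t[lo:hi]
                x[lo:hi] += w.amplitude * np.exp(-((tt - c) ** 2) / (2 * w.width_s**2))

    for spec in noise or []:
        x = x + _render_noise(spec, t, fs, template.r.amplitude, rng)

    r_idx = np.round(beat_times * fs).astype(np.int64)
    return ECGRecord(samples=x, fs=fs, r_peaks=r_idx,
                     record_id=record_id or f"syn{seed}",
                     subject_id=subject_id)


def corrupt_detections(
    truth: np.ndarray,
    fp_rate: float,
    fn_rate: float,
    jitter: int,
    record_len: int,
    seed: int = 0,
    min_gap_from_truth: int = 72,
) -> DetectionResult:
    """Simulate a faulty detector by perturbing a truth annotation set.

    Drops ``round(fn_rate * N)`` true peaks, jitters the survivors by an
    integer uniform on ``[-jitter, +jitter]``, and injects
    ``round(fp_rate * N)`` spurious indices, each at least
    ``min_gap_from_truth`` samples (0.2 s at 360 Hz by default, i.e. one
    refractory period, well outside the matching tolerance) from every
    true peak.  Output indices are sorted, unique and within
    ``[0, record_len)``.
    """
    if not (0 <= fp_rate <= 1) or not (0 <= fn_rate <= 1):
        raise ValueError("fp_rate and fn_rate must lie in [0, 1]")
    truth = np.asarray(truth, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = truth.size

    n_drop = int(round(fn_rate * n))
    keep = np.ones(n, dtype=bool)
    if n_drop:
        keep[rng.choice(n, size=n_drop, replace=False)] = False
    kept = truth[keep]
    if jitter:
        kept = kept + rng.integers(-jitter, jitter + 1, size=kept.size)
        kept = np.clip(kept, 0, record_len - 1)

    n_fp = int(round(fp_rate * n))
    spurious: list[int] = []
    attempts = 0
    while len(spurious) < n_fp:
        attempts += 1
        if attempts > 1000 * max(n_fp, 1):
            raise RuntimeError(
                "could not place spurious peaks away from true peaks; "
                "record too densely annotated for the requested fp_rate"
            )
        cand = int(rng.integers(0, record_len))
        if truth.size and np.min(np.abs(truth - cand)) < min_gap_from_truth:
            continue
        if spurious and min(abs(cand - s) for s in spurious) < min_gap_from_truth:
            continue
        spurious.append(cand)

    out = np.unique(np.concatenate([kept, np.asarray(spurious, dtype=np.int64)]))
    out = out[(out >= 0) & (out < record_len)]
    return DetectionResult(peaks=out, delay=0)
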