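"""Sample construction and data augmentation.

From every annotated beat whose window fits inside the record, eleven
positive (beat-labelled) segments are built: the centered window, six
shifted copies (±5, ±10, ±15 samples), the centered window with the
P-wave region (375 ms before the R-peak) attenuated by 30 %, with the
T-wave region (375 ms after) attenuated by 30 %, and with the whole
segment attenuated by 20 % and by 40 %.  Negative (non-beat) segments are
strided windows confined to the interval between consecutive beats, kept
at least 50 samples away from either R-peak.

Augmentation is meant for training partitions only; the evaluation
pipeline never augments test data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import ECGRecord

__all__ = [
    "Segment",
    "AugmentationConfig",
    "WindowOutOfBounds",
    "extract_window",
    "attenuate_wave",
    "global_attenuate",
    "positive_variants",
    "negative_windows",
    "build_segments",
    "window_ms_to_samples",
    "window_samples_to_ms",
]


class WindowOutOfBounds(Exception):
    """A requested window does not fit inside the record."""


@dataclass
class Segment:
    """A fixed-length labelled window cut from a source record."""

    values: np.ndarray
    label: str  # "beat" | "non_beat"
    record_id: str = ""
    center: int = -1  # center sample index in the source record
    variant: str = ""  # centered | shift±k | p_atten | t_atten | global20 | global40 | negative

    def __post_init__(self) -> None:
        if self.label not in ("beat", "non_beat"):
            raise ValueError(f"label must be 'beat' or 'non_beat', got {self.label!r}")
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class AugmentationConfig:
    """Knobs of the sample-construction scheme.

    Defaults reproduce the published recipe at 360 Hz: shifts of 5/10/15
    samples both ways, 30 % wave attenuation over 375 ms, global
    attenuations of 20 % and 40 %, negative windows at least 50 samples
    from each surrounding beat with a 5-sample stride, and an 833-ms
    window.
    """

    shifts: tuple[int, ...] = (5, 10, 15)
    wave_atten_frac: float = 0.30
    wave_extent_ms: float = 375.0
    global_atten_fracs: tuple[float, ...] = (0.20, 0.40)
    neg_margin: int = 50
    neg_stride: int = 5
    window_ms: float = 833.0

    def __post_init__(self) -> None:
        if not (0 <= self.wave_atten_frac < 1):
            raise ValueError("wave_atten_frac must be in [0, 1)")
        for f in self.global_atten_fracs:
            if not (0 <= f < 1):
                raise ValueError("global attenuation fractions must be in [0, 1)")
        if any(s <= 0 for s in self.shifts):
            raise ValueError("shifts must be positive sample counts")
        if self.neg_margin <= 0 or self.neg_stride <= 0:
            raise ValueError("neg_margin and neg_stride must be positive")

    @property
    def variants_per_beat(self) -> int:
        wave = 2 if self.wave_atten_frac > 0 else 0
        return 1 + 2 * len(self.shifts) + wave + len(self.global_atten_fracs)


def window_ms_to_samples(window_ms: float, fs: float) -> int:
    return int(round(window_ms * fs / 1000.0))


def window_samples_to_ms(n: int, fs: float) -> int:
    return int(round(n / fs * 1000.0))


def extract_window(record: ECGRecord, center: int, length: int) -> np.ndarray:
    """Cut exactly ``length`` samples with ``center`` at index ``length // 2``.

    Raises :class:`WindowOutOfBounds` when the window would cross the
    record boundary; callers skip such beats rather than pad.
    """
    start = center - length // 2
    end = start + length
    if start < 0 or end > len(record):
        raise WindowOutOfBounds(
            f"window [{start}, {end}) around center {center} exceeds record "
            f"of length {len(record)}"
        )
    return record.samples[start:end].copy()


def attenuate_wave(values: np.ndarray, side: str, frac: float,
                   extent_ms: float, fs: float) -> np.ndarray:
    """Scale the P- or T-wave region of an R-centered segment by ``1 - frac``.

    The region is the ``round(extent_ms * fs / 1000)`` samples strictly
    before (``p_wave``) or strictly after (``t_wave``) the center index,
    clipped to the segment bounds.
    """
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0, 1)")
    if side not in ("p_wave", "t_wave"):
        raise ValueError(f"side must be 'p_wave' or 't_wave', got {side!r}")
    values = np.asarray(values, dtype=np.float64).copy()
    center = values.size // 2
    n_ext = int(round(extent_ms * fs / 1000.0))
    if side == "p_wave":
        lo, hi = max(0, center - n_ext), center
    else:
        lo, hi = center + 1, min(values.size, center + 1 + n_ext)
    values[lo:hi] *= 1.0 - frac
    return values


def global_attenuate(values: np.ndarray, frac: float) -> np.ndarray:
    """Scale the entire segment by ``1 - frac``."""
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0, 1)")
    return np.asarray(values, dtype=np.float64) * (1.0 - frac)


def positive_variants(record: ECGRecord, r_index: int,
                      cfg: AugmentationConfig = AugmentationConfig(),
                      window_len: int | None = None) -> list[Segment]:
    """All beat-labelled variants of one annotated beat.

    With the default config this is exactly 11 segments (1 centered +
    6 shifted + 2 wave-attenuated + 2 globally attenuated).  If any of
    the required window positions falls outside the record the beat is
    skipped entirely and an empty list is returned.
    """
    L = window_len if window_len is not None else window_ms_to_samples(cfg.window_ms, record.fs)
    segs: list[Segment] = []
    try:
        centered = extract_window(record, r_index, L)
        shifted = {}
        for k in cfg.shifts:
            # +k: the R-peak sits k samples right of the segment center
            shifted[+k] = extract_window(record, r_index - k, L)
            shifted[-k] = extract_window(record, r_index + k, L)
    except WindowOutOfBounds:
        return []

    def add(values: np.ndarray, variant: str, center: int = r_index) -> None:
        segs.append(Segment(values=values, label="beat", record_id=record.record_id,
                            center=center, variant=variant))

    add(centered, "centered")
    for k in sorted(shifted, key=lambda s: (abs(s), s)):
        add(shifted[k], f"shift{k:+d}", center=r_index - k)
    if cfg.wave_atten_frac > 0:
        add(attenuate_wave(centered, "p_wave", cfg.wave_atten_frac,
                           cfg.wave_extent_ms, record.fs), "p_atten")
        add(attenuate_wave(centered, "t_wave", cfg.wave_atten_frac,
                           cfg.wave_extent_ms, record.fs), "t_atten")
    for f in cfg.global_atten_fracs:
        add(global_attenuate(centered, f), f"global{int(round(f * 100))}")
    return segs


def negative_windows(record: ECGRecord,
                     cfg: AugmentationConfig = AugmentationConfig(),
                     window_len: int | None = None) -> list[Segment]:
    """Strided non-beat windows between consecutive annotated beats.

    For each beat pair ``(r1, r2)`` windows start at ``r1 + neg_margin``
    and advance by ``neg_stride`` while the whole window stays inside
    ``[r1 + neg_margin, r2 - neg_margin]``.  Intervals too short for any
    window contribute nothing.
    """
    if record.r_peaks.size < 2:
        raise ValueError("negative windows need at least 2 annotated beats")
    L = window_len if window_len is not None else window_ms_to_samples(cfg.window_ms, record.fs)
    segs: list[Segment] = []
    for r1, r2 in zip(record.r_peaks[:-1], record.r_peaks[1:]):
        first = int(r1) + cfg.neg_margin
        last = int(r2) - cfg.neg_margin - L  # last feasible start
        start = first
        while start <= last:
            vals = record.samples[start: start + L].copy()
            segs.append(Segment(values=vals, label="non_beat",
                                record_id=record.record_id,
                                center=start + L // 2, variant="negative"))
            start += cfg.neg_stride
    return segs


def build_segments(records: list[ECGRecord],
                   cfg: AugmentationConfig = AugmentationConfig(),
                   model_len: int = 300,
                   augment: bool = True) -> list[Segment]:
    """Build the full labelled sample set from annotated records.

    Windows are cut at the native rate (``window_ms`` long) and each
    segment resampled to ``model_len`` samples when the rates differ.
    With ``augment=False`` only the centered positive per beat is kept —
    the configuration for test partitions.
    """
    from .io import resample_to_length

    out: list[Segment] = []
    base_cfg = cfg if augment else AugmentationConfig(
        shifts=(), global_atten_fracs=(), wave_atten_frac=0.0,
        neg_margin=cfg.neg_margin, neg_stride=cfg.neg_stride,
        window_ms=cfg.window_ms)
    for rec in records:
        L = window_ms_to_samples(cfg.window_ms, rec.fs)
        segs: list[Segment] = []
        for r in rec.r_peaks:
            if augment:
                segs.extend(positive_variants(rec, int(r), cfg, window_len=L))
            else:
                try:
                    w = extract_window(rec, int(r), L)
                except WindowOutOfBounds:
                    continue
                segs.append(Segment(values=w, label="beat", record_id=rec.record_id,
                                    center=int(r), variant="centered"))
        if rec.r_peaks.size >= 2:
            segs.extend(negative_windows(rec, base_cfg, window_len=L))
        if L != model_len:
            for s in segs:
                s.values = resample_to_length(s.values, model_len)
        out.extend(segs)
    return out
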