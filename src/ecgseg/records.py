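"""Core data containers shared across the pipeline.

An :class:`ECGRecord` is a single-lead trace with its ground-truth R-peak
annotations and the record/subject identity needed for subject-disjoint
splits.  A :class:`DetectionResult` is what an R-peak detector emits:
candidate peak indices plus the group delay of its filter cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ECGRecord", "DetectionResult"]


@dataclass
class ECGRecord:
    """Sampled single-lead ECG with annotated R-peaks.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude series in arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    r_peaks : ndarray of int
        0-based sample indices of annotated R-peaks, strictly increasing,
        each within ``[0, len(samples))``.
    record_id, subject_id : str
        Identity used by split construction; every record belongs to a
        single subject.
    """

    samples: np.ndarray
    fs: float
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    record_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.r_peaks.size:
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            lo, hi = int(self.r_peaks[0]), int(self.r_peaks[-1])
            if lo < 0 or hi >= self.samples.size:
                bad = lo if lo < 0 else hi
                raise ValueError(
                    f"annotation index {bad} outside signal of length {self.samples.size}"
                )
        if not self.subject_id:
            self.subject_id = self.record_id

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DetectionResult:
    """Candidate R-peak indices emitted by a detector.

    ``peaks`` are 0-based, strictly increasing sample indices already
    corrected into original-signal coordinates.  ``delay`` records the
    group delay (in samples) of the detector's filter cascade that was
    compensated for; it is informational.
    """

    peaks: np.ndarray
    delay: int = 0

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.int64)
        if self.peaks.size and np.any(np.diff(self.peaks) <= 0):
            raise ValueError("detected peaks must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peaks.size)
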