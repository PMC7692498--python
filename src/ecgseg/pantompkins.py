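"""Classic Pan-Tompkins QRS detector.

The cascade: band-pass (≈5–15 Hz) → five-point derivative → squaring →
moving-window integration (150 ms), followed by dual adaptive thresholds
(THR2 = THR1/2), a 200-ms refractory constraint, T-wave slope
discrimination, and RR-based searchback at 166 % of the running mean RR.

The band-pass is a linear-phase FIR designed at the native sampling rate
with its group delay compensated exactly, so reported peak indices live in
original-signal coordinates.  All thresholds adapt to the signal, making
detection equivariant to positive amplitude scaling.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .records import DetectionResult, ECGRecord

__all__ = [
    "bandpass",
    "derivative",
    "square",
    "moving_window_integrate",
    "detect",
    "PanTompkinsDetector",
]


def _bandpass_taps(fs: float, lowcut: float, highcut: float) -> np.ndarray:
    # one second of taps (odd) gives a sharp enough transition to kill
    # sub-hertz baseline wander while passing the 5-15 Hz QRS band
    numtaps = int(round(fs)) | 1
    return sps.firwin(numtaps, [lowcut, highcut], pass_zero=False, fs=fs)


def bandpass(values: np.ndarray, fs: float, lowcut: float = 5.0,
             highcut: float = 15.0, return_delay: bool = False):
    """Linear-phase FIR band-pass, group delay compensated.

    Output has the same length as the input and is aligned with it (the
    constant group delay of ``(numtaps - 1) / 2`` samples is removed).
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz (filter design degenerates below)")
    values = np.asarray(values, dtype=np.float64)
    taps = _bandpass_taps(fs, lowcut, highcut)
    delay = (taps.size - 1) // 2
    padded = np.concatenate([values, np.zeros(delay)])
    out = sps.lfilter(taps, 1.0, padded)[delay:]
    if return_delay:
        return out, delay
    return out


_DERIV_KERNEL = np.array([2.0, 1.0, 0.0, -1.0, -2.0])


def derivative(values: np.ndarray, fs: float) -> np.ndarray:
    """Five-point derivative ``y[n] = (fs/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])``.

    Causal; the first four output samples see zero-padding.  Length is
    preserved.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 5:
        raise ValueError("derivative needs at least 5 samples")
    return sps.lfilter(_DERIV_KERNEL * (fs / 8.0), 1.0, values)


def square(values: np.ndarray) -> np.ndarray:
    """Elementwise squaring; intensifies slopes and makes everything positive."""
    values = np.asarray(values, dtype=np.float64)
    return values * values


def moving_window_integrate(values: np.ndarray, fs: float,
                            width_ms: float = 150.0) -> np.ndarray:
    """Causal moving average over ``round(width_ms * fs / 1000)`` samples."""
    if width_ms <= 0:
        raise ValueError("width_ms must be > 0")
    values = np.asarray(values, dtype=np.float64)
    n = int(round(width_ms * fs / 1000.0))
    if n < 1:
        n = 1
    if n > values.size:
        raise ValueError(
            f"integration window of {n} samples longer than signal of {values.size}"
        )
    return sps.lfilter(np.full(n, 1.0 / n), 1.0, values)


class PanTompkinsDetector(BaseEstimator):
    """Adaptive dual-threshold Pan-Tompkins R-peak detector.

    Parameters
    ----------
    lowcut, highcut : float
        Band-pass edges in Hz.
    integration_width_ms : float
        Moving-window integration width (150 ms in the original design).
    refractory_s : float
        Minimum physiological spacing between beats (200 ms).
    searchback_factor : float
        A missing beat is searched for when no peak occurred within this
        multiple (1.66) of the running mean RR interval.
    peak_update, searchback_update : float
        Exponential update weights for the running signal/noise peak
        estimates (0.125; searchback acceptances use 0.25).
    thr_weight : float
        THR1 = noise + thr_weight * (signal - noise); THR2 = THR1 / 2.
    twave_check : bool
        Apply slope discrimination to candidates 200-360 ms after the
        previous beat.
    learning_s : float
        Length of the initial segment used to seed the thresholds.
    """

    def __init__(self, lowcut: float = 5.0, highcut: float = 15.0,
                 integration_width_ms: float = 150.0, refractory_s: float = 0.2,
                 searchback_factor: float = 1.66, peak_update: float = 0.125,
                 searchback_update: float = 0.25, thr_weight: float = 0.25,
                 twave_check: bool = True, learning_s: float = 2.0):
        self.lowcut = lowcut
        self.highcut = highcut
        self.integration_width_ms = integration_width_ms
        self.refractory_s = refractory_s
        self.searchback_factor = searchback_factor
        self.peak_update = peak_update
        self.searchback_update = searchback_update
        self.thr_weight = thr_weight
        self.twave_check = twave_check
        self.learning_s = learning_s

    # -- stages -----------------------------------------------------------

    def _preprocess(self, x: np.ndarray, fs: float):
        bp, bp_delay = bandpass(x, fs, self.lowcut, self.highcut, return_delay=True)
        der = derivative(bp, fs)
        der = np.concatenate([der[2:], np.zeros(2)])  # compensate 2-sample delay
        sq = square(der)
        mwi = moving_window_integrate(sq, fs, self.integration_width_ms)
        n_int = int(round(self.integration_width_ms * fs / 1000.0))
        d = (n_int - 1) // 2
        if d:
            mwi = np.concatenate([mwi[d:], np.zeros(d)])  # centre the window
        return bp, der, mwi, n_int, bp_delay + 2 + d

    def _localize(self, bp: np.ndarray, mwi_idx: int, n_int: int, fs: float) -> int:
        lo = max(0, mwi_idx - n_int)
        hi = min(bp.size, mwi_idx + n_int // 2 + 1)
        return lo + int(np.argmax(bp[lo:hi]))

    # -- main entry -------------------------------------------------------

    def detect(self, record: ECGRecord) -> DetectionResult:
        """Run the full cascade on a record.

        Returns peak indices in original-signal coordinates, spaced at
        least one refractory period apart.
        """
        fs = record.fs
        x = record.samples
        if x.size < 2 * fs:
            raise ValueError("record shorter than 2 s; detector needs a learning phase")

        bp, der, mwi, n_int, cascade_delay = self._preprocess(x, fs)
        refractory = int(round(self.refractory_s * fs))
        if mwi.max() <= 0:
            return DetectionResult(peaks=np.empty(0, dtype=np.int64), delay=cascade_delay)

        cand, _ = sps.find_peaks(mwi, distance=refractory)
        if cand.size == 0:
            return DetectionResult(peaks=np.empty(0, dtype=np.int64), delay=cascade_delay)

        learn = mwi[: int(self.learning_s * fs)]
        spki = 0.25 * float(learn.max())
        npki = 0.5 * float(learn.mean())

        def thr1() -> float:
            return npki + self.thr_weight * (spki - npki)

        qrs_mwi: list[int] = []  # accepted peaks, mwi coordinates
        noise_cand: list[int] = []  # rejected candidates, for searchback
        rr_hist: list[float] = []

        def rr_mean() -> float:
            recent = rr_hist[-8:]
            return float(np.mean(recent)) if recent else 0.0

        for c in cand:
            v = float(mwi[c])
            accepted = False
            if v > thr1():
                is_twave = False
                if (self.twave_check and qrs_mwi
                        and refractory <= c - qrs_mwi[-1] < int(round(0.36 * fs))):
                    w = int(round(0.075 * fs))
                    slope_now = np.max(np.abs(
                        der[max(0, c - w): c + w + 1]))
                    p = qrs_mwi[-1]
                    slope_prev = np.max(np.abs(
                        der[max(0, p - w): p + w + 1]))
                    is_twave = slope_now < 0.5 * slope_prev
                if not is_twave and (not qrs_mwi or c - qrs_mwi[-1] >= refractory):
                    if qrs_mwi:
                        rr_hist.append(float(c - qrs_mwi[-1]))
                    qrs_mwi.append(int(c))
                    spki = self.peak_update * v + (1 - self.peak_update) * spki
                    accepted = True
            if not accepted:
                noise_cand.append(int(c))
                npki = self.peak_update * v + (1 - self.peak_update) * npki

            # searchback: no beat within 166% of the running mean RR
            mean_rr = rr_mean()
            if qrs_mwi and mean_rr > 0 and c - qrs_mwi[-1] > self.searchback_factor * mean_rr:
                window = [k for k in noise_cand
                          if qrs_mwi[-1] + refractory <= k <= c - refractory]
                if window:
                    vals = mwi[window]
                    best = int(window[int(np.argmax(vals))])
                    bv = float(mwi[best])
                    if bv > thr1() / 2.0:
                        rr_hist.append(float(best - qrs_mwi[-1]))
                        qrs_mwi.append(best)
                        qrs_mwi.sort()
                        noise_cand.remove(best)
                        spki = (self.searchback_update * bv
                                + (1 - self.searchback_update) * spki)

        peaks = sorted({self._localize(bp, c, n_int, fs) for c in qrs_mwi})
        # enforce the refractory invariant in final coordinates
        final: list[int] = []
        for p in peaks:
            if final and p - final[-1] < refractory:
                continue
            final.append(p)
        return DetectionResult(peaks=np.asarray(final, dtype=np.int64),
                               delay=cascade_delay)


def detect(record: ECGRecord, **params) -> DetectionResult:
    """Convenience wrapper around :class:`PanTompkinsDetector`."""
    return PanTompkinsDetector(**params).detect(record)
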