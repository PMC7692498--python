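# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecgseg`, and what its synthetic experiments do and do not show.

## Synthetic ECG model

A heartbeat is a sum of five Gaussian waves (P, Q, R, S, T), each with an
amplitude, a center offset relative to the R-peak (seconds) and a width
(Gaussian sigma, seconds). Default template, relative to R = 1.0:

| wave | amplitude | offset (s) | width (s) |
|------|-----------|------------|-----------|
| P    | 0.15      | −0.22      | 0.05      |
| Q    | −0.10     | −0.04      | 0.01      |
| R    | 1.00      | 0.00       | 0.02      |
| S    | −0.20     | +0.04      | 0.01      |
| T    | 0.30      | +0.30      | 0.08      |

These are textbook proportions; everything is configurable. Beats are
placed at quasi-periodic R times with i.i.d. uniform RR jitter on
[−rr_jitter, +rr_jitter] — the simplest bounded model, which keeps the
detector's refractory assumption valid. Ground-truth annotations are the
rounded R times; generation is bit-reproducible under a fixed seed.

A record is rejected when `mean_rr − rr_jitter` is not larger than the
template footprint (largest |offset| + 3 sigma, 0.54 s for the default
template). This is the condition under which consecutive R waves stay
separated and each annotation remains a local maximum of the noise-free
signal; the far Gaussian tails of one beat's T wave may still overlap the
next beat's P wave at fast rates, which is physiological and harmless.

Noise components follow the standard ECG taxonomy: baseline wander
(low-frequency sinusoid, default 0.3 Hz), powerline hum (50 Hz sinusoid)
and band-limited high-frequency noise (white noise high-passed above
25 Hz) — the last being the mechanism that distorts P/T morphology and
drives the validator's sensitivity loss on off-the-person recordings.
Amplitudes are fractions of the R amplitude: peak amplitude for the
sinusoids, RMS for the stochastic high-frequency component (a peak
amplitude is not well defined for noise).

**What the generator does not emulate:** arrhythmic or ectopic beats,
beat-to-beat morphology variation, electrode motion artifacts, lead
polarity inversions, and non-stationary noise bursts. Passing the
synthetic suites therefore demonstrates the pipeline's mechanics and its
false-positive suppression under controlled corruption — not clinical
performance on real databases.

## Pan-Tompkins detector

Cascade: band-pass → five-point derivative
`y[n] = (fs/8)(2x[n] + x[n−1] − x[n−3] − 2x[n−4])` → squaring → 150-ms
moving-window integration. The band-pass is a linear-phase FIR
(~1 s of taps, Hamming window, 5–15 Hz) designed at the native sampling
rate, rather than the original 200-Hz integer-coefficient cascade: the
filter's group delay is then exactly `(numtaps−1)/2` samples and is
compensated, so peaks are reported in original-signal coordinates. The
`DetectionResult.delay` field records the compensated cascade delay for
anyone comparing raw stage outputs.

Thresholds follow the classic adaptation: running signal/noise peak
estimates updated with weight 0.125 (0.25 for searchback acceptances),
`THR1 = noise + 0.25·(signal − noise)`, `THR2 = THR1/2`; both are seeded
from the first 2 s of the integrated signal. Constraints: a 200-ms
refractory period; T-wave discrimination for candidates 200–360 ms after
the previous beat (rejected when their maximum derivative magnitude is
below half the previous beat's); searchback over rejected candidates when
no beat occurred within 166 % of the running mean of the last 8 RR
intervals, accepting the largest one above THR2. The final R index is the
argmax of the band-passed signal in a window around the integrated-signal
peak. Because every threshold derives from the signal itself, detection
is exactly equivariant to positive amplitude scaling.

The arrhythmia-mode threshold halving is not implemented (the evaluation
targets regular rhythms).

## Sample construction

Windows are 833 ms, cut at the native rate (300 samples at 360 Hz, 833 at
1000 Hz) and resampled to the model length of 300 with piecewise cubic
interpolation (exact on constants and ramps; endpoints preserved).
Records at non-360-Hz rates are windowed first and resampled per segment,
so annotation indices never shift.

Eleven positives per eligible beat: centered; shifts ±5/±10/±15 samples
(sign convention: +k places the R-peak k samples right of center); P- and
T-wave attenuation by 30 % over 375 ms before/after the center; global
attenuation by 20 % and 40 %. "Attenuated by 30 %" means multiplied by
0.70 — amplitude units are arbitrary, so only multiplicative scaling is
unit-free. Attenuated variants derive from the centered window, keeping
the multiplier at exactly 11. Beats whose windows cross a record boundary
are skipped, never padded: padding would fabricate morphology.

Negatives slide between consecutive beats with stride 5, the whole window
confined to `[r1+50, r2−50]`. Geometry note: at 360 Hz this requires an
RR interval above 400 samples (≈1.11 s), so the synthetic end-to-end
experiment uses a 1.2-s mean RR — a slow but physiological rhythm chosen
so the published negative-sampling rule yields a usable negative class
(~1.65 positives per negative, close to the published ~1.9:1 imbalance).
No class re-weighting is applied. Augmentation is applied to training
partitions only.

## The CNN validator

Four conv/max-pool stages (kernels 49/25/9/9, stride 1, no padding; pool
width and stride 2), two dense layers, dropout 0.5 before a 2-way
softmax; ReLU activations. For input 300 the temporal lengths are
252→126, 102→51, 43→21, 13→6. Channel counts (32/32/64/64) and dense
widths (512/128) are **not** fixed by the published architecture figure;
the defaults here were chosen to train on one CPU in minutes and are
fully configurable (≈345k parameters). Dropout rate and activations are
likewise conventional defaults.

Training: SGD with momentum 0.9, softmax cross-entropy, batch 256,
learning rate 0.01 (epochs 1–3), 0.005 (4–10), 0.001 (11–20), 0.0001
(21–30); 30 % of segments are held out for validation, stratified within
each record and label (the split is by segment, not by time). Inputs are
raw amplitudes by default; optional per-segment z-scoring is available
for badly scaled sources. The implementation is pure NumPy with im2col
(BLAS) convolutions and a single seeded generator, so training histories
are bit-reproducible. NaN loss aborts with a diagnostic rather than
continuing silently.

Model artifacts are a single `.npz` holding weights plus a JSON header
with a format tag and the full spec; loading verifies the tag and
round-trips predictions bitwise.

## Validation and evaluation

Each detection gets an 833-ms window; windows that do not fit in the
record are rejected (and count as detector FPs if unmatched — the CNN
cannot assess them). Matching is greedy one-to-one by increasing
distance, ties broken by earlier detection then earlier truth index;
tolerance is 15 samples at 360 Hz, scaled as `round(15/360·fs)`
elsewhere — the largest augmentation shift, i.e. the displacement the
model was taught to call "centered". Metrics are pooled over records
(micro-average). Undefined ratios (zero denominators) are reported as
explicit `None`, never silent zeros.

Two invariants are asserted unconditionally: validated TP/FP/Se never
exceed raw (acceptance is a subset), and train/test subject sets are
disjoint.

## Scaled end-to-end experiment

`ExperimentConfig` defaults: 20 training and 10 test records of 20 beats
at 360 Hz, mean RR 1.2 s, jitter 0.05 s; mild high-frequency + baseline
noise on training records, stronger on test records; detector output on
test records corrupted with 10 % injected spurious peaks (placed at least
one refractory period from any true beat); CNN trained 10 epochs. These
sizes keep the full experiment to a few CPU-minutes while leaving ~7,000
training segments — enough for the validator to reach near-zero held-out
error on this task.

Known limitation: training negatives, by the published rule, never
contain an R-peak anywhere in the window, while a spurious detection can
land 70–150 samples from a true beat, producing a window with a visibly
off-center beat that is outside the training distribution. The trained
validator rejects most but not all such windows; they account for the
residual validated FPs in the experiment report.
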