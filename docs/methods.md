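# Methods

## Problem setting

The package models a free-living mood-recognition study: a participant
wears a wristband during the day (about 12 h) for one to two weeks while a
phone app prompts them roughly five times a day, at times jittered by
±10 min, to report happiness and activeness on 5-level scales. The goal is
to predict the reported mood state from the physiological channels alone.

Timestamps are UTC epoch seconds and every interval is half-open
`[start, end)`.

## Signal conditioning

| channel | rate | chain |
| --- | --- | --- |
| ACC (x, y, z) | 32 Hz | Euclidean norm computed on the raw axes, then all four series band-passed 0.2–10 Hz, 3rd-order Butterworth |
| TEMP | 4 Hz | 2 °C jump rule (below) flags implausible samples; no filtering |
| EDA | 4 Hz | 1.5 Hz low-pass, 3rd-order Butterworth; tonic/phasic split below |
| HR | 1 Hz | z-score against the first 10 min of the wear day |

All filters are applied forward–backward (zero phase). The analysis is
offline, so there is no causality constraint, and phase distortion would
shift features in time relative to the EMA labels; the effective magnitude
response is the square of the designed filter's, which the tests check
against `sosfreqz` directly.

**Temperature rule.** A sample is invalid when it differs from the *last
valid* sample by strictly more than 2 °C — skin temperature cannot move
that fast, so such jumps indicate the sensor leaving the skin. The rule
discards single samples, not whole segments, and is idempotent: a second
pass over the surviving samples flags nothing. A window keeps its
temperature features when at least half its samples survive (the slope and
intercept are then fitted on the surviving samples at their true times);
otherwise the whole window is dropped for *all* modalities so feature rows
stay aligned.

**Tonic/phasic split.** The skin conductance level (SCL) is a 32-s moving
median of the filtered signal smoothed by a 0.05 Hz low-pass; the skin
conductance response (SCR) is the exact residual, so `EDA = SCL + SCR`
holds sample for sample. The median window must comfortably exceed the
duration of one phasic bump: a bump with instant rise and ~4 s exponential
decay stays visibly elevated for roughly 10 s, and a median only rejects
excursions occupying less than half its window. At 32 s the tonic estimate
moves by < 0.03 µS under a 1 µS bump while the residual recovers the bump
peak within a few percent; at 8 s the tonic estimate would chase the bump
by ~0.27 µS. Convex-optimization decompositions were deliberately avoided:
this split is deterministic, cheap, and exactly additive.

**Heart-rate baseline.** The first 10 min of each day define the baseline
mean and standard deviation; the whole day is z-scored against them, making
levels comparable across days and participants. A zero-spread baseline
falls back to a unit divisor; a day shorter than the baseline uses the
whole day (with a warning). The z-score is one concrete reading of
"normalized to a daily baseline"; it is invariant to constant offsets,
which the tests assert.

## Features

60-s windows advance by 54 s (10 % overlap) over the span where all
channels overlap; the last window must fit entirely inside the span.
Per window: 72 ACC (18 measures × 4 series), 13 TEMP, 27 HR
(14 time + 13 spectral), 82 EDA (26 measures × 3 components + the 4
difference statistics on the filtered signal only) = 194 named features,
in a stable documented column order (`features.feature_columns()`).

Spectral descriptors use a Welch PSD: Hann window, segments capped at 256
samples with 50 % overlap, no detrending, after subtracting the segment
mean once up front. Mean removal matters: a Hann-windowed constant leaks
DC into the low bins, which would give constant segments nonzero band
powers. `FPq` is the spectral-edge frequency (the lowest frequency below
which q % of total power lies) — the alternative reading, a percentile of
PSD amplitudes, is dimensionally a power rather than a frequency and sits
oddly among frequency descriptors. `FM`/`FSTD` are the mean and standard
deviation of the PSD amplitudes.

HRV band powers integrate the PSD of the normalized 1 Hz heart-rate series
over the conventional bands VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz.
With 60-s windows the frequency resolution is 1/60 Hz, so the VLF band
holds at most two bins and may legitimately be zero; `LFHF` is 0 by
convention when HF power vanishes. The smoothed-HR mean (`SM`) uses a
centered 5-s moving average with shrinking edge windows.

EDA statistics are computed per component (filtered signal, SCL, SCR):
amplitude statistics, first/second-derivative statistics, arc length
`ALSC = Σ√(1+Δx²)`, integral, normalized average power and RMS, the
arc-length ratios `ILSC = INSC/ALSC` and `ELSC = Σx²/ALSC` (documented
stand-ins for "area-perimeter" and "energy-perimeter" ratios), skewness,
Pearson kurtosis, and the 5th central moment (`MOSC`; the 2nd–4th moments
already appear as dedicated measures). Band powers cover 0.1–0.2 / 0.2–0.3
/ 0.3–0.4 Hz. The duplicate name "standard deviation of the second
derivative" is disambiguated internally as `SDSC2`.

Every feature is checked against a naive loop-level recomputation
(hand-rolled Hann periodogram averaging over `np.fft`, hand-interpolated
percentiles, explicit difference loops) to 1e-8 relative tolerance on
random fixture windows.

## Labels

`mood_from_answer` centers both Likert scales at 2 and takes the 45° octant
of `atan2(activeness−2, happiness−2)`, with sectors centered on pleasure
(0°), excitement (45°), arousal (90°), distress, displeasure, depression,
sleepiness and contentment; (2, 2) is a distinct neutral state that enters
the prevalence filter like any other class rather than being silently
dropped. The mapping is a concretization of the circumplex geometry — the
full 25-cell table is snapshot-tested and printable via
`wristmood explain-mapping`, and replaceable in code.

`expand_labels` gives each answer the interval `[t − W/2, t + W/2)`.
Whenever the claimed intervals of consecutive answers overlap, both are cut
at the midpoint `(t_i + t_{i+1})/2` — triggering on *geometric overlap*
(gap < W) subsumes the narrower "gap < W/2" trigger and guarantees the
partition property: no second of the day is ever claimed twice. Claims are
truncated at the recording bounds. A feature window receives a label when
at least 50 % of its seconds carry it (ties break toward the earlier
answer); other windows leave the supervised dataset. Windows are tiled at
the 10 % overlap of the feature extractor rather than anchored per labeled
second — anchoring one window at every labeled second would produce
near-duplicate rows differing by one sample and inflate split accuracies
through twinning.

## Classification protocols

Classes holding < 10 % of the samples are removed iteratively (shares are
recomputed after each removal, smallest class first) until stable; fewer
than two survivors is an error. Features are scaled per column so the
*training* minimum and maximum map to −1 and +1 (constant columns map to
0; test values may exceed the range). The SVM is `sklearn.svm.SVC` with an
RBF kernel; (C, γ) come from an exhaustive grid search under stratified
k-fold cross-validation run *inside each training set* (nested per repeat
and per held-out day — stricter than a single global search), with ties
resolved to the smallest C, then the smallest γ. Default grids are
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} with 5 folds.

* **Repeated split** — stratified 75/25 shuffle splits, 10 repeats;
  reported as mean ± std of test accuracy plus per-run and summed
  confusion matrices (trace/total reproduces each run's accuracy to
  1e-12).
* **Leave-one-day-out** — each wear day in turn is the test set; accuracy
  is the mean over days. Test samples whose class is absent from the
  training days are necessarily errors; days with fewer than two training
  classes are skipped with a warning.

Single-dimension experiments (valence-only or arousal-only targets) are
supported by `project_labels`, which collapses mood codes to the sign of
the corresponding circumplex axis.

## Synthetic data

The generator's defaults mirror the emulated study design: 14 wear days of
12 h, five prompts/day with ±10 min notification jitter and exponential
~30 s reaction times (the cohort summary in
`synthetic_data.STUDY_PARTICIPANTS` spans 9–15 days and 3.5–5.3 answered
prompts per valid day). A latent (valence, arousal) state steps through
the day and couples into the channels: HR = 70 bpm + 4 bpm per arousal
unit + AR(1) noise (sd 2 bpm, φ 0.95); EDA = ~2 µS tonic level with a slow
sinusoidal drift plus Poisson SCR bumps (base rate 0.02 Hz + 0.01 Hz per
arousal unit, log-normal ~0.3 µS amplitudes, 4 s decay); TEMP = 33 °C +
0.15 °C per valence unit + drift + occasional single-sample spikes beyond
the 2 °C rule; ACC = gravity on z + activity bursts (10/h + 6/h per
arousal unit, 2–8 s, ~0.2 g) in integer counts so files round-trip
exactly. EMA answers are the latent state quantized to the Likert grid at
the answer time, hence always consistent with the ground truth.

Two latent processes are available. `markov` switches states with
exponential sojourns (1/h by default). The fixtures instead use
`ema_locked`, which switches exactly at the midpoints between consecutive
answer times: extrapolated labels are then physiologically pure, so the
separability checks test the pipeline rather than label noise. The `null`
fixture zeroes every coupling *and* the slow drift terms — with drifts on,
each answer's segment carries a memorable tonic signature that random
splits can exploit (measured ~60 % vs. 33 % chance), a leakage phenomenon
worth knowing about in real data too; with drifts off the null sits at
chance (~36 % in the acceptance run, within the 3-SD binomial band).

What the generator does *not* emulate: realistic HRV spectra (heart rate is
AR(1) noise plus a level shift, so spectral HR features carry little
signal), motion artifacts in EDA, posture-dependent gravity orientation,
circadian temperature structure, missing data inside a day, or reporting
noise in the answers. Passing tests therefore demonstrate pipeline
correctness and protocol sanity, not expected accuracy on real
recordings.

## Problem sizes and evaluation configuration

Fixture evaluations (tests and the acceptance script) use two 6-h days
with six prompts/day (~750 labeled windows) and a reduced search grid
(C ∈ {1, 16, 256}, γ ∈ {2⁻¹¹, 2⁻⁷, 2⁻³}, 3 folds, exported as
`dataset_model.FAST_SVM`): on well-separated synthetic blobs the selected
model is insensitive to the finer default grid, and the reduced
configuration keeps the nested search (grid × folds × repeats/days)
proportionate to the fixture size. The library default remains the full
grid with 5 folds.

## Numerical conventions and degenerate inputs

* Percentiles use linear interpolation (the numpy default), matched by the
  hand-rolled oracle.
* Z-scored difference statistics (`MAVFDN`, `MAVSDN`) are 0 for
  zero-variance segments; skewness and kurtosis are likewise guarded.
* Empty spectral bands report zero power and a peak at the band's lower
  edge; an all-zero segment has all spectral features 0.
* `ALSC ≥ N−1 > 0` for any segment with ≥ 2 samples, so the arc-length
  ratios are always defined (guarded anyway).
* Windows with any non-finite feature are dropped with a log message;
  emitted rows never contain NaN.
* Recordings too short for a filter's padding, days shorter than the HR
  baseline, all-invalid temperature days and EMA-free days degrade with
  warnings rather than crashes; `split_into_days` flags days with < 10 min
  of data in any channel as non-valid (they are skipped by the pipeline).

## Known limitations

* Inter-beat-interval files are not parsed; heart-rate analysis uses the
  device's 1 Hz HR series. Tachogram-based HRV is out of scope.
* The blood-volume-pulse channel (64 Hz) is unused — no features reference
  it.
* The tonic/phasic split is a fixed linear/median scheme; it will
  underestimate SCR amplitude when bumps overlap densely.
* Leave-one-day-out accuracy is highly variable with only two days (one
  std over days is reported); real studies should expect the protocol to
  need many days.
* EMA timestamps are assumed to share one synchronized clock with the
  device.
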