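# Methods

## Scope and data model

`emgrepro` quantifies how stable task-related muscle activation patterns are
within and between people. The unit of analysis is the *cycle profile*: a
100-point, unitless activation envelope for one muscle in one repetition of a
standardized movement, amplitude-normalized to the subject's task maximum and
time-normalized to the movement cycle. Profiles are stored long-format
(`subject_id, muscle, rep_index, point_index, value`); that table is the
contract between the preprocessing and analysis stages, and row-groups of it
are the in-memory representation of a profile.

## Preprocessing pipeline

Stages are applied strictly in this order per channel:

1. **Band-pass 20–450 Hz**, Butterworth of design order 4, applied
   forward–backward (`scipy.signal.sosfiltfilt`). "Zero-lag order 4" is read
   as design-order 4 per pass — the common convention — giving an effective
   8th-order magnitude response and zero phase. Filtering uses scipy's
   default odd-reflection edge padding to suppress startup transients on
   short trials.
2. **50 Hz notch**, second-order IIR (`scipy.signal.iirnotch`) with quality
   factor 30 (≈1.7 Hz bandwidth), forward–backward. Only the fundamental is
   removed; harmonics (100/150 Hz) are left to the band-pass and averaging.
3. **Full-wave rectification** (absolute value).
4. **Linear envelope**: 8 Hz low-pass Butterworth, design order 4,
   forward–backward. Low-pass overshoot can dip slightly below zero; values
   are clipped at 0 because the envelope represents an activation magnitude.
5. **Time normalization**: linear interpolation onto 100 points at fractions
   j/99 of the record (endpoints preserved exactly). Trials are assumed
   pre-segmented — one file per repetition; segmentation of continuous
   recordings is an input contract, not a pipeline stage.
6. **Peak normalization**: all repetitions of a subject × muscle are divided
   by their common maximum, taken on the 100-point grid. Scaling commutes
   with linear interpolation, so normalizing after interpolation only changes
   which grid defines the peak; doing it on the final grid guarantees the
   stored-file invariant that the maximum over a subject × muscle's
   repetitions is exactly 1. Task-maximum normalization is used instead of
   maximum voluntary contraction because it requires no calibration
   contraction and applies to impaired populations.

No outlier removal is performed; any repetition whose peak exceeds 5× the
median peak of its subject × muscle group is logged for audit and kept.

## Similarity and descriptors

For profiles *a*, *b* (length 100) the default similarity is the normalized
cross-correlation maximized over integer lags |k| ≤ 25 (1 point = 1% of
cycle): `max_k Σ_i a[i] b[i+k] / (‖a‖ ‖b‖)` with truncated (no-padding)
overlap and full-vector norms, matching MATLAB-style `xcorr(...,'coeff')`
usage on non-negative envelopes. Truncation rather than zero-padding avoids
asymmetric deflation for envelopes with non-zero edges. Positive `best_lag`
means the second profile is delayed relative to the first; ties go to the
smallest |lag|, then to the negative lag, so results are bit-reproducible. A
Pearson-correlation-on-overlap variant (`method="pearson"`) is provided
because published values rarely disambiguate the two conventions; on
non-negative envelopes the normalized form is the default.

* **Intra-subject repeatability** (per muscle): the coefficient for every
  unordered repetition pair of a subject (C(5,2) = 10 pairs in the default
  design) is averaged per subject; the reported mean and SD (denominator
  n−1) are taken across the per-subject means, keeping subjects equally
  weighted regardless of missing repetitions. Pooling all pairs instead is
  available via `aggregate="pairs"`.
* **Inter-subject reproducibility** (per muscle): each subject's repetitions
  are first averaged pointwise into a subject-mean profile; the coefficient
  is computed for every unordered subject pair (C(27,2) = 351 in the default
  design) and the mean and SD (n−1) are taken over those pairwise values —
  the only population available at that level. All-pairs comparison is used
  rather than comparison to a grand-mean profile.
* **Composite score**: the arithmetic mean of a muscle's intra and inter
  means, at full precision; ranking is by descending composite, ties broken
  by descending intra mean, then input channel order. Rounding
  (half-away-from-zero, default 2 decimals) happens only at report time.
* **Group curves**: pointwise mean and SD (n−1) of subject-mean profiles.

## Synthetic cohort generator

The generator emulates the study design the analysis is meant for: 27
subjects × 8 muscles × 5 self-paced repetitions sampled at 2148 Hz, with trial
durations drawn uniformly from 2.0–4.0 s so time normalization is genuinely
exercised on unequal lengths.

Each muscle's activation template is a baseline plus Gaussian bursts
(center, width in % cycle; relative amplitude). Default burst placement
follows an illustrative four-phase cycle (reach/grasp ≈ 0–30%, lift ≈ 30–55%,
return ≈ 55–80%, release ≈ 80–100%): proximal shoulder muscles get large
early-cycle bursts, the elbow pair peaks during lift/return, and the distal
wrist muscles carry three smaller bursts. A raw channel is the perturbed
template (the target envelope) multiplied by unit-RMS Gaussian noise
band-limited to 20–450 Hz, plus 50 Hz interference with random phase
(amplitude 0.10 of the muscle's nominal peak) and a white noise floor
(0.06 of nominal peak). This signal model is chosen because
rectification + 8 Hz low-pass provably recovers the modulator; it makes no
claim to motor-unit physiology.

Variability has two levels, both per burst: subject effects (lognormal
amplitude factor with log-scale SD 1.1; center shift SD 11% cycle) drawn once
per subject, and trial effects (lognormal SD 0.7; shift SD 7% cycle) drawn
per repetition. The subject-level SDs control inter-subject reproducibility,
the trial-level SDs intra-subject repeatability. No quantitative population
values exist for these components, so the defaults were calibrated once so
that the full default cohort lands in the plausible ranges for this kind of
task (per-muscle intra mean within 0.70–0.95, inter mean within 0.70–0.90)
and then frozen; they are the package's definition of its default study
conditions, not estimates of any real population.

Randomness discipline: one master seed; subject effects use substream
(seed, 1, subject), trial draws use (seed, 2, subject, rep) via numpy's
`SeedSequence`, so any single trial regenerates without the rest of the
cohort, and a written cohort is byte-identical across runs.

What the generator does **not** emulate: motor-unit firing statistics,
electrode placement and crosstalk, movement-phase duration variability that
is non-uniform across the cycle (a single linear time base is perturbed per
burst, not warped), amplitude non-stationarities such as fatigue, or
artifact classes beyond line interference. Passing tests therefore show the
pipeline recovers the descriptors under a controlled envelope-plus-noise
model — not that any specific real cohort would yield those values.

## Numerical choices and degenerate inputs

* Envelope values are clipped at 0 after low-pass; profiles are validated
  finite and non-negative.
* `lagged_xcorr` rejects profiles not exactly 100 points, non-finite values,
  and the degenerate case of two constant profiles; the Pearson variant skips
  lags whose overlap is constant.
* Peak normalization refuses all-zero envelope sets rather than dividing
  by zero.
* SDs use denominator n−1 throughout and are NaN when only one value exists.
* Report rounding is half-away-from-zero, applied only at serialization;
  all stored tables keep full precision (`%.10g`).

## Problem sizes used in the test suite

The suite exercises the full study-scale cohort (27 × 8 × 5 at 2148 Hz,
≈5 s runtime) once for the range checks, and uses a reduced cohort
(4 subjects × 3 reps at 1074 Hz, 1.5–2.5 s trials, 20 master seeds) for the
jitter-monotonicity check, chosen so the expectation over seeds is stable
while the sweep stays tractable. Unit tests run on a 3 × 3 mini-cohort.

## Known limitations

* The composite score is a descriptive index; no inferential statistics
  (ICCs, hypothesis tests) are computed, matching the descriptive scope of
  the analysis.
* Phase-segmented (per-movement-phase) metrics are out of scope.
* The two cross-correlation conventions can differ substantially on
  envelopes with large shared baselines; comparisons across studies should
  state the convention.
* The real-data adapter expects trial CSVs matching the simulator's file
  contract; conversion from acquisition-system exports is the caller's
  responsibility.
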