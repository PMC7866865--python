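# Methods

## Pipeline

One trial = six synchronous channels (accelerometer x/y/z in g, gyroscope
x/y/z in deg/s) at a common sampling rate, labeled ADL or FALL by activity
code. The pipeline is: equalize every trial to 10 s → decimate to the target
rate → extract one 88-dimensional feature vector per record (or per fall
phase) → min-max normalize → classify → evaluate with subject-disjoint
5-fold cross-validation.

### Ingestion and unit conversion

Trial files carry integer sensor counts. Counts convert to physical units
linearly: `value = counts · (2 · full_range / 2^bits)`. The defaults
(±16 g / 13 bit accelerometer, ±2000 deg/s / 16 bit gyroscope) are the
ADXL345/ITG3200 datasheet constants; they are configuration, not
measurement, and an identity mode keeps raw counts for exactness tests.
Most features are scale-covariant and min-max normalization removes
per-column affine factors, so the choice of conversion constants does not
affect classification; it only fixes the physical scale of reported signal
values.

### Equalization and windowing

Records are cut to exactly `round(10 s × rate)` samples, removing
`floor((N−M)/2)` samples from the head and the remainder from the tail (the
odd sample goes to the tail; the convention is arbitrary but fixed). Records
shorter than 10 s raise an error rather than being padded — no conforming
activity profile produces one. The four 100-s walking/jogging activities are
recorded once and expanded into five non-overlapping windows at offsets
5, 25, 45, 65, 85 s, renumbered as trials 1–5, so every activity contributes
five records per subject. All sample intervals are 0-based half-open
`[start, stop)`.

### Decimation

Lower rates are produced by keeping every k-th sample starting at index 0
(pure sample removal, no anti-alias filter). This mirrors the decimation
procedure under study; an optional anti-aliased mode (scipy's zero-phase
decimator) exists for sensitivity analysis but is off by default. The target
rate must divide the source rate; stride composition holds
(`decimate(decimate(r, a), b) = decimate(r, b)` when both strides are
integral), and trimming commutes with decimation. First-sample anchoring is
a documented choice — at very low rates the retained samples, and hence the
features, are phase-sensitive.

### Features

Per channel (accel x/y/z, gyro x/y/z, and each sensor's Euclidean
magnitude): nine time-domain statistics and two spectral features, laid out
channel-major in a fixed, tested order. Conventions that the source
procedure leaves open, decided once:

- population variance (N divisor); std = √variance;
- percentiles by linear interpolation;
- periodogram `P_k = |FFT(s)_k|² / N` over the one-sided bins
  `k = 0..⌊N/2⌋`, DC included (there is no detrending step);
- spectral density reduced to the **mean** of `P_k` (total power differs
  only by the fixed factor `⌊N/2⌋+1` at constant N and is absorbed by
  normalization);
- spectral entropy in bits (log₂; base rescales the feature and is likewise
  absorbed), with `0·log 0 ≡ 0` and an all-zero spectrum assigned entropy 0.

Min-max normalization maps each training-fold column to [0, 1]; constant
columns map to 0; test values are not clipped. Fitting on training folds
only avoids leakage; a `normalize_scope="global"` switch replicates the
alternative reading (fit once on everything) for comparison.

### Fall phases

The impact point is the global maximum of the accelerometer magnitude
(earliest index on ties; the gyroscope is not consulted). The impact window
is `[i − round(1.5 s·rate), i + round(0.5 s·rate))` clamped to the record —
exactly 2 s whenever the impact is interior. Pre-fall and post-fall are the
remainders on each side; the three intervals always partition the record.
Phases emptied by clamping are skipped (with a warning counter) rather than
emitted as zero-length segments. ADL records are **not** phase-split: they
have no impact point by construction, so each contributes one whole-record
vector, giving `n_ADL + 3·n_fall − n_empty` vectors in the four-class task.
Segmentation is applied after decimation to 50 Hz (the rate used for the
multi-class task); the alternative order — locate the impact at 200 Hz,
slice, then decimate each segment — is expressible through the same API
(`find_impact`/`segment_phases`/`decimate`) for sensitivity analysis.

### Classifiers and evaluation

Five classifiers with parameters pinned explicitly (so results do not drift
with library versions): KNN (k = 5, Euclidean, uniform votes); SVM (RBF,
C = 1, gamma = 1/(d·Var X), one-vs-one multi-class voting with one-vs-rest
decision scores); decision tree (Gini, best split, unbounded depth); random
forest (100 trees, Gini, √d features per split); gradient boosting (100
stages, learning rate 0.1, log-loss, depth 3). No hyper-parameter tuning by
design.

Cross-validation partitions **subjects** into k = 5 folds (seeded shuffle,
round-robin deal; fold sizes differ by ≤ 1 subject), giving an 80/20
person-level split with 20 subjects. Per fold: fit scaler on train, train,
predict, confusion matrix, metrics. Reported values are per-fold means ± sd;
the report also keeps every fold's confusion matrix, so pooled metrics can
be computed by summing matrices and re-applying the metric functions. Binary
metrics use the standard confusion-matrix formulas with FALL positive;
multi-class metrics are macro scores (unweighted per-class one-vs-rest
averages), and multi-class accuracy is trace/total. AUROC is the
Mann-Whitney rank statistic (ties count ½), macro-averaged one-vs-rest for
four classes — the averaging convention is a package decision, since
"as provided by the library" underdetermines it. Zero-denominator metric
cells return 0 with a logged warning so aggregate tables have no missing
values; folds whose test split contains one class get no AUROC.

Fold assignments are computed once per experiment and reused across rates
and algorithms, so sweep comparisons are paired.

## Synthetic cohort

The generator emulates the cohort structure the pipeline assumes — not fall
biomechanics. Defaults mirror the filtered study design: 20 subjects ×
(19 ADLs + 15 fall types) × 5 trials per activity, except one trial for each
of the four long 100-s records; after window expansion this yields exactly
1900 ADL + 1500 fall = 3400 records. Signal model, with gravity on a
configurable vertical axis (default y):

- **gait** (walking/jogging/stairs): sinusoidal components at 1.5–2.8 Hz,
  amplitude ≈ 0.4 g on the vertical axis with correlated forward/lateral
  components and an oscillating angular rate;
- **transition** (sit/stand/lying activities): smooth ramps between two
  posture orientations and back, with an angular-rate burst at each ramp;
- **fall**: standing baseline with 0.1-g sway, a Gaussian transient of
  amplitude 6 g (σ = 60 ms) at an impact time drawn uniformly in [5, 10] s
  of the 15-s record (interior after trimming), a 250 deg/s angular-rate
  pulse, then a lying posture (gravity rotated to another axis);
- Gaussian sensor noise, σ = 0.05 g (accelerometer) and 2 deg/s (gyroscope).

All randomness flows from one seed; each record's substream is keyed by
(seed, subject, activity, trial), so any record is reproducible in isolation
and cohorts are byte-identical across runs.

The amplitudes were chosen once as plausible for waist-worn sensing (gait
accelerations of a few tenths of g; fall impacts of several g). They make
the classes separable in feature space **by construction**. Passing
end-to-end tests therefore demonstrates that the pipeline — ingestion,
preprocessing, features, segmentation, CV bookkeeping, metrics — is correct,
not that the classifiers would reach these scores on real falls: real
recordings add fall-like ADLs (jumps, stumbles), inter-subject variability,
sensor drift and orientation differences that the generator deliberately
omits. On the real SisFall download (supported through the same
`data_root`/manifest interface) scores will be lower.

## Problem sizes

Default test and acceptance runs use the full 20-subject design: 3400
binary records and 6400 four-class vectors at 50 Hz, with all five
classifiers on the binary task and the ensemble classifiers on the
four-class task. Unit tests use 2–5-subject cohorts.

## Known limitations

- Stride decimation aliases by design; conclusions at 1–5 Hz are
  phase-sensitive.
- No streaming/online ingestion; records are whole trials.
- The second accelerometer's columns are parsed but discarded, matching the
  single-accelerometer deployment assumption.
- No deep-learning models, feature selection, or threshold-based baselines.
- The generator's fall profile has a single dominant peak; multi-impact
  falls (bounces) would stress impact localization in ways not tested here.
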