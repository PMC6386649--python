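# Methods

`accelval` re-implements, as a tested library, the workflow used to
validate a consumer smartwatch accelerometer against a research-grade
monitor: paired-device agreement on controlled motion protocols, windowed
feature engineering from raw triaxial acceleration, activity-recognition
and energy-expenditure models under nested cross-validation, and a
window-length sensitivity study. Because the original study's raw
recordings are not public, every stage runs against a synthetic
paired-device benchmark whose generator reproduces the study's
separability structure. This note records the models, the defaults, and
the choices made where the design was genuinely open.

## Device agreement

Each axis of a recording is collapsed to one RMS value per whole second,
`sqrt(mean(x²))` over the samples of that second. Seconds are anchored to
the recording's first sample rather than wall-clock boundaries, which
makes the series deterministic without any clock synchronisation between
devices. Protocol boundary effects are removed by keeping only the
centered portion of each run (middle 2 of 3 minutes for shaker and
treadmill runs, middle 5 of 8 minutes for daily activities; sessions
shorter than the keep-window are kept whole). Agreement between two
devices is the Pearson correlation of their trimmed RMS series on the
overlapping seconds, always computed on the 1-second series — never on
raw samples — so devices with different native rates are comparable.

How the two real devices were time-synchronised is not recoverable;
alignment therefore uses plain timestamp intersection with no lag search.
An optional integer-second lag scan (`find_lag`, ±5 s, maximising mean
correlation across series pairs) exists for data that need it and is off
everywhere by default.

## The synthetic benchmark

The generator emulates three protocols at a 100 Hz reference rate:

* **Shaker** — a pure sinusoid on one axis (7 speeds, 0.5–3.5 Hz,
  repeated per axis), no gravity. The table is modelled as a
  constant-displacement shaker, so acceleration amplitude grows as
  `(2πf)²·d` — scaled to 1 g at the top speed. This matters: with equal
  amplitudes at every speed the concatenated per-axis RMS series would be
  near-constant and between-device correlation would be degenerate,
  which is incompatible with the high shaker correlations the protocol
  is designed to show.
* **Treadmill** — a quasi-periodic arm-swing surrogate whose frequency
  grows with belt speed (0.9 + 0.25·mph Hz) and amplitude roughly
  linearly (0.08·mph g), 6 speeds.
* **Daily activities** — 15 activities with the study taxonomy (body
  location, intensity, locomotion, duration, per-activity participant
  counts; 178 sessions at the default 40 participants). *Simple*
  activities emit one stationary process for the whole session; *complex*
  activities concatenate sub-action segments drawn from a per-activity
  pool of ≥ 3 parameterisations (frequency, amplitude, dominant axis,
  duration range), so a single label covers heterogeneous motion.
  Segment boundaries are not stored as labels — whole activities are the
  unit of labelling.

Every signal includes a static 1 g gravity component oriented by the
activity's posture (wrist hanging for walks, forearm raised for
upper-body work, intermediate for whole-body tasks) with a small random
tilt per session and per complex-activity segment; without a
gravitational reference the inclination-angle features would be
meaningless. Additive *truth* noise is low-passed at 3 Hz: body-movement
jitter is low-frequency, while wideband sensor noise belongs to the
device model. This distinction is load-bearing — broadband white noise at
the reference rate would dominate the L1 (modulus) spectral mass of every
window and destroy the band-power structure the features rely on.

Per-participant variation uses two lognormal scales: movement amplitude
(σ = 0.15) and tempo (σ = 0.08), applied to every session of that
participant. Walking fundamentals (1.5–2.05 Hz) are placed so that tempo
jitter keeps them inside the 0.6–2.5 Hz locomotion band; light-intensity
amplitudes (≈ 0.08–0.13 g) sit below moderate ones (≈ 0.24–0.55 g) so the
intensity classes are separable but overlap under amplitude scaling.

**Device simulation.** A device profile applies, in order: axis
misalignment (a proper rotation), gain, anti-aliased decimation to the
device rate (8th-order Butterworth low-pass at 0.45× the target rate,
zero-phase, then stride decimation), additive white sensor noise, and
symmetric range saturation. Saturation is applied last so a recording can
never exceed its stated dynamic range. Defaults: a 10 Hz, ±2 g smartwatch
with gain 0.9, (4°, −3°, 5°) strap misalignment and 0.015 g noise; a
100 Hz, ±8 g research monitor with unit gain and 0.005 g noise.

**METs.** Each session's simulated calorimetry value is drawn around a
per-activity nominal MET anchored inside its intensity band (sedentary
[1.0, 1.5], light [1.6, 2.9], moderate [3.0, 6.0]; e.g. computer work
1.3, mopping 3.5, fast RPE-5 walking 4.8), scaled by the participant's
tempo and perturbed with N(0, 0.3) measurement noise, floored just above
zero. Anchoring at a fixed per-activity value (rather than a fresh
uniform draw from the band) is what makes METs predictable from movement
features at all — a purely random band draw would cap attainable
regression quality far below what wrist features achieve on real data.

All randomness flows from the single config seed through named
`SeedSequence` substreams keyed by (seed, activity, participant, stage),
so bundles are bit-reproducible and independent of generation order.

**What the generator does not emulate.** Signals are statistical
surrogates, not biomechanics: no limb trajectories, no impact transients,
no device slippage over time, no free-living activity fragmentation or
inter-activity transitions. Passing tests show the *pipeline* recovers
structure a real deployment would rely on (band power for gait, near-zero
variance for sedentary behaviour, posture angles for body location); they
do not certify accuracy levels on real recordings.

## Windowed features

Recordings are cut into non-overlapping windows (defaults 1, 2, 4, 8, 15
and 16 s; both 15 and 16 are kept as listed, with no deduplication); the
trailing remainder is dropped, and a too-short recording yields an empty
table with a warning. Each window produces 15 features of the
vector-magnitude (VM) series and raw axes: mean and sample SD of VM,
band-power fraction in 0.6–2.5 Hz (p625), dominant frequency and its
modulus fraction, mean and SD of the inclination angle, VM variance,
skewness, kurtosis, spectral entropy, coefficient of variation, and the
three pairwise axis correlations.

Numerical choices, several of which resolve ambiguities in common
informal definitions of these features:

* **Spectrum.** One-sided DFT moduli of the mean-removed VM series with
  the DC bin excluded, after a periodic Hann taper. The taper is
  essential for modulus (L1) band fractions: an off-bin tone under a
  rectangular window leaks a logarithmically diverging share of its
  modulus mass across the whole band, making band fractions of
  rectangular-window spectra almost meaningless.
* **Covariance of VM** is read as the sample variance of the VM series —
  the covariance of a single series with itself; no second variable is
  defined, and variance stays distinct from SDVM (squared units).
* **Entropy** is spectral: Shannon entropy (bits) of the normalised VM
  modulus spectrum; a degenerate all-zero spectrum has entropy 0. This
  matches its motivation — separating activities with similar total power
  but different spectral patterns — where a value-histogram entropy would
  need an arbitrary binning.
* **Angle** is `arcsin(x / VM)` (range ±π/2), treating the device x-axis
  as vertical; zero-VM samples are excluded, and a window with fewer than
  two nonzero-VM samples raises an undefined-angle error.
* **Kurtosis** is non-excess (normal ≈ 3); skewness and kurtosis of a
  zero-variance window are defined as 0 so constant windows remain
  finite-featured. Dominant-frequency ties break to the lowest frequency;
  an all-zero spectrum reports (0, 0).
* **Correlations** involving a zero-variance axis yield 0 rather than an
  error, so sedentary windows remain featurizable.

A vectorised batch path (`featurize`) computes all windows at once and is
tested to agree exactly with the scalar reference path and with
independent direct-summation oracles to 1e-6 relative tolerance.

## Models and evaluation

Splits are over feature windows, not participants — the study's explicit
choice, since participants did not all perform all tasks. A clearly
separate by-participant grouping is *not* provided as a default anywhere;
window-level splitting inflates absolute accuracies and is reproduced
here deliberately. Five stratified outer folds hold out 20% test data
each; the 80% development data is split 80/20 into training and
validation. Folds are re-drawn up to 10 times if a class cannot be
stratified. Per fold, collinear features (|Pearson r| > 0.9 by default,
greedy removal of the feature with the highest mean absolute correlation,
ties keeping the alphabetically earlier name) and the hyper-parameter
choice are decided on development data only — candidates fit on training,
scored by validation accuracy (RMSE for regression), ties to the simpler
setting — then refit on all development data and measured once on the
untouched test fold. Each stage records a SHA-256 digest of the exact
rows it received, so leakage is an assertable property, not a convention.

Model families delegate to scikit-learn: decision tree (depth grid 3, 5,
unlimited), random forest (500 trees, √p features per split — a single
candidate, since the forest is insensitive to tuning here), RBF SVM
(C ∈ {1, 10}, scaled inputs) and a one-hidden-layer MLP (16 or 64 units,
scaled inputs). The study names these four families but specifies no
settings; the grids are documented defaults, not reconstructions.

Reported metrics: pooled micro-averaged accuracy over the five folds'
test predictions (primary; mean-of-folds is also available), per-class
balanced accuracy (mean of one-vs-rest sensitivity and specificity),
column-normalised confusion matrices (rows = predicted, columns = actual,
each non-empty column summing to 1), random-forest importance as total
mean decrease in Gini impurity (classification) or node RSS (regression)
with alphabetical tie-breaks, and for METs regression RMSE and
r² = 1 − SSE/SST on pooled test predictions.

## Experiments and problem sizes

The headline window length is 16 s. The full validation trains each
device's models separately (never pooled across devices) and summarises
per-task accuracy deltas between devices. The window sweep fits
5 folds × 6 lengths × 5 tasks of forests, some on ~53,000 one-second
windows; it therefore defaults to 100-tree forests (config-exposed),
which leaves the accuracy grid's ordering unchanged while keeping the
sweep tractable on a single CPU. Headline 16-second models always use the
500-tree default. The default benchmark (178 sessions × 2 devices,
8-minute sessions at 100 Hz reference) generates in well under a minute,
and the full acceptance pipeline — generation, extraction, five
classification tasks, agreement protocols, METs regression — completes in
a few minutes on one CPU.

## Known limitations

* Absolute accuracies on the synthetic benchmark exceed the study's
  printed values for several tasks: surrogate activities are cleaner than
  human movement, and window-level splitting lets highly similar windows
  of one session appear on both sides of a fold. Comparisons should be
  read as "the pipeline reproduces the structure and ordering", not as
  forecasts for new cohorts.
* The taxonomy ships as a data file and can be extended, but the default
  signal models are tuned only for the 15 study activities.
* No overlapping windows, wavelet/autocorrelation features, probability
  calibration, or class weighting beyond stratification.
* Proprietary device formats (.gt3x and similar) are out of scope; raw
  streams are delimited text (`timestamp,x,y,z` in seconds and g).
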