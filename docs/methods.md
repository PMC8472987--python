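# Methods

This note records the models, conventions and design choices behind
`ecgluco`, in the spirit of a statistical package's model
documentation. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic ECG generator

**Model.** A heartbeat is the sum of five Gaussian kernels, one per
wave peak: amplitude `a_w` (mV), center offset `c_w` (s, relative to
R) and width `σ_w` (s). Defaults: P(0.15, −0.17, 0.02),
Q(−0.12, −0.03, 0.008), R(1.0, 0, 0.01), S(−0.20, 0.03, 0.008),
T(0.30, 0.25, 0.04) — a simplification of the ECGSYN family of
Gaussian-event models that trades dynamical realism for exact,
analytic ground truth of every wave peak. A recording concatenates
beats at RR intervals `60/HR + N(0, jitter)` (default HR 70 bpm,
jitter sd 20 ms, RR floored at 0.3 s), then adds sinusoidal baseline
wander (0.05 mV at 0.25 Hz, random phase) and white noise (sd
0.01 mV). Per-beat morphology jitter (2 ms on non-R centers, 2 % on
amplitudes) keeps successive beats from being identical, as in real
ECG. One `numpy` Generator seeded per recording — for cohorts, from
`SeedSequence([dataset_seed, subject_index])` — makes every dataset
reproducible element-wise.

**QT rate adaptation.** Real QT intervals shorten as heart rate
rises; the rate-corrected QTc is the physiologically stable quantity.
The generator therefore shifts each beat's T-wave offset by
`0.154 (RR − 1)` — the inverse of the Framingham correction — using
the beat's own preceding RR. This is what gives the downstream QT
correction a real signal: on beats with constant template QT but
heart rates swept over 50–110 bpm, the corrected QT's coefficient of
variation falls far below the raw QT's (asserted in the test suite). It can be disabled (`rate_adaptation=False`).

**Class effect.** Hyperglycemic subjects get their Q→T timing
multiplied by `qt_scale = 1.08` and P→R timing by `pr_scale = 1.05`
on top of per-subject baselines. The *directions* (both prolong)
follow the acute-hyperglycemia literature; the magnitudes are free
generator parameters chosen to give a clearly detectable but
non-trivial effect, not physiologic estimates. Inter-subject
variability: lognormal 10 % on amplitudes, 8 % on widths, 8 ms on
center offsets, 2 % on baseline qt/pr scales, 8 bpm on resting HR.
Glucose values are drawn uniformly (70–100 mg/dL negative, 105–180
positive) so the >100 mg/dL labeling rule is exercised end to end.

**What the generator does not emulate** — and hence what passing
tests do not show about real data: motion/electrode artifacts,
ectopic beats and arrhythmias, respiratory modulation of RR and
amplitude, T-wave asymmetry (real T waves are skewed; Gaussian T
makes peak detection easier than in practice), inter-lead variation,
and any glucose effect beyond pure QT/PR timing shifts (e.g. T-wave
amplitude changes). Results on this generator bound what the code can
do under its own assumptions; they are not clinical performance
claims.

## Preprocessing

Trim 10 s from each end (electrode set-up artifacts), then a 4th-order
Butterworth band-pass, 1–40 Hz, applied forward-backward
(`sosfiltfilt`). Zero-phase filtering is chosen so group delay cannot
bias fiducial timing; the effective attenuation is the squared
single-pass magnitude. Band edges are analog-prototype corner
frequencies under the bilinear transform. The signal mean is removed
before filtering — a no-op for an ideal DC-rejecting filter that keeps
edge transients proportional to signal variation rather than to
electrode offset.

## Delineation

R detection follows the Pan–Tompkins recipe: five-point derivative
(`[1 2 0 −2 −1]/8`), squaring, 150-ms moving-window integration,
adaptive dual thresholds with running signal/noise estimates updated
with coefficient 0.125, a 200-ms refractory period, and search-back at
half threshold when an RR gap exceeds 1.66 × the running RR mean.
Thresholds are initialized from the first 2 s and derived entirely
from the data, so detection is invariant to positive rescaling.
Detections are refined to the local signal maximum within ±75 ms.

Beat windows are R-anchored and asymmetric, 200 ms before to 400 ms
after R — 600 samples at 1000 Hz. P, Q, S, T are extrema in fixed
windows relative to R: Q = min in (−80, 0) ms, S = min in (0, 80) ms,
P = max in (−200, −50) ms, T = max in (80, 380) ms. A window that is
flat (range < 1 µV) or whose extremum pins to the window edge marks
the wave missing; beats with any missing wave are dropped rather than
imputed, consistent with the conservative sample-removal stance of the
rest of the pipeline. Only peak fiducials are produced — no
onsets/offsets — because the feature set needs nothing else.

## Features

A fiducial point is `(t, a)`: time in **seconds** relative to R and
amplitude in **mV**. The 18 features are the Euclidean lengths
`√(Δt² + Δa²)` and slopes `Δa/Δt` of the nine pairs PQ, PR, PS, PT,
QR, QS, QT, RS, RT. The length deliberately mixes units — the same
arbitrariness a sample/pixel-space measurement has — and the
per-feature standardization later absorbs the scale. A consequence
worth knowing: with amplitudes of order 0.1–1 mV and time separations
of order 0.1–0.4 s, amplitude variability dominates several lengths,
so timing effects surface mainly through pairs with large time spans
(PT, QT, RT).

**QT correction.** `QTc = QT + 0.154 (1 − RR)`, `RR = 60/HR`
(Framingham; linear, well-behaved away from HR 60, unlike Bazett's
square-root form). The per-beat HR is taken from the beat's preceding
R-R interval (first beat: the following interval) — the method leaves
this unspecified; a preceding-interval convention is the natural
causal choice. The correction replaces the Q→T *time* separation
before the QT length and slope are formed; amplitudes and all other
pairs use raw times.

**Outlier removal.** Per-feature Tukey fences `Q1 − 1.5·IQR`,
`Q3 + 1.5·IQR` with linear-interpolation quartiles; a row is removed
if *any* feature is strictly outside its fences, so zero-IQR columns
flag nothing. Fences are fitted on the full beat matrix before the
train/test split by default, matching the original pipeline order;
this leaks mild distributional information across the split, so
`outlier_scope: "train"` refits on the training rows only for
leakage-free runs. At default generator settings the removal rate is
in the 12–19 % range (reported in the manifest and acceptance output).

**Standardization.** z-scores with population (n-denominator)
standard deviation, fitted on the training split by default
(`standardizer_scope: "all"` reproduces whole-matrix fitting).
Zero-variance features raise an error naming the feature.

## Classifiers

The deep model is nine dense hidden layers of 500 units and one
output unit. The training schedule is fixed: plain SGD on binary
cross-entropy, learning rate 1e-4 halved after every 20 consecutive
epochs without validation-loss improvement, early stopping after 100
such epochs with best-validation weights restored, at most 1000
epochs. Choices the schedule's description leaves open, filled with
the standard options for this architecture class: ReLU hidden
activations (He init), sigmoid output, batch size 32, a stratified
10 % validation split, one integer seed driving initialization,
shuffling and the validation split. The implementation is a NumPy
MLP (float32 weights, float64 loss accumulation, logits-space BCE for
stability) so training is bit-reproducible on one machine.

Reference families: logistic regression (C = 5), linear SVM (C = 50),
polynomial SVM (degree 6), Gaussian SVM (C = 2), all via scikit-learn
with a 10,000-iteration cap; SVM decision values are mapped through a
sigmoid for ROC scoring. The recording-level reference model uses 16
HRV/interval features and a single hidden layer of 9 tanh units
trained with the same SGD machinery.

## Evaluation conventions

AUC is trapezoidal integration over the unique-score threshold sweep
(equal to the normalized Mann–Whitney U with ties counted half; a
brute-force pair-counting oracle in the tests asserts the
equivalence). Sensitivity/specificity are reported at threshold 0.5
by default (how the original operating point was chosen is unstated);
a Youden-J threshold is available. The 80/20 split is shuffled,
stratified, row-level with train size `floor(0.8 n)`. k-fold CV is
stratified and shuffled with a fixed seed.

**Beat-level vs subject-level splits.** Row-level splitting puts
beats from one subject on both sides — the protocol being
replicated. Measured consequence (test suite): with the class effect
set to zero, a beat-level split still yields test AUCs far above 0.5
for every nonlinear model, because beats are subject-identifiable and
labels are constant within subject; this measures leakage, not
signal. `split_by_subject` keeps subjects whole, and the null-effect
test asserts every model family's grouped-split AUC falls inside a
95 % Monte-Carlo band built from subject-level label permutations.
The headline beat-level numbers should be read accordingly.

## HRV features (reference model)

RR series are successive R-time differences gated to (0.2 s, 3 s).
Time domain: SDNN (sample sd), RMSSD, pNN50, triangular index
(count / modal bin of a 1/128-s histogram) and TINN (base width of
the least-squares triangular fit to that histogram; quantized by the
fixed binning, so scale equivariance holds only coarsely). Frequency
domain: the tachogram is cubic-interpolated to 4 Hz, mean-removed,
and its periodogram integrated over VLF 0.0033–0.04 Hz, LF
0.04–0.15 Hz, HF 0.15–0.40 Hz (powers in ms²); the spectral
estimator is a package choice — the original used closed-source
software with undisclosed settings. On 40-s usable recordings the
VLF band holds less than one cycle, so a `low_confidence` flag
accompanies the band powers rather than hiding the limitation. TpTe
requires a T-end the delineator does not produce; it is proxied as a
fixed 0.08 s from the T peak and labelled approximate.

## Problem sizes and numerical choices

The package's own study sizes: 200 synthetic subjects (≈ 9000 beats)
for the classifier comparison and parameter-recovery checks, 100
subjects for the null-effect check, 120 for the recording-level
reference model, a 60-epoch cap for the headline deep-net fit and 30
epochs inside CV folds (the plateau schedule's constants are
unchanged; the cap binds first at these sizes). Quantile convention:
linear interpolation. Outlier comparisons: strict inequality.
Standardizer sd: population. Flat-window threshold in delineation:
1 µV. All tolerances asserted in tests are stated there explicitly.

## Known limitations

Delineation assumes upright R and T and inverted Q and S, as in the
generator's default morphology; inverted-lead recordings would need
sign handling. The beat-level evaluation inherits the subject-leakage
caveat above. The generator's class effect is a stylized timing shift;
absolute AUC values on synthetic cohorts characterize the pipeline,
not clinical performance. TINN is histogram-quantized. VLF on short
recordings is unreliable by construction.
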